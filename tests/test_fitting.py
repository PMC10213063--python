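import numpy as np
import pytest

from epiflat import (
    categorize_clone,
    factin_increment,
    fit_boundary_sigmoid,
    fit_clone_gaussians,
    fit_exponential,
)
from epiflat.fitting import FitError, decay_rate_ttest, gaussian1_model
from epiflat.profiles import MeanProfile


def make_mean(l, p, sem=1.0):
    l = np.asarray(l, float)
    p = np.asarray(p, float)
    sem_arr = np.full_like(p, sem) if np.isscalar(sem) else np.asarray(sem)
    return MeanProfile(l=l, P=p, sem=sem_arr, n=np.ones_like(p, dtype=int))


class TestFitExponential:
    @pytest.mark.parametrize("amplitude", [0.3, 1.0, 7.5])
    def test_noiseless_recovery_any_amplitude(self, amplitude):
        l = np.arange(0.1, 50, 0.21)
        fit = fit_exponential((l, amplitude * np.exp(-0.1 * l)))
        assert fit.converged
        assert fit.params["mu"] == pytest.approx(0.1, abs=1e-6)
        assert fit.params["A"] == pytest.approx(amplitude, rel=1e-6)

    def test_noisy_replicates_within_5_percent(self, rng):
        l = np.arange(0.1, 50, 0.21)
        clean = np.exp(-0.1 * l)
        mus = [
            fit_exponential((l, clean + rng.normal(0, 0.05, l.size))).params["mu"]
            for _ in range(100)
        ]
        assert abs(np.mean(mus) - 0.1) < 0.005

    def test_domain_restricted_to_positive_l(self):
        l = np.arange(-20, 50, 0.21)
        y = np.where(l > 0, np.exp(-0.1 * l), 1.0)  # plateau in the source
        fit = fit_exponential((l, y), domain_start=0.0)
        assert fit.domain[0] > 0
        assert fit.params["mu"] == pytest.approx(0.1, abs=1e-6)

    def test_negative_decay_flagged(self):
        l = np.arange(0.1, 30, 0.5)
        fit = fit_exponential((l, np.exp(0.05 * l)))
        assert fit.params["mu"] < 0
        assert fit.extra.get("negative_mu") is True

    def test_too_few_points_raises(self):
        with pytest.raises(FitError, match="need"):
            fit_exponential((np.arange(5.0), np.ones(5)), domain_start=0.0)


class TestFitBoundarySigmoid:
    def test_symmetric_sigmoid_centered_at_zero(self):
        l = np.arange(-30, 30, 0.21)
        y = 1.0 / (1.0 + np.exp(0.8 * l))
        fit = fit_boundary_sigmoid((l, y))
        assert fit.converged
        assert fit.params["l0"] == pytest.approx(0.0, abs=0.05)

    def test_known_boundary_recovered(self):
        l = np.arange(-30, 40, 0.21)
        y = 1.0 / (1.0 + np.exp(1.5 * (l + 3.0)))
        fit = fit_boundary_sigmoid((l, y))
        assert fit.params["l0"] == pytest.approx(-3.0, abs=0.5)

    def test_shift_moves_location_one_to_one(self):
        l = np.arange(-30, 50, 0.21)
        base = fit_boundary_sigmoid((l, 1 / (1 + np.exp(0.9 * (l - 2)))))
        moved = fit_boundary_sigmoid((l, 1 / (1 + np.exp(0.9 * (l - 10)))))
        assert moved.params["l0"] - base.params["l0"] == pytest.approx(8.0, abs=0.1)


class TestFactinIncrement:
    def test_identical_profiles_zero(self):
        l = np.arange(0, 10, 0.5)
        a = make_mean(l, np.sin(l) + 2, sem=0.1)
        l_out, inc = factin_increment(a, a)
        np.testing.assert_allclose(inc, 0.0, atol=1e-12)

    def test_three_pooled_se_units(self):
        l = np.arange(0, 10, 1.0)
        clone = make_mean(l, np.zeros_like(l), sem=3.0)
        wt = make_mean(l, np.zeros_like(l), sem=4.0)
        clone.P[4] = 15.0  # 15 / sqrt(9 + 16) = 3
        l_out, inc = factin_increment(clone, wt)
        assert inc[4] == pytest.approx(3.0, abs=1e-12)

    def test_zero_pooled_se_dropped(self):
        l = np.arange(0, 10, 1.0)
        sem = np.ones_like(l)
        sem[3] = 0.0
        clone = make_mean(l, l, sem=sem)
        wt = make_mean(l, l * 0, sem=np.zeros_like(l))
        l_out, inc = factin_increment(clone, wt)
        assert 3.0 not in l_out

    def test_type_check(self):
        with pytest.raises(TypeError):
            factin_increment(np.zeros(5), np.zeros(5))


class TestFitCloneGaussians:
    def test_single_bump(self):
        l = np.arange(-40, 40, 0.25)
        inc = 3.0 * np.exp(-((l + 10) ** 2) / 50.0)
        fit = fit_clone_gaussians(l, inc)
        assert fit.model == "gaussian1"
        assert fit.params["l0"] == pytest.approx(-10.0, abs=0.5)
        lo, hi = fit.extra["extent"]
        assert lo < -10 < hi

    def test_two_separated_bumps(self):
        l = np.arange(-40, 40, 0.25)
        inc = (
            4.0 * np.exp(-((l + 15) ** 2) / 8.0)
            + 3.0 * np.exp(-((l - 12) ** 2) / 8.0)
        )
        fit = fit_clone_gaussians(l, inc)
        assert fit.model == "gaussian2"
        centers = sorted([fit.params["l01"], fit.params["l02"]])
        assert centers[0] == pytest.approx(-15.0, abs=1.0)
        assert centers[1] == pytest.approx(12.0, abs=1.0)

    def test_both_scores_reported(self):
        l = np.arange(-20, 20, 0.25)
        fit = fit_clone_gaussians(l, 5.0 * np.exp(-(l**2) / 20.0))
        assert "r_squared_gaussian1" in fit.extra
        assert "r_squared_gaussian2" in fit.extra

    def test_flat_increment_skipped(self):
        l = np.arange(-20, 20, 0.25)
        with pytest.warns(UserWarning, match="skip"):
            result = fit_clone_gaussians(l, np.full_like(l, 0.5))
        assert result is None


class TestCategorizeClone:
    def test_posterior(self):
        assert categorize_clone((-30, -20), (-5, 5)) == "P"

    def test_posterior_anterior_contains_center(self):
        assert categorize_clone((-5, 10), (-5, 5)) == "PA"

    def test_anterior_touching(self):
        assert categorize_clone((4, 15), (-5, 5)) == "A"

    def test_anterior_abutting_within_tolerance(self):
        assert categorize_clone((6.5, 15), (-5, 5)) == "A"

    def test_far_anterior_uncategorized(self):
        assert categorize_clone((20, 30), (-5, 5)) is None

    def test_invalid_extent(self):
        with pytest.raises(ValueError):
            categorize_clone((5, 5), (-5, 5))


class TestDecayRateTTest:
    def test_identical_samples_nonsignificant(self, rng):
        a = rng.normal(0.1, 0.01, 20)
        t, p = decay_rate_ttest(a, a)
        assert p == pytest.approx(1.0)

    def test_shifted_samples_significant(self, rng):
        a = rng.normal(0.10, 0.005, 20)
        b = rng.normal(0.15, 0.005, 20)
        t, p = decay_rate_ttest(a, b)
        assert p < 1e-6


class TestDecayContourNecessity:
    """Fitting folded-tissue data against raw x-distance inflates the decay."""

    def test_apparent_decay_grows_with_fold_depth(self):
        from epiflat import contour_length

        dx, dz = 0.21, 0.45
        x = np.arange(500, dtype=float)
        apparent = []
        for depth in (0.0, 15.0, 30.0):
            a = 8 + depth * np.exp(-((x - 150) ** 2) / (2 * 20.0**2))
            l = contour_length(a, dx=dx, dz=dz).l
            signal = np.exp(-0.1 * l)  # true decay along the contour
            mu_l = fit_exponential((l, signal), domain_start=0.0).params["mu"]
            mu_x = fit_exponential((x * dx, signal), domain_start=0.0).params["mu"]
            assert mu_l == pytest.approx(0.1, abs=1e-6)
            apparent.append(mu_x)
        assert apparent[0] == pytest.approx(0.1, abs=1e-6)
        assert apparent[1] > apparent[0]
        assert apparent[2] > apparent[1]
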