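import numpy as np
import pytest

from epiflat import (
    align_profiles,
    average_profiles,
    depth_correction,
    fit_reference_sigmoid,
    normalize_profile,
    subtract_control,
)
from epiflat.fitting import FitError
from epiflat.flatten import RawProfile
from epiflat.profiles import (
    AlignmentError,
    MeanProfile,
    NormalizationError,
)


def sigmoid(l, A=1.0, mu=0.5, l0=30.0, C=0.0):
    return A / (1.0 + np.exp(mu * (l - l0))) + C


def make_mean(l, p, sem=None):
    l = np.asarray(l, float)
    p = np.asarray(p, float)
    sem = np.zeros_like(p) if sem is None else np.asarray(sem, float)
    return MeanProfile(l=l, P=p, sem=sem, n=np.ones_like(p, dtype=int))


class TestFitReferenceSigmoid:
    def test_noiseless_recovery(self):
        l = np.linspace(0, 60, 300)
        prof = RawProfile(p=sigmoid(l, A=0.8, mu=0.7, l0=30.0, C=0.05), l=l)
        fit = fit_reference_sigmoid(prof)
        assert fit.converged
        assert fit.params["l0"] == pytest.approx(30.0, abs=0.1)

    def test_step_function_limit(self):
        l = np.arange(0, 60, 0.2)
        prof = RawProfile(p=np.where(l < 24.1, 1.0, 0.0), l=l)
        fit = fit_reference_sigmoid(prof)
        assert fit.params["l0"] == pytest.approx(24.1, abs=0.2)

    def test_noisy_replicates_mean_within_one_um(self, rng):
        l = np.linspace(0, 60, 300)
        clean = sigmoid(l, A=1.0, mu=0.7, l0=30.0)
        locs = []
        for _ in range(50):
            noisy = clean + rng.normal(0, 0.05, size=l.size)
            fit = fit_reference_sigmoid(RawProfile(p=noisy, l=l))
            if fit.converged:
                locs.append(fit.params["l0"])
        assert len(locs) >= 45
        assert abs(np.mean(locs) - 30.0) < 1.0

    def test_flat_profile_raises(self):
        prof = RawProfile(p=np.full(100, 0.5), l=np.arange(100.0))
        with pytest.raises(FitError, match="dynamic range"):
            fit_reference_sigmoid(prof)


class TestAlignProfiles:
    def test_identical_profiles_average_to_single(self):
        l = np.arange(0, 20, 0.21)
        p = np.sin(l)
        profs = [RawProfile(p=p, l=l, plane_index=i) for i in range(4)]
        aligned = align_profiles(profs, [5.0] * 4)
        mean = average_profiles(aligned)
        ref = np.interp(mean.l, l - 5.0, p)
        np.testing.assert_allclose(mean.P, ref, atol=1e-9)

    def test_known_shifts_collapse(self, rng):
        base_l = np.arange(0, 40, 0.21)
        shape = np.exp(-0.1 * base_l)
        offsets = [0.0, 3.0, 7.5, 1.2]
        profs = [
            RawProfile(p=shape, l=base_l + off, plane_index=i)
            for i, off in enumerate(offsets)
        ]
        aligned = align_profiles(profs, [10.0 + off for off in offsets])
        inner = ~np.isnan(aligned.values).any(axis=0)
        spread = np.ptp(aligned.values[:, inner], axis=0)
        assert np.max(spread) < 0.21  # below grid spacing

    def test_missing_refs_dropped_and_counted(self):
        l = np.arange(0, 10, 0.5)
        profs = [RawProfile(p=l, l=l, plane_index=i) for i in range(3)]
        aligned = align_profiles(profs, [1.0, None, np.nan])
        assert aligned.n_planes == 1
        assert aligned.n_dropped == 2

    def test_all_dropped_raises(self):
        l = np.arange(10.0)
        with pytest.raises(AlignmentError):
            align_profiles([RawProfile(p=l, l=l)], [None])

    def test_shift_consistency_invariant(self):
        # shifting coordinates and references together leaves P(l') unchanged
        l = np.arange(0, 30, 0.21)
        p = np.cos(l / 3)
        profs_a = [RawProfile(p=p, l=l)]
        profs_b = [RawProfile(p=p, l=l + 11.0)]
        mean_a = average_profiles(align_profiles(profs_a, [8.0]))
        mean_b = average_profiles(align_profiles(profs_b, [19.0]))
        np.testing.assert_allclose(mean_a.P, mean_b.P, atol=1e-9)
        np.testing.assert_allclose(mean_a.l, mean_b.l, atol=1e-9)


class TestAverageProfiles:
    def test_two_constants(self):
        l = np.arange(0, 5, 0.5)
        profs = [
            RawProfile(p=np.full_like(l, 1.0), l=l),
            RawProfile(p=np.full_like(l, 3.0), l=l),
        ]
        mean = average_profiles(align_profiles(profs, [0.0, 0.0]))
        np.testing.assert_allclose(mean.P, 2.0, atol=1e-12)

    def test_copies_have_zero_sem(self):
        l = np.arange(0, 5, 0.5)
        profs = [RawProfile(p=l**2, l=l) for _ in range(5)]
        mean = average_profiles(align_profiles(profs, [0.0] * 5))
        np.testing.assert_allclose(mean.sem, 0.0, atol=1e-12)
        assert np.all(mean.n == 5)


class TestSubtractControl:
    def test_zero_control_is_identity(self):
        l = np.arange(0, 10, 0.5)
        P = make_mean(l, np.sin(l))
        out = subtract_control(P, make_mean(l, np.zeros_like(l)))
        np.testing.assert_allclose(out.P, P.P, atol=1e-12)

    def test_self_subtraction_is_zero(self):
        l = np.arange(0, 10, 0.5)
        P = make_mean(l, np.sin(l) + 2)
        out = subtract_control(P, P)
        np.testing.assert_allclose(out.P, 0.0, atol=1e-12)

    def test_linearity(self, rng):
        l = np.arange(0, 10, 0.5)
        p1, p2 = rng.random(l.size), rng.random(l.size)
        c1, c2 = rng.random(l.size), rng.random(l.size)
        a, b = 2.0, -0.7
        combined = subtract_control(
            make_mean(l, a * p1 + b * p2), make_mean(l, a * c1 + b * c2)
        )
        parts = (
            a * subtract_control(make_mean(l, p1), make_mean(l, c1)).P
            + b * subtract_control(make_mean(l, p2), make_mean(l, c2)).P
        )
        np.testing.assert_allclose(combined.P, parts, atol=1e-12)

    def test_disjoint_grids_raise(self):
        P = make_mean(np.arange(0, 5.0), np.ones(5))
        C = make_mean(np.arange(10, 15.0), np.ones(5))
        with pytest.raises(AlignmentError):
            subtract_control(P, C)

    def test_constructed_background_bump_removed(self):
        l = np.arange(-20, 20, 0.21)
        bump = 0.3 * np.exp(-(l**2) / 8.0)
        data = make_mean(l, 1.0 + bump)
        control = make_mean(l, 0.2 + bump)
        out = subtract_control(data, control)
        np.testing.assert_allclose(out.P, 0.8, atol=1e-12)


class TestDepthCorrection:
    def test_constant_depth_is_identity(self):
        l = np.arange(0, 30, 0.5)
        P = make_mean(l, np.exp(-0.1 * l))
        with pytest.warns(UserWarning, match="skipped"):
            out, slope = depth_correction(P, np.full_like(l, 3.0))
        assert slope is None
        np.testing.assert_array_equal(out.P, P.P)

    def test_linear_attenuation_recovered(self):
        l = np.arange(0, 40, 0.21)
        depth = np.linspace(0, 8, l.size)
        k = -0.02  # fractional change per um of depth
        P = make_mean(l, 1.0 * (1.0 + k * depth))
        out, slope = depth_correction(P, depth)
        assert slope == pytest.approx(k, rel=0.10)
        np.testing.assert_allclose(out.P, 1.0, atol=1e-9)

    def test_correction_reduces_decay_rate_variance(self):
        # replicates with random attenuation strength: uncorrected decay-rate
        # estimates spread with the attenuation draw, corrected ones do not.
        # The slope is fitted in a window where the true signal is constant.
        from epiflat import fit_exponential

        rng = np.random.default_rng(1)
        l = np.arange(-5, 60, 0.21)
        truth = np.where(
            l <= 0, 1.0, np.maximum(np.exp(-0.1 * np.maximum(l, 0)), 0.08)
        )
        depth = 0.15 * np.maximum(l, 0.0)
        fit_mask = (l > 0) & (l < 24)
        raw_mus, corr_mus = [], []
        for _ in range(20):
            k = rng.uniform(0.01, 0.05)
            obs = truth * (1 - k * depth) + rng.normal(0, 0.005, l.size)
            P = make_mean(l, obs)
            raw_mus.append(
                fit_exponential((l[fit_mask], obs[fit_mask])).params["mu"]
            )
            corrected, slope = depth_correction(P, depth, window_mask=l > 35)
            assert slope == pytest.approx(-k, abs=0.012)
            corr_mus.append(
                fit_exponential((l[fit_mask], corrected.P[fit_mask])).params["mu"]
            )
        assert np.var(corr_mus, ddof=1) < np.var(raw_mus, ddof=1)
        assert np.mean(corr_mus) == pytest.approx(0.1, abs=0.003)


class TestNormalizeProfile:
    def test_direct_substitution(self):
        l = np.arange(-10, 51, 1.0)
        p = np.where(l < 0, 2.0, np.where(l > 40, 0.5, 1.0))
        norm = normalize_profile(make_mean(l, p))
        # P_norm = (P - 0.5) / (2 - 0.5)
        src = norm.l < 0
        ant = norm.l > 40
        assert np.nanmean(norm.P_norm[src]) == pytest.approx(1.0, abs=1e-9)
        assert np.nanmean(norm.P_norm[ant]) == pytest.approx(0.0, abs=1e-9)
        assert norm.P_A == 0.5 and norm.source_mean == 2.0

    def test_constant_profile_degenerate(self):
        l = np.arange(-10, 51, 1.0)
        with pytest.raises(NormalizationError, match="degenerate"):
            normalize_profile(make_mean(l, np.ones_like(l)))

    def test_default_windows_are_wildtype(self):
        l = np.arange(-10, 51, 1.0)
        p = np.where(l < 0, 2.0, 0.5)
        norm = normalize_profile(make_mean(l, p))
        assert norm.anterior_threshold_um == 40.0
        assert norm.source_threshold_um == 0.0

    def test_empty_source_window_raises(self):
        l = np.arange(1, 60, 1.0)  # no l < 0 source positions
        with pytest.raises(NormalizationError, match="source"):
            normalize_profile(make_mean(l, l))

    def test_empty_anterior_window_raises(self):
        l = np.arange(-10, 10, 1.0)  # nothing beyond l = 40
        with pytest.raises(NormalizationError, match="anterior"):
            normalize_profile(make_mean(l, l))

    def test_idempotence(self):
        l = np.arange(-20, 60, 0.5)
        p = np.exp(-0.1 * np.maximum(l, 0)) + 0.3
        once = normalize_profile(make_mean(l, p))
        twice = normalize_profile(make_mean(once.l, once.P_norm))
        np.testing.assert_allclose(twice.P_norm, once.P_norm, atol=1e-9)
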