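"""Model fitting: exponential decay, sigmoid boundary, clone Gaussians.

All fits are least squares (:func:`scipy.optimize.curve_fit`) with
deterministic, data-driven initialization:

* exponential — amplitude from the first fitted point, decay rate from a
  log-linear regression on the positive values;
* sigmoid — location from the half-maximum crossing, steepness from the
  25-75% span;
* Gaussians — peaks of the increment profile.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

MIN_FIT_POINTS = 10


class FitError(RuntimeError):
    """Raised when a fit cannot even be attempted (bad domain/data)."""


@dataclass
class FitResult:
    """Parameters, goodness of fit, and provenance of one model fit."""

    model: str  # exponential | sigmoid | gaussian1 | gaussian2
    params: dict[str, float]
    r_squared: float
    domain: tuple[float, float]
    converged: bool
    extra: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        rec = {
            "model": self.model,
            "r_squared": self.r_squared,
            "domain_lo": self.domain[0],
            "domain_hi": self.domain[1],
            "converged": self.converged,
        }
        rec.update(self.params)
        return rec


def _as_xy(profile) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a profile object or (x, y) pair to finite coordinate arrays."""
    if isinstance(profile, tuple) and len(profile) == 2:
        x, y = profile
    else:
        x = getattr(profile, "l")
        for attr in ("P_norm", "P", "p"):
            y = getattr(profile, attr, None)
            if y is not None:
                break
        else:  # pragma: no cover
            raise TypeError(f"cannot extract intensities from {type(profile)}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def _r_squared(y: np.ndarray, y_fit: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def exponential_model(l, A, mu):
    return A * np.exp(-mu * l)


def sigmoid_model(l, A, mu, l0, C):
    return A / (1.0 + np.exp(np.clip(mu * (l - l0), -500, 500))) + C


def gaussian1_model(l, A, B, l0):
    return A * np.exp(-B * (l - l0) ** 2)


def gaussian2_model(l, A1, B1, l01, A2, B2, l02):
    return gaussian1_model(l, A1, B1, l01) + gaussian1_model(l, A2, B2, l02)


def fit_exponential(profile, domain_start: float = 0.0) -> FitResult:
    """Fit ``A * exp(-mu * l)`` for ``l > domain_start``; mu in um^-1.

    A negative fitted decay rate is allowed but flagged in ``extra``.
    """
    l, y = _as_xy(profile)
    mask = l > domain_start
    if mask.sum() < MIN_FIT_POINTS:
        raise FitError(
            f"only {int(mask.sum())} points beyond l={domain_start}, "
            f"need >= {MIN_FIT_POINTS}"
        )
    l, y = l[mask], y[mask]
    domain = (float(l.min()), float(l.max()))

    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(l[pos], np.log(y[pos]), 1)
        mu0, a0 = -float(slope), float(np.exp(intercept))
    else:
        mu0, a0 = 0.1, float(abs(y[0]) or 1.0)
    try:
        popt, _ = curve_fit(
            exponential_model, l, y, p0=[a0, mu0], maxfev=10000
        )
    except RuntimeError:
        return FitResult("exponential", {"A": a0, "mu": mu0}, -np.inf,
                         domain, converged=False)
    a_fit, mu_fit = (float(v) for v in popt)
    r2 = _r_squared(y, exponential_model(l, *popt))
    extra = {"negative_mu": mu_fit < 0} if mu_fit < 0 else {}
    return FitResult("exponential", {"A": a_fit, "mu": mu_fit}, r2, domain,
                     converged=True, extra=extra)


def _sigmoid_init(l: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Initial (A, mu, l0, C) from the half-maximum crossing and 25-75% span."""
    lo, hi = float(np.min(y)), float(np.max(y))
    amp = hi - lo

    def crossing(level: float) -> float:
        below = y <= level
        if below.all() or not below.any():
            return float(l[len(l) // 2])
        idx = int(np.clip(np.argmax(below), 1, len(l) - 1))
        y0, y1 = y[idx - 1], y[idx]
        if y1 == y0:
            return float(l[idx])
        t = (level - y0) / (y1 - y0)
        return float(l[idx - 1] + t * (l[idx] - l[idx - 1]))

    l0 = crossing(lo + 0.5 * amp)
    l25 = crossing(lo + 0.75 * amp)
    l75 = crossing(lo + 0.25 * amp)
    span = abs(l75 - l25)
    mu = 2.0 * np.log(3.0) / span if span > 0 else 1.0
    return amp, mu, l0, lo


def fit_sigmoid(
    profile,
    fix_amplitude: Optional[float] = None,
    with_offset: bool = True,
    model_name: str = "sigmoid",
) -> FitResult:
    """Fit a decreasing sigmoid ``A / (1 + exp(mu (l - l0))) + C``.

    ``fix_amplitude`` pins A (and drops C) for fitting normalized curves with
    the unit-amplitude boundary model.  ``l0`` is the inflection point.
    """
    l, y = _as_xy(profile)
    if len(l) < MIN_FIT_POINTS:
        raise FitError(f"need >= {MIN_FIT_POINTS} points, got {len(l)}")
    domain = (float(l.min()), float(l.max()))
    a0, mu0, l00, c0 = _sigmoid_init(l, y)

    if fix_amplitude is not None:
        def model(x, mu, l0):
            return sigmoid_model(x, fix_amplitude, mu, l0, 0.0)
        p0 = [mu0, l00]
        names = ["mu", "l0"]
    elif with_offset:
        model = sigmoid_model
        p0 = [a0, mu0, l00, c0]
        names = ["A", "mu", "l0", "C"]
    else:
        def model(x, A, mu, l0):
            return sigmoid_model(x, A, mu, l0, 0.0)
        p0 = [a0, mu0, l00]
        names = ["A", "mu", "l0"]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, l, y, p0=p0, maxfev=20000)
    except RuntimeError:
        return FitResult(model_name, dict(zip(names, p0)), -np.inf, domain,
                         converged=False)
    params = {name: float(v) for name, v in zip(names, popt)}
    if fix_amplitude is not None:
        params["A"] = float(fix_amplitude)
    r2 = _r_squared(y, model(l, *popt))
    converged = domain[0] <= params["l0"] <= domain[1]
    return FitResult(model_name, params, r2, domain, converged=converged)


def fit_boundary_sigmoid(profile) -> FitResult:
    """Locate the source/target boundary on a normalized profile.

    Fits the unit-amplitude sigmoid ``1 / (1 + exp(mu (l' - l0)))``; the
    location parameter ``l0`` (the inflection point) is the boundary.
    """
    return fit_sigmoid(profile, fix_amplitude=1.0, model_name="sigmoid")


def factin_increment(clone, wt):
    """Standardized F-actin difference of a clone region vs wild type.

    ``(A_clone - A_wt) / sqrt(sem_clone^2 + sem_wt^2)`` pointwise on the
    common grid; positions with zero pooled standard error are dropped.
    Both inputs are mean profiles (``.l``, ``.P``, ``.sem``) on a shared
    grid.  Returns ``(l, increment)`` arrays.
    """
    from .profiles import MeanProfile  # local import to avoid a cycle

    if not isinstance(clone, MeanProfile) or not isinstance(wt, MeanProfile):
        raise TypeError("factin_increment expects MeanProfile inputs")
    if len(clone.l) != len(wt.l) or not np.allclose(clone.l, wt.l):
        # resample wild type onto the clone grid over the overlap
        lo = max(clone.l.min(), wt.l.min())
        hi = min(clone.l.max(), wt.l.max())
        keep = (clone.l >= lo) & (clone.l <= hi)
        if not keep.any():
            raise FitError("clone and wild-type profiles share no grid overlap")
        l = clone.l[keep]
        c_p, c_sem = clone.P[keep], clone.sem[keep]
        w_p = np.interp(l, wt.l, wt.P)
        w_sem = np.interp(l, wt.l, wt.sem)
    else:
        l = clone.l
        c_p, c_sem, w_p, w_sem = clone.P, clone.sem, wt.P, wt.sem

    pooled = np.sqrt(c_sem**2 + w_sem**2)
    ok = pooled > 0
    return l[ok], (c_p[ok] - w_p[ok]) / pooled[ok]


def fit_clone_gaussians(
    l: np.ndarray,
    increment: np.ndarray,
    significance_floor: float = 2.0,
    selection_margin: float = 0.005,
) -> Optional[FitResult]:
    """Fit single and double Gaussians to an increment profile.

    Both models are fitted and both coefficients of determination recorded;
    the double Gaussian is selected only when it improves the coefficient of
    determination by more than ``selection_margin`` (the models are nested,
    so without a parsimony margin the larger one always scores at least as
    high).  The clone extent (stored
    in ``extra['extent']``) is the covering interval of the half-amplitude
    ranges of the fitted Gaussians.  Returns None (with a warning) when the
    increment never exceeds ``significance_floor`` or neither model
    converges.
    """
    l = np.asarray(l, dtype=float)
    y = np.asarray(increment, dtype=float)
    ok = np.isfinite(l) & np.isfinite(y)
    l, y = l[ok], y[ok]
    if len(l) < MIN_FIT_POINTS or np.max(y, initial=-np.inf) < significance_floor:
        warnings.warn("increment profile below significance floor; clone skipped")
        return None
    domain = (float(l.min()), float(l.max()))

    peaks, props = find_peaks(y, height=significance_floor)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(y))])
        props = {"peak_heights": np.array([y.max()])}
    order = np.argsort(props["peak_heights"])[::-1]
    peaks = peaks[order]

    span = max(domain[1] - domain[0], 1e-6)
    b0 = 1.0 / (0.05 * span) ** 2

    results: dict[str, Optional[tuple[np.ndarray, float]]] = {}
    p1 = [float(y[peaks[0]]), b0, float(l[peaks[0]])]
    results["gaussian1"] = _try_fit(gaussian1_model, l, y, p1)

    if peaks.size >= 2:
        second = peaks[1]
    else:
        second = int(np.clip(peaks[0] + len(l) // 4, 0, len(l) - 1))
    p2 = p1 + [float(max(y[second], 0.1)), b0, float(l[second])]
    results["gaussian2"] = _try_fit(gaussian2_model, l, y, p2)

    scores = {
        name: (res[1] if res is not None else -np.inf)
        for name, res in results.items()
    }
    if all(s == -np.inf for s in scores.values()):
        warnings.warn("neither Gaussian model converged; clone skipped")
        return None

    if scores["gaussian2"] > scores["gaussian1"] + selection_margin:
        best = "gaussian2"
    elif scores["gaussian1"] > -np.inf:
        best = "gaussian1"
    else:
        best = "gaussian2"
    popt, r2 = results[best]  # type: ignore[misc]
    if best == "gaussian1":
        params = dict(zip(["A", "B", "l0"], (float(v) for v in popt)))
        components = [(params["A"], params["B"], params["l0"])]
    else:
        params = dict(
            zip(["A1", "B1", "l01", "A2", "B2", "l02"], (float(v) for v in popt))
        )
        components = [
            (params["A1"], params["B1"], params["l01"]),
            (params["A2"], params["B2"], params["l02"]),
        ]

    halves = []
    for amp, b, center in components:
        if amp <= 0 or b <= 0:
            continue
        hw = np.sqrt(np.log(2.0) / b)
        halves.append((center - hw, center + hw))
    extent = (
        (min(h[0] for h in halves), max(h[1] for h in halves))
        if halves else None
    )
    return FitResult(
        best, params, r2, domain, converged=True,
        extra={
            "r_squared_gaussian1": scores["gaussian1"],
            "r_squared_gaussian2": scores["gaussian2"],
            "extent": extent,
        },
    )


def _try_fit(model, l, y, p0) -> Optional[tuple[np.ndarray, float]]:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, l, y, p0=p0, maxfev=20000)
    except RuntimeError:
        return None
    return popt, _r_squared(y, model(l, *popt))


@dataclass
class CloneRecord:
    """Located clone: extent in l' um, category, and its Gaussian fit."""

    extent: tuple[float, float]
    category: Optional[str]
    increment_peak: float
    gaussian_fit: FitResult

    def __post_init__(self) -> None:
        if self.extent[0] >= self.extent[1]:
            raise ValueError("clone extent must have l_start < l_end")


def categorize_clone(
    extent: tuple[float, float],
    fold_interval: tuple[float, float],
    fold_center: float = 0.0,
    touch_tolerance: float = 2.0,
) -> Optional[str]:
    """Classify a clone relative to the fold: 'P', 'PA', or 'A'.

    * PA — the extent contains the fold centre;
    * A  — the extent lies anterior of the centre and overlaps or abuts
      (gap <= ``touch_tolerance`` um) the fold interval;
    * P  — the extent lies on the posterior side;
    * None — anterior extent that never touches the fold (uncategorized).

    The posterior side is toward smaller l'; the fold centre sits at l' = 0
    by construction of the alignment.
    """
    start, end = extent
    if start >= end:
        raise ValueError("extent must have start < end")
    _, fold_end = fold_interval
    if start <= fold_center <= end:
        return "PA"
    if end < fold_center:
        return "P"
    if start <= fold_end + touch_tolerance:
        return "A"
    return None


def decay_rate_ttest(rates_a: Sequence[float], rates_b: Sequence[float]):
    """Two-sided two-sample t-test on decay-rate samples; returns (t, p)."""
    from scipy.stats import ttest_ind

    res = ttest_ind(np.asarray(rates_a, float), np.asarray(rates_b, float))
    return float(res.statistic), float(res.pvalue)
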