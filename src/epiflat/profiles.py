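"""Profile alignment, averaging, background subtraction, and normalization.

Per-plane intensity profiles p(l) are aligned by an independent reference
(reporter sigmoid location, fold centre, or a manual value) so that l' = 0
sits at the reference, resampled onto a common regular grid, averaged over
planes, optionally control-subtracted and depth-corrected, and finally
normalized so the source window averages 1 and the far-anterior baseline 0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fitting import FitError, FitResult, fit_sigmoid
from .flatten import RawProfile

DEFAULT_GRID_SPACING_UM = 0.21
#: Wild-type normalization windows: far anterior l' > 40 um, source l' < 0.
WT_ANTERIOR_THRESHOLD_UM = 40.0
WT_SOURCE_THRESHOLD_UM = 0.0
#: Clone-analysis variant: far anterior l' > 20 um, source l' < -15 um.
CLONE_ANTERIOR_THRESHOLD_UM = 20.0
CLONE_SOURCE_THRESHOLD_UM = -15.0

REFERENCE_KINDS = ("reporter-sigmoid", "fold-center", "morphogen-sigmoid",
                   "manual")


class AlignmentError(RuntimeError):
    """Raised when no plane survives alignment."""


class NormalizationError(RuntimeError):
    """Raised when the normalization denominator is degenerate."""


@dataclass
class AlignedProfileSet:
    """Per-plane profiles resampled onto one l' grid (NaN outside coverage)."""

    common_grid: np.ndarray
    values: np.ndarray  # (n_planes, n_grid)
    plane_indices: list[int]
    reference_kind: str = "manual"
    n_dropped: int = 0

    @property
    def n_planes(self) -> int:
        return self.values.shape[0]


@dataclass
class MeanProfile:
    """Plane-averaged intensity with per-position standard error and count."""

    l: np.ndarray
    P: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n = np.asarray(self.n)


@dataclass
class NormalizedProfile:
    """Profile rescaled so the source window mean is 1, the baseline 0."""

    l: np.ndarray
    P_norm: np.ndarray
    anterior_threshold_um: float
    source_threshold_um: float
    P_A: float
    source_mean: float
    sem: np.ndarray = field(default=None)  # type: ignore[assignment]


def fit_reference_sigmoid(profile, dynamic_range_floor: float = 0.05) -> FitResult:
    """Fit ``A / (1 + exp(mu (l - l0))) + C`` to a reference-reporter profile.

    The location parameter ``l0`` (the inflection point) is the per-plane
    alignment reference.  Fails (``converged=False``) when the fit does not
    converge or ``l0`` leaves the data range; raises :class:`FitError` when
    the profile has no dynamic range to fit.
    """
    l = np.asarray(profile.l, dtype=float)
    y = np.asarray(getattr(profile, "p", getattr(profile, "P", None)), dtype=float)
    rng_span = np.nanmax(y) - np.nanmin(y)
    if not np.isfinite(rng_span) or rng_span < dynamic_range_floor:
        raise FitError(
            f"profile dynamic range {rng_span:.4g} below floor "
            f"{dynamic_range_floor}"
        )
    return fit_sigmoid((l, y), with_offset=True, model_name="sigmoid")


def align_profiles(
    profiles: Sequence[RawProfile],
    refs: Sequence[Optional[float]],
    grid_spacing: float = DEFAULT_GRID_SPACING_UM,
    reference_kind: str = "manual",
) -> AlignedProfileSet:
    """Shift each profile so its reference maps to l' = 0 and resample.

    Profiles are linearly interpolated onto a shared regular l' grid;
    positions outside a plane's own coverage are NaN.  Planes with a missing
    or non-finite reference are dropped (and counted); an empty survivor set
    raises :class:`AlignmentError`.
    """
    if len(profiles) != len(refs):
        raise ValueError("profiles and refs must have equal length")
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    kept = [
        (prof, float(ref))
        for prof, ref in zip(profiles, refs)
        if ref is not None and np.isfinite(ref)
    ]
    n_dropped = len(profiles) - len(kept)
    if not kept:
        raise AlignmentError("no plane has a usable alignment reference")

    lo = min((prof.l - ref).min() for prof, ref in kept)
    hi = max((prof.l - ref).max() for prof, ref in kept)
    # grid through 0 so l' = 0 is always a grid point
    grid = np.arange(np.floor(lo / grid_spacing), np.ceil(hi / grid_spacing) + 1)
    grid = grid * grid_spacing

    values = np.full((len(kept), len(grid)), np.nan)
    for i, (prof, ref) in enumerate(kept):
        shifted = prof.l - ref
        inside = (grid >= shifted.min()) & (grid <= shifted.max())
        values[i, inside] = np.interp(grid[inside], shifted, prof.p)

    return AlignedProfileSet(
        common_grid=grid,
        values=values,
        plane_indices=[prof.plane_index for prof, _ in kept],
        reference_kind=reference_kind,
        n_dropped=n_dropped,
    )


def average_profiles(aligned: AlignedProfileSet) -> MeanProfile:
    """Arithmetic mean over planes with per-position SEM and plane count."""
    if aligned.n_planes == 0:
        raise AlignmentError("empty aligned set")
    vals = aligned.values
    n = np.sum(np.isfinite(vals), axis=0)
    keep = n >= 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals[:, keep], axis=0)
        std = np.nanstd(vals[:, keep], axis=0, ddof=1)
    std = np.where(n[keep] > 1, std, 0.0)
    sem = std / np.sqrt(n[keep])
    return MeanProfile(l=aligned.common_grid[keep], P=mean, sem=sem, n=n[keep])


def subtract_control(P: MeanProfile, control: MeanProfile) -> MeanProfile:
    """Pointwise control subtraction on the overlap of the two grids.

    The control is interpolated onto the data grid; positions outside the
    control's coverage are dropped.  Standard errors combine in quadrature.
    """
    lo = max(P.l.min(), control.l.min())
    hi = min(P.l.max(), control.l.max())
    keep = (P.l >= lo) & (P.l <= hi)
    if not keep.any():
        raise AlignmentError("data and control grids do not overlap")
    l = P.l[keep]
    ctrl_p = np.interp(l, control.l, control.P)
    ctrl_sem = np.interp(l, control.l, control.sem)
    return MeanProfile(
        l=l,
        P=P.P[keep] - ctrl_p,
        sem=np.sqrt(P.sem[keep] ** 2 + ctrl_sem**2),
        n=P.n[keep],
    )


def depth_correction(
    P: MeanProfile,
    depth: np.ndarray,
    window_mask: Optional[np.ndarray] = None,
    min_points: int = 10,
    min_depth_range_um: float = 2.0,
    divisor_floor: float = 0.05,
) -> tuple[MeanProfile, Optional[float]]:
    """Correct linear depth attenuation estimated from a reference window.

    A straight line ``I ~ a + b * depth`` is least-squares fitted over the
    window; the fractional slope ``s = b / a`` defines the multiplicative
    correction ``corrected = observed / (1 + s * depth)`` (divisor floored).
    With insufficient depth variation the profile is returned unchanged and
    the slope is None.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.shape != P.l.shape:
        raise ValueError("depth must align with the profile grid")
    mask = np.ones_like(depth, bool) if window_mask is None else (
        np.asarray(window_mask, dtype=bool)
    )
    d_win, i_win = depth[mask], P.P[mask]
    ok = np.isfinite(d_win) & np.isfinite(i_win)
    d_win, i_win = d_win[ok], i_win[ok]
    if len(d_win) < min_points or np.ptp(d_win) < min_depth_range_um:
        warnings.warn(
            "insufficient depth variation in the correction window; "
            "depth correction skipped"
        )
        return P, None
    b, a = np.polyfit(d_win, i_win, 1)
    if a == 0:
        warnings.warn("degenerate depth fit; depth correction skipped")
        return P, None
    s = float(b / a)
    divisor = np.maximum(1.0 + s * depth, divisor_floor)
    return (
        MeanProfile(l=P.l, P=P.P / divisor, sem=P.sem / divisor, n=P.n),
        s,
    )


def normalize_profile(
    P: MeanProfile,
    anterior_threshold_um: float = WT_ANTERIOR_THRESHOLD_UM,
    source_threshold_um: float = WT_SOURCE_THRESHOLD_UM,
    tolerance: float = 1e-12,
) -> NormalizedProfile:
    """Rescale so the source-window mean is 1 and the anterior baseline 0.

    ``P_norm(l') = (P(l') - P_A) / (mean_source(P) - P_A)`` with the far
    anterior defined by ``l' > anterior_threshold_um`` and the source by
    ``l' < source_threshold_um``.
    """
    anterior = P.l > anterior_threshold_um
    source = P.l < source_threshold_um
    if not anterior.any():
        raise NormalizationError(
            f"empty far-anterior window (l' > {anterior_threshold_um} um)"
        )
    if not source.any():
        raise NormalizationError(
            f"empty source window (l' < {source_threshold_um} um)"
        )
    p_a = float(np.nanmean(P.P[anterior]))
    source_mean = float(np.nanmean(P.P[source]))
    denom = source_mean - p_a
    if abs(denom) < tolerance:
        raise NormalizationError(
            f"degenerate normalization denominator |{denom:.3g}| < {tolerance}"
        )
    return NormalizedProfile(
        l=P.l,
        P_norm=(P.P - p_a) / denom,
        anterior_threshold_um=anterior_threshold_um,
        source_threshold_um=source_threshold_um,
        P_A=p_a,
        source_mean=source_mean,
        sem=P.sem / abs(denom),
    )
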