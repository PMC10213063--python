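"""Apical-surface extraction and fold detection/tracking on x-z planes.

The apical profile a(x) of each x-z plane is the mean z-index of the k
brightest pixels per column of the junctional-marker channel.  Folds are
local peaks of a(x); per plane the widest peak inside a search window
around the previous plane's fold centre is kept, and its half-prominence
crossings delimit the fold.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, peak_widths

if TYPE_CHECKING:  # pragma: no cover
    from .stack import ImageStack

DEFAULT_TOP_K = 5
DEFAULT_TRACK_WINDOW = 50.0


@dataclass
class ApicalProfile:
    """Per-column apical height of one x-z plane, in fractional z-pixels."""

    a: np.ndarray
    plane_index: int = 0
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones_like(self.a, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.a.shape:
            raise ValueError("valid_mask must match profile length")

    def __len__(self) -> int:
        return len(self.a)

    def interpolated(self) -> "ApicalProfile":
        """Fill invalid columns by linear interpolation from valid neighbours."""
        if self.valid_mask.all():
            return self
        if not self.valid_mask.any():
            raise ValueError("profile has no valid columns to interpolate from")
        x = np.arange(len(self.a))
        filled = self.a.copy()
        filled[~self.valid_mask] = np.interp(
            x[~self.valid_mask], x[self.valid_mask], self.a[self.valid_mask]
        )
        return ApicalProfile(filled, self.plane_index, np.ones_like(self.valid_mask))


@dataclass
class FoldDescriptor:
    """Start / centre / end x-locations of a fold in one x-z plane."""

    x_S: float
    x_F: float
    x_E: float
    depth: float = 0.0
    plane_index: int = 0

    def __post_init__(self) -> None:
        if not (self.x_S < self.x_F < self.x_E):
            raise ValueError(
                f"fold descriptor requires x_S < x_F < x_E, got "
                f"({self.x_S}, {self.x_F}, {self.x_E})"
            )


class TrackingError(RuntimeError):
    """Raised when fold tracking fails on too many planes."""


def extract_apical_profile(
    plane: np.ndarray,
    k: int = DEFAULT_TOP_K,
    intensity_floor: float = 0.0,
    plane_index: int = 0,
) -> ApicalProfile:
    """Extract a(x) as the mean z-index of the k brightest pixels per column.

    Parameters
    ----------
    plane
        2D x-z image of shape ``(nz, nx)`` (z is axis 0).
    k
        Number of brightest pixels averaged per column.
    intensity_floor
        Columns whose brightest pixel is below this value are flagged invalid.

    Ties among the k brightest pixels are broken toward lower z,
    deterministically.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError(f"plane must be 2D, got shape {plane.shape}")
    nz, nx = plane.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if nz < k:
        raise ValueError(f"plane has {nz} z-rows, fewer than k={k}")

    # Stable selection: sort by (-intensity, z) so equal intensities keep the
    # lower-z pixel first.
    order = np.argsort(-plane, axis=0, kind="stable")
    top_z = order[:k, :]
    a = top_z.mean(axis=0)
    valid = plane.max(axis=0) >= intensity_floor
    return ApicalProfile(a, plane_index=plane_index, valid_mask=valid)


def detect_fold(
    profile: ApicalProfile,
    prev_center: Optional[float] = None,
    window: float = DEFAULT_TRACK_WINDOW,
    min_prominence: float = 1.0,
    invert: bool = False,
) -> Optional[FoldDescriptor]:
    """Find the widest apical peak near the previous fold centre.

    Among the peaks of a(x) within ``prev_center +/- window`` (all peaks when
    ``prev_center`` is None), the one with the largest full width at half
    prominence is returned.  ``x_S`` and ``x_E`` are the half-prominence
    crossings.  ``invert`` selects folds pointing toward lower z.

    Returns None when no qualifying peak exists.
    """
    a = profile.interpolated().a
    signal = -a if invert else a
    peaks, props = find_peaks(signal, prominence=min_prominence)
    if peaks.size == 0:
        return None
    if prev_center is not None:
        in_window = np.abs(peaks - prev_center) <= window
        peaks = peaks[in_window]
        if peaks.size == 0:
            return None
        props = {key: val[in_window] for key, val in props.items()}

    widths, _, left_ips, right_ips = peak_widths(
        signal, peaks, rel_height=0.5,
        prominence_data=(props["prominences"], props["left_bases"],
                         props["right_bases"]),
    )
    best = int(np.argmax(widths))
    x_f = float(peaks[best])
    x_s = float(left_ips[best])
    x_e = float(right_ips[best])
    if not (x_s < x_f < x_e):
        return None
    return FoldDescriptor(
        x_S=x_s,
        x_F=x_f,
        x_E=x_e,
        depth=float(props["prominences"][best]),
        plane_index=profile.plane_index,
    )


def track_fold(
    stack: "ImageStack",
    seed_center: float,
    channel: str = "junctional",
    window: float = DEFAULT_TRACK_WINDOW,
    k: int = DEFAULT_TOP_K,
    min_prominence: float = 1.0,
    invert: bool = False,
    max_missing_fraction: float = 0.5,
) -> list[Optional[FoldDescriptor]]:
    """Track the fold plane by plane, seeding each search on the last hit.

    ``seed_center`` is the manually provided fold x-location for the first
    plane.  Raises :class:`TrackingError` when more than
    ``max_missing_fraction`` of the planes yield no fold.
    """
    descriptors: list[Optional[FoldDescriptor]] = []
    center = float(seed_center)
    n_missing = 0
    for y in range(stack.ny):
        profile = extract_apical_profile(stack.plane(channel, y), k=k, plane_index=y)
        desc = detect_fold(
            profile, prev_center=center, window=window,
            min_prominence=min_prominence, invert=invert,
        )
        descriptors.append(desc)
        if desc is None:
            n_missing += 1
        else:
            center = desc.x_F
    if n_missing > max_missing_fraction * stack.ny:
        raise TrackingError(
            f"fold lost in {n_missing}/{stack.ny} planes "
            f"(seed_center={seed_center})"
        )
    return descriptors


def descriptors_to_records(
    descriptors: Sequence[Optional[FoldDescriptor]],
) -> list[dict]:
    """Tabular (CSV/JSON-ready) form of a tracked fold."""
    records = []
    for y, desc in enumerate(descriptors):
        if desc is None:
            records.append({"plane_index": y, "found": False})
        else:
            records.append(
                {
                    "plane_index": desc.plane_index,
                    "found": True,
                    "x_S": desc.x_S,
                    "x_F": desc.x_F,
                    "x_E": desc.x_E,
                    "depth": desc.depth,
                }
            )
    return records
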