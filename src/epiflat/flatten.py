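"""Per-plane flattening, band cropping, and contour-length reparameterization.

Flattening shifts every column of an x-z plane along z so that the apical
edge aligns with its maximum; the shift is integer-pixel so the z-projection
(per-column sum) is conserved exactly.  The contour map accumulates the
per-step Euclidean distance along the apical profile,
``d(x) = sqrt(dx^2 + ((a(x) - a(x-1)) * dz)^2)``, turning the pixel x-axis
into an arc-length coordinate in micrometres.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .surface import ApicalProfile

DEFAULT_DX_UM = 0.21
DEFAULT_DZ_UM = 0.45


@dataclass
class FlattenedPlane:
    """An x-z plane after per-column z-shifts.

    ``image`` is padded in z so no pixels are lost: its z-extent is the input
    extent plus the largest shift.  ``shift[x] = round(max(a) - a(x)) >= 0``.
    """

    image: np.ndarray
    shift: np.ndarray
    roi_top_z: int
    dz: float = DEFAULT_DZ_UM


@dataclass
class ContourMap:
    """Cumulative contour length l(x) and per-step increments d(x), in um."""

    l: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        self.d = np.asarray(self.d, dtype=float)


@dataclass
class RawProfile:
    """Band-mean intensity per column paired with its contour coordinate."""

    p: np.ndarray
    l: np.ndarray
    plane_index: int = 0
    channel: str = ""

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.l = np.asarray(self.l, dtype=float)
        if self.p.shape != self.l.shape:
            raise ValueError("intensity and contour coordinate lengths differ")


def flatten_plane(plane: np.ndarray, profile: ApicalProfile) -> FlattenedPlane:
    """Shift each column so the apical edge aligns with max(a).

    The shift is ``round(max(a) - a(x))`` z-pixels per column, applied with
    zero padding; the output keeps every input pixel, so per-column sums are
    conserved.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError(f"plane must be 2D, got shape {plane.shape}")
    nz, nx = plane.shape
    a = profile.interpolated().a
    if len(a) != nx:
        raise ValueError(
            f"profile length {len(a)} does not match plane x-extent {nx}"
        )
    shift = np.rint(a.max() - a).astype(int)
    if (shift < 0).any():  # pragma: no cover - max() guarantees this
        raise ValueError("negative column shift")
    max_shift = int(shift.max())
    out = np.zeros((nz + max_shift, nx), dtype=plane.dtype)
    for x in range(nx):
        out[shift[x]: shift[x] + nz, x] = plane[:, x]
    return FlattenedPlane(
        image=out, shift=shift, roi_top_z=int(round(a.max()))
    )


def crop_band(
    flat: FlattenedPlane, height_um: float, dz: float = DEFAULT_DZ_UM
) -> np.ndarray:
    """Crop the fixed-depth quantification band below the flattened apex.

    The band is a rectangle of ``ceil(height_um / dz)`` rows whose top row is
    the flattened apical edge.
    """
    if height_um <= 0:
        raise ValueError("band height must be positive")
    n_rows = math.ceil(height_um / dz)
    top = flat.roi_top_z
    if top + n_rows > flat.image.shape[0]:
        raise ValueError(
            f"band of {n_rows} rows from z={top} exceeds flattened z-extent "
            f"{flat.image.shape[0]}"
        )
    return flat.image[top: top + n_rows, :]


def contour_length(
    profile: ApicalProfile | np.ndarray,
    dx: float = DEFAULT_DX_UM,
    dz: float = DEFAULT_DZ_UM,
) -> ContourMap:
    """Cumulative arc length along the apical profile, in micrometres.

    ``l(0) = 0``; each step adds the Euclidean distance between neighbouring
    surface points with anisotropic voxel scaling.  A flat profile gives
    ``l(x) = x * dx`` exactly.  The real-valued (unrounded) profile is used.
    """
    if dx <= 0 or dz <= 0:
        raise ValueError("voxel dimensions must be positive")
    a = profile.interpolated().a if isinstance(profile, ApicalProfile) else (
        np.asarray(profile, dtype=float)
    )
    da = np.diff(a) * dz
    d = np.concatenate([[0.0], np.sqrt(dx * dx + da * da)])
    if not np.any(da):  # flat profile: exact multiples of dx, no cumsum drift
        return ContourMap(l=np.arange(a.size) * dx, d=d)
    return ContourMap(l=np.cumsum(d), d=d)


def band_profile(
    band: np.ndarray,
    contour: ContourMap,
    plane_index: int = 0,
    channel: str = "",
    valid_mask: np.ndarray | None = None,
) -> RawProfile:
    """Band-mean intensity per column, expressed against contour length."""
    band = np.asarray(band)
    if band.ndim != 2:
        raise ValueError("band must be 2D")
    if band.shape[1] != len(contour.l):
        raise ValueError(
            f"band x-extent {band.shape[1]} does not match contour length "
            f"{len(contour.l)}"
        )
    p = band.mean(axis=0)
    l = contour.l
    if valid_mask is not None:
        valid_mask = np.asarray(valid_mask, dtype=bool)
        p = p[valid_mask]
        l = l[valid_mask]
    return RawProfile(p=p, l=l, plane_index=plane_index, channel=channel)
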