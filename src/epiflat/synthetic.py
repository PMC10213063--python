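"""Synthetic multi-channel stacks with known ground truth.

Every downstream stage (surface extraction, flattening, contour correction,
alignment, fitting) is tested against stacks produced here: a single-layer
apical surface (flat or with one Gaussian fold), a morphogen channel decaying
exponentially along the apical contour, a sigmoidal reference reporter,
optional elevated-F-actin clone patches, additive Gaussian noise, and
optional linear depth attenuation.  Intensities are floats in [0, 1] (before
noise); 16-bit quantization is an explicit optional step on the stack.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .flatten import contour_length
from .stack import DEFAULT_CHANNELS, ImageStack

# z-width of the junctional surface blob; at 1.0 the 5th-brightest pixel of
# a column (0.135 of peak) is indistinguishable from 5% noise, so the
# top-5 extraction rule loses columns — 1.5 keeps rank 5 at 0.41 of peak.
JUNCTIONAL_SIGMA_PX = 1.5
ATTENUATION_FLOOR = 0.1


class GeometryError(ValueError):
    """Raised when the requested surface/band does not fit the z-range."""


@dataclass(frozen=True)
class TissueSpec:
    """Geometry of a synthetic single-layer epithelium."""

    nx: int = 400
    ny: int = 16
    nz: int = 68
    dx: float = 0.21
    dy: float = 0.21
    dz: float = 0.45
    surface_base_z: float = 8.0
    surface_tilt_px_per_x: float = 0.0  # linear depth gain along x
    fold_center_x: float = 200.0
    fold_depth_px: float = 0.0
    fold_sigma_px: float = 15.0
    fold_drift_px_per_plane: float = 0.0
    roi_height_um: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("image extents must be >= 1 pixel")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel dimensions must be positive")
        if self.fold_depth_px < 0 or self.fold_sigma_px <= 0:
            raise ValueError("fold depth must be >= 0 and sigma > 0")
        if self.roi_height_um <= 0:
            raise ValueError("roi height must be positive")

    @property
    def band_rows(self) -> int:
        return math.ceil(self.roi_height_um / self.dz)

    def surface(self, plane_index: int = 0) -> np.ndarray:
        """True apical height a(x) for one x-z plane, fractional z-pixels."""
        x = np.arange(self.nx, dtype=float)
        center = self.fold_center_x + self.fold_drift_px_per_plane * plane_index
        bump = self.fold_depth_px * np.exp(
            -((x - center) ** 2) / (2.0 * self.fold_sigma_px**2)
        )
        return self.surface_base_z + self.surface_tilt_px_per_x * x + bump

    def validate_geometry(self) -> None:
        tilt_extent = self.surface_tilt_px_per_x * (self.nx - 1)
        a_max = self.surface_base_z + self.fold_depth_px + max(tilt_extent, 0.0)
        a_min = self.surface_base_z + min(tilt_extent, 0.0)
        if a_min < 0 or a_max > self.nz - 1:
            raise GeometryError(
                f"fold profile [{self.surface_base_z}, {a_max}] exceeds "
                f"z-range [0, {self.nz - 1}]"
            )
        if round(a_max) + self.band_rows > self.nz:
            raise GeometryError(
                f"quantification band ({self.band_rows} rows below z={a_max}) "
                f"exceeds z-extent {self.nz}"
            )


@dataclass(frozen=True)
class SignalSpec:
    """Signal content painted onto the tissue geometry.

    ``clone_intervals`` is a list of ``(x_start, x_end, factor)`` tuples:
    half-open pixel intervals where the F-actin band signal is multiplied by
    ``factor``.
    """

    decay_rate_mu: float = 0.1
    source_boundary_l: float = 35.0
    sigmoid_steepness: float = 2.0
    clone_intervals: tuple[tuple[int, int, float], ...] = ()
    clone_y_range: tuple[int, int] | None = None  # planes carrying the clone
    noise_sigma: float = 0.0
    depth_attenuation_slope: float = 0.0
    morphogen_amplitude: float = 0.8
    reference_amplitude: float = 0.8
    factin_base: float = 0.4
    background: float = 0.05

    def __post_init__(self) -> None:
        if self.decay_rate_mu < 0:
            raise ValueError("decay rate must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        last_end = -1
        for x0, x1, _ in sorted(self.clone_intervals):
            if x0 >= x1:
                raise ValueError(f"empty clone interval ({x0}, {x1})")
            if x0 <= last_end:
                raise ValueError("clone intervals overlap")
            last_end = x1

    def validate_against(self, tissue: TissueSpec) -> None:
        for x0, x1, _ in self.clone_intervals:
            if x0 < 0 or x1 > tissue.nx:
                raise ValueError(
                    f"clone interval ({x0}, {x1}) outside [0, {tissue.nx})"
                )


@dataclass
class GroundTruth:
    """Exact geometry and signal parameters behind a generated stack."""

    a: np.ndarray  # (ny, nx) true apical heights, fractional z-px
    l: np.ndarray  # (ny, nx) true contour length per column, um
    mu: float
    source_boundary_l: float
    fold_center_x: np.ndarray  # (ny,) per-plane fold centre
    fold_half_width_px: float  # analytic half-prominence half-width
    clone_intervals: tuple[tuple[int, int, float], ...]
    morphogen_amplitude: float
    background: float

    def clone_extents_l(self, plane_index: int = 0) -> list[tuple[float, float]]:
        """Clone x-intervals mapped to contour-length coordinates."""
        l = self.l[plane_index]
        return [
            (float(l[x0]), float(l[min(x1, len(l) - 1)]))
            for x0, x1, _ in self.clone_intervals
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mu": self.mu,
            "source_boundary_l": self.source_boundary_l,
            "fold_center_x": self.fold_center_x.tolist(),
            "fold_half_width_px": self.fold_half_width_px,
            "clone_intervals": [list(c) for c in self.clone_intervals],
            "morphogen_amplitude": self.morphogen_amplitude,
            "background": self.background,
            "a": self.a.tolist(),
            "l": self.l.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def generate_stack(
    tissue: TissueSpec, signal: SignalSpec
) -> tuple[ImageStack, GroundTruth]:
    """Render a 4-channel stack (junctional, morphogen, reference, F-actin).

    The junctional channel is a Gaussian blob of z-width 1 px centred on the
    true surface.  Morphogen, reference, and F-actin are painted uniformly
    over the quantification band (surface down to surface + roi height);
    outside the band every channel sits at the background level.  Equal seeds
    give byte-identical stacks.
    """
    tissue.validate_geometry()
    signal.validate_against(tissue)
    rng = np.random.default_rng(tissue.seed)

    nz, ny, nx = tissue.nz, tissue.ny, tissue.nx
    data = np.empty((4, nz, ny, nx), dtype=np.float64)
    a_true = np.empty((ny, nx))
    l_true = np.empty((ny, nx))
    z = np.arange(nz, dtype=float)[:, None]  # (nz, 1) broadcast over x

    clone_factor = np.ones(nx)
    for x0, x1, factor in signal.clone_intervals:
        clone_factor[x0:x1] = factor

    bg = signal.background
    for y in range(ny):
        a = tissue.surface(y)
        a_true[y] = a
        l = contour_length(a, dx=tissue.dx, dz=tissue.dz).l
        l_true[y] = l

        junctional = np.exp(
            -((z - a[None, :]) ** 2) / (2.0 * JUNCTIONAL_SIGMA_PX**2)
        )

        top = np.rint(a).astype(int)
        band = (z >= top[None, :]) & (z < (top + tissue.band_rows)[None, :])

        in_clone_planes = (
            signal.clone_y_range is None
            or signal.clone_y_range[0] <= y < signal.clone_y_range[1]
        )
        l_shift = np.maximum(l - signal.source_boundary_l, 0.0)
        morpho_col = signal.morphogen_amplitude * np.exp(
            -signal.decay_rate_mu * l_shift
        )
        ref_col = signal.reference_amplitude / (
            1.0 + np.exp(signal.sigmoid_steepness * (l - signal.source_boundary_l))
        )
        factin_col = signal.factin_base * (
            clone_factor if in_clone_planes else np.ones(nx)
        )

        data[0, :, y, :] = bg + (1.0 - bg) * junctional
        data[1, :, y, :] = bg + band * morpho_col[None, :]
        data[2, :, y, :] = bg + band * ref_col[None, :]
        data[3, :, y, :] = bg + band * factin_col[None, :]

    if signal.depth_attenuation_slope != 0.0:
        factor = np.clip(
            1.0 - signal.depth_attenuation_slope * z.ravel() * tissue.dz,
            ATTENUATION_FLOOR,
            None,
        )
        data *= factor[None, :, None, None]

    if signal.noise_sigma > 0.0:
        data += rng.normal(0.0, signal.noise_sigma, size=data.shape)

    stack = ImageStack(
        data,
        dx=tissue.dx,
        dy=tissue.dy,
        dz=tissue.dz,
        channel_names=DEFAULT_CHANNELS,
    )
    centers = tissue.fold_center_x + tissue.fold_drift_px_per_plane * np.arange(ny)
    truth = GroundTruth(
        a=a_true,
        l=l_true,
        mu=signal.decay_rate_mu,
        source_boundary_l=signal.source_boundary_l,
        fold_center_x=centers.astype(float),
        fold_half_width_px=tissue.fold_sigma_px * math.sqrt(2.0 * math.log(2.0)),
        clone_intervals=signal.clone_intervals,
        morphogen_amplitude=signal.morphogen_amplitude,
        background=signal.background,
    )
    return stack, truth


#: Reported reference decay constant for the morphogen gradient, um^-1.
REFERENCE_DECAY_RATE = 0.1

_PRESETS: dict[str, tuple[dict, dict]] = {
    # Flat wing-disc-like tissue; 15 um quantification band.
    "wing_wt": (
        dict(fold_depth_px=0.0, roi_height_um=15.0, nz=60,
             surface_base_z=10.0),
        dict(decay_rate_mu=0.1, source_boundary_l=35.0, noise_sigma=0.05),
    ),
    # Eye-disc-like tissue with a furrow-like fold anterior of the boundary.
    "eye_wt": (
        dict(fold_depth_px=22.0, fold_sigma_px=15.0, fold_center_x=200.0,
             roi_height_um=15.0, nz=68, surface_base_z=8.0),
        dict(decay_rate_mu=0.1, source_boundary_l=35.0, noise_sigma=0.05),
    ),
    # Wing disc with an induced fold; shallower 10 um band, depth attenuation.
    "wing_fold": (
        dict(fold_depth_px=18.0, fold_sigma_px=14.0, fold_center_x=200.0,
             roi_height_um=10.0, nz=64, surface_base_z=8.0),
        dict(decay_rate_mu=0.1, source_boundary_l=35.0, noise_sigma=0.05,
             depth_attenuation_slope=0.01),
    ),
    # Eye disc with the fold suppressed inside an elevated-F-actin clone.
    "eye_no_furrow_clone": (
        dict(fold_depth_px=22.0, fold_sigma_px=15.0, fold_center_x=200.0,
             roi_height_um=15.0, nz=68, surface_base_z=8.0),
        dict(decay_rate_mu=0.1, source_boundary_l=35.0, noise_sigma=0.05,
             clone_intervals=((218, 268, 2.0),), clone_y_range=(0, 8)),
    ),
    # Reference parameter-recovery preset: folded tissue, decay 0.1 um^-1.
    "hh_reference": (
        dict(fold_depth_px=22.0, fold_sigma_px=15.0, fold_center_x=200.0,
             roi_height_um=15.0, nz=68, surface_base_z=8.0),
        dict(decay_rate_mu=REFERENCE_DECAY_RATE, source_boundary_l=35.0,
             noise_sigma=0.05),
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, seed: int = 0) -> tuple[TissueSpec, SignalSpec]:
    """Return a fully populated, seedable (TissueSpec, SignalSpec) pair."""
    try:
        tissue_kwargs, signal_kwargs = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {PRESET_NAMES}"
        ) from None
    return TissueSpec(seed=seed, **tissue_kwargs), SignalSpec(**signal_kwargs)


def spec_to_dict(tissue: TissueSpec, signal: SignalSpec) -> dict:
    """JSON-ready dump of a spec pair (sidecar metadata for written stacks)."""
    return {"tissue": asdict(tissue), "signal": asdict(signal)}
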