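"""End-to-end orchestration: stack + config -> profiles, fits, clone records.

The run is deterministic given the stack and configuration.  Four experiment
kinds are supported:

* ``wildtype_gradient`` — single region, reporter-sigmoid (or fold/manual)
  alignment, normalization, exponential decay fit;
* ``fold_induction``   — same flow with a shallower band and optional depth
  correction;
* ``clone_analysis``   — a clone region and a wild-type region: F-actin
  increment, Gaussian clone localization/categorization, morphogen sigmoid
  location and decay fit;
* ``dv_comparison``    — two regions whose decay rates are reported as a
  ratio (first normalized to the second).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import (
    CloneRecord,
    FitError,
    FitResult,
    categorize_clone,
    factin_increment,
    fit_boundary_sigmoid,
    fit_clone_gaussians,
    fit_exponential,
)
from .flatten import RawProfile, band_profile, contour_length, crop_band, flatten_plane
from .profiles import (
    AlignedProfileSet,
    MeanProfile,
    NormalizedProfile,
    align_profiles,
    average_profiles,
    depth_correction,
    fit_reference_sigmoid,
    normalize_profile,
    subtract_control,
)
from .stack import ImageStack
from .surface import (
    FoldDescriptor,
    descriptors_to_records,
    extract_apical_profile,
    track_fold,
)

logger = logging.getLogger("epiflat")

EXPERIMENT_KINDS = (
    "wildtype_gradient", "clone_analysis", "fold_induction", "dv_comparison",
)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name (and plane if known)."""


@dataclass
class RunConfig:
    """All knobs of one analysis run; serializable to/from YAML or JSON."""

    channel_map: dict[str, int] = field(
        default_factory=lambda: {
            "junctional": 0, "morphogen": 1, "reference": 2, "factin": 3,
        }
    )
    dx: float = 0.21
    dy: float = 0.21
    dz: float = 0.45
    experiment_kind: str = "wildtype_gradient"
    reference_kind: str = "reporter-sigmoid"
    roi_height_um: float = 15.0
    anterior_threshold_um: float = 40.0
    source_threshold_um: float = 0.0
    posterior_toward_low_x: bool = False
    fold_seed_x: Optional[float] = None
    fold_invert: bool = False
    manual_reference_um: Optional[float] = None
    flattening: bool = True
    contour_correction: bool = True
    contour_smoothing_sigma_px: float = 0.0
    apply_depth_correction: bool = False
    depth_window_min_um: float = 0.0
    fit_domain_start_um: float = 0.0
    fit_domain_from_sigmoid: bool = False
    grid_spacing_um: float = 0.21
    crop: Optional[tuple[int, int, int, int]] = None  # x0, x1, y0, y1
    regions: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)
    top_k: int = 5
    intensity_floor: float = 0.0
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment_kind not in EXPERIMENT_KINDS:
            raise ValueError(
                f"unknown experiment kind {self.experiment_kind!r}; "
                f"choose from {EXPERIMENT_KINDS}"
            )
        if self.anterior_threshold_um <= self.source_threshold_um:
            raise ValueError(
                "normalization windows must satisfy "
                "anterior_threshold_um > source_threshold_um"
            )
        needed = {"junctional", "morphogen"}
        if self.reference_kind == "reporter-sigmoid":
            needed.add("reference")
        if self.experiment_kind == "clone_analysis":
            needed.add("factin")
        missing = needed - set(self.channel_map)
        if missing:
            raise ValueError(f"channel_map is missing channels {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "crop" in raw and raw["crop"] is not None:
            raw["crop"] = tuple(raw["crop"])
        if "regions" in raw:
            raw["regions"] = {k: tuple(v) for k, v in raw["regions"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


@dataclass
class RegionResult:
    """Single-region outputs: per-plane profiles through normalized fits."""

    raw_profiles: dict[str, list[RawProfile]]
    aligned: dict[str, AlignedProfileSet]
    mean_profiles: dict[str, MeanProfile]
    normalized: Optional[NormalizedProfile]
    exp_fit: Optional[FitResult]
    sigmoid_fit: Optional[FitResult]
    fold_descriptors: list[Optional[FoldDescriptor]]
    fold_ref_l: Optional[float]
    fold_interval_l: Optional[tuple[float, float]]
    depth_slope: Optional[float]
    n_dropped_planes: int


@dataclass
class PipelineResult:
    """Bundle returned by :func:`run_pipeline`."""

    regions: dict[str, RegionResult]
    clones: list[CloneRecord]
    decay_ratio: Optional[float]
    provenance: dict

    @property
    def main(self) -> RegionResult:
        return next(iter(self.regions.values()))


def _maybe_smooth(profile, config: RunConfig) -> np.ndarray:
    """Optionally pre-smooth a(x) before the contour-length step (off by
    default; see ``contour_smoothing_sigma_px``)."""
    a = profile.interpolated().a
    if config.contour_smoothing_sigma_px > 0:
        from scipy.ndimage import gaussian_filter1d

        return gaussian_filter1d(a, config.contour_smoothing_sigma_px)
    return a


def _channel_name(stack: ImageStack, config: RunConfig, role: str) -> str:
    idx = config.channel_map[role]
    if idx >= stack.n_channels:
        raise PipelineError(
            f"channel_map[{role!r}] = {idx} but stack has only "
            f"{stack.n_channels} channels"
        )
    return stack.channel_names[idx]


def _extract_region_profiles(
    stack: ImageStack, config: RunConfig
) -> tuple[dict[str, list[RawProfile]], list, list[Optional[FoldDescriptor]]]:
    """Surface extraction, optional flattening, band profiles per channel."""
    junctional = _channel_name(stack, config, "junctional")
    required = {"morphogen"}
    if config.reference_kind == "reporter-sigmoid":
        required.add("reference")
    if config.experiment_kind == "clone_analysis":
        required.add("factin")
    for role in sorted(required):
        _channel_name(stack, config, role)  # raises on bad mapping
    quant_roles = [
        role for role in ("morphogen", "reference", "factin")
        if role in required
        or (
            role in config.channel_map
            and config.channel_map[role] < stack.n_channels
        )
    ]

    fold_descriptors: list[Optional[FoldDescriptor]] = []
    if config.fold_seed_x is not None:
        fold_descriptors = track_fold(
            stack, config.fold_seed_x, channel=junctional,
            k=config.top_k, invert=config.fold_invert,
        )

    profiles: dict[str, list[RawProfile]] = {role: [] for role in quant_roles}
    apical_profiles = []
    for y in range(stack.ny):
        try:
            profile = extract_apical_profile(
                stack.plane(junctional, y), k=config.top_k,
                intensity_floor=config.intensity_floor, plane_index=y,
            ).interpolated()
            apical_profiles.append(profile)
            if config.contour_correction:
                contour = contour_length(
                    _maybe_smooth(profile, config), dx=config.dx, dz=config.dz
                )
            else:
                contour = contour_length(
                    np.zeros(len(profile)), dx=config.dx, dz=config.dz
                )
            for role in quant_roles:
                plane = stack.plane(_channel_name(stack, config, role), y)
                if config.flattening:
                    flat = flatten_plane(plane, profile)
                    band = crop_band(flat, config.roi_height_um, dz=config.dz)
                else:
                    top = int(round(profile.a.max()))
                    n_rows = int(np.ceil(config.roi_height_um / config.dz))
                    band = plane[top: top + n_rows, :]
                profiles[role].append(
                    band_profile(band, contour, plane_index=y, channel=role)
                )
        except (ValueError, FitError) as exc:
            raise PipelineError(f"plane {y}: {exc}") from exc
    return profiles, apical_profiles, fold_descriptors


def _fold_contour_coords(
    fold_descriptors: list[Optional[FoldDescriptor]],
    apical_profiles: list,
    config: RunConfig,
) -> list[Optional[tuple[float, float, float]]]:
    """Per-plane (l(x_S), l(x_F), l(x_E)) of the fold (None when lost)."""
    coords: list[Optional[tuple[float, float, float]]] = []
    for desc, profile in zip(fold_descriptors, apical_profiles):
        if desc is None:
            coords.append(None)
            continue
        if config.contour_correction:
            contour = contour_length(
                _maybe_smooth(profile, config), dx=config.dx, dz=config.dz
            )
        else:
            contour = contour_length(
                np.zeros(len(profile)), dx=config.dx, dz=config.dz
            )
        x_axis = np.arange(len(profile))
        coords.append(
            tuple(
                float(np.interp(x, x_axis, contour.l))
                for x in (desc.x_S, desc.x_F, desc.x_E)
            )
        )
    return coords


def _fold_reference_l(
    fold_descriptors: list[Optional[FoldDescriptor]],
    apical_profiles: list,
    config: RunConfig,
) -> list[Optional[float]]:
    """Per-plane contour coordinate of the fold centre (None when lost)."""
    return [
        c[1] if c is not None else None
        for c in _fold_contour_coords(fold_descriptors, apical_profiles, config)
    ]


def _plane_references(
    profiles: dict[str, list[RawProfile]],
    fold_descriptors: list[Optional[FoldDescriptor]],
    apical_profiles: list,
    config: RunConfig,
) -> list[Optional[float]]:
    kind = config.reference_kind
    if kind == "manual":
        if config.manual_reference_um is None:
            raise PipelineError(
                "reference_kind 'manual' requires manual_reference_um"
            )
        n = len(next(iter(profiles.values())))
        return [config.manual_reference_um] * n
    if kind == "fold-center":
        if not fold_descriptors:
            raise PipelineError(
                "reference_kind 'fold-center' requires fold tracking "
                "(set fold_seed_x)"
            )
        return _fold_reference_l(fold_descriptors, apical_profiles, config)
    role = {"reporter-sigmoid": "reference", "morphogen-sigmoid": "morphogen"}.get(kind)
    if role is None:
        raise PipelineError(f"unknown reference kind {kind!r}")
    refs: list[Optional[float]] = []
    for prof in profiles[role]:
        try:
            fit = fit_reference_sigmoid(prof)
        except FitError:
            refs.append(None)
            continue
        refs.append(fit.params["l0"] if fit.converged else None)
    return refs


def analyze_region(
    stack: ImageStack,
    config: RunConfig,
    control: Optional[MeanProfile] = None,
) -> RegionResult:
    """Run the single-region flow: extract, flatten, align, average, fit."""
    t0 = time.perf_counter()
    profiles, apical_profiles, fold_descriptors = _extract_region_profiles(
        stack, config
    )
    refs = _plane_references(profiles, fold_descriptors, apical_profiles, config)

    aligned: dict[str, AlignedProfileSet] = {}
    means: dict[str, MeanProfile] = {}
    for role, prof_list in profiles.items():
        aligned[role] = align_profiles(
            prof_list, refs, grid_spacing=config.grid_spacing_um,
            reference_kind=config.reference_kind,
        )
        means[role] = average_profiles(aligned[role])

    fold_ref_l = None
    fold_interval_l = None
    if fold_descriptors:
        coords = [
            c for c in _fold_contour_coords(
                fold_descriptors, apical_profiles, config)
            if c is not None
        ]
        if coords:
            fold_ref_l = float(np.mean([c[1] for c in coords]))
            fold_interval_l = (
                float(np.mean([c[0] - c[1] for c in coords])),
                float(np.mean([c[2] - c[1] for c in coords])),
            )

    morpho = means["morphogen"]
    if control is not None:
        morpho = subtract_control(morpho, control)

    depth_slope = None
    if config.apply_depth_correction:
        shift_profiles = [
            RawProfile(
                p=(prof.a - prof.a.min()) * config.dz,
                l=profiles["morphogen"][i].l,
                plane_index=prof.plane_index,
            )
            for i, prof in enumerate(apical_profiles)
        ]
        depth_aligned = align_profiles(
            shift_profiles, refs, grid_spacing=config.grid_spacing_um
        )
        depth_mean = average_profiles(depth_aligned)
        depth = np.interp(morpho.l, depth_mean.l, depth_mean.P)
        morpho, depth_slope = depth_correction(
            morpho, depth, window_mask=morpho.l > config.depth_window_min_um
        )

    normalized = normalize_profile(
        morpho,
        anterior_threshold_um=config.anterior_threshold_um,
        source_threshold_um=config.source_threshold_um,
    )

    sigmoid_fit: Optional[FitResult] = None
    try:
        sigmoid_fit = fit_boundary_sigmoid(normalized)
    except FitError:
        logger.warning("boundary sigmoid fit failed")

    domain_start = config.fit_domain_start_um
    if (
        config.fit_domain_from_sigmoid
        and sigmoid_fit is not None
        and sigmoid_fit.converged
    ):
        domain_start = sigmoid_fit.params["l0"]
    exp_fit: Optional[FitResult] = None
    try:
        exp_fit = fit_exponential(normalized, domain_start=domain_start)
    except FitError as exc:
        logger.warning("exponential fit skipped: %s", exc)

    logger.info(
        "region analyzed: %d planes (%d dropped), %.2f s",
        stack.ny, aligned["morphogen"].n_dropped, time.perf_counter() - t0,
    )
    return RegionResult(
        raw_profiles=profiles,
        aligned=aligned,
        mean_profiles=means,
        normalized=normalized,
        exp_fit=exp_fit,
        sigmoid_fit=sigmoid_fit,
        fold_descriptors=fold_descriptors,
        fold_ref_l=fold_ref_l,
        fold_interval_l=fold_interval_l,
        depth_slope=depth_slope,
        n_dropped_planes=aligned["morphogen"].n_dropped,
    )


def _crop_config(config: RunConfig, rect: tuple[int, int, int, int]) -> RunConfig:
    """Shift x-referenced config values into a cropped region's frame."""
    seed_x = config.fold_seed_x
    if seed_x is not None:
        seed_x = seed_x - rect[0]
    return dataclasses.replace(config, crop=None, fold_seed_x=seed_x)


def _clone_flow(
    stack: ImageStack, config: RunConfig
) -> tuple[dict[str, RegionResult], list[CloneRecord]]:
    if set(config.regions) < {"clone", "wildtype"}:
        raise PipelineError(
            "clone_analysis requires regions 'clone' and 'wildtype'"
        )
    wt_cfg = dataclasses.replace(
        _crop_config(config, config.regions["wildtype"]),
        reference_kind="fold-center",
    )
    wt_region = analyze_region(stack.crop(*config.regions["wildtype"]), wt_cfg)
    if wt_region.fold_ref_l is None:
        raise PipelineError("wild-type region: fold location unavailable")

    # clone region: fold may be suppressed, so reuse the wild-type fold
    # location (the regions share the x-frame) as a manual reference
    clone_cfg = dataclasses.replace(
        _crop_config(config, config.regions["clone"]),
        reference_kind="manual",
        manual_reference_um=wt_region.fold_ref_l, fold_seed_x=None,
    )
    clone_region = analyze_region(stack.crop(*config.regions["clone"]), clone_cfg)

    l_inc, increment = factin_increment(
        clone_region.mean_profiles["factin"], wt_region.mean_profiles["factin"]
    )

    clones: list[CloneRecord] = []
    gauss = fit_clone_gaussians(l_inc, increment)
    if gauss is not None and gauss.extra.get("extent") is not None:
        fold_interval = wt_region.fold_interval_l or (-1.0, 1.0)
        extent = gauss.extra["extent"]
        clones.append(
            CloneRecord(
                extent=extent,
                category=categorize_clone(extent, fold_interval),
                increment_peak=float(np.max(increment)),
                gaussian_fit=gauss,
            )
        )
    return {"wildtype": wt_region, "clone": clone_region}, clones




def run_pipeline(
    stack: ImageStack,
    config: RunConfig,
    control: Optional[MeanProfile] = None,
) -> PipelineResult:
    """Run the configured experiment on one stack.

    ``control`` is an optional negative-control mean profile (aligned to the
    same reference frame) subtracted before normalization.
    """
    if config.crop is not None and config.experiment_kind != "clone_analysis":
        stack = stack.crop(*config.crop)

    regions: dict[str, RegionResult] = {}
    clones: list[CloneRecord] = []
    decay_ratio: Optional[float] = None

    if config.experiment_kind in ("wildtype_gradient", "fold_induction"):
        regions["main"] = analyze_region(stack, config, control=control)
    elif config.experiment_kind == "clone_analysis":
        regions, clones = _clone_flow(stack, config)
    elif config.experiment_kind == "dv_comparison":
        if len(config.regions) != 2:
            raise PipelineError("dv_comparison requires exactly two regions")
        names = list(config.regions)
        for name in names:
            sub_cfg = _crop_config(config, config.regions[name])
            regions[name] = analyze_region(
                stack.crop(*config.regions[name]), sub_cfg, control=control
            )
        fits = [regions[name].exp_fit for name in names]
        if all(f is not None and f.converged for f in fits):
            decay_ratio = fits[0].params["mu"] / fits[1].params["mu"]

    provenance = {
        "epiflat_version": __version__,
        "config": dataclasses.asdict(config),
        "n_planes": stack.ny,
        "dropped_planes": {
            name: region.n_dropped_planes for name, region in regions.items()
        },
        "reference_kind": config.reference_kind,
        "normalization_windows": {
            "anterior_um": config.anterior_threshold_um,
            "source_um": config.source_threshold_um,
        },
    }
    return PipelineResult(
        regions=regions, clones=clones, decay_ratio=decay_ratio,
        provenance=provenance,
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write profiles as CSV and fits/clones/provenance as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for region_name, region in result.regions.items():
        for role, prof_list in region.raw_profiles.items():
            for prof in prof_list:
                for x, (l_um, value) in enumerate(zip(prof.l, prof.p)):
                    rows.append(
                        {
                            "region": region_name, "channel": role,
                            "plane_index": prof.plane_index, "x": x,
                            "l_um": l_um, "intensity": value,
                        }
                    )
    pd.DataFrame(rows).to_csv(outdir / "profiles.csv", index=False)

    mean_rows = []
    for region_name, region in result.regions.items():
        norm = region.normalized
        for role, mp in region.mean_profiles.items():
            for l_um, value, sem, n in zip(mp.l, mp.P, mp.sem, mp.n):
                mean_rows.append(
                    {
                        "region": region_name, "channel": role,
                        "l_prime_um": l_um, "mean_intensity": value,
                        "sem": sem, "n_planes": int(n),
                    }
                )
        if norm is not None:
            for l_um, value in zip(norm.l, norm.P_norm):
                mean_rows.append(
                    {
                        "region": region_name, "channel": "morphogen_norm",
                        "l_prime_um": l_um, "mean_intensity": value,
                        "sem": np.nan, "n_planes": 0,
                    }
                )
    pd.DataFrame(mean_rows).to_csv(outdir / "mean_profiles.csv", index=False)

    fits = {}
    for region_name, region in result.regions.items():
        fits[region_name] = {
            "exponential": region.exp_fit.to_record() if region.exp_fit else None,
            "sigmoid": (
                region.sigmoid_fit.to_record() if region.sigmoid_fit else None
            ),
            "depth_slope": region.depth_slope,
            "fold": descriptors_to_records(region.fold_descriptors),
        }
    if result.decay_ratio is not None:
        fits["decay_ratio"] = result.decay_ratio
    fits["clones"] = [
        {
            "extent": list(clone.extent),
            "category": clone.category,
            "increment_peak": clone.increment_peak,
            "model": clone.gaussian_fit.model,
            "r_squared_gaussian1": clone.gaussian_fit.extra.get(
                "r_squared_gaussian1"
            ),
            "r_squared_gaussian2": clone.gaussian_fit.extra.get(
                "r_squared_gaussian2"
            ),
        }
        for clone in result.clones
    ]
    (outdir / "fits.json").write_text(json.dumps(fits, indent=2))
    (outdir / "provenance.json").write_text(
        json.dumps(result.provenance, indent=2, default=str)
    )
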