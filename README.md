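# epiflat

Quantification of protein gradients (e.g. morphogen distributions) in curved
epithelial monolayers from multi-channel 3D confocal stacks.

Standard quantification of immunostained tissue picks an arbitrary image
plane or z-projects the stack; both distort measurements when the epithelium
is curved or folded. `epiflat` instead:

1. extracts the **apical profile** a(x) of every x–z plane from a junctional
   marker channel (mean z-index of the 5 brightest pixels per column),
2. detects and tracks **folds** (widest peak of a(x) within ±50 px of the
   previous plane's fold),
3. **flattens** each plane by integer per-column z-shifts (the z-projection
   is conserved exactly) and crops a fixed-depth quantification band below
   the apical edge,
4. reparameterizes the x-axis by the **apical contour length**
   d(x) = √(Δx² + ((a(x) − a(x−1))·Δz)²) so folded tissue is measured along
   the epithelium,
5. **aligns** per-plane intensity profiles to an independent reference
   (reporter sigmoid location, fold centre, or a manual position), averages
   over y, optionally subtracts a control profile and corrects linear depth
   attenuation, and **normalizes** so the source window averages 1 and the
   far-anterior baseline 0,
6. **fits** exponential decay rates, sigmoid boundary locations, and
   single/double Gaussian clone positions with P/PA/A categorization.

A first-class synthetic-data module generates 4-channel stacks (junctional,
morphogen, reference reporter, F-actin) with exact ground truth — flat or
folded surfaces, exponential contour-decay, sigmoidal reporter, clone
patches, noise, and depth attenuation — so the whole pipeline is testable
without real data.

## CLI

```sh
# generate a synthetic stack (presets: wing_wt, eye_wt, wing_fold,
# eye_no_furrow_clone, hh_reference)
epiflat simulate stack.ome.tif --preset eye_wt --seed 1

# run the full pipeline; writes profiles.csv, mean_profiles.csv, fits.json,
# provenance.json
epiflat analyze stack.ome.tif --config run.yaml --out results/

# fit a model to a profile CSV
epiflat fit profile.csv --model exponential --domain-start 0
```

`analyze` is configured by a YAML file mirroring `epiflat.RunConfig`
(channel map, voxel size, experiment kind, ROI band height, normalization
windows, reference kind, crop regions, ...). Experiment kinds:
`wildtype_gradient`, `fold_induction`, `clone_analysis` (clone + wild-type
regions, F-actin increment, Gaussian clone localization), and
`dv_comparison` (two regions, decay-rate ratio).

## Library

```python
from epiflat import RunConfig, generate_stack, preset, run_pipeline

stack, truth = generate_stack(*preset("hh_reference", seed=1))
result = run_pipeline(stack, RunConfig())
print(result.main.exp_fit.params["mu"])  # decay rate, um^-1
```

## Layout

- `src/epiflat/synthetic.py` — seeded stack generator + presets
- `src/epiflat/surface.py` — apical-profile extraction, fold detection/tracking
- `src/epiflat/flatten.py` — flattening, band crop, contour length, band profiles
- `src/epiflat/profiles.py` — alignment, averaging, control subtraction,
  depth correction, normalization
- `src/epiflat/fitting.py` — exponential/sigmoid/Gaussian fits, clone records
- `src/epiflat/io.py`, `pipeline.py`, `cli.py` — TIFF I/O, orchestration, CLI
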