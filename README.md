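# vesselleak

Single-vessel blood–brain-barrier (BBB) leakage quantification for 4D
two-photon time-lapse imaging, validated end to end on synthetic vascular
phantoms.

The pipeline takes a (t, z, y, x) fluorescence stack plus a structural
vessel channel and produces vessel-type-resolved leakage readouts:

- **phantom** — seeded generators for voxelized vessel networks
  (penetrating arteriole/venule trees + capillaries), two-compartment
  extravasation time-lapses, RBC line scans, and multi-channel histology
  images, each with a full ground-truth ledger.
- **preprocess** — FWHM-parameterized 3D Gaussian smoothing, rolling-ball
  background subtraction and smoothed-MIP flat-field normalization
  (structure-only; leakage frames are refused without an explicit
  override), and affine 3D registration by NCC.
- **vasculature** — pluggable segmentation (Otsu / Sauvola / fixed /
  external mask), 26-connectivity skeleton graph, physical-unit EDT
  diameters, hierarchical 0th/1st/2nd-order classification from seeded
  arteriole/venule roots (<6 µm unordered segments are capillaries), and
  5–15 µm perivascular shells with nearest-vessel ownership.
- **traces** — per-vessel perivascular/intravascular traces and the
  conventional indices: AUC of the baseline-normalized trace, late-window
  (50–60 min) fold change ΔF/F0, and averaged differential ΔF/Δt.
- **embedding** — UMAP projection of normalized extravasation patterns
  (Euclidean, n_neighbors=5, min_dist=0.4), the UMAP-distance index
  (mean distance to control-group vessels, class-stratified,
  self-excluding), grid tuning by Spearman correlation with the
  conventional indices, k-means cluster composition tables, and
  rank-based ROC-AUC / Mann–Whitney diagnostics (per-animal by default).
- **hemodynamics** — Radon-transform line-scan velocimetry (Sobel +
  variance-of-projection angle detection with parabolic refinement),
  Patlak linear regression for Ktrans, plasma flow from vessel geometry
  and RBC velocity (hematocrit 0.45), and Renkin–Crone inversion to a
  flow-normalized PS.
- **histology2d** — local-threshold binarization, 15 µm disk perivascular
  rings, α-SMA-based arterial/venous vessel partition, TRITC⁺ area-ratio
  extravasation, and ZO-1 mean intensity inside CD31 ROIs normalized to
  the control group.
- **pipeline / cli** — end-to-end orchestration with YAML config,
  per-run manifest (versions, seeds, content hashes), and the
  `vesselleak` command-line interface.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (analytic
identities, brute-force oracles, generator-ground-truth recoveries, and
the end-to-end disease-pattern discrimination on simulated 4/4/3-animal
cohorts). The full suite runs in a few minutes on one CPU.

## CLI

```sh
vesselleak simulate --out sim/ --seed 3 --shape 16,72,72 --condition SE
vesselleak preprocess --in sim/timelapse.ome.tif --out smoothed.ome.tif --smooth-fwhm 1.0
vesselleak segment --in structure.ome.tif --out seg/
vesselleak indices --timelapse sim/timelapse.ome.tif --labels sim/lumen_labels.ome.tif --out idx/
vesselleak embed --indices idx/indices.csv --traces idx/traces.csv --out emb/ --n-neighbors 5 --min-dist 0.4 --seed 42
vesselleak velocity --in linescan.tif --out velocity.csv
vesselleak permeability --traces idx/traces.csv --segments segments.csv --out perm.csv
vesselleak histology --in histo.tif --out histo.csv
vesselleak run --config cfg.yaml          # full phantom-to-diagnostics run
```

Exit codes: 0 ok, 1 user error, 2 internal error. `vesselleak run`
writes indices/embedding/diagnostics/permeability CSV+JSON artifacts and
a manifest with content hashes into the configured run directory.

## Conventions worth knowing

- Axis order is (t, z, y, x), 0-based; voxel sizes are physical µm and
  all EDT/dilation radii are isotropic in µm (anisotropy-aware).
- ΔF/F0 is the fold ratio mean(F)/F0 with F0 the mean of the first 5
  frames; a constant trace gives ΔF/F0 = 1, ΔF/Δt = 0, AUC = duration.
- Line-scan images are (lines, space); streak angle is measured from the
  time axis, so v = (dx/dt)·tan θ and stationary shadows give θ = 0.
- Patlak fits start at t ≥ 5 min; plasma flow is normalized by the
  perivascular ROI volume to share min⁻¹ units with Ktrans before the
  Renkin–Crone inversion. Ktrans ≥ F_p (flow-limited) is flagged, not
  clipped.
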