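# gliaquant

Quantitative analysis pipelines for microglia phenotype studies, with
ground-truth synthetic data generators so every stage is testable offline:

- **`gliaquant.synth`** — generators for time-lapse movies of motile,
  shape-shifting cells, voltage-step sweep sets with planted conductances,
  miniature-EPSC traces with Poisson biexponential events, uptake/washout
  degradation time courses, and cytokine/expression assay matrices. All
  generators are deterministic in `spec + seed` and return complete ground
  truth alongside the data.
- **`gliaquant.motility`** — segmentation (Gaussian smoothing + Otsu +
  hole-filling + min-area), greedy nearest-centroid tracking, and the three
  motility statistics: cell speed (µm/min), membrane change |ΔA|/p (µm per
  frame pair), and morphing speed (roundish ↔ polarized transitions/hour,
  classified by skeleton-ramification counting — polarized means ≥ 2
  ramifications).
- **`gliaquant.ephys`** — step-protocol I/V curves measured over the last
  two-thirds of each step, difference currents, reversal-potential
  estimation by sign-change interpolation, mEPSC detection with
  amplitude AND area thresholds at k× the noise SD (k in 3–4), and series
  resistance QC (discard at > 25% drift).
- **`gliaquant.kinetics`** — per-interval degradation/release deltas from
  internal (densitometry) and supernatant (ELISA) levels, with an optional
  calibration factor for mass-balance accounting, and per-replicate
  condition comparisons.
- **`gliaquant.omics`** — below-background flag filtering, 75th-percentile
  normalization, fold-change + moderated-t differential selection
  (p < .05, |log2FC| > 1), covariance/correlation PCA with
  proportion-of-variance reporting, and unpaired/paired t, one-way ANOVA +
  Bonferroni and Kolmogorov–Smirnov group comparisons.

## CLI

Everything is reachable through one entry point:

```bash
# generate synthetic inputs
gliaquant simulate movie   --config movie.yaml   --seed 1 --out sim/
gliaquant simulate sweeps  --config sweeps.yaml  --seed 1 --out sim/
gliaquant simulate mepsc   --config mepsc.yaml   --seed 1 --out sim/
gliaquant simulate kinetics --config kin.yaml    --seed 1 --out sim/
gliaquant simulate assay   --config assay.yaml   --seed 1 --out sim/

# analyze
gliaquant motility run --movie sim/movie.tif --out results/ [--resample-to-1min]
gliaquant ephys iv     --before before/sweeps.h5 --after after/sweeps.h5 --out results/
gliaquant ephys mepsc  --trace sim/trace.h5 --k 3.5 --out results/
gliaquant ephys qc     --rs 10,11,12
gliaquant kinetics deltas --table sim/timecourse.csv --calibration 1.0 --out results/
gliaquant omics degs   --matrix assay.tsv --flags assay.flags.tsv \
                       --samples assay.samples.csv --groups treated,control --out results/
gliaquant omics pca    --matrix assay.tsv --samples assay.samples.csv --out results/
gliaquant stats compare --table groups.csv --design anova_bonferroni
```

Config YAML keys mirror the spec dataclasses in `gliaquant.synth`
(`MovieSpec`, `SweepSpec`, `MepscSpec`, `KineticsSpec`, `AssaySpec`).

File conventions: movies are multi-page float32 TIFFs with a JSON sidecar
carrying `pixel_size_um` / `frame_interval_s`; traces and sweep sets are
HDF5 (or two-column CSV); assay matrices are TSV with a parallel 0/1 flag
TSV (1 = well above background) and a sample-annotation CSV.

## Validation report

The raw data behind the original measurements are not publicly deposited,
so validation is property-based: every benchmark generates synthetic inputs
with planted ground truth, runs the pipeline, and measures recovery
(oracle equivalence of the motility metrics, membrane-dynamics/speed
dissociation, reversal-potential recovery, detector operating curve,
kinetics mass balance, DEG type-I calibration, normalization/PCA
identities, Rs QC rule). Reproduce the full report with:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The same quantities are asserted at their tolerances in
`tests/test_acceptance.py`.
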