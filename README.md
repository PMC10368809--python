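# mifspatial

Spatial phenotyping of two-panel multiplex-immunofluorescence (mIF)
tumour sections, for computational pathology and tumour-immunology
groups who want a tested, scriptable version of the classic
inForm/StarDist-style workflow: detect nuclei, call per-cell marker
levels, map cells to tumour-nest (TN) vs stroma (TS) compartments,
measure who-sits-next-to-whom, and relate all of it to survival.

Because patient-level mIF cohorts are rarely shareable, the package also
ships a first-class synthetic generator — scenes, cohorts, expression
tables — with the statistical structure the downstream analysis assumes,
so every stage is testable end to end without any external data.

## What it computes

- **Segmentation evaluation** — predicted vs ground-truth nuclei matched
  one-to-one at IoU > 0.6 (strict), reported as precision, recall,
  F1 = 2PR/(P+R) and binary pixel accuracy.
- **Per-cell marker calls** — fluorescent fields intersected with
  (dilated) nuclei; mean intensity binned at per-marker thresholds
  Z/2Z/3Z into negative/low/median/high fluorescence strength (FS);
  H-score = %low·1 + %med·2 + %high·3 ∈ [0, 300]; ordered-rule phenotype
  calling (Treg, CD4 T, activated T, B, neutrophil; CD8 T, macrophage,
  M2 macrophage, CSC, plus a PD-L1 flag).
- **Spatial features** — Delaunay triangulation of cell centroids per
  section/panel; the 30 within-panel pair features (2 panels ×
  (C(5,2) + 5)) as mean edge length in µm, averaged across a patient's
  sections.
- **Composition features** — 11 phenotypes × {TN, TS} × {%, cells/mm²,
  H-score} = 66 content features, assembled with the spatial features and
  clinical covariates into one row per patient.
- **Survival statistics** — covariate-adjusted Cox PH (Efron ties),
  Kaplan–Meier/log-rank, maximal-χ² optimal cutpoints with an optional
  permutation correction, inverse-variance fixed-effects pooling of
  stratum hazard ratios, descriptive cohort summaries.
- **Six-gene risk score** — NDEGS = 0.706·CTSZ + 1.225·PLAUR +
  1.268·NME2 + 1.339·NPM1 + 1.349·EIF3E + 1.555·PPIA with frozen
  coefficients; 7:3 train/validation evaluation (cutoff learned on
  training only), IPCW time-dependent AUC at 1/3/5 years; TMB
  classification at the 20 mut/Mb boundary.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
from mifspatial.synth import SceneSpec, generate_scene
from mifspatial.quantify import QuantifyConfig, quantify_scene
from mifspatial.spatial import spatial_feature_table

spec = SceneSpec(n_cells=500, seed=7, blur_sd=0.0, noise_sd=0.0)
channels, truth = generate_scene(spec)          # two 6-page stacks + truth
cells = quantify_scene(
    channels,
    {p: truth.panels[p].nucleus_labels for p in channels},
    truth.compartment_mask, spec.pixel_size_um,
    QuantifyConfig(background_quantile=0.8, thresholds=truth.z_thresholds),
)
cells["patient_id"] = "P0001"
feats = spatial_feature_table(cells)            # 1 patient x 30 features
```

Running the numbered drivers reproduces the full narrative; e.g.
`python analysis/03_quantify_cells.py` prints

```
quantified 1000 cells across both panels
FS-level recovery 100.00% of 5000 (cell, marker) pairs
phenotype recovery 100.00%
```

— on a noiseless scene with oracle nuclei, the quantification path
recovers every generated fluorescence-strength level and phenotype: the
binning, intersection and rule table are exact inverses of the generative
model. `python analysis/05_survival_analysis.py` fits the planted
stromal-neutrophil effect (`HR 0.894` per %, true `exp(-0.08) = 0.923`,
inside the 95% CI), recovers an optimal cutoff with raw and
permutation-corrected p-values, and pools the per-stage stratum effects
(`pooled HR 0.929, 95% CI 0.876–0.986`). The drivers under `analysis/`
are, in order: cohort simulation, segmentation benchmark, per-cell
quantification, spatial/content feature assembly, survival analysis, and
the six-gene score evaluation; each writes its tables under `results/`.

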