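# Methods

`mifspatial` implements a spatial-phenotyping pipeline for two-panel
multiplex immunofluorescence (mIF) of tumour sections, together with the
survival statistics used to relate its features to outcome and a frozen
six-gene expression risk score. Because patient-level mIF data of this
kind are rarely shareable, the package ships a synthetic generator that
produces every input the pipeline consumes; all guarantees quoted below
are measured on that generator's output and say nothing beyond it about
any particular real dataset.

## The imaging model

Each patient contributes serial 4 µm sections stained with two 5-plex
panels plus DAPI (panel 1: FOXP3, CD38, CD4, CD20, CD66b; panel 2: CD8,
CD68, PD-L1, CD163, CD133). The two panels share the tissue's
tumour-nest (TN) / tumour-stroma (TS) geometry but are different physical
slices, so individual cells can never be matched across panels and every
per-cell quantity is panel-local. Spatial pairs are therefore only
formed within a panel — this is why two 5-class panels give
2·(C(5,2)+5) = 30 pairwise distance features, not C(10,2)+10.

## Synthetic scenes

- **Geometry.** The tissue is an inscribed ellipse (outside = non-tissue);
  tumour nests are 3 random disks of radius 60–140 px, the remaining
  tissue is stroma. Default scene 1024×768 px at 0.5 µm/px (a
  full-resolution 4028×3012 mode exists); the small default keeps a
  rendered 500-cell scene near one second.
- **Cell positions.** A hard-core Gibbs point process: dart-throwing
  initialisation with hard-core radius equal to the mean nucleus diameter,
  then Metropolis birth–death sweeps (one proposed relocation per cell per
  sweep) under the pairwise potential `U = -Σ s_AB·(1 − d/R)` for
  interacting phenotype pairs within range R = 30 µm. The default is 50
  sweeps: measured mixing is already strong (a strength-3 attraction halves
  the mean cross-pair Delaunay distance) and cohort-scale studies stay
  cheap; `n_sweeps` is a spec field for longer runs. With zero
  interactions the sweeps are skipped — the hard-core dart-throwing process
  is already the null.
- **Nuclei.** Star-convex polygons with 8 radial rays, radii jittered
  ±30% around 5 px, rasterised without overlap (later nuclei never steal
  earlier pixels; disjointness is guaranteed by construction).
- **Intensities.** Marker intensity per cell is lognormal:
  `exp(N(log 3, 0.4))` for cells whose phenotype expresses the marker,
  `exp(N(log 0.2, 0.4))` otherwise, with the generator threshold Z = 1.
  The truth fluorescence-strength (FS) level is the Z/2Z/3Z bin the draw
  lands in, so on noiseless scenes the quantification path can recover
  truth exactly. Channels are painted per nucleus, optionally Gaussian
  blurred (default σ 0.8 px) and noised (default σ 0.02). No staining
  intensity distributions are published for this assay; the lognormal
  model is a declared assumption, not an inference, and tests that rely on
  exact recovery disable blur and noise.
- **What is not emulated:** optics (PSF), autofluorescence spectra,
  spectral unmixing, section-to-section thickness artefacts, imaging
  batch effects. Passing tests therefore demonstrate the *pipeline's*
  correctness, not robustness to those real-data effects.

## Cohorts and survival

Stage groups IA–IIA (prevalence 0.693) and IIB–IIIB (0.307) shift the
phenotype mixture additively (late stage: stromal neutrophils and CD133+
CSCs down, CD163+ M2 macrophages up), after which mixtures are
renormalised. Covariates: sex, age, T stage, visceral pleural invasion,
vascular tumour emboli. Event times follow a Weibull
proportional-hazards model (shape 1.2, scale 1500 days) whose linear
predictor is a configurable β over the patient's *realised* composition
features and covariates; referencing a feature the scenes do not produce
is an error. Censoring mixes an administrative horizon with uniform
random censoring; the uniform bound is solved numerically so the expected
censored fraction matches the requested rate for the realised sample.
`censoring_rate` 0 and 1 are exact boundaries (all events / all censored).

## Quantification

Fluorescent fields are pixels strictly above a background quantile
(default 0.95) of the channel; field pixels are attributed to the nearest
nucleus within a 2 px dilation (≈1 µm at 0.5 µm/px, to catch
membrane/cytoplasm staining — the dilation radius is a config knob since
no canonical value exists), and unattributed fluorescent pixels are
discarded as non-specific. Per-cell mean intensity is binned at the
per-marker positive threshold Z: `<Z` negative, `[Z,2Z)` low, `[2Z,3Z)`
median, `≥3Z` high; boundaries belong to the upper bin (a deliberate
convention — the thresholds themselves have no stated boundary side).
Z is a config input, defaulting to Otsu on the per-cell intensity
distribution when not supplied; in the original workflow it is set by
pathologists per marker.

Phenotypes are called by an ordered first-match rule table
(panel 1: CD4+FOXP3+ → Treg, CD4+ → CD4 T, CD38+ → activated T,
CD20+ → B, CD66b+ → neutrophil; panel 2: CD68+CD163+ → M2 macrophage,
CD68+ → macrophage, CD8+ → CD8 T, CD133+ → CSC; otherwise "other").
PD-L1 is an independent flag, never an exclusive phenotype. The rule
table is a documented reconstruction and fully replaceable by the caller.

The H-score of a marker over a cell population is
`%low·1 + %median·2 + %high·3` on a 0–100 percent scale (range 0–300).

## Spatial features

Cells of one section/panel are joined by Delaunay triangulation of their
centroids; the connection length of an edge is the Euclidean distance in
µm. A pair feature (A,B) is the arithmetic mean length of edges whose
endpoints carry classes A and B (median available via config); same-class
pairs require both endpoints in the class. Only Delaunay-adjacent pairs
contribute — the triangulation defines adjacency; an all-pairs
nearest-neighbour alternative exists behind a flag but is never the
default. Features undefined in a section (no qualifying edge) stay
missing; per patient, each feature averages over the sections where it is
defined. Degenerate inputs (fewer than 3 distinct points, collinear sets,
duplicate centroids) warn and degrade explicitly rather than fail.
A brute-force empty-circumcircle oracle checks the triangulation on small
point sets; rigid-motion invariance and scale equivariance are property
tests.

## Content features

The content schema is 11 phenotypes (the ten marker classes plus "other")
× 2 compartments × 3 metrics = 66 columns: percentage of cells in sight
(panel-local denominator), density (cells/mm² of compartment area), and
the H-score of the phenotype's defining marker ("other" has none, so its
H-score is structurally missing). This 66-column decomposition is a
reconstruction — only the total count is fixed by convention — and the
schema is configurable. Missing values are empty CSV fields, never
zero-imputed.

## Survival statistics

- **Cox fits** delegate to lifelines (Efron tie handling), with explicit
  pre-checks (≥10 events, no constant covariate) and a diagnostic error on
  separation/non-convergence. The contract is the returned HR, Wald CI
  and p per term.
- **KM/log-rank** delegate to lifelines. The cutpoint scan uses an
  internal vectorised two-group log-rank χ² (hypergeometric variance over
  distinct event times) that is cross-checked against lifelines in tests.
- **Optimal cutpoint** (the X-tile idea): candidates are observed feature
  values whose `value > c` split leaves both groups ≥ `min_group_frac`
  (default 0.1) of the cohort; the returned cutoff maximises the χ², ties
  breaking toward the lower cutoff for determinism. The raw p is
  anti-conservative under maximal selection; an optional permutation p
  (re-maximising per permutation) corrects it, and the null-calibration
  test verifies both the uniformity of the permutation p and the
  anti-conservatism of the raw one. The Miller–Siegmund analytic
  correction is deliberately not implemented.
- **Fixed-effects pooling**: inverse-variance weights `1/SE²`, pooled SE
  `(Σw)^(-1/2)`, Wald CI/p. Strata are caller-defined (e.g. per-stage or
  per-FS-level effects of the same feature); the package does not assert
  one stratification.
- No multiple-testing correction is applied across feature–outcome scans
  by default; Benjamini–Hochberg is available to callers via statsmodels.

## The six-gene score

`NDEGS = 0.706·CTSZ + 1.225·PLAUR + 1.268·NME2 + 1.339·NPM1 +
1.349·EIF3E + 1.555·PPIA` with frozen coefficients; the gene selection
itself (penalised Cox) is out of scope. The coefficients are bound to the
normalisation scale of the expression values, which the caller must keep
consistent; the package never rescales silently. Cohorts split 7:3
(seeded permutation); the cutoff is learned on training only and applied
unchanged to validation. Time-dependent AUC is the IPCW
cumulative/dynamic estimator (scikit-survival) with the censoring
distribution estimated on training; horizons the censoring distribution
cannot support are dropped from the top down. TMB is mutation rows per
megabase interrogated (default 38 Mb); ≥20 mut/Mb is TMB-H, with the
boundary deliberately inclusive.

## Problem sizes and numerical choices

Simulation-based checks use scenes of 120–500 cells (5000 for composition
convergence, positions only), cohorts of 150–200 patients at point-level
(no rasters), 10–50 seeds per stochastic check and n = 1000 for Cox
recovery; these sizes give stable statistics while keeping the whole
suite and the acceptance script each under a minute of compute on one
core. Determinism: every stochastic routine takes an explicit seed and
feeds a local `numpy` generator; identical spec+seed reproduces scenes
byte-for-byte. Degenerate inputs (empty masks, constant channels,
all-censored cohorts, single-stratum pools) return defined results or
raise typed errors with context, as specified per function.

## Known limitations

- The classical nucleus detector (Gaussian → Otsu → watershed) is a
  simple baseline meant to exercise the evaluation machinery; it is not a
  learned instance segmenter and will undersplit on heavily overlapping
  real nuclei.
- The greedy descending-IoU matcher equals the optimal assignment in all
  tested regimes (and provably for thresholds ≥ 0.5) but the equivalence
  is checked, not proven, below 0.5.
- Pixel accuracy is binary foreground agreement; both per-image and
  pixel-pooled averaging are reported because the convention is ambiguous.
- The stage-shift, interaction and intensity parameters of the generator
  are defaults chosen to be biologically plausible, not fitted to any
  dataset.
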