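# Methods

## The screen

For every (gene, region) pair the pipeline fits a univariate ordinary
least squares regression of expression on donor age in years and tests the
slope against zero with the two-sided t statistic on n − 2 degrees of
freedom. Age is continuous on [0.33, 40] (4 months to 40 years; prenatal
samples are excluded at ingestion). Expression stays on the provided
RPKM-like scale — no log transform — so slopes read directly as expression
units per year. There are no covariates and no donor random effects: the
screen is deliberately the simplest age-trend model, applied uniformly to
every pair, and its outputs (slope, SE, t, p, R²) are fully determined by
the per-pair data.

A pair is called a DEGA (differentially expressed gene with age) when its
raw p falls below `alpha_raw` (default 0.05); direction is the sign of the
slope. Benjamini–Hochberg q-values are attached across all successfully
fit pairs of the whole screen — the screen is one joint search, so the
multiplicity correction spans it; per-region correction is available as a
config switch (`per_region_fdr`) but off by default. Pairs passing
q ≤ `fdr_alpha` form a higher-confidence tier carried as a flag
(`fdr_pass`) rather than replacing the raw-p call, so downstream overlap
and compartment analyses can use either tier.

With a raw-p cutoff the expected DEGA union over R regions is inflated by
false positives: a null gene enters the union with probability
1 − (1 − α)^R (≈ 56% at α = 0.05, R = 16). This is a property of the
screen design, not a bug; it is why the FDR tier exists, and why the
parameter-recovery test of union convergence is run on a single region.

### Numerical choices

* **Perfect fits.** RSS ≤ 1e−12 · max(TSS, 1) is treated as an exact line:
  status `perfect_fit`, p = 0, R² = 1. Volcano tables map p = 0 (and any
  p underflowing 1e−300) to −log10 p = 300, a documented cap.
* **Constant responses.** TSS = 0 gives slope 0, t 0, p 1, R² 0, status
  `ok` — no signal, not an error.
* **Degenerate pairs.** Fewer than `min_samples` (default 3, the minimum
  leaving one residual degree of freedom) observations, zero age variance,
  or a listed gene absent from the matrix produce status `degenerate` with
  NaN statistics. They stay in the results grid so the screen always
  enumerates |panel| × |regions| rows, and they are excluded from the FDR
  pool (q = NaN).
* **FDR pool.** q-values are computed over `ok` and `perfect_fit` rows
  together: an exact fit is a successful test (p = 0) and belongs in the
  multiplicity correction.

## Inputs

The expression dialect is a CSV triplet (matrix without header, columns
metadata with donor/age/sex/structure acronym, rows metadata with gene
symbols). Age strings parse as whole post-conceptional weeks (prenatal,
excluded), months (/12, full precision — "4 mos" is 0.3333…, displayed as
0.33) or years. Structure acronyms map onto 16 controlled region codes via
an editable table; unmapped acronyms drop the sample with a warning rather
than aborting, to tolerate atlas variants. Duplicate gene symbols collapse
to their per-sample arithmetic mean (symmetric and order-independent), with
the collapse count logged.

The gene panel is a two-column TSV (symbol, semicolon-separated
compartments from a 16-label vocabulary; empty defaults to `other`). The
shipped `data/cilia_gene_panel_synthetic.tsv` is a synthetic stand-in for a
curated 445-gene cilia panel: it seeds each compartment with real
cilia-associated symbols (tubulins, SNAP25, CCDC28B, IFT/BBSome/motor
components, ciliary GPCRs) and fills the remainder with clearly synthetic
CILSYN### placeholders. Analyses of real data should substitute a real
curation; everything downstream treats the panel purely as input.

## The synthetic data generator

`generate_dataset` emulates the postnatal atlas design the screen targets:

* **Cohort.** 42 donors by default (sex ratio 19 F : 23 M), each with one
  age drawn uniformly on [0.33, 40] years and shared across all of that
  donor's regions — one brain, many regions — which reproduces the
  cross-region dependence that makes region overlaps non-independent.
  Ages are snapped to the grid representable by the metadata dialect
  (whole months below 2 years, whole years above), so a written dataset
  round-trips exactly; the grid is dense enough that the design stays
  effectively uniform.
* **Coverage.** Each donor × region cell is observed with probability
  1 − `missing_rate` (default 0.2, emulating incomplete atlas coverage).
  A draw leaving any region with fewer than 3 samples is an error.
* **Expression.** expr = intercept + slope·age + N(0, `noise_sd`) on the
  raw scale, truncated at zero with truncation events counted and logged.
  A configurable fraction of (gene, region) pairs (default 0.2, matching
  the order of the hit rate such screens report) receives a true slope of
  magnitude uniform in 0.1–5 units/year with random sign — bracketing the
  reported coefficient range of real screens (−5.1 to 22.3) — and
  intercepts are uniform in 5–50. Defaults: `noise_sd` 10.

The generator does **not** emulate: count noise (no negative-binomial
layer — residuals are Gaussian, so the t-test is exactly calibrated by
construction and calibration tests check the pipeline, not distributional
robustness), mean–variance coupling, batch or donor effects beyond the
shared age, or correlated genes within a region beyond the age trend.
Passing tests therefore demonstrate correctness of the estimator and
bookkeeping, not robustness to real RNA-seq noise.

Calibration-style tests (type-I error, p-uniformity) use intercepts well
above zero relative to the noise SD so truncation never triggers; truncation
under low intercepts biases OLS slightly and is deliberately visible in the
logs.

## Downstream analyses

* **Co-expression.** Pearson correlation of raw expression among a
  region's DEGAs over that region's samples; zero-variance genes are
  dropped with a warning. Display order comes from average-linkage
  agglomerative clustering on d = 1 − R. The dendrogram's merge tree is
  scipy's; leaf orientation is resolved data-dependently (the child with
  the larger mean total-correlation score first, ties by smallest original
  index), which makes the order equivariant under gene relabelling —
  scipy's native leaf order is index-dependent and would not be. Linkage
  and distance are configurable design choices, not canonical.
* **Region sets.** Overlap counts ignore direction (a gene down in one
  region and up in another still intersects). Regions with zero DEGAs are
  kept as isolated network nodes. The bipartite gene-region graph is
  exported as GraphML plus an edge-list TSV; layout coordinates are
  presentation, not analysis, and are not computed.
* **Compartments.** Multi-compartment genes count once per compartment,
  so compartment totals are not a partition of the panel and their DEGA
  counts can sum past the union. At whole-screen (ALL) scope a gene's
  direction is the majority across its DEGA regions; exact ties go to an
  explicit `mixed` bucket rather than being forced to a side. Regions with
  zero compartment DEGAs report undefined (NaN) direction fractions, not
  zero.
* **Power.** Exact power of the two-sided slope test via the noncentral t
  (noncentrality β₁·√Sxx/σ); at β₁ = 0 it equals α exactly. A "uniform
  ages, n samples" design is represented deterministically by the n
  quantile midpoints of U(0.33, 40), so the analytic and Monte-Carlo
  routes share one design and agree to simulation error. The far-tail
  term of scipy's noncentral t can underflow to NaN at large
  noncentrality; it is replaced by its limit (0 or 1) and the sum clipped
  to [0, 1]. Effect size is parameterized as (slope, σ, design) rather
  than f² or correlation.

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → screen → coexpression → overlap →
compartments, writing every table under one directory plus a
`manifest.json` with the seed, package version and input checksums.
Every downstream table is recomputable from `screen_results.tsv` alone,
and a rerun with the same config and seed is byte-identical (the manifest
deliberately omits wall-clock fields).

Problem sizes used by the test suite and acceptance script — 10,000 null
pairs at n = 42 for calibration, 504 planted pairs for CI coverage,
400 genes in one region for union convergence — were chosen as the
smallest designs whose binomial/Monte-Carlo error is well inside the
asserted tolerances; the full default screen (445 × 16 at 42 donors) runs
in well under a second.

## Known limitations

* Only linear age trajectories; genes with U-shaped or saturating
  trajectories will be mis-ranked by design (use spline models elsewhere).
* No count-model inference; RPKM-scale Gaussian OLS is exactly what is
  implemented, including its heteroscedasticity blindness.
* The raw-p DEGA tier has the union inflation described above; the FDR
  tier is the conservative alternative.
* The shipped gene panel is synthetic; biological conclusions require a
  real curation and a real expression export.
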