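# Methods

This note documents the models and procedures implemented in `stemsen`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions used at degenerate inputs.

## Lifespan and clonogenicity

Serially passaged epithelial stem-cell cultures are described per passage by
an inoculum (cells plated), a colony-forming efficiency CFE ∈ [0, 1], a cell
yield UCY, and an aborted-colony fraction. The clonogenic cells at a passage
are `I = inoculum × CFE`, and the population doublings accumulated within
the passage are

    PD = log₂(UCY / I) = (1 / log₁₀ 2) · log₁₀(UCY / I) ≈ 3.322 · log₁₀(UCY / I).

We implement the exact base-2 logarithm rather than the rounded 3.322
multiplier (which differs by about 0.006%): population doublings are by
definition the log₂ of the expansion ratio, so doubling the yield at fixed
clonogenic input adds exactly one doubling, and doublings chain additively
across passages. Cumulative doublings divide each passage's yield by that
passage's own clonogenic count (each passage restarts from a fresh
inoculum); a `use_initial_clonogenic` flag switches the denominator to the
first passage's count for sensitivity analysis. The first passage with
CFE = 0 contributes zero doublings and terminates the lifespan; any later
record claiming CFE > 0 is rejected as inconsistent rather than silently
dropped. The half-abortion passage is the first passage whose aborted
fraction reaches the level (≥, default 0.5). Days-in-culture is carried as
metadata only; no day-level kinetics are modelled.

qPCR relative expression uses the ΔΔCt method: `ΔCt = Ct_target − Ct_ref`
within each sample, `ΔΔCt = ΔCt_sample − ΔCt_calibrator`, fold change
`2^(−ΔΔCt)`. This assumes near-equal amplification efficiencies of target
and reference. The marker-versus-lifespan relationship is an ordinary
least-squares regression of passages reached on initial marker level
(≥ 3 cultures required).

## FPKM preprocessing and trend selection

The input is a long-form matrix of FPKM values, one series of K ≥ 2
passages per (feature, culture), with a per-series `ok`/`fail` status.
Stages, in order:

1. **Status filter.** A feature flagged `fail` in any culture is removed.
2. **Low-expression filter.** A feature is removed globally when, in at
   least one culture, `sum(series) < 5` or `series[0] < 1`. Both
   inequalities are strict — boundary values (sum exactly 5, initial
   exactly 1) are kept. Thresholds are in FPKM units and configurable.
3. **Housekeeping anomaly flagging.** For each culture, a time-point is
   flagged when the housekeeping FPKM there deviates from the median of
   that culture's housekeeping series by more than `fold_limit` (default 3)
   in either direction. Flagged time-points are excluded from trend
   classification in that culture only; setting `fold_limit = inf` disables
   flagging. This formalizes the ad-hoc exclusion of a single implausible
   housekeeping measurement: a spike in the reference gene would otherwise
   corrupt every normalized series at that time-point.
4. **Housekeeping normalization.** Each series is divided point-wise by the
   culture's housekeeping (default GAPDH) series; a zero housekeeping value
   is an error naming the time-point.
5. **Baseline normalization.** Each series is divided by its first value,
   so every feature starts at exactly 1; a non-positive first value
   excludes the feature with a logged reason (after the low-expression
   filter this is rare — initial FPKM ≥ 1 survives it). No pseudocount is
   added by default.
6. **log₂ evolution.** Element-wise log₂ of the baseline-normalized series;
   the first element is exactly 0.

A feature is called **up** in a culture when every consecutive log₂
difference (over non-flagged time-points) exceeds `min_step`, **down** when
every difference is below `−min_step`, otherwise **none**. `min_step`
defaults to 0 — any strictly monotone pattern counts — because no magnitude
tolerance is inherent in the selection; it is exposed for stricter calls.
The cross-culture consensus is the shared non-none direction over all
required cultures, else none. Classification is antisymmetric under time
reversal and invariant under positive scaling of the raw series (scaling
cancels in baseline normalization).

The coefficient of variation (sample SD, n−1 denominator, over the mean) of
each raw series is reported as a quality metric; it is never used as a
filter. Significance gating of trend candidates (the role a differential
expression engine's q-values would play) is deliberately left to the stats
module: the slope fits and FDR machinery are exposed, but no
negative-binomial differential test is reimplemented.

## Statistics

- **Linear fits** are closed-form OLS with slope standard error from the
  unbiased residual variance `SSE/(n−2)`. A constant response with zero
  residual is reported as R² = 1 (the line fits perfectly).
- **Slope comparison (ANCOVA).** Two series get independent OLS fits; the
  slope difference is tested with
  `t = (b₁ − b₂) / sqrt(s²_pooled (1/Sxx₁ + 1/Sxx₂))`,
  `s²_pooled = (SSE₁ + SSE₂)/(n₁ + n₂ − 4)`, two-sided. This equals the
  interaction-term t-test of the full two-group linear model (verified
  against `statsmodels` OLS to machine precision). Intercept differences
  are reported secondarily; the slope test is the primary comparison.
  Degenerate data with zero pooled residual variance return p = 1 for equal
  slopes and p = 0 (flagged) otherwise.
- **BH FDR** is the standard step-up adjustment
  `q₍ᵢ₎ = min_{j≥i} min(1, m·p₍ⱼ₎/j)` (via `statsmodels`). The adjusted
  vector is monotone in p, dominates p, and is a fixed point of the
  step-up monotonization (the cumulative minimum taken from the largest p
  downward). Note the full adjustment is *not* idempotent under
  re-application — re-adjusting rescales by m/rank again — so q-values
  should be computed once from raw p-values.
- **One-way ANOVA, Student's t** use pooled variances; two identical
  samples give t = 0, p = 1, and internally constant samples with unequal
  means give p = 0 with an infinite statistic rather than NaN. For two
  groups F = t² exactly. Two-way ANOVA is out of scope (no factorial
  dataset arises in this pipeline).
- **Multiple-range (Bonferroni)** runs all m(m−1)/2 pairwise pooled
  t-tests and flags a pair when its raw p is below `alpha / n_pairs`
  (the common reading of the classical multiple-range procedure with
  Bonferroni adjustment; the LSD-style studentized variant is not
  implemented). Used for comparing 10–20 per-cell RTL values between
  conditions.

## Enrichment

One-sided overrepresentation only (depletion is not analyzed): for a query
of n genes with k hits in a term of K background members out of N
background genes, `p = P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` — Fisher's
exact test in its enrichment direction — and
`fold = (k/n)/(K/N)` (0 when k = 0). Terms are tested independently; no
ontology-graph correction is applied. The background defaults to the union
of annotation members when the caller supplies none; the end-to-end
workflow instead defaults to all features that entered trend analysis,
which is the universe its query lists are drawn from. The query must be a
subset of the background — a mismatch is an error, not a silent drop.

## Image quantification

Images are single-channel 16-bit grayscale; ROIs are 0-based, row-major
rectangles (half-open), polygons, or run-length masks. Background
subtraction takes a scalar level or a matched reference image, in which
case the estimate is the median of reference pixels outside the supplied
ROIs; results are clipped at zero. Spot detection thresholds the
background-subtracted image strictly above a cut (default: ROI mean + 3 SD
when not given), labels 8-connected components, and keeps components of at
least `min_area` (default 2) pixels. "Intensity of a spot" means the mean
pixel intensity, so `mean × area` is the integrated intensity; a per-cell
relative telomere length is `RTL = Σ_spots mean × area` (arbitrary units,
0 for a spotless cell). RTL is invariant under spot enumeration order and
under translation of the cell within the image.

CTCF follows the standard ImageJ-community definition:
`integrated density over the cell ROI − cell area × mean of pooled
background-ROI pixels`; background ROIs must be disjoint from the cell, and
negative values are reported as-is.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *structure* and *planted signal* of the
study's inputs, not their biological realism.

- **FPKM matrices.** Defaults mirror the study design: 4 cultures, 3
  passages, a stable housekeeping gene, 10% up- and 10% down-regulated
  features at 2 fold per step, baselines log-uniform on [5, 500] FPKM.
  Noise is multiplicative lognormal with unit mean — FPKM is positive and
  right-skewed — with coefficient of variation 0.10 by default; replicate
  dispersion is not reported for this kind of experiment, so 10% is a
  convention for well-measured bulk libraries, not a measured value.
  Direction assignment is deterministic (first block up, next block down),
  so planted fractions are exact. Not emulated: count-level sampling,
  length/GC bias, batch structure, isoform-switching.
- **Colony series.** Expected CFE decays exponentially and is truncated to
  0 at the planted exhaustion passage; the aborted fraction ramps linearly
  to 1; yields realise a constant planted number of doublings per passage
  (default 4). Optional lognormal noise perturbs CFE and yield. Not
  emulated: clonal heterogeneity (holoclone/meroclone/paraclone mixtures),
  counting error in colony scoring.
- **FISH images.** Nuclei are rectangular ROIs on a grid; spots are
  constant-intensity rectangles with a 1-pixel exclusion margin (so they
  stay 8-disconnected), integer amplitudes above a uniform background, and
  bounded-retry placement (an error if packing fails). Ground-truth RTL is
  exact by construction. Noise is additive Gaussian — a Gaussian
  approximation of photon/readout noise — with "SNR" meaning spot amplitude
  over noise SD. Not emulated: point-spread functions, spot overlap,
  chromatic cross-talk, uneven illumination.
- **Diffuse images.** A rectangle of exact planted area at the cell level
  on a uniform background, with a disjoint background patch; planted
  `CTCF = area × (cell − background)`.

Consequently, passing recovery tests demonstrates that the quantifiers are
*correct* (they compute exactly what they claim on inputs with known
truth), and that trend selection is well calibrated at the stated noise
level — not that the pipeline is robust to the full failure modes of real
microscopy or sequencing data.

## Problem sizes and numerical conventions

The test suite and the acceptance script run at the study's own scale:
1,000 features × 4 cultures × 3 passages for trend recovery; 2,000
Monte-Carlo replicates (n = 6 points per series, σ = 1) for ANCOVA type-I
error and for power at a slope difference of 5 standard errors of the
slope-difference estimator (analytic power 0.991 at df = 8); all
hypergeometric tables with N ≤ 60 (≈ 6.4 × 10⁵ tail values) against an
exact integer-arithmetic oracle; 20 FISH fields × 4 cells for image
recovery, with SNR-10 fields using 8–12 spots of 25–49 px per cell so the
per-cell relative standard error (noise_sd / (amplitude √Σarea) ≈ 0.5%)
sits well inside the 2% recovery band.

Ties and degenerate cases: strict inequalities throughout the expression
filters; trend calls need ≥ 2 usable time-points, else none; CV of a
zero-mean series is NaN (reported missing); all RNG flows through
`numpy.random.default_rng` seeds, and identical seed + configuration gives
byte-identical files end to end (JSON is written with sorted keys, tables
with fixed float formatting).

## Known limitations

- Trend selection with `min_step = 0` is permissive at 3 time-points: a
  flat gene has a non-negligible per-culture chance of a monotone noise
  path, controlled mainly by the cross-culture consensus requirement
  (≈ 0.5% of calls at the default conditions are such false directions).
- The ANCOVA assumes independent Gaussian residuals with a common variance
  across both series; it is exact only under those assumptions.
- Enrichment treats terms independently; correlated (nested) gene sets
  share counts and their q-values are not corrected for that dependence.
- Spot detection assumes spots are brighter than their surroundings and
  separated by at least one background pixel; merging/splitting of real,
  blurred telomeric signals is not modelled.
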