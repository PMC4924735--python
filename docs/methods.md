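# Methods

This note documents the statistical procedures `mentx` implements, the
choices made where the methodology was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Normalization chain

Raw linear intensities pass through five stages, in this order: qspline
inter-array normalization → median probe-set summarization → log2 →
per-gene batch correction → per-array median-centering. Batch correction
and centering run on the log2 scale because an additive linear model and
"centered data" are only meaningful there; the end state is centered log2
data.

**qspline.** For each array, a monotone mapping is fitted through matched
quantile anchors between that array and a reference pseudo-array defined
as the geometric mean of the per-anchor quantiles across arrays. Defaults:
14 interior anchor quantiles (extremes excluded for spline stability) and
a monotone piecewise-cubic interpolant (PCHIP), which guarantees a
non-decreasing transform without explicit constraints. Below the lowest
anchor the mapping continues multiplicatively (through the origin), which
keeps small intensities positive, continuous and monotone; above the
highest anchor it continues linearly with the boundary slope. A single
array is returned unchanged with a warning. Normalizing twice is a
near-identity (anchors are re-estimated, so agreement is ~1e-3 relative,
not exact).

**Probe summarization** takes the per-sample median over a gene's probes
(even counts: mean of the middle pair); unmapped probes are dropped and
counted in the report.

**Batch correction** fits, per gene, intensity ~ intercept + batch by
least squares and subtracts each batch's fitted deviation from the gene's
grand mean. This equals batch-mean removal with the grand mean restored:
post-correction batch means are equal by construction and per-gene grand
means are preserved exactly on balanced designs. Only batch main effects
are removed; no biological covariates are protected, so batch labels
confounded with subgroups will deflate true signal — the cohort simulator
assigns batches independently of subgroup, which sidesteps this in tests
but not necessarily in real data. Single-sample batches are retained with
a warning (estimable but noisy).

## Differential expression and permutation FDR

Per gene, the two-sided pooled-variance (Student) t-test on log2 values;
effect sizes are the log2 mean difference and its linear fold change
2^Δ. A variance floor of 1e-12 guards constant genes: equal-mean constant
genes report t = 0, p = 1 and a `degenerate` flag. Fold-change thresholds
apply two-sidedly (FC > t or FC < 1/t) with all inequalities strict, so a
gene at exactly p = 0.01 is excluded.

The FDR of a joint (p, FC) cutoff is estimated by permuting group labels
(default 100 permutations): the estimate is the median (configurable to
mean) null pass-count divided by the observed pass-count, capped at 1.
Zero observed passes yield an undefined estimate rather than a division
error. The estimator is list-wise, not per-gene.

## Signature intersection and candidate selection

The signature is the union of the triple intersection of up-lists and the
triple intersection of down-lists from the three aggressive-vs-1NR
contrasts; the WHO III contrast uses p < 0.001 so the three lists are of
comparable size. Genes called up in one contrast and down in another are
excluded and reported rather than raising — real data produce such genes.
All Venn regions are reported per direction; each list's size equals the
sum of its region memberships.

Candidate selection requires (a) p < 0.01 in WHO III vs I with a fold
change above the 90th or below the 10th percentile of that contrast's FC
distribution, and (b) support (p < 0.01, |FC| beyond 1.25 two-sidedly) in
at least two subgroup contrasts. Percentiles use linear interpolation
throughout the package. A configurable allow-list admits manually chosen
genes, flagged as manual. Note the percentile rule is symmetric: with toy
fold changes 1..10 both the FC = 10 gene (above 9.1) and the FC = 1 gene
(below 1.9) qualify.

## Clustering and PCA

Sample clustering uses 1 − Pearson correlation across the signature genes
with average linkage — the common expression-heatmap convention; the
distance matrix is computed explicitly so agglomeration ties resolve by
the deterministic lowest-index rule and runs are reproducible. Default
k = 3 reflects the benign / intermediate / aggressive cluster structure
such cohorts show; k is exposed. PCA centers genes and uses SVD with a
deterministic sign convention (largest-magnitude loading positive);
explained-variance fractions are non-increasing and sum to 1 at full rank.

## qPCR quantification

Relative expression = E^(ref Cq − mean target Cq) with efficiency E = 2
(one doubling per cycle; no standard-curve module). The reference is the
arithmetic mean of the per-housekeeper replicate-mean Cq values, which on
the linear scale is geometric-mean normalization against both
housekeepers. This is ΔCq-only quantification (no calibrator sample);
values are proportional to ΔΔCq results, so group comparisons are
unaffected. Replicate outliers are kept by default; a median-of-replicates
mode exists. Mann-Whitney comparisons use the exact distribution when both
groups have n ≤ 8 and no cross-group ties, otherwise the tie-corrected
normal approximation; fully tied data report p = 1.

## Matched pairs

Ratios are recurrent/primary relative expression (for log2 input,
2^difference). Thresholds are inclusive: ratio ≥ 2 is an increase,
≤ 0.5 a decrease. Patients with more than two surgical time points are
paired consecutively by default (first-vs-last available). Category counts
partition the pairs with data; missing values are reported, not imputed.

## Survival analysis

The survival cohort retains primary, treatment-naive tumors with complete
resection (Simpson 1–3) and either an observed progression event or
≥ 36 months of follow-up; every exclusion is logged per record. Time is
PFS in months from the index surgery. Kaplan–Meier, log-rank and Cox
models are computed by lifelines; Cox uses Efron tie handling (the
less-biased standard) and reports Wald CIs per term plus the model
likelihood-ratio test, whose p-value (a log-rank-type statistic) is the
headline p for univariate models. Categorical covariates expand against
the alphabetically first level (e.g. WHO II vs I, III vs I). Fits with
fewer than five events per covariate warn.

Dichotomization: high = strictly above the cut (median or 75th
percentile, linear interpolation); ties at the cut go to low. The
combined two-gene analysis cuts the hazard-increasing gene at the upper
quartile and the protective gene at the median, yielding four groups
compared by a k-group log-rank test. Multivariate covariates are selected
as exactly those significant (p < 0.05) univariately — a pure function of
the univariate p-values — and among candidate genes only those with
unadjusted univariate p < 0.001 (at most two) enter.

## IHC scoring

H-score = %weak + 2·%moderate + 3·%strong ∈ [0, 300], validated so the
fractions sum to ≤ 100. PTTG1 is scored as the maximum positive-cell
count over 40× high-power fields (hot spot). The combined score is
PTTG1 × 100 / LEPR-H-score; LEPR-negative sections (H = 0) yield an
undefined value rather than an exception, with a configurable ceiling
substitute available for plotting. Staining fractions are manual inputs;
no image analysis is attempted.

## Synthetic cohorts

The generator emulates a 62-sample discovery design: per-grade totals
20 / 14 / 28 with subgroup cells 1NR=10, 1R=6, 1M=4, 2NR=6, 2R=5, 2M=3,
3NR=4, 3R=11, 3NA=13 (the grade totals are the study design; the within-
grade split is the package's own choice, set to a plausible mix of
recurrent and non-recurrent cases). Expression: per-gene baseline
N(8, 1), 208 planted up and 124 planted down genes shifted by ±1.0 log2
in every aggressive sample (R/M of grades I–II and all WHO III), residual
noise N(0, 0.5), and per-(gene, batch) offsets N(0, 0.3) entering only
the raw linear matrix. A gradient mode scales effects by grade for
PCA-spectrum experiments. PFS is exponential with hazard
0.02 · exp(β_P z_P + β_L z_L) per month on the standardized planted
biomarker expressions (β_P = log 2, β_L = −log 2), censored by an
independent exponential clock truncated at 120 months; NR-labelled
samples are guaranteed ≥ 36 event-free months so labels and definitions
stay consistent. Matched pairs (6 stable-grade, 7 progressing), Cq
triplicates (housekeepers exactly constant, so zero-noise tables invert
exactly) and staining fractions derived from a target H-score complete
the bundle. Identical seeds give identical cohorts.

What the simulator does *not* emulate: probe-level bead chemistry,
heavy-tailed intensity distributions, correlated gene modules beyond the
planted block, informative censoring, center effects on outcome, or
label noise in the clinico-pathological subgroups. Passing tests
therefore demonstrate the correctness and calibration of the machinery
under the assumed model, not robustness to real-data pathology.

A note on intersection sensitivity: with these planted conditions the
per-contrast detection powers are ≈ 0.93 (1M+R, 10 vs 10), ≈ 0.88
(2M+R, 8 vs 10) and ≈ 0.96 (WHO III, 28 vs 10), so the triple
intersection recovers ≈ 84% of planted genes — below any single
contrast's power but with a spurious fraction near zero. This is the
expected behaviour of an intersection design at these sample sizes, not
an implementation loss; the test suite checks recovery against the
closed-form power bound.

## Problem sizes

Default simulations use 5000 genes × 62 samples; permutation FDR uses 100
permutations; Cox recovery studies use n = 500 with 10 estimation seeds
and 200 coverage replicates. These sizes give stable estimates (binomial
/ Monte-Carlo error well inside the asserted tolerances) while keeping
the full suite and the acceptance script fast on a single CPU.

## Known limitations

- Accession-level reanalysis (the GEO series-matrix reader) tolerates
  absent clinical metadata but cannot reconstruct subgroup labels that
  were never deposited; mapping metadata to annotations is the caller's
  responsibility.
- Batch correction does not protect biological covariates (see above).
- The permutation-FDR null distribution summarizes pass counts by their
  median; an alternative percentile summary is configurable but both are
  coarse for very small permutation counts.
- No moderated/shrinkage t statistics, background correction, detection
  filtering, pathway enrichment or competing-risks models.
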