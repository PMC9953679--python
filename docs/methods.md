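# Methods notes

This note documents the models, the synthetic-data assumptions, the
numerical choices, and the places where the design was genuinely open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis problem

The target design is a hospitalized community-acquired pneumonia (CAP)
cohort profiled on expression arrays at admission, with in-hospital death
as the outcome: roughly 200 arrays, ~7% deaths, ~20k gene-level features,
and processing batches. The difficulty is the extreme class imbalance
(about 13 deaths): single-model per-gene tests are unstable, so the stack
couples a variance-moderated linear model with a subsampling
stability-selection step, and complements the per-gene view with gene-set
enrichment, a per-gene survival screen, and interaction-network context.

## Synthetic cohort generator

`synthdata` draws each sample's outcome as Bernoulli(mortality rate
13/198 by default) or with an exactly fixed death count; batches are
assigned round-robin (or at random) over 4 default batches; clinical
covariates follow the cohort's marginal frequencies (septic shock 7.5%,
PSI high-risk 64%, age median 75 with IQR 62.5–84 mapped to a clipped
normal). Expression is generated directly on the log2 (RMA output) scale

    x_gs = baseline_g + batch_{g,b(s)} + died_s·δ_g + ε_gs,

with gene baselines N(7, 1.5²), additive per-(gene, batch) offsets
N(0, batch_sd²), planted effects δ_g = ±effect_size on a random `n_de`
subset (75% up-regulated in the died group by default, mirroring the
36/13 up/down split of the reported DE table), and noise
ε ~ N(0, gene_sd²), gene_sd = 0.5 log2 units by default. Survival times
are in-hospital days: deaths get truncated-exponential event times (mean
10 d) within the 30-day follow-up, survivors are censored at a discharge
time (exponential, mean 9 d, capped at follow-up). When a hazard-linked
gene is requested, times instead come from a proportional-hazards
simulation (hazard r₀·exp(coef·z) on the standardized expression) and
the outcome/event columns are re-derived from the simulated events —
otherwise the planted association would be confined to the handful of
pre-assigned deaths and carry almost no power.

What the generator deliberately does **not** emulate: probe-level raw
intensities, correlated clinical covariates, heavy-tailed or
batch-by-outcome confounded expression, microbiological etiology.
Passing tests therefore demonstrate correctness of the machinery and its
calibration under a clean additive Gaussian model, not robustness to
every artifact of real array data.

## Preprocessing

Quantile normalization maps each array's order statistics to the
across-array mean of order statistics; ties within an array receive the
mean of the tied reference values. It is idempotent and rank-preserving;
a single-column input is returned unchanged with a warning. Probe-to-gene
summarization fits `x_ps = overall + probe_p + sample_s` per gene by
Tukey median polish (rows swept first, at most 10 sweeps, stop when the
sum of absolute residuals changes by <1% — standard RMA practice) and
reports `overall + sample_s`. Note the identifiability convention: probe
effects carry median 0, so summarized values equal the generative truth
plus the median of the true probe effects. Background correction (normexp
convolution) is **not** implemented: the package consumes log2 data that
is assumed background-clean, because everything downstream operates on
the normalized matrix. An optional exclusion list (e.g. control probes)
is applied before normalization.

## Cohort summaries

Categorical Table-1 rows use the continuity-corrected chi-square test,
replaced by Fisher's exact test whenever an expected cell count is below
5 (the source cohort description names no tests; both p-values are kept
in the output for transparency). Continuous rows use median (IQR, linear
interpolation) and a two-sided Mann–Whitney U with tie and continuity
correction. Percentages are rounded to one decimal.

## Moderated differential expression

Per gene, OLS on a design with intercept, outcome indicator (died = 1)
and one-hot batch columns (first batch reference). Empirical-Bayes
hyperparameters (s₀², d₀) come from moment matching of log s²_g against
the scaled-F model — the mean and variance of log s²_g corrected by
digamma/trigamma terms, with the trigamma inverse solved by Newton
iteration; genes with numerically zero residual variance are excluded
from the fit and reported with p = 1. `prior_df=0` disables shrinkage
(ordinary t; verified against a gene-by-gene OLS oracle and against the
limma reference implementation via Rscript in the tests) and
`prior_df=inf` pools completely.

Stability selection draws, per iteration, a subsample fraction uniformly
in [0.55, 0.77] ("balanced": each outcome group subsampled at that same
fraction, preserving the died:survived ratio; an "equalized" strategy
with equal absolute group counts is available behind a flag since the
wording of such procedures is often ambiguous). The batch covariate is
rebuilt from the levels present in each subsample. Degenerate draws
(outcome group < 2) are redrawn up to 100 times. The per-iteration
fraction redraw (rather than one fraction per analysis) was chosen for
variance coverage.

**Gating.** `select_top_genes` keeps genes with full-data p < 0.05 and
selection count ≥ `min_count`. The default `min_count=250` mirrors the
range of counts printed in the reported 49-gene table (252–533), which
reflects weak real-data effects. Under strong planted effects that
default does not control the false-discovery proportion: planted genes
saturate near 1000/1000 while null genes that pass the p-gate keep
moderate counts because consecutive subsamples overlap heavily. For
signal-recovery evaluation the package therefore uses the
stability-selection literature's standard selection-frequency threshold
π = 0.75 (count ≥ 750 of 1000); both gates are plain parameters.

## GSEA

Ranking metric: signal-to-noise (μ₁−μ₂)/(σ₁+σ₂) with each σ floored at
0.2·|μ| (0.2 when μ = 0), the GSEA convention; a Welch-t metric is
available for very small groups. Ties in the ranking break
lexicographically by symbol for determinism. The running sum increments
|r|^p/N_R at hits (weight p = 1 by default, the "weighted" scheme) and
decrements 1/(N−N_H) at misses; ES is the extremum. The null is built by
phenotype-label permutation (default) or by size-matched random gene
sets; NES divides ES by the mean same-sign null ES; NOM p is the
same-sign tail fraction with add-one correction, floored at 1/(n_perm+1);
FDR q is the ratio of pooled-normalized-null to observed tail fractions,
clipped to [0, 1] and made monotone non-increasing in |NES| within each
sign class. The significance filter implements "p < 0.05 and/or
q < 0.25" as OR (an AND mode exists). With ~13 deaths, phenotype
permutation is borderline (a warning fires below 7 per group, advising
gene-set permutation). One documented quirk of the source study: its
abstract and its results section disagree on which outcome group the
four positively enriched sets belong to; this package follows the
results-table convention (positive NES = enriched in the died group).

## Survival screen

Samples are split at the median expression of each gene, ties at the
median going to the high group (the "above/below the median" rule leaves
ties unspecified; configurable). Kaplan–Meier estimation and the log-rank
test are delegated to lifelines behind the module surface (hand
product-limit and observed-vs-expected/hypergeometric-variance oracles in
the tests). The protective direction is the group with the higher KM
survival at end of follow-up; p < 0.05 is "significant" and p < 0.1
"trend" (both configurable).

## Network

Edge lists are simple text (first two whitespace/tab-separated columns
are interactors, `#` comments ignored), uppercased, de-duplicated,
self-loops dropped. `seed_subnetwork(order=1)` keeps seeds, their direct
neighbors and all edges among them. Hub ranking is degree-first with
normalized betweenness as tie-break and name as final tie-break; the hub
criterion of web tools is unpublished, so this explicit rule is the
package's own and reproducing any specific published hub list is out of
scope.

## Pipeline

One global seed is fanned out through `SeedSequence(entropy=seed,
spawn_key=(stage_index,))` with fixed stage indices, so toggling a stage
never shifts another stage's randomness. The manifest records parameters,
SHA-256 checksums and timings per stage; identical config + seed yields
identical checksums. Default problem sizes for the synthetic pipeline
(2000 genes, 50 planted DE, 1000 subsample iterations, 1000 permutations)
keep a full run in the tens of seconds while preserving the study's
sample design; the full 20,893-gene scale is a configuration change, not
a code path change.

## Known limitations

- No normexp background correction; probe-level simulation is out of scope.
- The moderated-t implementation covers a single two-level contrast with
  batch adjustment, not arbitrary contrast matrices or paired designs.
- FDR q-values inherit the known conservativeness/instability of the
  tail-ratio estimator at small permutation counts.
- No covariate-adjusted (Cox) survival modelling — the screen is the
  univariable median-split log-rank, matching the analysis it implements.
- The synthetic generator's Gaussian, additive-batch world is a best case
  for the linear model; real-data robustness is not demonstrated by
  these tests.
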