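# Methods

## The model

The package treats a transcriptomic cohort as a genes × samples matrix of
log-scale expression. The working hypothesis is that a handful of
biological programs (immune infiltration, interferon response, hormonal
signaling, proliferation, stroma/matrix, signal transduction) each drive
a block of co-expressed genes, and that a robust, portable signature can
be built by (a) finding those blocks with a resampling-stabilized
clustering, and (b) pruning each block down to its biologically connected,
tightly co-expressed core using an external interaction network. A block
is then summarized per sample by the *median* expression of its genes — a
statistic that is insensitive to any single gene, monotone under global
shifts, and transfers across platforms as long as gene identifiers
intersect.

## Normalization

Batch structure is handled per dataset label: every gene is median-
centered within each dataset, then the sample columns of each dataset are
quantile-normalized onto the mean sorted profile of that dataset, with
tied values sharing the mean of their tied reference positions. Both
operators are idempotent and preserve shape and identifiers; merging
across datasets afterwards uses the gene intersection. Whether the
original analyses centered within dataset or across the merged set is
ambiguous; the per-dataset reading is implemented because it is the only
one under which the subsequent per-dataset quantile step is coherent.

Missing values are allowed on input: a gene with more than 20% missing
entries is dropped (logged), and remaining gaps are imputed by the gene
median — neutral for the median-based metagene downstream.

## Marker-based stratification

HER2-like sample calls use the bimodal expression of a marker gene
(ERBB2 in the motivating application). A two-component Gaussian mixture
is fitted by EM with five quantile-based starts (component means
initialized at quantile pairs straddling the median); the best converged
log-likelihood is kept. The cutoff is the equal-posterior point between
the component means, found by bisection of
`w1·N(x|μ1,σ1) − w2·N(x|μ2,σ2)` (grid fallback when the weights are so
skewed that no sign change exists between the means). Samples strictly
above the cutoff are positive; ties are negative. Fits with mean
separation under one pooled standard deviation are flagged as effectively
unimodal. EM runs at tolerance 1e-6 on the per-sample log-likelihood
change with a 500-iteration cap: a tighter 1e-8 tolerance leaves weakly
separated mixtures un-converged at the cap, turning the intended
"unimodal warning" outcome into a hard error.

## Signature discovery

1. **Variance filter.** Across-sample SD (ddof = 1) strictly greater
   than `sd_threshold` (default 0.8 on log scale).
2. **Consensus clustering.** `n_resamples` (default 250) subsamples of
   `resample_fraction` (default 0.8) of the genes, drawn without
   replacement; each subsample is clustered by agglomerative Ward
   linkage on Pearson distance 1 − r and cut at every candidate k.
   The Ward update is the classic "ward.D" Lance–Williams recurrence on
   the supplied dissimilarities (no squaring) — SciPy's `ward` is the
   D2 convention and is deliberately not used; the implementation is
   cross-checked against R `hclust(method="ward.D")` in the tests.
   Equal-cost merges break to the lexicographically smallest pair, so
   dendrograms are deterministic. Consensus(i,j) = co-clustered count /
   co-sampled count; pairs never co-sampled are tracked and must stay
   under 1% (otherwise the run aborts advising more resamples). Final
   per-k labels come from Ward on 1 − consensus, cut by merge order
   (robust to the inversions ward.D can produce off-Euclidean input).
   The area under the consensus-entry CDF is computed exactly as
   1 − mean(entries) (∫₀¹F = 1 − E[X] for X in [0,1]); delta-areas use
   the standard relative-gain form with a running-max denominator,
   floored at zero. `chosen_k` maximizes the delta-area unless `fixed_k`
   pins it — on cleanly separated blocks the first delta (which equals
   its own area) dominates, so analyses that already know the cluster
   count (the motivating signature fixed six) should pin k, as the CLI's
   `--k` does.
3. **Network filter.** A gene survives if some incident edge has
   confidence ≥ `network_score_threshold` (default 0.7) *and* its other
   endpoint is in the same cluster. Genes absent from the network are
   removed.
4. **Correlation filter.** Genes are linked when pairwise Pearson
   r ≥ `correlation_threshold` (default 0.5; signed — anticorrelated
   genes do not merge); connected components of size ≥ 2 survive and the
   largest component inherits the cluster's label (connectivity rather
   than clique membership, since consensus clusters are already
   coherent; smaller components are logged and dropped).

Every gene entering the funnel keeps `passed_variance` /
`passed_network` / `passed_correlation` flags so the selection can be
audited.

## Metagene scoring and dichotomization

Score(c, s) = median over the cluster's genes present in the matrix
(absent genes are skipped with a warning; even counts use the mean of the
two middle values). Status is high when the score strictly exceeds the
across-sample median of the cohort passed in — per analysis cohort, not
pooled — with ties going to low (deterministic, and conservative for the
"high = exposed" convention). Inter-metagene structure is reported as the
Pearson correlation matrix of score rows; constant metagenes yield NaN
rather than a number. A hypergeometric utility suggests cluster labels
from named gene sets (BH-adjusted across sets); it replaces manual
ontology curation and is advisory only.

## Association battery

* ANOVA (scipy `f_oneway`) for expression-by-status contrasts; zero
  within-group variance is reported as p = 0 when group means differ and
  p = 1 when they coincide.
* Logistic regression (statsmodels `Logit`) for pCR with odds ratios,
  Wald 95% CIs and Wald p-values. The reference level of a categorical
  covariate is its first listed level. |coefficient| > 15 on the logit
  scale flags separation (a level with no events) as non-estimable.
* Survival: Kaplan–Meier with Greenwood bands and the log-rank test
  (lifelines); Cox proportional hazards with Efron tie handling
  (lifelines), Wald CIs, monotone likelihood reported as non-estimable.
* Multivariate models include every covariate with any estimable
  univariate p strictly below 0.10, preserving input order; p < 0.05 is
  the declared significance level.
* TIL analysis: Pearson r (with two-sided p) between a metagene score
  and the intratumoral or stromal lymphocyte percentage, plus the ANOVA
  of the percentage by metagene status.

Wald (not profile-likelihood) intervals and complete-case handling of
missing covariates are package-wide conventions, chosen for determinism
and auditability; profile intervals could be added behind the same
result type.

## Synthetic cohorts

The generator exists so that every stage is testable without cohort
downloads. Each module has one standard-normal latent score per sample;
module scores are correlated across modules via a user-supplied
correlation matrix (default: identity except a −0.46 immune↔hormonal
entry). A module gene is √ρ·z + √(1−ρ)·ε, so any two genes of a module
correlate at ρ (default 0.8) and every module gene has unit variance —
comfortably past the SD > 0.8 filter, while independent noise genes at
SD 0.5 (default 60 of them) fall below it. The single-factor block
construction guarantees a positive semi-definite joint covariance by
design. Default module sizes are 28/11/20/22/36/21 (138 genes),
mirroring the published six-cluster signature.

The marker gene is a two-component Gaussian mixture (default 50/50,
means 0 and 5, SD 0.5 — a 10-SD separation; the component drawn per
sample is recorded as ground truth). The interaction network gives
within-module pairs an edge with probability `p_in` (default 1) and
scores uniform on [0.7, 0.999]; all other pairs get sparse decoys
(probability 0.02) scored uniform on [0.15, 0.699]; an optional isolated
fraction per module exercises the network filter's removal path.

Clinical outcomes hang off the true immune score: ER-positivity is
Bernoulli with logit 0 − 1.5·score; pCR follows a logistic model with
default odds ratios 0.29 (ER-positive), 3.71 (immune-high) and 4.16
(high grade) on a base rate of logistic(−1.1); survival is exponential
with hazard 0.01/month times hazard ratios 0.58 (immune-high) and 3.29
(node-positive), censored by administrative uniform censoring whose
horizon is calibrated by bisection to the requested censored fraction
(default 0.3); TIL percentage is clip(16.5 + 9.4·score + N(0, 11²), 0,
100), which yields stratum means near 24% (immune-high) vs 9% and a
score–TIL correlation near 0.65. Effect-size defaults follow the
published predictive/prognostic estimates; link intercepts, slopes and
the TIL noise scale are chosen to give realistic response rates (~25%
reference-class pCR), a realistic ER mix, and the reported TIL stratum
means, and are fixed.

What the generator does *not* emulate: probe-level artifacts, platform
maps, nonlinear batch effects, realistic gene identifiers, correlated
censoring, or confounding between grade/nodal status and the immune
score. Passing recovery tests therefore demonstrates correctness of the
pipeline's logic under its own modeling assumptions, not performance on
real cohorts.

## Problem sizes and numerics

The validation suite runs discovery at n = 300 samples with 250
resamples (seconds on one CPU), the correlation-recovery and association
checks at n = 2000, the Cox coverage study over 200 replicates, and the
module-free null study over 100 seeds with 50 resamples each — sizes at
which the Monte-Carlo error of each checked quantity is comfortably
inside its asserted tolerance. All randomness flows from one master seed
through numpy `SeedSequence` streams, so every stage is reproducible and
independently re-seedable.

Known limitations: ward.D on non-Euclidean input can produce height
inversions (handled by cutting on merge order, but dendrogram heights
should not be read as calibrated distances); the delta-area criterion is
biased toward small k on clean block structure (pin k when it is known);
the equal-posterior cutoff is only meaningful when the marker really is
bimodal — consult the `unimodal_warning` flag; and the logistic/Cox
separation heuristics are thresholds, not likelihood-ratio diagnostics.
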