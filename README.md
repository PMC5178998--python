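# metasig

Network-driven metagene signature discovery and evaluation for gene
expression cohorts, modeled on the analysis of HER2-positive breast
carcinoma: find robust, biologically connected gene clusters in a
training cohort, summarize each cluster as a per-sample *metagene* (the
median expression of its genes), and test the dichotomized metagenes
against treatment response, survival and lymphocyte infiltration.

## Who this is for

Computational biologists building expression-based classifiers from
microarray or RNA-seq compendia who want the full funnel — normalization,
marker-based sample stratification, consensus clustering, interaction-
network filtering, scoring and the clinical association battery — as
tested, scriptable Python, plus a synthetic-cohort generator so every
stage can be validated without downloading cohort data.

## The method

Given a genes × samples log-expression matrix **X** (median-centered and
quantile-normalized per dataset) restricted to marker-positive samples
(HER2-like calls from a two-component Gaussian mixture on the marker
gene's bimodal expression):

1. **Variance filter** — keep genes with across-sample SD > 0.8.
2. **Consensus clustering** — repeatedly subsample 80% of the genes,
   cluster each subsample by agglomerative Ward linkage (the classic
   "ward.D" Lance–Williams update on the supplied dissimilarities) on
   Pearson distance d(i,j) = 1 − r(i,j), and record for every gene pair
   the fraction of co-draws in which it co-clusters. The per-k consensus
   matrices give a data-driven cluster count via the CDF delta-area
   criterion, or k can be pinned (the motivating signature fixed k = 6).
3. **Network filter** — within each cluster, keep genes that have at
   least one interaction edge with confidence score ≥ 0.7 to another
   cluster member (String-style edge list input).
4. **Correlation filter** — within each cluster, link genes whose
   pairwise Pearson r ≥ 0.5 and keep the largest connected component
   (≥ 2 genes). Survivors form the signature.

Each cluster c is scored per sample s as
`metagene(c, s) = median over assigned genes g of X[g, s]`, and
dichotomized *high*/*low* at the across-sample median (ties → low).
The evaluation battery fits univariate logistic models for pathological
complete response (pCR) and univariate Cox proportional-hazards models
for disease-specific survival, carries covariates with univariate
p < 0.10 into multivariate models (p < 0.05 declared significant),
draws Kaplan–Meier curves with log-rank tests, and correlates the immune
metagene with intratumoral/stromal tumor-infiltrating-lymphocyte (TIL)
percentages.

## Worked example

```python
import pandas as pd
from metasig import *

sim = SimulationConfig(seed=11)          # six planted modules, 300 samples
expr, truth = simulate_expression(sim)
net  = simulate_network(truth, sim)
clin = simulate_clinical(truth, sim)

cfg = PipelineConfig(fixed_k=6, rng_seed=11)
sig, _ = discover_signature(expr, net, cfg)
print(len(sig), {lab: len(sig.cluster_genes(lab)) for lab in sig.cluster_labels})

mm = dichotomize(score_metagenes(expr, sig))
print(metagene_correlations(mm).round(2))
```

prints

```
138 {'C1': 28, 'C2': 11, 'C3': 20, 'C4': 22, 'C5': 36, 'C6': 21}
      C1    C2    C3    C4    C5    C6
C1  1.00 -0.01 -0.01 -0.56  0.07 -0.07
...
```

All 138 planted module genes are recovered in six clusters whose sizes
match the generative module sizes, and the immune-like cluster C1 is
anticorrelated with the hormonal-like cluster C4 (generative score
correlation −0.46; the sample estimate at n = 300 is −0.56). Fitting the
association battery on the simulated clinical table:

```python
label = "C1"  # the immune-like cluster
design = pd.DataFrame({
    "er_positive":   (clin["er_status"] == "positive").astype(float),
    "immunity_high": (mm.status.loc[label] == "high").astype(float),
    "grade_high":    (clin["grade_class"] == "III").astype(float),
}, index=clin.index)
for r in fit_logistic(clin["pcr"], design):
    print(f"{r.term}: OR={r.estimate:.2f} [{r.ci_low:.2f}-{r.ci_high:.2f}] p={r.p:.3g}")
r = fit_cox(clin["time"], clin["event"], design[["immunity_high"]])[0]
print(f"{r.term}: HR={r.estimate:.2f} [{r.ci_low:.2f}-{r.ci_high:.2f}] p={r.p:.3g}")
```

```
er_positive=1.0: OR=0.22 [0.12-0.40] p=7.07e-07
immunity_high=1.0: OR=2.20 [1.25-3.87] p=0.00644
grade_high=1.0: OR=5.86 [3.17-10.83] p=1.69e-08
immunity_high=1.0: HR=0.74 [0.57-0.97] p=0.0292
```

ER-positive samples respond less, immune-high samples respond more and
survive longer — the structure the generator plants (log-odds and
log-hazards per covariate are configurable in `SimulationConfig`).

The same pipeline runs from the shell:

```sh
metasig simulate  --out run/ --n-samples 300
metasig discover  --expression run/expression.tsv --network run/network.tsv --out run/ --k 6
metasig score     --expression run/expression.tsv --signature run/signature.tsv --out run/
metasig associate --scores run/metagene_scores.tsv --status run/metagene_status.tsv \
                  --clinical run/clinical.csv --out run/
```

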