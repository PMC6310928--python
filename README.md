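# immunosubtyper

Immune-signature based subtyping of bulk tumor expression cohorts.

Triple-negative breast cancer (and other tumor types) can be stratified by
the amount and quality of immune activity in the tumor microenvironment.
This package implements that analysis as a reusable, tested pipeline for
bioinformaticians working with log-scale gene-by-sample expression
matrices:

1. **Signature scoring** — single-sample gene-set enrichment (ssGSEA)
   scores for a collection of immune signatures (typically 29 sets covering
   immune cell types, functions, and pathways), plus immune/stromal
   infiltration scores whose sum maps to tumor purity through a cosine
   transform.
2. **Subtype discovery** — hierarchical clustering (z-score, Euclidean,
   Ward) of the signature-score matrix into three clusters, labeled
   `Immunity_H` / `Immunity_M` / `Immunity_L` by decreasing median immune
   score.
3. **Subtype prediction** — per-cohort min–max scaling
   x′ = (x − x_min)/(x_max − x_min) of each signature score, a 100-tree
   random forest, stratified 10-fold cross-validation, and cross-cohort
   transfer (each cohort normalized by its own extrema).
4. **Characterization** — two-class GSEA with phenotype-permutation FDR,
   cross-cohort common-pathway intersection, pathway-activity vs
   immune-score Spearman correlation, soft-powered co-expression networks
   (w = |r|^β) with the hub rule "≥ 10 neighbors at weight > 0.25",
   seed-gene subnetworks, and Kaplan–Meier / log-rank survival comparisons
   including median-expression splits.
5. **Synthetic cohorts** — a generator that plants the exact structure the
   analysis assumes (ordered signature shifts H > M > L, correlated gene
   blocks with hubs, subtype-dependent survival), so the whole pipeline is
   exercised and validated without any data downloads.

## The core statistic

For one sample, genes are ranked by expression (descending, ties broken by
gene id). With N genes, N_h of them in the set, the ssGSEA enrichment
score is

    ES = Σ_{i=1..N} ( P_hit(i) − P_miss(i) )

where P_hit accumulates (N − i + 1)^α, normalized over in-set genes
(α = 0.25 by default), and P_miss accumulates 1/(N − N_h). The two-class
GSEA score is the classic weighted Kolmogorov–Smirnov statistic: the
signed maximum deviation of the same kind of running sum over a list
ranked by signal-to-noise (mean_A − mean_B)/(sd_A + sd_B) with floored
standard deviations. Both statistics are verified against exhaustive
step-enumeration oracles in the test suite.

## Worked example

```python
import immunosubtyper as ims
import pandas as pd

cohort = ims.generate_cohort(ims.GeneratorConfig(seed=7))
scores = ims.score_collection(cohort.expression, cohort.signatures)
est = ims.estimate_scores(cohort.expression, cohort.immune_set, cohort.stromal_set)
labeled = ims.label_clusters(ims.cluster_samples(scores, k=3), est.immune_score)

labels = pd.Series(labeled.labels, index=list(labeled.sample_ids))
print(est.immune_score.groupby(labels).median().round(1))

norm = ims.minmax_normalize(scores)
metrics = ims.cross_validate(norm, labels, folds=10, seed=7)
print(metrics.accuracy, metrics.weighted_f)
```

prints

```
Immunity_H    909.6
Immunity_L    236.9
Immunity_M    573.9
1.0 1.0
```

The median immune score decreases from `Immunity_H` to `Immunity_L` — the
ordering that defines the labels — and on this synthetic cohort (300
samples, 29 planted signatures, shifts of 1.0 / 0.5 / 0 log-units against
unit noise) the subtypes are clean enough that 10-fold cross-validation
classifies them perfectly. Survival separates too: the log-rank test of
`Immunity_H` against the rest gives χ² = 13.49, p = 2.4e−4 under the
generator's protective hazard (multiplier 0.5 for H).

A command-line interface mirrors the library
(`immunosubtyper simulate|score|estimate|subtype|train|predict|cv|network|survive`);
run `immunosubtyper --help` for the subcommands.

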