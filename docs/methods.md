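# Methods

## Scope and data model

The package operates on a log-scale gene-by-sample expression matrix
(`ExpressionMatrix`), gene-set collections in GMT format
(`GeneSetCollection`), and a clinical table of (sample, time, event)
records. Expression is assumed to be preprocessed: already log-scaled,
batch-handled, and gene-identified; no normalization or identifier mapping
happens on read. Duplicate gene rows in an input TSV are collapsed to the
row with the highest mean expression — a common convention for
probe-level duplicates — with a logged warning.

## ssGSEA scoring

For each sample independently, genes are ranked by expression descending;
ties are broken by gene id (alphabetical), which makes scores fully
deterministic. With N genes in the universe and N_h set genes present,
position i contributes a hit increment (N − i + 1)^α normalized over
in-set genes, or a miss increment 1/(N − N_h), and the enrichment score is
the sum over all positions of the running difference. Properties that
follow and are asserted in tests: invariance under any strictly monotone
transform of one sample's expression (only ranks matter), exact sign flip
on reversing the ranking at α = 0, and a non-decreasing response to
shifting all in-set genes up.

* `alpha` defaults to 0.25 — the standard single-sample enrichment
  exponent in the field; it is configurable and recorded in every
  `SignatureScoreMatrix`.
* A set reduced to a single present gene is still scoreable by the
  statistic; the collection-level scorer skips sets with fewer than two
  present genes (with a warning and a skip report) because one-gene
  signatures are not meaningful at cohort scale.
* A set covering the entire universe is an error (the miss denominator is
  zero).

Raw enrichment scores are not normalized across samples; the only
rescaling in the pipeline is the min–max transform at the classification
stage.

## Immune, stromal, and purity scores

Immune and stromal scores are ssGSEA scores of an immune and a stromal
signature set; their sum is the combined infiltration score, and tumor
purity is `cos(0.6049872018 + 0.0001467884 × combined)`. The cosine
transform and its constants come from the published ESTIMATE method. A
transformed purity outside [0, 1] is reported as-is with a boolean flag
rather than clipped, so downstream consumers can decide how to treat
out-of-calibration samples. The package ships no signature gene sets:
users supply their own GMTs (the synthetic generator provides planted
ones for testing).

## Subtype discovery and labeling

Signatures are z-scored across samples (zero-variance signatures dropped
with a warning), samples are clustered with Euclidean distance and Ward
linkage, and the tree is cut at k = 3. Distance, linkage, and
standardization are recorded in the assignment's parameters and are
configurable; the defaults were chosen for stability on continuous score
matrices. k is fixed at 3 by default — the three-subtype structure is the
object of study — with no automatic model selection.

Clusters are then ranked by median immune score: highest → `Immunity_H`,
middle → `Immunity_M`, lowest → `Immunity_L`. Ties in the median are
broken by cluster size (larger ranks higher), then by cluster index, so
labeling is deterministic. The immune score used for ordering is the
ESTIMATE-style immune score, not any single signature's enrichment.

## Classification protocol

Each signature is min–max scaled across the samples of a cohort
(x′ = (x − x_min)/(x_max − x_min)); a constant feature maps to zeros with
a warning, and the per-feature extrema are stored so held-out values can
be flagged when they fall outside the training range. The classifier is a
random forest with 100 trees; all other hyperparameters stay at library
defaults and are recoverable from the fitted model object. Evaluation
pools out-of-fold predictions from stratified 10-fold cross-validation
into a single confusion matrix; accuracy is its trace over total and the
weighted F-score is the support-weighted mean of per-class F1 (a class
never predicted and never present contributes F1 = 0). When the fold
count equals the sample count the split degenerates to leave-one-out
without stratification. Cross-cohort transfer normalizes the new cohort
by its own extrema — the transform is defined per dataset — and matches
features by name, order-insensitively. Probability ties inside the forest
resolve to lexicographic class order (the library's convention).

## Enrichment analysis

Two-class GSEA ranks genes by signal-to-noise
(mean_A − mean_B)/(sd_A + sd_B) with each class sd floored at
max(0.2·|class mean|, 0.2); the floor keeps near-constant genes from
dominating the extremes of the ranking. The enrichment score is the
signed maximum deviation of the weighted Kolmogorov–Smirnov running sum
(hit weights |metric|^p, p = 1 by default; miss weight 1/(N − N_h)).
Significance comes from phenotype (sample-label) permutations preserving
class sizes: NES divides the observed ES by the mean |null ES| of
matching sign, the nominal p is the matching-sign null tail, and FDR is
computed either by the positive/negative NES-pool convention (default) or
by Benjamini–Hochberg on nominal p-values (`fdr_mode="bh"`); both modes
are surfaced because R implementations of the procedure differ. When
fewer distinct label assignments exist than requested permutations, the
exhaustive set is used with a warning. "Common pathways" across cohorts
are the intersection of FDR-significant pathways with a consistent
direction.

The rank-based statistics are compositional: coordinately shifting one
large gene group in a sample displaces the relative ranks of all other
genes, so in a cohort with a strong planted immune axis even "background"
gene sets acquire small systematic score differences between subtypes.
Null-calibration tests therefore run on cohorts generated without effects.

## Co-expression networks

Edge weights are soft-powered absolute Pearson correlations
w = |r|^β with β = 6 (the common unsigned default; configurable). Module
detection is a deliberately simplified stand-in for full weighted
co-expression module analysis: average-linkage clustering of the 1 − w
distance with a static cut at height 0.95, clusters of at least
`min_size` genes becoming modules and the remainder pooling into a grey
set. The cut height was chosen so that blocks with within-block r ≈ 0.8
(mean distance ≈ 0.74 at β = 6) merge below it while uncorrelated genes
(distance ≈ 1) stay above; topological overlap, dynamic tree cutting, and
eigengenes are intentionally out of scope. Module–subtype association
scores a module as the ssGSEA of its gene set (a single-gene module uses
that gene's expression) and tests Kruskal–Wallis across subtypes plus
BH-adjusted one-vs-rest Mann–Whitney per subtype.

The hub rule is literal: a hub is a gene with **at least 10** neighbors
connected at weight **strictly greater than 0.25**. Subnetwork extraction
returns the induced edge list over seed genes plus every neighbor
attached to at least one seed above the threshold.

## Statistics and survival

Rank tests, ANOVA, Fisher's exact (two-sided, hypergeometric), Spearman,
and BH adjustment wrap scipy/statsmodels with contract checks (group
sizes, p ranges, degenerate inputs: identical values in all groups return
statistic 0, p = 1 for the rank tests). Kaplan–Meier and the log-rank
test (standard hypergeometric variance, no continuity correction) wrap
lifelines. The median-split survival comparison uses strict inequalities:
samples above the median versus below it, with samples exactly at the
median excluded — this is flagged in the result — and errors if either
group ends up with fewer than two subjects. All tests are two-sided.

## The synthetic cohort generator

The generator emulates the statistical shape the analysis assumes, not a
specific platform's marginals:

| parameter | default | meaning |
|---|---|---|
| `n_per_subtype` | (100, 100, 100) | samples per planted subtype |
| `n_genes` | 5000 | gene universe |
| `n_signatures` | 29 | planted immune signatures, 10–30 genes each |
| `delta_h`, `delta_m` | 1.0, 0.5 | log-unit shifts of signature genes in H / M (L gets 0) |
| `noise_sd` | 1.0 | i.i.d. Gaussian noise around per-gene means |
| `n_coexpr_blocks`, `coexpr_block_size` | 5, 20 | latent-factor blocks |
| `within_block_r` | 0.7 | member–member correlation inside a block |
| `hub_loading` | 4.0 | hub gene's factor loading (in noise-sd units) |
| `pathway_coupling` | 0.6 | coupled/anti-coupled pathway shift relative to the immune axis |
| `baseline_hazard`, `hazard_multipliers` | 0.1, (0.5, 1, 1) | exponential survival, H protective |
| `censoring_rate` | 0.3 | Bernoulli censoring probability |

Signature sizes and per-gene baseline means are drawn from a fixed
"structure" stream so that cohorts generated from the same configuration
under different seeds share their planted design (the premise of the
cross-cohort transfer experiment); everything else derives from
`config.seed`. Stromal genes track the immune axis at half amplitude,
mimicking the empirical co-variation of stromal content with immune
infiltration. The hub loading of 4 noise-sd units puts hub-to-member
correlation near 0.81, just above the 0.25^(1/6) ≈ 0.794 needed for hub
edges to clear the w > 0.25 rule at β = 6, so planted hubs are detectable
but not trivially so. Censoring is Bernoulli with the censored
observation drawn uniformly below the latent event time; this makes the
realized censoring fraction match the configured rate in expectation and
exactly zero when the rate is zero.

What the generator does **not** emulate: count-based (negative binomial)
RNA-seq noise, heavy-tailed or platform-specific marginals, correlated
signature overlap, copy-number structure, or single-cell sparsity.
Passing tests on these cohorts demonstrates that the pipeline recovers
the structure it is designed to find when that structure is present at
the stated effect sizes — not that real cohorts contain such structure.

## Problem sizes and numerical choices

The validation suite runs the full pipeline on 300-sample, 5000-gene
cohorts (scoring, clustering, 10-fold CV, transfer), 1000-replicate
type-I calibrations for the five tests the analysis relies on at n = 50
per group, permutation GSEA calibration on 200-gene, 30-sample matrices
with 500 permutations, and network recovery at 100 samples. Oracle
equivalence for the two enrichment statistics is asserted to 1e−9 on
random universes of up to 8–10 genes against exhaustive step-enumeration
implementations kept independent of the package code. Floating-point
ties in ranking are impossible by construction (continuous noise);
deterministic tie-breaks (gene id, cluster size, cluster index,
lexicographic class order) cover every discrete decision.

## Known limitations

* The simplified module detector has no dynamic tree cut; very unequal
  block correlation strengths may require adjusting `cut_height`.
* The NES-pool FDR is floored at one pooled-null count, so extremely
  significant pathways report a small positive q rather than 0.
* Purity is meaningful only for immune/stromal sets on the calibration
  scale of the published cosine transform; arbitrary gene sets yield
  purity values that may leave [0, 1] (flagged, not clipped).
* Cross-cohort prediction assumes the new cohort measured all training
  signatures; there is no imputation for missing features.
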