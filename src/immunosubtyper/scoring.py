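"""Single-sample gene-set enrichment (ssGSEA) and derived per-sample scores.

The ssGSEA statistic quantifies coordinate up-regulation of a gene set
within one sample: genes are ranked by expression (descending), in-set
genes accumulate rank-weighted increments, out-of-set genes accumulate a
uniform penalty, and the enrichment score is the sum of the running
difference over all rank positions.  Immune and stromal signature scores
summed give an overall infiltration score, which maps to tumor purity via
a cosine transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureScoreMatrix",
    "EstimateResult",
    "ssgsea_score",
    "score_collection",
    "estimate_scores",
    "marker_process_scores",
    "MARKER_PROCESSES",
]

#: Purity transform constants from the ESTIMATE method:
#: purity = cos(a + b * estimate_score).
_PURITY_INTERCEPT = 0.6049872018
_PURITY_SLOPE = 0.0001467884

#: Marker genes defining the three biological-process scores.
MARKER_PROCESSES: dict[str, tuple[str, ...]] = {
    "stemness": ("ABCA8", "ALDH1A1"),
    "proliferation": ("MKI67",),
    "emt": ("ZEB1", "ZEB2", "SNAIL", "CDH2", "TGFB1"),
}


@dataclass(frozen=True)
class SignatureScoreMatrix:
    """Signature-by-sample enrichment scores plus the alpha used to compute them."""

    data: pd.DataFrame
    alpha: float
    skipped: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.data.size and not np.all(np.isfinite(self.data.to_numpy())):
            raise ValueError("signature score matrix contains non-finite values")

    @property
    def signature_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class EstimateResult:
    """Per-sample immune, stromal, combined scores and cosine-transform purity.

    ``purity_in_range`` flags samples whose transformed purity fell inside
    [0, 1]; out-of-range values are reported as-is, not clipped.
    """

    data: pd.DataFrame

    @property
    def immune_score(self) -> pd.Series:
        return self.data["immune_score"]

    @property
    def stromal_score(self) -> pd.Series:
        return self.data["stromal_score"]

    @property
    def estimate_score(self) -> pd.Series:
        return self.data["estimate_score"]

    @property
    def purity(self) -> pd.Series:
        return self.data["purity"]


def _ranked_order(expr: ExpressionMatrix) -> np.ndarray:
    """Per-sample gene ordering: expression descending, ties by gene id.

    Returns an (n_samples, n_genes) integer array of gene indices; row s
    lists gene positions from top-ranked to bottom-ranked for sample s.
    """
    values = expr.values  # genes x samples
    # alphabetical rank of each gene id, used as the deterministic tie-break
    id_rank = np.argsort(np.argsort(np.asarray(expr.gene_ids, dtype=object)))
    orders = np.empty((values.shape[1], values.shape[0]), dtype=np.int64)
    for s in range(values.shape[1]):
        orders[s] = np.lexsort((id_rank, -values[:, s]))
    return orders


def _ssgsea_from_order(
    orders: np.ndarray, in_set: np.ndarray, alpha: float
) -> np.ndarray:
    """ES for each sample given precomputed per-sample gene orderings.

    ``in_set`` is a boolean mask over genes.  The hit increment at rank
    position i (1-based) is (N - i + 1)^alpha, normalized over in-set
    genes; the miss increment is 1/(N - Nh).  ES is the sum over positions
    of (cumulative hit - cumulative miss).
    """
    n_samples, n_genes = orders.shape
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set has no genes in the expression universe")
    if n_hit == n_genes:
        raise ValueError("gene set covers the whole gene universe (miss denominator zero)")
    positions = np.arange(1, n_genes + 1, dtype=float)
    rank_weight = np.abs(n_genes - positions + 1) ** alpha
    hit_mask = in_set[orders]  # samples x genes, in ranked order
    hit_inc = np.where(hit_mask, rank_weight[None, :], 0.0)
    hit_inc /= hit_inc.sum(axis=1, keepdims=True)
    miss_inc = np.where(hit_mask, 0.0, 1.0 / (n_genes - n_hit))
    running = np.cumsum(hit_inc - miss_inc, axis=1)
    return running.sum(axis=1)


def ssgsea_score(
    expr: ExpressionMatrix, gene_set: GeneSet, alpha: float = 0.25
) -> pd.Series:
    """ssGSEA enrichment score of one gene set for every sample.

    Only genes present in the expression universe count; a set reduced to
    zero present genes, or covering the whole universe, is an error.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    in_set = np.isin(np.asarray(expr.gene_ids, dtype=object), list(gene_set.genes))
    orders = _ranked_order(expr)
    scores = _ssgsea_from_order(orders, in_set, alpha)
    return pd.Series(scores, index=expr.sample_ids, name=gene_set.name)


def score_collection(
    expr: ExpressionMatrix, sets: GeneSetCollection, alpha: float = 0.25
) -> SignatureScoreMatrix:
    """Score every gene set of a collection against an expression matrix.

    Sets with fewer than two genes present in the matrix are skipped with a
    warning and listed in the result's ``skipped`` report; zero scoreable
    sets is an error.  Column order follows the sample order of ``expr``.
    """
    if expr.n_samples == 0 or expr.n_genes == 0:
        raise ValueError("expression matrix is empty")
    orders = _ranked_order(expr)
    gene_arr = np.asarray(expr.gene_ids, dtype=object)
    rows: list[np.ndarray] = []
    names: list[str] = []
    skipped: list[str] = []
    for gene_set in sets:
        in_set = np.isin(gene_arr, list(gene_set.genes))
        if in_set.sum() < 2:
            logger.warning(
                "gene set %r: %d genes present (< 2), skipped",
                gene_set.name,
                int(in_set.sum()),
            )
            skipped.append(gene_set.name)
            continue
        rows.append(_ssgsea_from_order(orders, in_set, alpha))
        names.append(gene_set.name)
    if not rows:
        raise ValueError("no scoreable gene sets in the collection")
    data = pd.DataFrame(np.vstack(rows), index=names, columns=expr.sample_ids)
    return SignatureScoreMatrix(data=data, alpha=alpha, skipped=tuple(skipped))


def estimate_scores(
    expr: ExpressionMatrix,
    immune_set: GeneSet,
    stromal_set: GeneSet,
    alpha: float = 0.25,
) -> EstimateResult:
    """Immune/stromal/combined infiltration scores and cosine-transform purity.

    The immune and stromal scores are ssGSEA scores of the two signature
    sets; their sum feeds purity = cos(0.6049872018 + 0.0001467884 * sum).
    Purity outside [0, 1] is reported as-is and flagged.
    """
    immune = ssgsea_score(expr, immune_set, alpha=alpha)
    stromal = ssgsea_score(expr, stromal_set, alpha=alpha)
    combined = immune + stromal
    purity = np.cos(_PURITY_INTERCEPT + _PURITY_SLOPE * combined)
    in_range = (purity >= 0) & (purity <= 1)
    if not in_range.all():
        logger.warning(
            "purity out of [0, 1] for %d samples (reported unclipped)",
            int((~in_range).sum()),
        )
    data = pd.DataFrame(
        {
            "immune_score": immune,
            "stromal_score": stromal,
            "estimate_score": combined,
            "purity": purity,
            "purity_in_range": in_range,
        }
    )
    data.index.name = "sample_id"
    return EstimateResult(data)


def marker_process_scores(
    expr: ExpressionMatrix,
    alpha: float = 0.25,
    processes: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Stemness / proliferation / EMT activity per sample from marker genes.

    A process with a single marker present uses that gene's expression row
    directly; with two or more present, its ssGSEA score; with none, the
    process is absent (an all-NaN row, flagged by a warning).
    """
    if processes is None:
        processes = MARKER_PROCESSES
    universe = set(expr.gene_ids)
    rows = {}
    for name, markers in processes.items():
        present = [g for g in markers if g in universe]
        if not present:
            logger.warning("process %r: no marker genes present, flagged absent", name)
            rows[name] = pd.Series(np.nan, index=expr.sample_ids)
        elif len(present) == 1:
            rows[name] = expr.data.loc[present[0]].astype(float)
        else:
            rows[name] = ssgsea_score(expr, GeneSet.from_genes(name, present), alpha=alpha)
    out = pd.DataFrame(rows).T
    out.columns = expr.sample_ids
    return out
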