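"""Two-class gene-set enrichment analysis with phenotype-permutation FDR.

Genes are ranked by a signal-to-noise ratio between two phenotype classes
(floored standard deviations), each pathway gets a weighted
Kolmogorov-Smirnov enrichment score (signed maximum deviation of the
running sum), and significance comes from permuting sample labels:
normalized enrichment scores (NES), matching-sign nominal p-values, and
either the NES-pool FDR convention or plain BH on nominal p-values.
Pathways surviving FDR in several cohorts with a consistent direction are
"common pathways"; pathway activity can also be correlated with the immune
score directly (Spearman, BH-adjusted).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .io import ExpressionMatrix, GeneSetCollection
from .scoring import SignatureScoreMatrix
from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "RankedGeneList",
    "rank_by_snr",
    "gsea_es",
    "gsea_permutation",
    "common_pathways",
    "pathway_immune_correlation",
]


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered by ranking metric, descending; ties broken by gene id."""

    genes: tuple[str, ...]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric differ in length")
        diffs = np.diff(self.metric)
        if np.any(diffs > 1e-12):
            raise ValueError("metric must be sorted descending")


def _snr(values: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Signal-to-noise per gene: (mean_A - mean_B) / (sd_A + sd_B), floored sds.

    Each class sd is floored at max(0.2 * |class mean|, 0.2), the GSEA
    convention that keeps low-variance genes from dominating.
    """
    a = values[:, mask_a]
    b = values[:, ~mask_a]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum(a.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mean_a), 0.2))
    sd_b = np.maximum(b.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mean_b), 0.2))
    return (mean_a - mean_b) / (sd_a + sd_b)


def rank_by_snr(expr: ExpressionMatrix, two_class_labels: pd.Series) -> RankedGeneList:
    """Rank all genes by signal-to-noise between class A and class B.

    ``two_class_labels`` must take exactly two values over the samples of
    ``expr``; the alphabetically first value is class A (positive metric =
    up in A).  Both classes need >= 3 samples.
    """
    y = two_class_labels.loc[expr.sample_ids]
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    mask_a = (y == classes[0]).to_numpy()
    if mask_a.sum() < 3 or (~mask_a).sum() < 3:
        raise ValueError("both classes need >= 3 samples")
    metric = _snr(expr.values, mask_a)
    gene_ids = np.asarray(expr.gene_ids, dtype=object)
    id_rank = np.argsort(np.argsort(gene_ids))
    order = np.lexsort((id_rank, -metric))
    return RankedGeneList(genes=tuple(gene_ids[order]), metric=metric[order])


def _es_from_ordered(
    in_set: np.ndarray, metric: np.ndarray, p_weight: float
) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    ``in_set``: boolean mask in ranked order; hit increments |metric|^p
    normalized over in-set genes, miss increments 1/(N - Nh).
    """
    n = len(in_set)
    n_hit = int(in_set.sum())
    weights = np.abs(metric) ** p_weight
    hit_w = np.where(in_set, weights, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all in-set metrics are exactly zero at p > 0: fall back to uniform
        hit_w = np.where(in_set, 1.0, 0.0)
        total = float(n_hit)
    running = np.cumsum(hit_w / total - np.where(in_set, 0.0, 1.0 / (n - n_hit)))
    return float(running[np.argmax(np.abs(running))])


def gsea_es(ranked: RankedGeneList, gene_set, p_weight: float = 1.0) -> float:
    """Enrichment score of one gene set against a ranked list."""
    genes = np.asarray(ranked.genes, dtype=object)
    in_set = np.isin(genes, list(gene_set.genes))
    n_hit = int(in_set.sum())
    if n_hit < 2:
        raise ValueError(f"gene set {gene_set.name!r}: {n_hit} genes in ranked list (< 2)")
    if n_hit == len(genes):
        raise ValueError("gene set covers the whole ranked list")
    return _es_from_ordered(in_set, ranked.metric, p_weight)


def _all_es(
    values: np.ndarray,
    gene_ids: np.ndarray,
    masks_a: np.ndarray,
    set_members: list[np.ndarray],
    p_weight: float,
) -> np.ndarray:
    """ES for every (class mask, gene set) pair; masks_a is (n_perm, n_samples)."""
    id_rank = np.argsort(np.argsort(gene_ids))
    out = np.empty((masks_a.shape[0], len(set_members)))
    for i, mask in enumerate(masks_a):
        metric = _snr(values, mask)
        order = np.lexsort((id_rank, -metric))
        metric_ord = metric[order]
        for j, members in enumerate(set_members):
            out[i, j] = _es_from_ordered(members[order], metric_ord, p_weight)
    return out


def gsea_permutation(
    expr: ExpressionMatrix,
    labels: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    p_weight: float = 1.0,
    fdr_mode: str = "nes_pool",
) -> pd.DataFrame:
    """Phenotype-permutation GSEA over a collection of pathways.

    Returns one row per scoreable pathway: ES, NES (ES divided by the mean
    |null ES| of matching sign), nominal p from the matching-sign null
    tail, FDR q (``nes_pool`` = the positive/negative NES-pool convention,
    ``bh`` = Benjamini-Hochberg on nominal p), and direction (up_in_A for
    positive ES, where A is the alphabetically first class).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if fdr_mode not in ("nes_pool", "bh"):
        raise ValueError(f"unknown fdr_mode {fdr_mode!r}")
    y = labels.loc[expr.sample_ids]
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    mask_obs = (y == classes[0]).to_numpy()
    n_a = int(mask_obs.sum())
    n = len(mask_obs)
    if n_a < 3 or n - n_a < 3:
        raise ValueError("both classes need >= 3 samples")

    n_distinct = math.comb(n, n_a)
    rng = np.random.default_rng(seed)
    if n_distinct <= n_perm:
        logger.warning(
            "only %d distinct label assignments (< n_perm=%d): using all of them",
            n_distinct,
            n_perm,
        )
        from itertools import combinations

        masks = np.zeros((n_distinct, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n_a)):
            masks[i, list(idx)] = True
    else:
        masks = np.zeros((n_perm, n), dtype=bool)
        for i in range(n_perm):
            masks[i, rng.choice(n, size=n_a, replace=False)] = True

    gene_ids = np.asarray(expr.gene_ids, dtype=object)
    members: list[np.ndarray] = []
    names: list[str] = []
    for gene_set in sets:
        in_set = np.isin(gene_ids, list(gene_set.genes))
        n_hit = int(in_set.sum())
        if n_hit < 2 or n_hit == len(gene_ids):
            logger.warning("pathway %r skipped (%d genes in universe)", gene_set.name, n_hit)
            continue
        members.append(in_set)
        names.append(gene_set.name)
    if not members:
        raise ValueError("no scoreable pathways")

    values = expr.values
    es_obs = _all_es(values, gene_ids, mask_obs[None, :], members, p_weight)[0]
    es_null = _all_es(values, gene_ids, masks, members, p_weight)

    nes_obs = np.empty_like(es_obs)
    nominal_p = np.empty_like(es_obs)
    nes_null = np.full_like(es_null, np.nan)
    for j in range(len(names)):
        null_j = es_null[:, j]
        pos = null_j[null_j >= 0]
        neg = null_j[null_j < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        # normalize null and observed ES by the matching-sign null mean
        with np.errstate(invalid="ignore"):
            nes_null[null_j >= 0, j] = null_j[null_j >= 0] / mean_pos
            nes_null[null_j < 0, j] = null_j[null_j < 0] / mean_neg
        if es_obs[j] >= 0:
            nes_obs[j] = es_obs[j] / mean_pos if pos.size else np.inf
            nominal_p[j] = (pos >= es_obs[j]).sum() / pos.size if pos.size else 0.0
        else:
            nes_obs[j] = es_obs[j] / mean_neg if neg.size else -np.inf
            nominal_p[j] = (neg <= es_obs[j]).sum() / neg.size if neg.size else 0.0

    if fdr_mode == "bh":
        fdr_q = bh_adjust(nominal_p)
    else:
        fdr_q = _nes_pool_fdr(nes_obs, nes_null)

    direction = np.where(es_obs >= 0, f"up_in_{classes[0]}", f"up_in_{classes[1]}")
    out = pd.DataFrame(
        {
            "pathway": names,
            "ES": es_obs,
            "NES": nes_obs,
            "nominal_p": nominal_p,
            "fdr_q": fdr_q,
            "direction": direction,
        }
    ).set_index("pathway")
    out.attrs["classes"] = tuple(classes)
    out.attrs["n_perm"] = masks.shape[0]
    out.attrs["fdr_mode"] = fdr_mode
    return out


def _nes_pool_fdr(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
    """FDR by the GSEA positive/negative NES-pool convention.

    For an observed NES* >= 0: q = [share of pooled null NES >= NES*] /
    [share of observed NES >= NES*] (mirrored for negative), clipped to
    [0, 1] and floored at one pooled-null count to avoid q = 0 claims.
    """
    pool = nes_null[np.isfinite(nes_null)]
    pos_pool = pool[pool >= 0]
    neg_pool = pool[pool < 0]
    pos_obs = nes_obs[nes_obs >= 0]
    neg_obs = nes_obs[nes_obs < 0]
    q = np.empty_like(nes_obs)
    for j, nes in enumerate(nes_obs):
        if nes >= 0:
            null_tail = (pos_pool >= nes).mean() if pos_pool.size else 0.0
            obs_tail = (pos_obs >= nes).mean() if pos_obs.size else 1.0
            null_tail = max(null_tail, 1.0 / max(pos_pool.size, 1))
        else:
            null_tail = (neg_pool <= nes).mean() if neg_pool.size else 0.0
            obs_tail = (neg_obs <= nes).mean() if neg_obs.size else 1.0
            null_tail = max(null_tail, 1.0 / max(neg_pool.size, 1))
        q[j] = min(null_tail / obs_tail, 1.0) if obs_tail > 0 else 1.0
    return q


def common_pathways(
    tables: list[pd.DataFrame], q_threshold: float = 0.05
) -> list[str]:
    """Pathways significant with the same direction in every cohort.

    Intersection across >= 2 enrichment tables of pathways with
    fdr_q < q_threshold; a pathway significant but in opposite directions
    is excluded.  An empty intersection is a valid (empty) result.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 enrichment tables")
    surviving: list[dict[str, str]] = []
    for table in tables:
        sig = table[table["fdr_q"] < q_threshold]
        surviving.append(dict(zip(sig.index, sig["direction"])))
    common = set(surviving[0])
    for d in surviving[1:]:
        common &= set(d)
    consistent = [
        p for p in common if len({d[p] for d in surviving}) == 1
    ]
    return sorted(consistent)


def pathway_immune_correlation(
    pathway_scores: SignatureScoreMatrix, immune_score: pd.Series
) -> pd.DataFrame:
    """Spearman correlation of each pathway's activity with the immune score.

    Returns rho, p, and BH-adjusted q per pathway; constant pathway rows
    are flagged (rho undefined) and excluded from the adjustment.
    """
    samples = pathway_scores.sample_ids
    if len(samples) < 4:
        raise ValueError("need >= 4 samples")
    imm = immune_score.loc[samples].to_numpy(dtype=float)
    rows = []
    for name in pathway_scores.signature_names:
        vals = pathway_scores.data.loc[name].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            rows.append({"pathway": name, "rho": np.nan, "p": np.nan, "constant": True})
            continue
        rho, p = sps.spearmanr(vals, imm)
        rows.append({"pathway": name, "rho": float(rho), "p": float(p), "constant": False})
    out = pd.DataFrame(rows).set_index("pathway")
    out["q"] = np.nan
    ok = ~out["constant"]
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
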