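"""Discovery and labeling of the three immunity subtypes.

Samples are clustered hierarchically (per-signature z-score, Euclidean
distance, Ward linkage, tree cut at k = 3) on their signature-score
profiles, then clusters are ordered by median immune score and labeled
Immunity_H / Immunity_M / Immunity_L from highest to lowest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .scoring import SignatureScoreMatrix
from .stats import TestResult, anova, kruskal_wallis

logger = logging.getLogger(__name__)

__all__ = ["SubtypeAssignment", "SUBTYPE_LABELS", "cluster_samples", "label_clusters",
           "compare_subtype_feature"]

#: Ordered labels, highest immune score first.
SUBTYPE_LABELS = ("Immunity_H", "Immunity_M", "Immunity_L")


@dataclass(frozen=True)
class SubtypeAssignment:
    """Per-sample cluster index (0-based) and, once labeled, subtype label.

    ``linkage_matrix`` records the merge history; ``params`` the distance,
    linkage method, and k used.
    """

    sample_ids: tuple[str, ...]
    cluster_index: np.ndarray
    linkage_matrix: np.ndarray
    params: dict
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.cluster_index):
            raise ValueError("sample ids and cluster indices differ in length")
        if self.labels is not None and len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must cover every sample")

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_index.max()) + 1

    def label_of(self, sample_id: str) -> str:
        if self.labels is None:
            raise ValueError("assignment is unlabeled")
        return self.labels[self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"sample_id": self.sample_ids, "cluster": self.cluster_index}
        )
        if self.labels is not None:
            out["label"] = self.labels
        return out


def cluster_samples(scores: SignatureScoreMatrix, k: int = 3) -> SubtypeAssignment:
    """Ward hierarchical clustering of samples in signature-score space.

    Signatures are z-scored across samples first; zero-variance signatures
    are dropped with a warning.  Deterministic given input order.
    """
    n_samples = len(scores.sample_ids)
    if n_samples < k:
        raise ValueError(f"{n_samples} samples < k = {k}")
    data = scores.data
    sd = data.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "dropping %d zero-variance signatures before z-scoring: %s",
            int(flat.sum()),
            list(data.index[flat])[:5],
        )
        data = data.loc[~flat]
        sd = sd[~flat]
    if data.shape[0] < 2:
        raise ValueError("need >= 2 signatures with nonzero variance")
    z = data.sub(data.mean(axis=1), axis=0).div(sd, axis=0)
    link = linkage(z.to_numpy().T, method="ward", metric="euclidean")
    clusters = fcluster(link, t=k, criterion="maxclust") - 1
    return SubtypeAssignment(
        sample_ids=tuple(scores.sample_ids),
        cluster_index=clusters,
        linkage_matrix=link,
        params={"distance": "euclidean", "linkage": "ward", "k": k, "zscore": True},
    )


def label_clusters(
    assignment: SubtypeAssignment, immune_score: pd.Series
) -> SubtypeAssignment:
    """Order clusters by median immune score and attach Immunity_H/M/L labels.

    Highest median -> Immunity_H, lowest -> Immunity_L.  Ties are broken by
    cluster size (larger ranks higher), then by cluster index.  With k != 3
    the labels are Immunity_1 (highest) .. Immunity_k (lowest).
    """
    missing = [s for s in assignment.sample_ids if s not in immune_score.index]
    if missing:
        raise ValueError(f"immune score missing for samples: {missing[:5]}")
    scores = immune_score.loc[list(assignment.sample_ids)].to_numpy(dtype=float)
    cluster_ids = np.unique(assignment.cluster_index)
    medians = {c: float(np.median(scores[assignment.cluster_index == c])) for c in cluster_ids}
    sizes = {c: int((assignment.cluster_index == c).sum()) for c in cluster_ids}
    # sort descending by (median, size), ascending by index for full determinism
    ranked = sorted(cluster_ids, key=lambda c: (-medians[c], -sizes[c], c))
    if len(cluster_ids) == 3:
        names = SUBTYPE_LABELS
    else:
        names = tuple(f"Immunity_{i + 1}" for i in range(len(cluster_ids)))
    label_of_cluster = {c: names[rank] for rank, c in enumerate(ranked)}
    labels = tuple(label_of_cluster[c] for c in assignment.cluster_index)
    return SubtypeAssignment(
        sample_ids=assignment.sample_ids,
        cluster_index=assignment.cluster_index,
        linkage_matrix=assignment.linkage_matrix,
        params={**assignment.params, "label_order": [label_of_cluster[c] for c in cluster_ids]},
        labels=labels,
    )


def compare_subtype_feature(
    feature: pd.Series, assignment: SubtypeAssignment, test: str = "kruskal_wallis"
) -> TestResult:
    """Compare a per-sample feature across subtype groups.

    ``test`` is ``kruskal_wallis`` or ``anova``; every group must have at
    least two samples.
    """
    if assignment.labels is None:
        groups_keys = [str(c) for c in assignment.cluster_index]
    else:
        groups_keys = list(assignment.labels)
    values = feature.loc[list(assignment.sample_ids)].to_numpy(dtype=float)
    by_group: dict[str, np.ndarray] = {}
    for key in dict.fromkeys(groups_keys):
        mask = np.asarray([g == key for g in groups_keys])
        by_group[key] = values[mask]
    if len(by_group) < 2:
        raise ValueError("need >= 2 groups")
    for key, vals in by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {key!r} has {len(vals)} sample(s), need >= 2")
    arrays = list(by_group.values())
    if test == "kruskal_wallis":
        return kruskal_wallis(*arrays)
    if test == "anova":
        return anova(*arrays)
    raise ValueError(f"unknown test {test!r}")
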