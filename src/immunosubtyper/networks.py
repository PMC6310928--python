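"""Co-expression networks, simplified module detection, and hub genes.

Edges carry soft-powered adjacency weights w = |pearson r|^beta.  Modules
come from average-linkage clustering of the 1 - w distance with a static
tree cut (a deliberate simplification of full weighted co-expression
module detection; topological overlap and dynamic tree cutting are out of
scope).  A hub gene is a gene connected to at least ``min_neighbors``
other genes with weight strictly greater than ``min_weight`` — by default
>= 10 neighbors at w > 0.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix, GeneSet
from .scoring import ssgsea_score
from .stats import bh_adjust, kruskal_wallis, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionNetwork",
    "GeneModule",
    "build_network",
    "detect_modules",
    "module_subtype_association",
    "find_hubs",
    "extract_subnetwork",
]


@dataclass(frozen=True)
class CoexpressionNetwork:
    """Symmetric gene-gene adjacency with weights in [0, 1]."""

    genes: tuple[str, ...]
    weights: np.ndarray  # (n_genes, n_genes), zero diagonal
    beta: float

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape != (len(self.genes), len(self.genes)):
            raise ValueError("weight matrix shape mismatch")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any((w < 0) | (w > 1)):
            raise ValueError("weights must lie in [0, 1]")

    def weight(self, a: str, b: str) -> float:
        i, j = self.genes.index(a), self.genes.index(b)
        return float(self.weights[i, j])

    def edge_list(self, min_weight: float = 0.0) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.genes), k=1)
        keep = self.weights[iu, ju] > min_weight
        return pd.DataFrame(
            {
                "gene_a": np.asarray(self.genes, dtype=object)[iu[keep]],
                "gene_b": np.asarray(self.genes, dtype=object)[ju[keep]],
                "weight": self.weights[iu[keep], ju[keep]],
            }
        )


@dataclass(frozen=True)
class GeneModule:
    label: str
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


def build_network(expr: ExpressionMatrix, beta: float = 6.0) -> CoexpressionNetwork:
    """Soft-powered co-expression adjacency: w = |pearson r|^beta.

    Zero-variance genes are dropped with a warning; fewer than 8 samples
    is an error (pairwise correlations too unstable to power a network).
    """
    if expr.n_samples < 8:
        raise ValueError(f"{expr.n_samples} samples < 8: correlations unstable")
    values = expr.values
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance genes", int((~keep).sum()))
        values = values[keep]
    genes = tuple(np.asarray(expr.gene_ids, dtype=object)[keep])
    if len(genes) < 2:
        raise ValueError("need >= 2 genes with nonzero variance")
    r = np.corrcoef(values)
    w = np.abs(np.clip(r, -1.0, 1.0)) ** beta
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2  # enforce exact symmetry against fp noise
    return CoexpressionNetwork(genes=genes, weights=w, beta=beta)


def detect_modules(
    net: CoexpressionNetwork, min_size: int = 10, cut_height: float = 0.95
) -> tuple[list[GeneModule], GeneModule]:
    """Average-linkage clustering of 1 - w with a static cut.

    Clusters of size >= ``min_size`` become modules (labeled M1, M2, ... in
    decreasing size); everything else pools into the grey module.  Returns
    (modules, grey).
    """
    n = len(net.genes)
    if n < min_size:
        raise ValueError(f"{n} genes < min_size {min_size}")
    dist = 1.0 - net.weights
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = linkage(condensed, method="average")
    clusters = fcluster(link, t=cut_height, criterion="distance")
    genes = np.asarray(net.genes, dtype=object)
    modules: list[GeneModule] = []
    grey: list[str] = []
    ids, counts = np.unique(clusters, return_counts=True)
    # larger clusters first; cluster id breaks ties for determinism
    for cid in ids[np.lexsort((ids, -counts))]:
        members = tuple(genes[clusters == cid])
        if len(members) >= min_size:
            modules.append(GeneModule(label=f"M{len(modules) + 1}", genes=members))
        else:
            grey.extend(members)
    if not modules:
        logger.warning("no module reached min_size=%d; all genes grey", min_size)
    return modules, GeneModule(label="grey", genes=tuple(grey))


def module_subtype_association(
    module: GeneModule, expr: ExpressionMatrix, assignment
) -> pd.DataFrame:
    """How strongly a module's activity separates the subtypes.

    Module activity is the ssGSEA score of the module's gene set (a
    single-gene module uses that gene's expression row).  Reports the
    Kruskal-Wallis p across subtypes and, per subtype, a one-vs-rest
    Mann-Whitney p with BH adjustment across subtypes.
    """
    if not module.genes:
        raise ValueError("empty module")
    present = [g for g in module.genes if g in set(expr.gene_ids)]
    if not present:
        raise ValueError(f"module {module.label!r} has no genes in the matrix")
    if len(present) == 1:
        activity = expr.data.loc[present[0]].astype(float)
    else:
        activity = ssgsea_score(expr, GeneSet.from_genes(module.label, present))
    labels = assignment.labels if assignment.labels is not None else tuple(
        str(c) for c in assignment.cluster_index
    )
    act = activity.loc[list(assignment.sample_ids)].to_numpy(dtype=float)
    label_arr = np.asarray(labels, dtype=object)
    groups = [act[label_arr == lab] for lab in dict.fromkeys(labels)]
    kw = kruskal_wallis(*groups)
    rows = []
    for lab in dict.fromkeys(labels):
        mask = label_arr == lab
        mw = mann_whitney(act[mask], act[~mask])
        rows.append(
            {
                "subtype": lab,
                "median_activity": float(np.median(act[mask])),
                "mw_p": mw.p_value,
            }
        )
    out = pd.DataFrame(rows).set_index("subtype")
    out["mw_q"] = bh_adjust(out["mw_p"].to_numpy())
    out.attrs["kruskal_p"] = kw.p_value
    out.attrs["kruskal_statistic"] = kw.statistic
    out.attrs["module"] = module.label
    return out


def find_hubs(
    net: CoexpressionNetwork,
    restrict_to: list[str] | None = None,
    min_neighbors: int = 10,
    min_weight: float = 0.25,
) -> list[str]:
    """Genes with >= min_neighbors edges of weight strictly > min_weight.

    ``restrict_to`` limits which genes may be called hubs; neighbors are
    still counted over the whole network.  An empty result is allowed.
    """
    degree = (net.weights > min_weight).sum(axis=1)
    genes = np.asarray(net.genes, dtype=object)
    hubs = genes[degree >= min_neighbors]
    if restrict_to is not None:
        allowed = set(restrict_to)
        hubs = [g for g in hubs if g in allowed]
    return list(hubs)


def extract_subnetwork(
    net: CoexpressionNetwork, seed_genes: list[str], min_weight: float = 0.25
) -> pd.DataFrame:
    """Seeds plus every neighbor attached to a seed above threshold.

    Returns the induced edge list (gene_a, gene_b, weight) over that node
    set, keeping only edges with w > min_weight.  Seed genes with no
    qualifying edge still appear (as isolated rows with gene_b = NaN is
    avoided: isolated seeds are reported via the attrs['nodes'] list).
    """
    present = [g for g in seed_genes if g in net.genes]
    if not present:
        raise ValueError(f"no seed genes present in network: {seed_genes[:5]}")
    idx = {g: i for i, g in enumerate(net.genes)}
    seed_idx = np.asarray([idx[g] for g in present])
    attached = (net.weights[seed_idx] > min_weight).any(axis=0)
    node_mask = attached.copy()
    node_mask[seed_idx] = True
    nodes = np.flatnonzero(node_mask)
    genes = np.asarray(net.genes, dtype=object)
    sub_w = net.weights[np.ix_(nodes, nodes)]
    iu, ju = np.triu_indices(len(nodes), k=1)
    keep = sub_w[iu, ju] > min_weight
    edges = pd.DataFrame(
        {
            "gene_a": genes[nodes[iu[keep]]],
            "gene_b": genes[nodes[ju[keep]]],
            "weight": sub_w[iu[keep], ju[keep]],
        }
    )
    edges.attrs["nodes"] = list(genes[nodes])
    edges.attrs["seeds"] = present
    return edges
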