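"""Synthetic cohorts with planted immune-subtype structure.

The generator emulates the statistical shape of a log-scale bulk
expression cohort of a triple-negative breast cancer study: three latent
subtypes in which a designated collection of immune-signature genes is
coordinately up- (H), intermediately- (M), or down-regulated (L);
correlated co-expression blocks driven by a shared latent factor with one
highly loaded hub gene per block; pathway blocks coupled (or
anti-coupled) to the immune axis; and exponential survival with a
subtype-dependent hazard plus independent censoring.  Everything is
reproducible from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_cohort",
           "generate_two_cohorts", "planted_truth_report"]

_SUBTYPES = ("Immunity_H", "Immunity_M", "Immunity_L")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Effect sizes are additive shifts in log-expression units applied to
    immune-signature genes: delta_H for subtype H samples, delta_M for M,
    zero for L.  Co-expression blocks share a latent factor; member genes
    load at a level implied by ``within_block_r`` and each block's hub
    gene loads at ``hub_loading`` noise-sd units.  Survival times are
    exponential with rate = baseline_hazard * multiplier(subtype).
    """

    n_per_subtype: tuple[int, int, int] = (100, 100, 100)
    n_genes: int = 5000
    n_signatures: int = 29
    signature_size_range: tuple[int, int] = (10, 30)
    delta_h: float = 1.0
    delta_m: float = 0.5
    noise_sd: float = 1.0
    n_coexpr_blocks: int = 5
    coexpr_block_size: int = 20
    within_block_r: float = 0.7
    hub_loading: float = 4.0
    n_pathway_blocks: int = 4
    pathway_block_size: int = 15
    pathway_coupling: float = 0.6
    baseline_hazard: float = 0.1
    hazard_multipliers: tuple[float, float, float] = (0.5, 1.0, 1.0)
    censoring_rate: float = 0.3
    stromal_set_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_subtype):
            raise ValueError("subtype sizes must be positive")
        if not (self.delta_h > self.delta_m >= 0):
            raise ValueError("need delta_h > delta_m >= 0")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not (0 < self.within_block_r < 1):
            raise ValueError("within_block_r must lie in (0, 1)")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    expression: ExpressionMatrix
    truth: pd.Series  # sample_id -> planted subtype
    clinical: ClinicalTable
    signatures: GeneSetCollection
    immune_set: GeneSet
    stromal_set: GeneSet
    coupled_pathways: GeneSetCollection
    anticoupled_pathways: GeneSetCollection
    coexpr_blocks: tuple[tuple[str, ...], ...]
    hub_genes: tuple[str, ...]
    config: GeneratorConfig = field(repr=False)


#: Seed of the structure stream: signature sizes and gene means belong to
#: the study design, so they are shared by every cohort drawn from the same
#: config (only sampling noise varies with ``config.seed``).
_STRUCTURE_SEED = 715517


def _partition_genes(cfg: GeneratorConfig, rng: np.random.Generator):
    """Reserve disjoint gene index ranges for every planted structure."""
    sig_sizes = rng.integers(
        cfg.signature_size_range[0], cfg.signature_size_range[1] + 1, cfg.n_signatures
    )
    needed = (
        int(sig_sizes.sum())
        + cfg.n_coexpr_blocks * cfg.coexpr_block_size
        + cfg.n_pathway_blocks * cfg.pathway_block_size * 2
        + cfg.stromal_set_size
    )
    if cfg.n_genes < needed:
        raise ValueError(
            f"n_genes={cfg.n_genes} smaller than total planted-set size {needed}"
        )
    cursor = 0
    sig_idx = []
    for size in sig_sizes:
        sig_idx.append(np.arange(cursor, cursor + size))
        cursor += int(size)
    blocks = []
    for _ in range(cfg.n_coexpr_blocks):
        blocks.append(np.arange(cursor, cursor + cfg.coexpr_block_size))
        cursor += cfg.coexpr_block_size
    coupled, anticoupled = [], []
    for _ in range(cfg.n_pathway_blocks):
        coupled.append(np.arange(cursor, cursor + cfg.pathway_block_size))
        cursor += cfg.pathway_block_size
    for _ in range(cfg.n_pathway_blocks):
        anticoupled.append(np.arange(cursor, cursor + cfg.pathway_block_size))
        cursor += cfg.pathway_block_size
    stromal = np.arange(cursor, cursor + cfg.stromal_set_size)
    cursor += cfg.stromal_set_size
    return sig_idx, blocks, coupled, anticoupled, stromal


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw one cohort under ``config``; identical seeds give identical cohorts."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    structure_rng = np.random.default_rng(_STRUCTURE_SEED)
    n_samples = sum(cfg.n_per_subtype)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]

    subtype_of = np.repeat(np.arange(3), cfg.n_per_subtype)
    rng.shuffle(subtype_of)
    truth = pd.Series(
        [_SUBTYPES[s] for s in subtype_of], index=sample_ids, name="subtype"
    )

    sig_idx, blocks, coupled, anticoupled, stromal_idx = _partition_genes(
        cfg, structure_rng
    )

    # baseline: gene means drawn once per study design, i.i.d. noise per cohort
    gene_means = structure_rng.normal(loc=6.0, scale=1.5, size=cfg.n_genes)
    X = gene_means[:, None] + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, n_samples))

    # planted immune-signature shifts: H up by delta_h, M by delta_m, L flat
    delta = np.array([cfg.delta_h, cfg.delta_m, 0.0])[subtype_of]
    all_sig_genes = np.concatenate(sig_idx)
    X[np.ix_(all_sig_genes, np.arange(n_samples))] += delta[None, :]

    # stromal genes track the immune axis at reduced amplitude (stromal
    # content co-varies with infiltration, as observed in bulk cohorts)
    X[stromal_idx] += 0.5 * delta[None, :]

    # co-expression blocks: shared latent factor, hub gene loaded highest
    r = cfg.within_block_r
    member_loading = cfg.noise_sd * np.sqrt(r / (1 - r))
    hub_genes = []
    for block in blocks:
        factor = rng.normal(0.0, 1.0, n_samples)
        loadings = np.full(len(block), member_loading)
        loadings[0] = cfg.hub_loading * cfg.noise_sd
        hub_genes.append(gene_ids[block[0]])
        X[block] += loadings[:, None] * factor[None, :]

    # pathway blocks coupled / anti-coupled to the immune axis
    coupling = cfg.pathway_coupling
    for block in coupled:
        X[block] += coupling * delta[None, :]
    anti_delta = np.array([0.0, cfg.delta_m, cfg.delta_h])[subtype_of]
    for block in anticoupled:
        X[block] += coupling * anti_delta[None, :]

    expression = ExpressionMatrix(
        pd.DataFrame(X, index=gene_ids, columns=sample_ids)
    )

    signatures = GeneSetCollection.from_sets(
        GeneSet.from_genes(
            f"ImmuneSig{k + 1:02d}", [gene_ids[i] for i in idx], "planted immune signature"
        )
        for k, idx in enumerate(sig_idx)
    )
    immune_set = GeneSet.from_genes(
        "ImmuneUnion", [gene_ids[i] for i in all_sig_genes], "union of planted signatures"
    )
    stromal_set = GeneSet.from_genes(
        "StromalSet", [gene_ids[i] for i in stromal_idx], "planted stromal signature"
    )
    coupled_sets = GeneSetCollection.from_sets(
        GeneSet.from_genes(f"CoupledPathway{k + 1}", [gene_ids[i] for i in idx])
        for k, idx in enumerate(coupled)
    )
    anticoupled_sets = GeneSetCollection.from_sets(
        GeneSet.from_genes(f"AnticoupledPathway{k + 1}", [gene_ids[i] for i in idx])
        for k, idx in enumerate(anticoupled)
    )

    # survival: exponential with subtype hazard, Bernoulli censoring with
    # the censored time drawn uniformly below the latent event time
    rates = cfg.baseline_hazard * np.asarray(cfg.hazard_multipliers)[subtype_of]
    event_times = rng.exponential(1.0 / rates)
    censored = rng.random(n_samples) < cfg.censoring_rate
    observed = np.where(censored, event_times * rng.random(n_samples), event_times)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "time": observed,
                "event": (~censored).astype(int),
            }
        ),
        endpoint="OS",
    )

    return SyntheticCohort(
        expression=expression,
        truth=truth,
        clinical=clinical,
        signatures=signatures,
        immune_set=immune_set,
        stromal_set=stromal_set,
        coupled_pathways=coupled_sets,
        anticoupled_pathways=anticoupled_sets,
        coexpr_blocks=tuple(
            tuple(gene_ids[i] for i in block) for block in blocks
        ),
        hub_genes=tuple(hub_genes),
        config=cfg,
    )


def generate_two_cohorts(
    config: GeneratorConfig, seeds: tuple[int, int]
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Two cohorts with identical planted structure and independent noise.

    Gene ids, signature membership, and effect sizes are shared; samples
    and noise are drawn independently per seed.
    """
    if seeds[0] == seeds[1]:
        logger.warning("identical seeds: the two cohorts will be identical")
    a = generate_cohort(replace(config, seed=seeds[0]))
    b = generate_cohort(replace(config, seed=seeds[1]))
    return a, b


def planted_truth_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """Summary of the realized planted structure, for assertions.

    One row per subtype: sample count, realized mean shift of signature
    genes relative to subtype L, plus cohort-level realized censoring
    fraction in the attrs.
    """
    sig_genes = sorted(cohort.immune_set.genes)
    expr = cohort.expression.data.loc[sig_genes]
    truth = cohort.truth
    ref = expr.loc[:, truth[truth == "Immunity_L"].index].to_numpy().mean()
    rows = []
    for subtype in _SUBTYPES:
        samples = truth[truth == subtype].index
        mean_shift = expr.loc[:, samples].to_numpy().mean() - ref
        rows.append(
            {"subtype": subtype, "n": len(samples), "realized_shift": mean_shift}
        )
    out = pd.DataFrame(rows).set_index("subtype")
    out.attrs["censoring_fraction"] = float(1 - cohort.clinical.events.mean())
    out.attrs["n_genes"] = cohort.expression.n_genes
    return out
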