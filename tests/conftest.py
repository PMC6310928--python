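"""Shared fixtures: small hand-built matrices and the default synthetic cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import immunosubtyper as ims


@pytest.fixture(scope="session")
def tiny_expr() -> ims.ExpressionMatrix:
    """4-gene, 1-sample matrix with a clean ranking g1 > g2 > g3 > g4."""
    return ims.ExpressionMatrix(
        pd.DataFrame({"s1": [4.0, 3.0, 2.0, 1.0]}, index=["g1", "g2", "g3", "g4"])
    )


@pytest.fixture(scope="session")
def default_cohort() -> ims.SyntheticCohort:
    """The default study conditions: 100 samples per subtype, 5000 genes,
    29 signatures, delta_H = 1.0, delta_M = 0.5, noise_sd = 1."""
    return ims.generate_cohort(ims.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def default_scores(default_cohort) -> ims.SignatureScoreMatrix:
    return ims.score_collection(default_cohort.expression, default_cohort.signatures)


@pytest.fixture(scope="session")
def default_estimate(default_cohort) -> ims.EstimateResult:
    return ims.estimate_scores(
        default_cohort.expression,
        default_cohort.immune_set,
        default_cohort.stromal_set,
    )


@pytest.fixture(scope="session")
def labeled_assignment(default_scores, default_estimate) -> ims.SubtypeAssignment:
    assignment = ims.cluster_samples(default_scores, k=3)
    return ims.label_clusters(assignment, default_estimate.immune_score)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
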