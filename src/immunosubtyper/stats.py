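"""Statistical tests and survival procedures used across the pipeline.

Thin, contract-checked wrappers around scipy / statsmodels / lifelines:
rank tests and ANOVA for subtype comparisons, Fisher's exact test for
categorical association, Benjamini-Hochberg adjustment, the Kaplan-Meier
product-limit estimator, the log-rank test, and the median-split survival
comparison (samples strictly above vs strictly below the median; samples
equal to the median are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

from .io import ClinicalTable

__all__ = [
    "TestResult",
    "SurvivalCurve",
    "km_estimate",
    "logrank_test",
    "median_split_survival",
    "fisher_exact_2x2",
    "bh_adjust",
    "mann_whitney",
    "kruskal_wallis",
    "anova",
    "spearman",
]


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...] = ()
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError(f"{self.test}: non-finite statistic")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.test}: p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan-Meier step function: S(t) at each distinct event time.

    ``times`` ascend, ``survival`` is non-increasing with S(0) = 1 implied,
    ``at_risk`` counts subjects at risk just before each time, and
    ``censor_times`` marks censored observation times.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must ascend")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if self.survival.size and (self.survival[0] > 1 or self.survival[-1] < 0):
            raise ValueError("survival outside [0, 1]")

    def probability_at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous step)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit survival estimate.

    With only censored observations the estimate is identically 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # drop the t=0 anchor row lifelines prepends (unless 0 is an actual time)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if grid.size and grid[0] == 0.0 and 0.0 not in times:
        grid, surv = grid[1:], surv[1:]
    at_risk = np.array([(times >= t).sum() for t in grid], dtype=int)
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(times[events == 0]),
    )


def logrank_test(group_a: tuple, group_b: tuple) -> TestResult:
    """Two-group log-rank test (chi-square, 1 df, no continuity correction)."""
    t_a, e_a = (np.asarray(x) for x in group_a)
    t_b, e_b = (np.asarray(x) for x in group_b)
    if len(t_a) < 2 or len(t_b) < 2:
        raise ValueError("both groups need >= 2 subjects")
    if e_a.sum() + e_b.sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(t_a, t_b, event_observed_A=e_a, event_observed_B=e_b)
    return TestResult(
        test="logrank",
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes=(len(t_a), len(t_b)),
    )


def median_split_survival(
    expr_row: pd.Series, clinical: ClinicalTable
) -> tuple[TestResult, SurvivalCurve, SurvivalCurve]:
    """Survival difference between high and low expressors of one gene.

    High = strictly above the median, low = strictly below; samples equal
    to the median are excluded.  Either group ending up with fewer than two
    subjects is an error.
    """
    common = [s for s in clinical.sample_ids if s in expr_row.index]
    if len(common) < 4:
        raise ValueError("need >= 4 samples with both expression and clinical records")
    values = expr_row.loc[common].to_numpy(dtype=float)
    clin = clinical.data.set_index("sample_id").loc[common]
    med = float(np.median(values))
    high = values > med
    low = values < med
    n_excluded = int((~high & ~low).sum())
    if high.sum() < 2 or low.sum() < 2:
        raise ValueError(
            f"median split leaves groups of {int(high.sum())} and {int(low.sum())} "
            f"({n_excluded} samples at the median excluded); need >= 2 each"
        )
    t = clin["time"].to_numpy(dtype=float)
    e = clin["event"].to_numpy(dtype=int)
    result = logrank_test((t[high], e[high]), (t[low], e[low]))
    result = TestResult(
        test="logrank_median_split",
        statistic=result.statistic,
        p_value=result.p_value,
        group_sizes=result.group_sizes,
        extra={"median": med, "n_excluded_at_median": n_excluded},
    )
    return result, km_estimate(t[high], e[high]), km_estimate(t[low], e[low])


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arr_f = np.asarray(table, dtype=float)
        if np.any(arr_f < 0) or np.any(arr_f != np.round(arr_f)):
            raise ValueError("cells must be non-negative integers")
        arr = arr_f.astype(int)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        test="fisher_exact",
        statistic=float(odds) if np.isfinite(odds) else float(arr[0, 0]),
        p_value=float(p),
        group_sizes=tuple(arr.sum(axis=1)),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def mann_whitney(x, y) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need >= 2 samples")
    if np.ptp(np.concatenate([x, y])) == 0:
        return TestResult("mann_whitney", float(len(x) * len(y) / 2), 1.0, (len(x), len(y)))
    stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult("mann_whitney", float(stat), float(p), (len(x), len(y)))


def kruskal_wallis(*groups) -> TestResult:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 samples")
    if np.ptp(np.concatenate(groups)) == 0:
        return TestResult("kruskal_wallis", 0.0, 1.0, tuple(len(g) for g in groups))
    stat, p = sps.kruskal(*groups)
    return TestResult("kruskal_wallis", float(stat), float(p), tuple(len(g) for g in groups))


def anova(*groups) -> TestResult:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 samples")
    stat, p = sps.f_oneway(*groups)
    return TestResult("anova", float(stat), float(p), tuple(len(g) for g in groups))


def spearman(x, y) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p), (len(x),))
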