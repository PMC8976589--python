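"""Statistical battery for the two-group, two-timepoint comparison.

Implements the tests used to compare culture-positive with
culture-negative episodes: Mann-Whitney U (tie-corrected asymptotic or
exact), Pearson chi-square without continuity correction (Yates
available), the two-sided Fisher exact test under the probability-mass
convention, and ROC analysis with the Hanley-McNeil standard error.

The nonparametric machinery is delegated to scipy; the ROC/AUC result
(rank-based AUC, Hanley-McNeil SE, Wald CI, null-variance z test
against AUC = 0.5) is assembled here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .cohort_io import Cohort
from .score_core import MissingPolicy, Rubric, DEFAULT_RUBRIC, compute_breakdown

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "RocResult",
    "Orientation",
    "GroupComparison",
    "mann_whitney",
    "chi2_uncorrected",
    "chi2_yates",
    "fisher_two_sided",
    "roc_auc",
    "hanley_mcneil_se",
    "compare_groups",
    "extract_variable",
    "select_test",
    "StatsError",
    "SCORE_VARIABLES",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class StatsError(ValueError):
    """Raised for inputs on which a statistic is undefined."""


class Orientation(str, Enum):
    HIGHER_PREDICTS_POSITIVE = "higher_predicts_positive"
    LOWER_PREDICTS_POSITIVE = "lower_predicts_positive"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = culture-negative / culture-positive and
    columns = indicator-present / indicator-absent."""

    a: int  # negative group, indicator present
    b: int  # negative group, indicator absent
    c: int  # positive group, indicator present
    d: int  # positive group, indicator absent

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise StatsError(f"cell {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def expected(self) -> np.ndarray:
        r1, r2, c1, c2 = self.margins()
        n = self.total
        if n == 0:
            raise StatsError("empty contingency table")
        return np.outer([r1, r2], [c1, c2]) / n


@dataclass(frozen=True)
class TestResult:
    p_value: float
    method: str
    statistic: Optional[float] = None
    df: Optional[int] = None
    n_used: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise StatsError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class RocResult:
    """AUC with Hanley-McNeil standard error and Wald 95% CI.

    ``auc`` is computed after applying ``orientation`` (values are
    negated under ``lower_predicts_positive``), so it is the probability
    that a randomly chosen culture-positive episode looks *more
    suspicious* than a randomly chosen negative one, ties counting 1/2.
    ``p_value`` tests AUC = 0.5 by a z test with the null-variance form
    (N+1)/(12 n_pos n_neg).
    """

    auc: float
    orientation: Orientation
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise StatsError("CI does not bracket the AUC")


# -- rank tests -------------------------------------------------------------

def _clean(sample: Sequence, name: str) -> np.ndarray:
    arr = np.asarray([v for v in sample if v is not None], dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise StatsError(f"group {name!r} is empty after missing-value removal")
    return arr


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "asymptotic",
    exact_limit: int = 25,
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode="asymptotic"`` uses the tie-corrected normal approximation
    without continuity correction.  ``mode="exact_if_small"`` enumerates
    the exact permutation distribution when the pooled sample has no
    ties and at most ``exact_limit`` observations, falling back to the
    asymptotic form otherwise.  The U statistic reported is the one for
    the first sample, from mid-ranks.
    """
    if mode not in ("asymptotic", "exact_if_small"):
        raise ValueError(f"unknown mode {mode!r}")
    xa, ya = _clean(x, "x"), _clean(y, "y")
    pooled = np.concatenate([xa, ya])
    n1, n2 = xa.size, ya.size
    if np.ptp(pooled) == 0.0:
        # all observations tied: no evidence either way
        return TestResult(p_value=1.0, method="mann_whitney_asymptotic",
                          statistic=n1 * n2 / 2.0, n_used=(n1, n2))
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (mode == "exact_if_small" and not has_ties and n1 + n2 <= exact_limit)
    scipy_method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided",
                           method=scipy_method, use_continuity=False)
    method = "mann_whitney_exact" if use_exact else "mann_whitney_asymptotic"
    return TestResult(p_value=min(float(res.pvalue), 1.0), method=method,
                      statistic=float(res.statistic), n_used=(n1, n2))


# -- contingency tests ------------------------------------------------------

def _chi2(table: ContingencyTable2x2, correction: bool) -> TestResult:
    if min(table.margins()) == 0:
        raise StatsError("chi-square statistic undefined: a margin is zero")
    res = sps.chi2_contingency(table.as_array(), correction=correction)
    method = "chi2_yates" if correction else "chi2_uncorrected"
    return TestResult(p_value=float(res.pvalue), method=method,
                      statistic=float(res.statistic), df=1,
                      n_used=(table.a + table.b, table.c + table.d))


def chi2_uncorrected(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    return _chi2(table, correction=False)


def chi2_yates(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-square with the Yates continuity correction."""
    return _chi2(table, correction=True)


def fisher_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test, probability-mass convention.

    The p-value sums the hypergeometric probabilities of every table
    with the observed margins whose probability does not exceed that of
    the observed table.
    """
    if table.total == 0:
        raise StatsError("empty contingency table")
    res = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return TestResult(p_value=min(float(res.pvalue), 1.0), method="fisher_two_sided",
                      n_used=(table.a + table.b, table.c + table.d))


def select_test(table: ContingencyTable2x2, policy: str = "auto") -> TestResult:
    """Run the contingency test chosen by ``policy``.

    ``auto`` follows the classic expected-cell rule: Fisher's exact test
    whenever any expected cell count is below 5, the uncorrected
    chi-square otherwise.
    """
    if policy == "chi2":
        return chi2_uncorrected(table)
    if policy == "fisher":
        return fisher_two_sided(table)
    if policy != "auto":
        raise ValueError(f"unknown test policy {policy!r}")
    if min(table.margins()) == 0 or table.expected().min() < 5.0:
        return fisher_two_sided(table)
    return chi2_uncorrected(table)


# -- ROC --------------------------------------------------------------------

def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) identity, ties counted 1/2."""
    pooled = np.concatenate([pos, neg])
    ranks = sps.rankdata(pooled)
    r_pos = ranks[: pos.size].sum()
    u_pos = r_pos - pos.size * (pos.size + 1) / 2.0
    return u_pos / (pos.size * neg.size)


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of a rank AUC.

    Uses Q1 = A/(2-A) and Q2 = 2A^2/(1+A), the classic approximation
    derived under an exponential-score model.
    """
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a))
    return math.sqrt(max(var, 0.0) / (n_pos * n_neg))


def roc_auc(
    values: Sequence[float],
    labels: Sequence[bool],
    orientation: Orientation = Orientation.HIGHER_PREDICTS_POSITIVE,
) -> RocResult:
    """Rank-based AUC for a marker against the culture outcome.

    Pairs with missing values are dropped.  Under
    ``lower_predicts_positive`` the marker is negated before ranking.
    A constant marker yields AUC 0.5 with a warning.
    """
    orientation = Orientation(orientation)
    pairs = [(v, bool(l)) for v, l in zip(values, labels, strict=True)
             if v is not None and math.isfinite(v)]
    pos = np.array([v for v, l in pairs if l], dtype=float)
    neg = np.array([v for v, l in pairs if not l], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise StatsError("ROC analysis needs both a positive and a negative group")
    if orientation is Orientation.LOWER_PREDICTS_POSITIVE:
        pos, neg = -pos, -neg
    if np.ptp(np.concatenate([pos, neg])) == 0.0:
        warnings.warn("constant marker: AUC fixed at 0.5", stacklevel=2)
        auc = 0.5
    else:
        auc = _rank_auc(pos, neg)
    n_pos, n_neg = int(pos.size), int(neg.size)
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    ci_low = min(max(auc - Z_95 * se, 0.0), auc)
    ci_high = max(min(auc + Z_95 * se, 1.0), auc)
    # null-variance z test of AUC = 0.5 (Mann-Whitney null variance)
    se0 = math.sqrt((n_pos + n_neg + 1) / (12.0 * n_pos * n_neg))
    p = 2.0 * sps.norm.sf(abs(auc - 0.5) / se0)
    return RocResult(auc=auc, orientation=orientation, se=se,
                     ci_low=ci_low, ci_high=ci_high,
                     p_value=min(p, 1.0), n_pos=n_pos, n_neg=n_neg)


# -- cohort-level comparison ------------------------------------------------

#: derived score variables accepted by :func:`extract_variable`
SCORE_VARIABLES = ("total_score", "analytical_subscore", "respiratory_subscore")

_RAW_VARIABLES = ("wbc", "plt", "crp", "sf_ratio", "spo2", "fio2")


def extract_variable(
    cohort: Cohort,
    variable: str,
    timing: str,
    rubric: Rubric = DEFAULT_RUBRIC,
) -> list:
    """Per-episode values of a raw marker or derived score at one timing.

    Returns a list aligned with ``cohort.episodes``; missing -> None.
    """
    if timing not in ("t1", "t2"):
        raise ValueError(f"timing must be 't1' or 't2', got {timing!r}")
    out = []
    for ep in cohort:
        obs = ep.obs_t1 if timing == "t1" else ep.obs_t2
        if variable in _RAW_VARIABLES:
            out.append(getattr(obs, variable))
        elif variable in SCORE_VARIABLES:
            bd = compute_breakdown(obs, MissingPolicy.PROPAGATE_MISSING, rubric)
            out.append(getattr(bd, {"total_score": "total"}.get(variable, variable)))
        else:
            raise ValueError(
                f"unknown variable {variable!r}; raw markers: {_RAW_VARIABLES}, "
                f"scores: {SCORE_VARIABLES}"
            )
    return out


@dataclass(frozen=True)
class GroupComparison:
    """Median/IQR summaries per group plus the Mann-Whitney result."""

    variable: str
    timing: str
    median_neg: float
    iqr_neg: tuple
    n_neg: int
    median_pos: float
    iqr_pos: tuple
    n_pos: int
    test: TestResult


def _summary(values: np.ndarray, percentile_rule: str) -> tuple:
    method = {"interpolate": "linear", "package_compat": "weibull"}[percentile_rule]
    q1, med, q3 = np.percentile(values, [25, 50, 75], method=method)
    return float(med), (float(q1), float(q3))


def compare_groups(
    cohort: Cohort,
    variable: str,
    timing: str,
    rubric: Rubric = DEFAULT_RUBRIC,
    mode: str = "asymptotic",
    percentile_rule: str = "interpolate",
) -> GroupComparison:
    """Compare a variable between culture groups at one timing.

    Summaries are medians with 25th-75th percentile IQRs
    (``interpolate``: linear interpolation between order statistics;
    ``package_compat``: the weighted-average (n+1)p convention used by
    legacy statistical packages).  The test is the two-sided
    Mann-Whitney U on pairwise-complete cases.
    """
    if percentile_rule not in ("interpolate", "package_compat"):
        raise ValueError(f"unknown percentile rule {percentile_rule!r}")
    values = extract_variable(cohort, variable, timing, rubric)
    labels = [ep.culture_positive for ep in cohort]
    neg = np.array([v for v, l in zip(values, labels) if not l and v is not None], float)
    pos = np.array([v for v, l in zip(values, labels) if l and v is not None], float)
    if neg.size == 0 or pos.size == 0:
        raise StatsError(
            f"no non-missing values for {variable!r} at {timing} in the "
            f"{'negative' if neg.size == 0 else 'positive'} group"
        )
    med_n, iqr_n = _summary(neg, percentile_rule)
    med_p, iqr_p = _summary(pos, percentile_rule)
    test = mann_whitney(neg, pos, mode=mode)
    return GroupComparison(
        variable=variable, timing=timing,
        median_neg=med_n, iqr_neg=iqr_n, n_neg=int(neg.size),
        median_pos=med_p, iqr_pos=iqr_p, n_pos=int(pos.size),
        test=test,
    )
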