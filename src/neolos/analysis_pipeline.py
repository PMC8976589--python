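"""End-to-end two-timepoint analysis of a suspected-sepsis cohort.

Given a cohort file, the pipeline scores every episode at both timings,
compares raw markers and score totals between culture-positive and
culture-negative groups (Mann-Whitney with median/IQR summaries),
cross-tabulates the paired-change indicators (escalating score, falling
platelets, rising CRP, interval intubation) with the expected-cell-rule
test selection, and promotes every variable whose comparison p-value
falls below the significance threshold to ROC analysis.

No multiplicity adjustment is applied; every p-value is reported
unadjusted and labelled as such.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import __version__
from .cohort_io import Cohort, derive_changes
from .score_core import Rubric, DEFAULT_RUBRIC
from .stats_engine import (
    ContingencyTable2x2,
    GroupComparison,
    Orientation,
    RocResult,
    StatsError,
    TestResult,
    compare_groups,
    chi2_uncorrected,
    extract_variable,
    fisher_two_sided,
    roc_auc,
    select_test,
)

__all__ = [
    "AnalysisPlan",
    "AnalysisReport",
    "run_analysis",
    "reproduce_published_tables",
    "PUBLISHED_TABLES",
    "INDICATOR_LABELS",
]

#: default battery: every marker and score variable at both timings
_DEFAULT_COMPARISONS: Tuple[Tuple[str, str], ...] = tuple(
    (var, timing)
    for var in ("wbc", "plt", "crp", "total_score",
                "analytical_subscore", "respiratory_subscore")
    for timing in ("t1", "t2")
)

INDICATOR_LABELS = {
    "score_increased": "Higher score in the second measure",
    "plt_decreased": "Lower PLT count in the second measure",
    "crp_increased": "Higher CRP value in the second measure",
    "intubated_between": "Intubation between both measures",
}

#: published paired-change cross-tabulations (counts and the p-values as
#: printed), used by the ``reproduce-table`` command: rows are
#: culture-negative / culture-positive, columns indicator present/absent.
PUBLISHED_TABLES = (
    ("Higher score in the second measure", ContingencyTable2x2(3, 11, 10, 5), "chi2", 0.014),
    ("Lower PLT count in the second measure", ContingencyTable2x2(9, 6, 13, 3), "fisher", 0.252),
    ("Higher CRP value in the second measure", ContingencyTable2x2(4, 10, 12, 4), "chi2", 0.011),
    ("Intubation between both measures", ContingencyTable2x2(0, 15, 7, 10), "fisher", 0.008),
)


@dataclass(frozen=True)
class AnalysisPlan:
    """What to compare, cross-tabulate and promote to ROC analysis."""

    comparisons: Tuple[Tuple[str, str], ...] = _DEFAULT_COMPARISONS
    indicators: Tuple[str, ...] = tuple(INDICATOR_LABELS)
    roc_threshold: float = 0.05
    test_policy: str = "auto"  # auto | chi2 | fisher
    mw_mode: str = "asymptotic"
    percentile_rule: str = "interpolate"
    change_tolerance: float = 0.0
    # platelets fall in sepsis, so lower values predict a positive culture
    orientations: Dict[str, Orientation] = field(
        default_factory=lambda: {"plt": Orientation.LOWER_PREDICTS_POSITIVE}
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.roc_threshold < 1.0:
            raise ValueError("roc_threshold must be in (0, 1)")
        for ind in self.indicators:
            if ind not in INDICATOR_LABELS:
                raise ValueError(f"unknown change indicator {ind!r}")

    def orientation_for(self, variable: str) -> Orientation:
        return self.orientations.get(variable, Orientation.HIGHER_PREDICTS_POSITIVE)

    def digest(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class IndicatorResult:
    indicator: str
    table: ContingencyTable2x2
    test: TestResult


@dataclass(frozen=True)
class RocRow:
    variable: str
    timing: str
    result: RocResult


@dataclass
class AnalysisReport:
    comparisons: List[GroupComparison]
    skipped: List[Tuple[str, str, str]]  # (variable, timing, reason)
    indicators: List[IndicatorResult]
    roc: List[RocRow]
    provenance: Dict[str, str]

    # -- serialization -----------------------------------------------------

    def table_rows(self):
        header = ("variable", "timing", "negative_summary", "positive_summary",
                  "n_neg", "n_pos", "test", "p_value", "adjustment",
                  "auc", "auc_ci", "auc_p", "orientation")
        rows = []

        def fmt_summary(median, iqr):
            return f"{median:g} [{iqr[0]:g}-{iqr[1]:g}]"

        roc_by_key = {(r.variable, r.timing): r.result for r in self.roc}
        for c in self.comparisons:
            roc = roc_by_key.get((c.variable, c.timing))
            rows.append((
                c.variable, c.timing,
                fmt_summary(c.median_neg, c.iqr_neg),
                fmt_summary(c.median_pos, c.iqr_pos),
                c.n_neg, c.n_pos, c.test.method,
                f"{c.test.p_value:.4f}", "unadjusted",
                f"{roc.auc:.3f}" if roc else "",
                f"{roc.ci_low:.2f}-{roc.ci_high:.2f}" if roc else "",
                f"{roc.p_value:.4f}" if roc else "",
                roc.orientation.value if roc else "",
            ))
        for variable, timing, reason in self.skipped:
            rows.append((variable, timing, "", "", "", "", "skipped", "",
                         reason, "", "", "", ""))
        for ind in self.indicators:
            t = ind.table
            rows.append((
                INDICATOR_LABELS[ind.indicator], "t1->t2",
                f"{t.a}/{t.a + t.b}", f"{t.c}/{t.c + t.d}",
                t.a + t.b, t.c + t.d, ind.test.method,
                f"{ind.test.p_value:.4f}", "unadjusted", "", "", "", "",
            ))
        return header, rows

    def to_jsonable(self) -> dict:
        return {
            "provenance": dict(self.provenance),
            "comparisons": [
                {
                    "variable": c.variable,
                    "timing": c.timing,
                    "median_neg": c.median_neg,
                    "iqr_neg": list(c.iqr_neg),
                    "n_neg": c.n_neg,
                    "median_pos": c.median_pos,
                    "iqr_pos": list(c.iqr_pos),
                    "n_pos": c.n_pos,
                    "test": {
                        "method": c.test.method,
                        "statistic": c.test.statistic,
                        "p_value": c.test.p_value,
                        "adjustment": "unadjusted",
                    },
                }
                for c in self.comparisons
            ],
            "skipped": [
                {"variable": v, "timing": t, "reason": r} for v, t, r in self.skipped
            ],
            "change_indicators": [
                {
                    "indicator": i.indicator,
                    "label": INDICATOR_LABELS[i.indicator],
                    "table": [[i.table.a, i.table.b], [i.table.c, i.table.d]],
                    "test": {
                        "method": i.test.method,
                        "statistic": i.test.statistic,
                        "p_value": i.test.p_value,
                        "adjustment": "unadjusted",
                    },
                }
                for i in self.indicators
            ],
            "roc": [
                {
                    "variable": r.variable,
                    "timing": r.timing,
                    "auc": r.result.auc,
                    "orientation": r.result.orientation.value,
                    "se": r.result.se,
                    "ci_low": r.result.ci_low,
                    "ci_high": r.result.ci_high,
                    "p_value": r.result.p_value,
                    "n_pos": r.result.n_pos,
                    "n_neg": r.result.n_neg,
                }
                for r in self.roc
            ],
        }


def _indicator_table(cohort: Cohort, indicator: str, tolerance: float,
                     rubric: Rubric) -> ContingencyTable2x2:
    counts = {("neg", True): 0, ("neg", False): 0,
              ("pos", True): 0, ("pos", False): 0}
    for ep in cohort:
        flag = getattr(derive_changes(ep, tolerance, rubric), indicator)
        if flag is None:
            continue  # pairwise-complete: this episode drops out of this row
        counts[("pos" if ep.culture_positive else "neg", bool(flag))] += 1
    return ContingencyTable2x2(
        a=counts[("neg", True)], b=counts[("neg", False)],
        c=counts[("pos", True)], d=counts[("pos", False)],
    )


def run_analysis(
    cohort: Cohort,
    plan: Optional[AnalysisPlan] = None,
    rubric: Rubric = DEFAULT_RUBRIC,
) -> AnalysisReport:
    """Run the full comparison battery on a cohort.

    Deterministic given its inputs.  Variables whose comparison cannot
    be computed (e.g. all values missing in one group) are flagged and
    skipped; the pipeline continues.
    """
    plan = plan or AnalysisPlan()
    if cohort.n_positive == 0 or cohort.n_negative == 0:
        raise StatsError(
            "cohort must contain both culture-positive and culture-negative "
            f"episodes (got {cohort.n_negative} negative / {cohort.n_positive} positive)"
        )
    comparisons: List[GroupComparison] = []
    skipped: List[Tuple[str, str, str]] = []
    for variable, timing in plan.comparisons:
        try:
            comparisons.append(
                compare_groups(cohort, variable, timing, rubric,
                               mode=plan.mw_mode,
                               percentile_rule=plan.percentile_rule)
            )
        except StatsError as exc:
            skipped.append((variable, timing, str(exc)))

    indicators: List[IndicatorResult] = []
    for indicator in plan.indicators:
        table = _indicator_table(cohort, indicator, plan.change_tolerance, rubric)
        if table.total == 0:
            skipped.append((indicator, "t1->t2", "no pairwise-complete episodes"))
            continue
        indicators.append(IndicatorResult(
            indicator=indicator, table=table,
            test=select_test(table, plan.test_policy),
        ))

    roc: List[RocRow] = []
    labels = [ep.culture_positive for ep in cohort]
    for comp in comparisons:
        if comp.test.p_value < plan.roc_threshold:
            values = extract_variable(cohort, comp.variable, comp.timing, rubric)
            roc.append(RocRow(
                variable=comp.variable, timing=comp.timing,
                result=roc_auc(values, labels,
                               plan.orientation_for(comp.variable)),
            ))

    provenance = {
        "input": cohort.source or "<in-memory>",
        "loaded_at": cohort.loaded_at or "",
        "n_negative": str(cohort.n_negative),
        "n_positive": str(cohort.n_positive),
        "plan_digest": plan.digest(),
        "software_version": __version__,
    }
    return AnalysisReport(comparisons=comparisons, skipped=skipped,
                          indicators=indicators, roc=roc, provenance=provenance)


def reproduce_published_tables():
    """Recompute the four published paired-change tests from their counts.

    Returns ``(label, table, method, computed_p, printed_p)`` tuples.
    The platelet row is printed with a chi-square footnote in the source
    table, but its p-value is only reproduced by the two-sided Fisher
    exact test; the computation here uses the test the arithmetic
    supports.
    """
    out = []
    for label, table, method, printed in PUBLISHED_TABLES:
        test = chi2_uncorrected(table) if method == "chi2" else fisher_two_sided(table)
        out.append((label, table, test.method, test.p_value, printed))
    return out
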