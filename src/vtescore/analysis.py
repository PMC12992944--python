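"""Statistical evaluation of the prophylaxis protocol.

Covers the study's estimators: incidence with exact (Clopper–Pearson)
binomial confidence intervals, the pre/post two-proportion comparison
(continuity-corrected chi-squared, or Fisher's exact test when expected
counts are small), screening-test metrics treating "high risk" (score >= 3)
as a positive screen for postpartum VTE, and number needed to screen / treat.

scipy.stats provides the test machinery and statsmodels the exact binomial
interval; this module fixes the study's conventions (two-sided Fisher by the
point-probability rule, Yates correction by default for the 2x2, percentages
reported with round-half-up at printed precision while raw proportions are
retained unrounded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .types import ConfusionMatrix, TwoByTwoTable

__all__ = [
    "round_half_up",
    "incidence",
    "clopper_pearson_ci",
    "two_proportion_test",
    "build_confusion",
    "screening_metrics",
    "nns_nnt",
    "IncidenceEstimate",
    "TestResult",
    "MetricEstimate",
    "ScreeningEvaluation",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (reporting convention for percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class IncidenceEstimate:
    """Incidence as a percentage with an exact binomial CI (percent scale)."""

    events: int
    n: int
    percent: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def rounded(self, ndigits: int = 2) -> float:
        return round_half_up(self.percent, ndigits)


def clopper_pearson_ci(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval (proportion scale).

    Inverts the binomial tails (equivalently, beta quantiles); the lower
    bound is 0 when ``successes`` is 0 and the upper bound 1 at ``n``.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    if not 0 <= successes <= n or n <= 0:
        raise ValueError("need 0 <= successes <= n with n > 0")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="beta")
    return (0.0 if successes == 0 else float(lo), 1.0 if successes == n else float(hi))


def incidence(events: int, n: int, level: float = 0.95) -> IncidenceEstimate:
    """Event incidence, percent scale, with Clopper–Pearson CI."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= events <= n:
        raise ValueError("events must lie in [0, n]")
    lo, hi = clopper_pearson_ci(events, n, level)
    return IncidenceEstimate(
        events=events,
        n=n,
        percent=100.0 * events / n,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        level=level,
    )


@dataclass
class TestResult:
    p_value: float
    statistic: Optional[float]
    method: str


def _expected_counts(table: TwoByTwoTable) -> np.ndarray:
    arr = np.array(
        [
            [table.events_a, table.n_a - table.events_a],
            [table.events_b, table.n_b - table.events_b],
        ],
        dtype=float,
    )
    row = arr.sum(axis=1, keepdims=True)
    col = arr.sum(axis=0, keepdims=True)
    return row * col / arr.sum()


def two_proportion_test(table: TwoByTwoTable, method: str = "auto") -> TestResult:
    """Two-sided comparison of two incidences on a 2x2 table.

    ``yates_chi2`` is the continuity-corrected chi-squared; ``fisher`` the
    exact conditional test, two-sided by summing tables whose point
    probability does not exceed the observed one; ``auto`` uses Fisher when
    any expected cell is below 5. Degenerate margins (an all-zero row or
    column) yield p = 1 with a warning.
    """
    if method not in ("auto", "yates_chi2", "fisher"):
        raise ValueError(f"unknown method {method!r}")
    arr = np.array(
        [
            [table.events_a, table.n_a - table.events_a],
            [table.events_b, table.n_b - table.events_b],
        ]
    )
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 margins; test undefined, returning p = 1")
        return TestResult(p_value=1.0, statistic=None, method="degenerate")

    if method == "auto":
        method = "fisher" if (_expected_counts(table) < 5).any() else "yates_chi2"

    if method == "fisher":
        res = stats.fisher_exact(arr, alternative="two-sided")
        return TestResult(p_value=float(res.pvalue), statistic=float(res.statistic), method="fisher")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=True)
    return TestResult(p_value=float(p), statistic=float(chi2), method="yates_chi2")


def build_confusion(
    score_distribution_counts: Mapping[int, int],
    event_scores: Sequence[int],
    threshold: int = 3,
) -> ConfusionMatrix:
    """Screening 2x2 from a cohort's score histogram and its events' scores.

    A patient screens positive at ``score >= threshold``. The histogram
    covers the whole cohort (events included); event scores must therefore be
    consistent with it.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    total = int(sum(score_distribution_counts.values()))
    events = len(event_scores)
    if events > total:
        raise ValueError("more events than patients")
    positives = int(sum(c for s, c in score_distribution_counts.items() if s >= threshold))
    tp = sum(1 for s in event_scores if s >= threshold)
    fp = positives - tp
    fn = events - tp
    tn = total - positives - fn
    if fp < 0 or tn < 0:
        raise ValueError("event scores inconsistent with the score histogram")
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class MetricEstimate:
    """One screening metric (percent scale) with its exact CI.

    ``defined`` is False when the ratio's denominator is zero (e.g.
    sensitivity with no events); the point and CI are then NaN rather than a
    silent 0.
    """

    percent: float
    ci_low: float
    ci_high: float
    defined: bool = True


@dataclass
class ScreeningEvaluation:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    accuracy: MetricEstimate
    ci_method: str = "clopper_pearson"
    level: float = 0.95


def _metric(numer: int, denom: int, level: float) -> MetricEstimate:
    if denom == 0:
        return MetricEstimate(float("nan"), float("nan"), float("nan"), defined=False)
    lo, hi = clopper_pearson_ci(numer, denom, level)
    return MetricEstimate(100.0 * numer / denom, 100.0 * lo, 100.0 * hi)


def screening_metrics(cm: ConfusionMatrix, level: float = 0.95) -> ScreeningEvaluation:
    """Sensitivity/specificity/PPV/NPV/accuracy with Clopper–Pearson CIs."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return ScreeningEvaluation(
        sensitivity=_metric(cm.tp, cm.tp + cm.fn, level),
        specificity=_metric(cm.tn, cm.tn + cm.fp, level),
        ppv=_metric(cm.tp, cm.tp + cm.fp, level),
        npv=_metric(cm.tn, cm.tn + cm.fn, level),
        accuracy=_metric(cm.tp + cm.tn, cm.total, level),
        level=level,
    )


def nns_nnt(arr: float, treated_fraction: float) -> tuple[float, float]:
    """Number needed to screen and to treat, from the absolute risk reduction.

    NNS = 1/ARR (patients screened per event prevented); NNT scales NNS by
    the fraction actually treated pharmacologically.
    """
    if not 0 < arr <= 1:
        raise ValueError("absolute risk reduction must be in (0, 1]")
    if not 0 < treated_fraction <= 1:
        raise ValueError("treated fraction must be in (0, 1]")
    nns = 1.0 / arr
    return nns, nns * treated_fraction


def compare_incidence(
    pre: pd.DataFrame, post: pd.DataFrame, outcome: str = "vte_event", method: str = "auto"
) -> dict:
    """Pre/post incidence comparison on two cohorts with outcome columns."""
    for name, df in (("preprotocol", pre), ("protocol", post)):
        if outcome not in df.columns:
            raise ValueError(f"{name} cohort lacks outcome column {outcome!r}")
    table = TwoByTwoTable(
        events_a=int(pre[outcome].sum()),
        n_a=len(pre),
        events_b=int(post[outcome].sum()),
        n_b=len(post),
    )
    test = two_proportion_test(table, method=method)
    return {
        "preprotocol": incidence(table.events_a, table.n_a),
        "protocol": incidence(table.events_b, table.n_b),
        "test": test,
        "table": table,
    }
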