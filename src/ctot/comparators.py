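"""Comparator analysis strategies for censored ΔCq data.

Four strategies commonly used around uncertain qPCR observations, each
followed by a two-independent-groups t-test:

* MC  — substitute the quality cutoff C1 for uncertain Cq values, i.e. use
        the censoring bound C1 − Cq(normalizer) as if it were observed.
* CO  — drop censored observations (complete-observation analysis).
* CNA — decline to analyze any target with censored observations.
* BFD — benchmark on the full uncensored truth (simulation only).

On censoring-free data all four reduce to the same t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .normalize import NormalizedDataset
from .ranks import ALTERNATIVES, TestResult

METHODS = ("MC", "CO", "CNA", "BFD")


@dataclass
class ComparatorOutcome:
    """Result of one comparator strategy on one dataset."""

    method: str
    usable: bool
    group1_values: list[float]
    group2_values: list[float]
    result: TestResult | None = None
    degenerate_reason: str | None = None


def mc_transform(data: NormalizedDataset) -> tuple[list[float], list[float]]:
    """ΔY with uncertain values set to their bound C1 − Cq(normalizer).

    Because censored observations already store that bound as ``delta_y``,
    this is simply the stored values split by group.
    """
    return data.group_values(1), data.group_values(2)


def co_transform(data: NormalizedDataset) -> tuple[list[float], list[float]]:
    """ΔY of complete (φ = 1) observations only; groups may shrink."""
    g1 = [o.delta_y for o in data.observations if o.group == 1 and o.phi == 1]
    g2 = [o.delta_y for o in data.observations if o.group == 2 and o.phi == 1]
    return g1, g2


def cna_applicable(data: NormalizedDataset) -> bool:
    """True iff every observation in both groups is an event (φ = 1)."""
    return all(o.phi == 1 for o in data.observations)


def _t_alternative(alternative: str) -> str:
    # Higher group-1 rate <=> lower group-1 ΔY mean, so rate1_greater maps to
    # the "less" tail of the t-test on ΔY.
    return {"two_sided": "two-sided",
            "rate1_greater": "less",
            "rate1_less": "greater"}[alternative]


def t_test_two_groups(
    x,
    y,
    alternative: str = "two_sided",
    var_equal: bool = False,
) -> TestResult:
    """Two-independent-groups t-test (Welch by default).

    Undersized (< 2 per group) or zero-variance-degenerate input yields a
    degenerate result with p = 1 instead of an exception, so simulation
    harnesses can count it as a non-rejection.
    """
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def _degenerate(reason: str) -> TestResult:
        return TestResult(statistic_u=0.0, variance_v=0.0, z=0.0, p_value=1.0,
                          pvalue_mode="asymptotic", alternative=alternative,
                          degenerate=True, degenerate_reason=reason)

    if x.size < 2 or y.size < 2:
        return _degenerate("fewer than 2 observations in a group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if float(x.mean()) == float(y.mean()):
            return _degenerate("zero variance in both groups, equal means")
        return _degenerate("zero variance in both groups")
    res = stats.ttest_ind(x, y, equal_var=var_equal,
                          alternative=_t_alternative(alternative))
    stat = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(stat) or not np.isfinite(p):
        return _degenerate("non-finite t statistic")
    return TestResult(statistic_u=stat, variance_v=1.0, z=stat, p_value=p,
                      pvalue_mode="asymptotic", alternative=alternative)


def run_method(
    method: str,
    data: NormalizedDataset,
    true_delta_y: tuple[list[float], list[float]] | None = None,
    alternative: str = "two_sided",
    var_equal: bool = False,
) -> ComparatorOutcome:
    """Dispatch one comparator strategy and run its t-test.

    BFD requires ``true_delta_y``, the pre-censoring simulation truth as
    (group-1 values, group-2 values).
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}; one of {METHODS}")
    if method == "MC":
        g1, g2 = mc_transform(data)
    elif method == "CO":
        g1, g2 = co_transform(data)
    elif method == "CNA":
        if not cna_applicable(data):
            return ComparatorOutcome(
                method="CNA", usable=False,
                group1_values=[], group2_values=[],
                degenerate_reason="uncertain observations present; not analyzed",
            )
        g1, g2 = data.group_values(1), data.group_values(2)
    else:  # BFD
        if true_delta_y is None:
            raise ConfigurationError("BFD requires the uncensored truth (true_delta_y)")
        g1, g2 = list(true_delta_y[0]), list(true_delta_y[1])

    result = t_test_two_groups(g1, g2, alternative=alternative, var_equal=var_equal)
    usable = not result.degenerate
    return ComparatorOutcome(
        method=method, usable=usable,
        group1_values=list(g1), group2_values=list(g2),
        result=result,
        degenerate_reason=result.degenerate_reason,
    )
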