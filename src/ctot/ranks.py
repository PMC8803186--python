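"""The cycle-to-threshold (CTOT) test core.

Two-group qPCR data with right-censored ΔCq values are treated like
time-to-event data: each distinct observed ΔY among event observations
(φ = 1) is a "detection point" d.  At each d, conditional on the margins,
the group-1 event count O_d1 is hypergeometric; the test statistic is the
weighted sum of observed-minus-expected counts

    U = Σ_d w_d (O_d1 − E_d1),      V = Σ_d w_d² Var(O_d1),

with Fleming–Harrington weights w_d = Ŝ(d−)^p (1 − Ŝ(d−))^q built from the
pooled Kaplan–Meier left limit.  p = q = 0 gives the log-rank test.  For the
small samples typical of qPCR experiments the p-value comes from the exact
permutation distribution of U over all C(n, n1) relabelings; asymptotic and
Monte-Carlo modes are available for larger samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import comb, sqrt

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, ValidationError
from .normalize import NormalizedDataset

ALTERNATIVES = ("two_sided", "rate1_greater", "rate1_less")


@dataclass
class RiskRow:
    """Counts and hypergeometric moments at one detection point d."""

    d: float
    p_d1: int
    p_d2: int
    o_d1: int
    o_d2: int
    e_d1: float
    v_d1: float
    s_minus: float | None = None  # pooled KM left limit S(d-)
    w_d: float | None = None  # Fleming-Harrington weight

    @property
    def p_d(self) -> int:
        return self.p_d1 + self.p_d2

    @property
    def o_d(self) -> int:
        return self.o_d1 + self.o_d2


@dataclass
class TestResult:
    """Outcome of a two-group test: statistic, p-value and diagnostics."""

    statistic_u: float
    variance_v: float
    z: float
    p_value: float
    pvalue_mode: str  # exact | montecarlo | asymptotic
    alternative: str
    fh_p: float = 0.0
    fh_q: float = 0.0
    n_enumerated: int | None = None
    n_resamples: int | None = None
    seed: int | None = None
    degenerate: bool = False
    degenerate_reason: str | None = None


def _obs_arrays(data: NormalizedDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(values, phi, group) arrays; value is ΔY for events, the bound for censored."""
    values = np.array([o.delta_y for o in data.observations], dtype=float)
    phi = np.array([o.phi for o in data.observations], dtype=int)
    group = np.array([o.group for o in data.observations], dtype=int)
    return values, phi, group


def build_risk_table(data: NormalizedDataset) -> list[RiskRow]:
    """Tabulate risk sets, event counts and hypergeometric moments.

    One row per distinct event value d, ascending.  A sample is at risk at d
    when its value (event ΔY or censoring bound) is ≥ d; censored samples
    tied with an event value stay in the risk set at that value.  With no
    events at all the table is empty (handled downstream, not an error).
    """
    values, phi, group = _obs_arrays(data)
    event_values = np.unique(values[phi == 1])
    rows: list[RiskRow] = []
    for d in event_values:
        at_risk = values >= d
        event_here = (phi == 1) & (values == d)
        p1 = int(np.sum(at_risk & (group == 1)))
        p2 = int(np.sum(at_risk & (group == 2)))
        o1 = int(np.sum(event_here & (group == 1)))
        o2 = int(np.sum(event_here & (group == 2)))
        p, o = p1 + p2, o1 + o2
        e1 = o * p1 / p
        if p > 1:
            frac = p1 / p
            v1 = o * frac * (1.0 - frac) * (p - o) / (p - 1)
        else:
            v1 = 0.0
        rows.append(RiskRow(d=float(d), p_d1=p1, p_d2=p2, o_d1=o1, o_d2=o2,
                            e_d1=e1, v_d1=v1))
    return rows


def km_left_limits(rows: list[RiskRow]) -> list[RiskRow]:
    """Fill each row's pooled Kaplan-Meier left limit Ŝ(d−) in place."""
    s = 1.0
    for row in rows:
        row.s_minus = s
        s *= 1.0 - row.o_d / row.p_d
    return rows


def fh_weights(rows: list[RiskRow], p: float = 0.0, q: float = 0.0) -> list[RiskRow]:
    """Fill Fleming-Harrington weights w_d = Ŝ(d−)^p (1−Ŝ(d−))^q in place.

    0^0 is taken as 1, so p = q = 0 gives unit weights (the log-rank test).
    """
    if p < 0 or q < 0:
        raise ValidationError(f"Fleming-Harrington exponents must be >= 0, got p={p}, q={q}")
    for row in rows:
        if row.s_minus is None:
            raise ValidationError("call km_left_limits before fh_weights")
        row.w_d = row.s_minus ** p * (1.0 - row.s_minus) ** q
    return rows


def linear_statistic(rows: list[RiskRow]) -> tuple[float, float]:
    """U = Σ w_d (O_d1 − E_d1) and V = Σ w_d² Var(O_d1); (0, 0) when empty."""
    u = 0.0
    v = 0.0
    for row in rows:
        if row.w_d is None:
            raise ValidationError("call fh_weights before linear_statistic")
        u += row.w_d * (row.o_d1 - row.e_d1)
        v += row.w_d ** 2 * row.v_d1
    return u, v


def logrank_scores(data: NormalizedDataset, rows: list[RiskRow]) -> np.ndarray:
    """Per-observation scores c_i with Σ_{i in group 1} c_i = U.

    c_i = φ_i·w(y_i) − Σ_{d ≤ y_i} w_d·O_d/P_d.  This permutation-equivalent
    reformulation makes U linear in the group labels, so the exact test can
    enumerate subset sums of a fixed score vector instead of rebuilding the
    risk table per labeling.
    """
    values, phi, _ = _obs_arrays(data)
    d = np.array([row.d for row in rows], dtype=float)
    w = np.array([row.w_d for row in rows], dtype=float)
    increments = np.array([row.w_d * row.o_d / row.p_d for row in rows], dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(increments)])
    # number of detection points <= y_i
    k = np.searchsorted(d, values, side="right")
    scores = -cum[k]
    if len(d):
        is_event = phi == 1
        pos = np.searchsorted(d, values[is_event])
        scores[is_event] += w[pos]
    return scores


@lru_cache(maxsize=32)
def _subset_matrix(n: int, n1: int) -> np.ndarray:
    """0/1 matrix with one row per size-n1 subset of range(n)."""
    m = comb(n, n1)
    out = np.zeros((m, n))
    for i, subset in enumerate(itertools.combinations(range(n), n1)):
        out[i, list(subset)] = 1.0
    return out


def default_tie_tolerance(scores: np.ndarray) -> float:
    """Absolute tolerance treating float-arithmetic ties as exact ties."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        return 0.0
    return 1e-12 * scores.size * float(np.max(np.abs(scores)))


def exact_permutation_pvalue(
    scores,
    n1: int,
    alternative: str = "two_sided",
    tol: float | None = None,
    enumeration_limit: int = 200_000,
) -> float:
    """Exact permutation p-value of T = Σ_{i in group 1} c_i.

    The first ``n1`` entries of ``scores`` are the observed group 1.  All
    C(n, n1) subsets are enumerated; two-sided extremeness is absolute
    deviation of T from its permutation mean μ = n1·mean(scores).  The
    observed labeling is always counted, so p ∈ (0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"unknown alternative {alternative!r}")
    n_subsets = comb(n, n1)
    if n_subsets > enumeration_limit:
        raise ConfigurationError(
            f"C({n}, {n1}) = {n_subsets} exceeds the enumeration limit "
            f"{enumeration_limit}; use montecarlo_permutation_pvalue"
        )
    if tol is None:
        tol = default_tie_tolerance(scores)
    t_obs = float(scores[:n1].sum())
    t_all = _subset_matrix(n, n1) @ scores
    mu = n1 * float(scores.mean())
    if alternative == "two_sided":
        count = int(np.sum(np.abs(t_all - mu) >= abs(t_obs - mu) - tol))
    elif alternative == "rate1_greater":
        count = int(np.sum(t_all >= t_obs - tol))
    else:
        count = int(np.sum(t_all <= t_obs + tol))
    return count / n_subsets


def montecarlo_permutation_pvalue(
    scores,
    n1: int,
    B: int = 100_000,
    seed: int | np.random.Generator | None = None,
    alternative: str = "two_sided",
    tol: float | None = None,
) -> float:
    """Monte-Carlo permutation p-value (1 + #extreme)/(B + 1).

    Same extremeness rules as :func:`exact_permutation_pvalue`; reproducible
    given ``seed``.
    """
    scores = np.asarray(scores, dtype=float)
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"unknown alternative {alternative!r}")
    if B < 1:
        raise ValidationError("B must be >= 1")
    if tol is None:
        tol = default_tie_tolerance(scores)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs = float(scores[:n1].sum())
    mu = n1 * float(scores.mean())
    tiled = np.tile(scores, (B, 1))
    rng.permuted(tiled, axis=1, out=tiled)
    t_all = tiled[:, :n1].sum(axis=1)
    if alternative == "two_sided":
        count = int(np.sum(np.abs(t_all - mu) >= abs(t_obs - mu) - tol))
    elif alternative == "rate1_greater":
        count = int(np.sum(t_all >= t_obs - tol))
    else:
        count = int(np.sum(t_all <= t_obs + tol))
    return (1 + count) / (B + 1)


def asymptotic_pvalue(u: float, v: float, alternative: str = "two_sided") -> float:
    """Normal-approximation p-value from Z = U/√V; p = 1 when V = 0."""
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"unknown alternative {alternative!r}")
    if v <= 0:
        return 1.0
    z = u / sqrt(v)
    if alternative == "two_sided":
        return float(2.0 * norm.cdf(-abs(z)))
    if alternative == "rate1_greater":
        return float(norm.cdf(-z))
    return float(norm.cdf(z))


def ctot_test(
    data: NormalizedDataset,
    fh_p: float = 0.0,
    fh_q: float = 0.0,
    alternative: str = "two_sided",
    pvalue_mode: str = "auto",
    enumeration_limit: int = 200_000,
    B: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> TestResult:
    """Run the CTOT (exact weighted log-rank) test on a normalized dataset.

    ``pvalue_mode`` is one of ``auto`` (exact when C(n, n1) fits the
    enumeration limit, else Monte Carlo), ``exact``, ``montecarlo``,
    ``asymptotic``.  A sign convention worth remembering: U > 0 means group 1
    reaches the fluorescence threshold in excess of expectation — a higher
    cycle-to-threshold rate, hence lower ΔCq and a higher target level in
    group 1.  Degenerate data (no detection points, or zero variance) give
    p = 1 with a flag rather than an error, so simulation harnesses can
    count them as non-rejections.
    """
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"unknown alternative {alternative!r}")
    rows = build_risk_table(data)
    km_left_limits(rows)
    fh_weights(rows, fh_p, fh_q)
    u, v = linear_statistic(rows)

    seed_out = seed if isinstance(seed, int) else None

    def _result(p: float, mode: str, *, n_enum=None, n_res=None,
                degenerate=False, reason=None) -> TestResult:
        z = u / sqrt(v) if v > 0 else 0.0
        return TestResult(
            statistic_u=u, variance_v=v, z=z, p_value=p, pvalue_mode=mode,
            alternative=alternative, fh_p=fh_p, fh_q=fh_q,
            n_enumerated=n_enum, n_resamples=n_res, seed=seed_out,
            degenerate=degenerate, degenerate_reason=reason,
        )

    if not rows:
        return _result(1.0, pvalue_mode if pvalue_mode != "auto" else "exact",
                       degenerate=True, reason="no detection points")
    if v <= 0:
        return _result(1.0, pvalue_mode if pvalue_mode != "auto" else "exact",
                       degenerate=True, reason="zero variance")

    if pvalue_mode == "asymptotic":
        return _result(asymptotic_pvalue(u, v, alternative), "asymptotic")

    # Order scores so group-1 observations come first (the permutation
    # functions' observed-labeling convention).
    scores = logrank_scores(data, rows)
    groups = np.array([o.group for o in data.observations])
    order = np.argsort(groups, kind="stable")
    scores = scores[order]
    n1 = int(np.sum(groups == 1))
    n = scores.size

    mode = pvalue_mode
    if mode == "auto":
        mode = "exact" if comb(n, n1) <= enumeration_limit else "montecarlo"
    if mode == "exact":
        p = exact_permutation_pvalue(scores, n1, alternative,
                                     enumeration_limit=enumeration_limit)
        return _result(p, "exact", n_enum=comb(n, n1))
    if mode == "montecarlo":
        p = montecarlo_permutation_pvalue(scores, n1, B=B, seed=seed,
                                          alternative=alternative)
        return _result(p, "montecarlo", n_res=B)
    raise ConfigurationError(f"unknown pvalue_mode {pvalue_mode!r}")
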