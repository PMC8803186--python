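"""Power and type-I-error simulation studies.

The harness simulates two-group qPCR replicates under known truth, applies
the CTOT exact test and the comparator strategies (MC, CO, CNA) plus the
full-data benchmark (BFD) to every replicate, and pools rejection decisions.

Power studies restrict to replicates containing at least one uncertain
(censored) observation — the replicates where the methods actually differ —
and report, per method, the correct-decision count, the empirical power and
its Wald 95% Monte-Carlo confidence interval.  Type-I studies run the four
null log-normal parameter sets and report empirical rejection rates per
scenario and, for CTOT, additionally on the pooled uncertain-observation
subset.

Determinism: every replicate's random stream is derived from the master
seed and a (scenario index, replicate index) counter via
``numpy.random.SeedSequence`` spawn keys, so any scenario subset can be
re-run independently and reports are bit-identical for a given config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
from scipy import stats

from .comparators import run_method
from .errors import ValidationError
from .normalize import normalize_target
from .ranks import ctot_test
from .simulate import (
    FAMILIES,
    Scenario,
    SimulatedReplicate,
    draw_power_scenarios,
    simulate_replicate,
    type1_scenarios,
)

ALL_METHODS = ("CTOT", "MC", "CO", "CNA", "BFD")

#: Decision statuses.  Degenerate and not-analyzed outcomes count as
#: non-rejections in power and as non-errors in type-I accounting, but are
#: tallied separately.
STATUSES = ("reject", "nonreject", "degenerate", "not_analyzed")


@dataclass
class ReplicateDecision:
    """Per-method decisions for one simulated replicate."""

    status: dict[str, str]
    p_values: dict[str, float | None]
    has_uncertain: bool
    pattern: str  # none | one_group | both_groups


@dataclass
class StudyReport:
    """Pooled decisions of a power or type-I study."""

    kind: str  # power | type1
    family: str | None
    methods: tuple[str, ...]
    alpha: float
    n_replicates_total: int
    n_rep: int  # replicates retained (>= 1 uncertain observation) in power mode
    counts: dict[str, dict[str, int]]
    power: dict[str, float | None]
    ci: dict[str, tuple[float, float] | None]
    pct_one_group_uncertain: float | None
    config: dict = field(default_factory=dict)

    def as_rows(self) -> list[dict]:
        """Flat rows (one per method) for TSV reporting."""
        rows = []
        for m in self.methods:
            lo, hi = self.ci[m] if self.ci[m] is not None else (None, None)
            rows.append({
                "family": self.family or "", "method": m,
                "n_total": self.n_replicates_total, "n_rep": self.n_rep,
                "correct": self.counts[m]["reject"],
                "degenerate": self.counts[m]["degenerate"],
                "not_analyzed": self.counts[m]["not_analyzed"],
                "power": self.power[m], "ci_low": lo, "ci_high": hi,
                "pct_one_group_uncertain": self.pct_one_group_uncertain,
            })
        return rows


def monte_carlo_ci(p_hat: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wald 95% Monte-Carlo CI p̂ ± z·sqrt(p̂(1−p̂)/n), truncated to [0, 1]."""
    if not (0.0 <= p_hat <= 1.0):
        raise ValidationError(f"p_hat must be in [0, 1], got {p_hat}")
    if n < 1:
        raise ValidationError("n must be >= 1")
    half = z * sqrt(p_hat * (1.0 - p_hat) / n)
    return (max(0.0, p_hat - half), min(1.0, p_hat + half))


def t_test_power(mu1: float, mu2: float, sd: float, n_per_group: int,
                 alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test via the noncentral t.

    df = 2n − 2 and noncentrality |μ1 − μ2|·sqrt(n/2)/sd.
    """
    if sd <= 0:
        raise ValidationError("sd must be > 0")
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    df = 2 * n_per_group - 2
    nc = abs(mu1 - mu2) * sqrt(n_per_group / 2.0) / sd
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def _censoring_pattern(rep: SimulatedReplicate) -> tuple[bool, str]:
    groups_censored = {
        rec.group_label
        for rec in rep.dataset.records
        if rec.target_id == "target"
        and (not rec.is_determined or rec.cq >= rep.dataset.c1)
    }
    if not groups_censored:
        return False, "none"
    return True, ("both_groups" if len(groups_censored) == 2 else "one_group")


def evaluate_replicate(
    rep: SimulatedReplicate,
    alpha: float = 0.05,
    c1: float | None = None,
    methods: tuple[str, ...] = ALL_METHODS,
    var_equal: bool = False,
) -> ReplicateDecision:
    """Run every requested method on one replicate and record decisions.

    CTOT runs as the exact two-sided test; MC/CO/CNA via t-tests; BFD on the
    retained uncensored truth.  Rejection is p ≤ α.  Degeneracies are
    recorded, never raised.
    """
    if c1 is None:
        c1 = rep.dataset.c1
    data = normalize_target(rep.dataset, "target", c1)
    has_uncertain, pattern = _censoring_pattern(rep)

    status: dict[str, str] = {}
    p_values: dict[str, float | None] = {}
    for method in methods:
        if method == "CTOT":
            res = ctot_test(data, alternative="two_sided", pvalue_mode="auto")
            p_values[method] = res.p_value
            if res.degenerate:
                status[method] = "degenerate"
            else:
                status[method] = "reject" if res.p_value <= alpha else "nonreject"
            continue
        outcome = run_method(method, data, true_delta_y=rep.true_delta_y,
                             var_equal=var_equal)
        if method == "CNA" and not outcome.usable and outcome.result is None:
            status[method] = "not_analyzed"
            p_values[method] = None
        elif not outcome.usable:
            status[method] = "degenerate"
            p_values[method] = outcome.result.p_value if outcome.result else None
        else:
            p = outcome.result.p_value
            p_values[method] = p
            status[method] = "reject" if p <= alpha else "nonreject"
    return ReplicateDecision(status=status, p_values=p_values,
                             has_uncertain=has_uncertain, pattern=pattern)


def _replicate_rng(seed: int, scenario_index: int, rep_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(scenario_index, rep_index))
    )


def _pool(decisions: list[ReplicateDecision], methods: tuple[str, ...],
          alpha: float) -> tuple[dict, dict, dict]:
    counts = {m: {s: 0 for s in STATUSES} for m in methods}
    for dec in decisions:
        for m in methods:
            counts[m][dec.status[m]] += 1
    n_rep = len(decisions)
    power = {}
    ci = {}
    for m in methods:
        if n_rep == 0:
            power[m] = None
            ci[m] = None
        else:
            p = counts[m]["reject"] / n_rep
            power[m] = p
            ci[m] = monte_carlo_ci(p, n_rep)
    return counts, power, ci


def run_power_study(
    families: tuple[str, ...] = FAMILIES,
    n_scenarios: int = 100,
    reps_per_scenario: int = 1000,
    n_per_group: int = 5,
    alpha: float = 0.05,
    c1: float = 40.0,
    seed: int = 0,
    methods: tuple[str, ...] = ALL_METHODS,
    sigma_scheme: str = "alternating",
    var_equal: bool = False,
) -> dict[str, StudyReport]:
    """Empirical power per family, pooled over scenarios × replicates.

    Scenario parameters are random draws (β0 ~ N(10, 2.24), β1 ~ N(1, 4.47));
    almost surely β1 ≠ 0, so a correct decision is a two-sided rejection at
    α.  Only replicates with at least one uncertain observation are retained;
    the report also carries the fraction of retained replicates whose
    censoring is confined to one group.
    """
    reports: dict[str, StudyReport] = {}
    for fam_idx, family in enumerate(families):
        scen_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(9000 + fam_idx,))
        )
        scenarios = draw_power_scenarios(
            family, n_scenarios=n_scenarios, rng=scen_rng,
            sigma_scheme=sigma_scheme, n_per_group=n_per_group, c1=c1,
        )
        decisions: list[ReplicateDecision] = []
        n_total = 0
        one_group = 0
        for s_idx, scenario in enumerate(scenarios):
            for r_idx in range(reps_per_scenario):
                rng = _replicate_rng(seed, 1000 * fam_idx + s_idx, r_idx)
                rep = simulate_replicate(scenario, rng, replicate_index=r_idx)
                n_total += 1
                has_uncertain, pattern = _censoring_pattern(rep)
                if not has_uncertain:
                    continue
                dec = evaluate_replicate(rep, alpha=alpha, c1=c1,
                                         methods=methods, var_equal=var_equal)
                decisions.append(dec)
                if pattern == "one_group":
                    one_group += 1
        counts, power, ci = _pool(decisions, methods, alpha)
        n_rep = len(decisions)
        reports[family] = StudyReport(
            kind="power", family=family, methods=methods, alpha=alpha,
            n_replicates_total=n_total, n_rep=n_rep,
            counts=counts, power=power, ci=ci,
            pct_one_group_uncertain=(one_group / n_rep if n_rep else None),
            config={
                "seed": seed, "n_scenarios": n_scenarios,
                "reps_per_scenario": reps_per_scenario,
                "n_per_group": n_per_group, "c1": c1,
                "sigma_scheme": sigma_scheme,
                "t_test": "pooled" if var_equal else "welch",
            },
        )
    return reports


@dataclass
class Type1Report:
    """Empirical type-I error rates under the null parameter sets."""

    alpha: float
    methods: tuple[str, ...]
    reps_per_scenario: int
    scenario_ids: list[str]
    rates: dict[str, dict[str, float]]  # scenario_id -> method -> rate
    cis: dict[str, dict[str, tuple[float, float]]]
    pooled_ctot_uncertain_rate: float | None
    n_uncertain: int
    pooled_ctot_uncertain_ci: tuple[float, float] | None
    config: dict = field(default_factory=dict)


def run_type1_study(
    scenarios: list[Scenario] | None = None,
    reps: int = 10_000,
    alpha: float = 0.05,
    c1: float = 40.0,
    seed: int = 0,
    methods: tuple[str, ...] = ALL_METHODS,
    var_equal: bool = False,
) -> Type1Report:
    """Empirical type-I rates over the null scenarios, all replicates.

    Additionally pools the CTOT rejections over the replicates (across all
    scenarios) with at least one uncertain observation, the subset where
    censoring actually matters, with its own CI at the realized subset size.
    """
    if scenarios is None:
        scenarios = type1_scenarios(c1=c1)
    for sc in scenarios:
        if sc.beta1 != 0.0:
            raise ValidationError(
                f"type-I scenarios require beta1 = 0, got {sc.beta1} in {sc.scenario_id}"
            )
    rates: dict[str, dict[str, float]] = {}
    cis: dict[str, dict[str, tuple[float, float]]] = {}
    uncertain_rejects = 0
    n_uncertain = 0
    for s_idx, scenario in enumerate(scenarios):
        rejects = {m: 0 for m in methods}
        for r_idx in range(reps):
            rng = _replicate_rng(seed, s_idx, r_idx)
            rep = simulate_replicate(scenario, rng, replicate_index=r_idx)
            dec = evaluate_replicate(rep, alpha=alpha, c1=c1, methods=methods,
                                     var_equal=var_equal)
            for m in methods:
                if dec.status[m] == "reject":
                    rejects[m] += 1
            if dec.has_uncertain and "CTOT" in methods:
                n_uncertain += 1
                if dec.status["CTOT"] == "reject":
                    uncertain_rejects += 1
        sid = scenario.scenario_id or f"scenario-{s_idx}"
        rates[sid] = {m: rejects[m] / reps for m in methods}
        cis[sid] = {m: monte_carlo_ci(rates[sid][m], reps) for m in methods}
    pooled = uncertain_rejects / n_uncertain if n_uncertain else None
    return Type1Report(
        alpha=alpha, methods=methods, reps_per_scenario=reps,
        scenario_ids=list(rates),
        rates=rates, cis=cis,
        pooled_ctot_uncertain_rate=pooled,
        n_uncertain=n_uncertain,
        pooled_ctot_uncertain_ci=(monte_carlo_ci(pooled, n_uncertain)
                                  if pooled is not None else None),
        config={"seed": seed, "reps": reps, "c1": c1, "alpha": alpha,
                "t_test": "pooled" if var_equal else "welch"},
    )
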