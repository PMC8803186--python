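"""Simulation of censored qPCR datasets from three ΔCq families.

ΔCq is drawn on the cycle (log) scale with location m = β0 + x·β1 (x = 0
for group 1, x = 1 for group 2) and scale σ:

* ``lognormal``   — ΔCq ~ Normal(m, σ), so e^ΔCq is log-normal;
* ``weibull``     — ΔCq = m + σ·G with G a standard minimum-Gumbel variate
  (CDF 1 − exp(−e^g)), so e^ΔCq is Weibull with shape 1/σ;
* ``loglogistic`` — ΔCq ~ Logistic(m, σ), so e^ΔCq is log-logistic with
  γ = σ.

σ is uniformly the scale of the cycle-scale distribution across families.
Each sample's normalizer Cq is Normal(25, 0.45) and the reported
Cq = ΔCq + normalizer; a sample is "undetermined" when Cq ≥ C1, exactly the
limit-of-detection censoring seen on real instruments.  The uncensored
truth is retained for the BFD benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CqDataset, CqRecord
from .errors import ConfigurationError, ValidationError

FAMILIES = ("lognormal", "weibull", "loglogistic")

NORMALIZER_MEAN = 25.0
NORMALIZER_SD = 0.45


@dataclass(frozen=True)
class Scenario:
    """One simulation parameter set (a hypothetical molecular target)."""

    family: str
    beta0: float  # intercept, cycles
    beta1: float  # group effect, cycles
    sigma: float  # cycle-scale dispersion
    n_per_group: int = 5
    c1: float = 40.0
    normalizer_mean: float = NORMALIZER_MEAN
    normalizer_sd: float = NORMALIZER_SD
    scenario_id: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")


@dataclass
class SimulatedReplicate:
    """One simulated two-group dataset plus its uncensored truth."""

    dataset: CqDataset
    true_delta_y: tuple[list[float], list[float]]
    scenario: Scenario
    replicate_index: int = 0


def sample_delta_cq(
    family: str,
    beta0: float,
    beta1: float,
    sigma: float,
    x: int,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n ΔCq values from one family at location β0 + x·β1, scale σ."""
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown family {family!r}; one of {FAMILIES}")
    m = beta0 + x * beta1
    if family == "lognormal":
        return rng.normal(m, sigma, size=n)
    if family == "weibull":
        # minimum-Gumbel via log of a unit exponential: P(log E <= g) = 1 - e^{-e^g}
        return m + sigma * np.log(rng.exponential(size=n))
    return rng.logistic(loc=m, scale=sigma, size=n)


def simulate_replicate(
    scenario: Scenario,
    rng: np.random.Generator,
    replicate_index: int = 0,
) -> SimulatedReplicate:
    """Simulate one replicate: per-sample normalizer, ΔCq, and censoring.

    Cq = ΔCq + normalizer exactly; a target record is undetermined iff
    Cq ≥ C1.  Group labels ``g1``/``g2`` sort into groups 1 and 2.
    """
    n = scenario.n_per_group
    records: list[CqRecord] = []
    truth: list[list[float]] = [[], []]
    for x, label in ((0, "g1"), (1, "g2")):
        normalizers = rng.normal(scenario.normalizer_mean, scenario.normalizer_sd, size=n)
        delta = sample_delta_cq(scenario.family, scenario.beta0, scenario.beta1,
                                scenario.sigma, x, n, rng)
        truth[x] = list(map(float, delta))
        for i in range(n):
            sid = f"{label}s{i + 1}"
            cq = float(delta[i] + normalizers[i])
            records.append(CqRecord(sample_id=sid, group_label=label,
                                    target_id="normalizer",
                                    cq=float(normalizers[i])))
            if cq < scenario.c1:
                # CqRecord requires Cq > 0; a (vanishingly rare) non-positive
                # draw from a heavy-tailed family is clipped, staying an event.
                records.append(CqRecord(sample_id=sid, group_label=label,
                                        target_id="target", cq=max(cq, 1e-3)))
            else:
                records.append(CqRecord(sample_id=sid, group_label=label,
                                        target_id="target", cq=None,
                                        is_determined=False))
    dataset = CqDataset(records=records, c1=scenario.c1,
                        normalizer_target="normalizer",
                        max_cycles=max(40, int(np.ceil(scenario.c1))))
    return SimulatedReplicate(dataset=dataset,
                              true_delta_y=(truth[0], truth[1]),
                              scenario=scenario,
                              replicate_index=replicate_index)


def draw_power_scenarios(
    family: str,
    n_scenarios: int = 100,
    rng: np.random.Generator | int | None = None,
    sigma_scheme: str = "alternating",
    n_per_group: int = 5,
    c1: float = 40.0,
) -> list[Scenario]:
    """Draw power-study scenarios: β0 ~ N(10, 2.24), β1 ~ N(1, 4.47).

    σ is assigned per ``sigma_scheme``: ``alternating`` cycles 1, 2, 1, 2 …
    across scenario index; ``all1``/``all2`` fix it; ``random`` picks
    uniformly from {1, 2}.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    beta0 = rng.normal(10.0, 2.24, size=n_scenarios)
    beta1 = rng.normal(1.0, 4.47, size=n_scenarios)
    if sigma_scheme == "alternating":
        sigmas = [1.0 if i % 2 == 0 else 2.0 for i in range(n_scenarios)]
    elif sigma_scheme == "all1":
        sigmas = [1.0] * n_scenarios
    elif sigma_scheme == "all2":
        sigmas = [2.0] * n_scenarios
    elif sigma_scheme == "random":
        sigmas = list(rng.choice([1.0, 2.0], size=n_scenarios))
    else:
        raise ConfigurationError(f"unknown sigma_scheme {sigma_scheme!r}")
    return [
        Scenario(family=family, beta0=float(beta0[i]), beta1=float(beta1[i]),
                 sigma=float(sigmas[i]), n_per_group=n_per_group, c1=c1,
                 scenario_id=f"{family}-{i}")
        for i in range(n_scenarios)
    ]


def type1_scenarios(n_per_group: int = 5, c1: float = 40.0) -> list[Scenario]:
    """The four null (β1 = 0) log-normal parameter sets.

    Set 1: β0 = 5, σ = 1; Set 2: β0 = 10, σ = 1; Set 3: β0 = 5, σ = 2;
    Set 4: β0 = 10, σ = 2.
    """
    grid = [(5.0, 1.0), (10.0, 1.0), (5.0, 2.0), (10.0, 2.0)]
    return [
        Scenario(family="lognormal", beta0=b0, beta1=0.0, sigma=s,
                 n_per_group=n_per_group, c1=c1,
                 scenario_id=f"null-b0{b0:g}-s{s:g}")
        for b0, s in grid
    ]
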