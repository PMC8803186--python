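"""Interpretable summaries of censored ΔCq data.

Mirrors the interpretable parameters of time-to-event analysis: the
cycle-to-threshold rate (hazard analogue), its ratio between groups
(hazard-ratio analogue, estimated by the O/E ratio), the per-group
Kaplan-Meier median ΔY, and the proportion of uncertain quantifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .normalize import NormalizedDataset
from .ranks import build_risk_table


@dataclass
class SummaryStats:
    """Group-wise interpretable parameters for one target."""

    n1: int
    n2: int
    proportion_uncertain: tuple[float, float]
    km_median_delta_y: tuple[float | None, float | None]  # None = not reached
    o_totals: tuple[int, int]
    e_totals: tuple[float, float]
    ctot_ratio: float | None  # None when undefined (a group without events)


def _km_median(values: np.ndarray, phi: np.ndarray) -> float | None:
    """Smallest event value d with Kaplan-Meier Ŝ(d) <= 0.5, or None."""
    event_values = np.unique(values[phi == 1])
    s = 1.0
    for d in event_values:
        at_risk = int(np.sum(values >= d))
        events = int(np.sum((phi == 1) & (values == d)))
        s *= 1.0 - events / at_risk
        if s <= 0.5 + 1e-12:
            return float(d)
    return None


def summarize(data: NormalizedDataset) -> SummaryStats:
    """Compute proportions uncertain, KM medians and the O/E CTOT ratio.

    The CTOT ratio is (O1/E1)/(O2/E2) from the pooled risk table with unit
    weights — a standard score-based surrogate for the rate ratio that is
    closed-form and stable at very small group sizes.  It is undefined
    (None) unless both expected totals and the group-2 observed total are
    positive.
    """
    values = np.array([o.delta_y for o in data.observations], dtype=float)
    phi = np.array([o.phi for o in data.observations], dtype=int)
    group = np.array([o.group for o in data.observations], dtype=int)

    props = []
    medians = []
    for g in (1, 2):
        mask = group == g
        props.append(float(np.mean(phi[mask] == 0)))
        medians.append(_km_median(values[mask], phi[mask]))

    rows = build_risk_table(data)
    o1 = sum(r.o_d1 for r in rows)
    o2 = sum(r.o_d2 for r in rows)
    e1 = sum(r.e_d1 for r in rows)
    e2 = sum(r.o_d * r.p_d2 / r.p_d for r in rows)

    if e1 > 0 and e2 > 0 and o2 > 0:
        ratio = (o1 / e1) / (o2 / e2)
    else:
        ratio = None

    return SummaryStats(
        n1=data.n1, n2=data.n2,
        proportion_uncertain=(props[0], props[1]),
        km_median_delta_y=(medians[0], medians[1]),
        o_totals=(o1, o2),
        e_totals=(e1, e2),
        ctot_ratio=ratio,
    )
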