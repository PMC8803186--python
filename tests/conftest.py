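"""Shared fixtures and independent oracles for the test suite.

The exact-test oracle below deliberately avoids the package's score
reformulation: for every candidate labeling it rebuilds the risk table from
scratch with plain Python loops and recomputes the weighted statistic U, so
agreement with the package's subset-sum enumeration validates both the
p-value and the score identity at once.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ctot.normalize import NormalizedDataset, NormalizedObservation


def make_dataset(group1, group2, c1=40.0, target="t"):
    """Build a NormalizedDataset from [(delta_y, phi), ...] per group."""
    obs = []
    for g, items in ((1, group1), (2, group2)):
        for i, (value, phi) in enumerate(items):
            obs.append(
                NormalizedObservation(
                    sample_id=f"g{g}s{i}", group=g, delta_y=float(value),
                    phi=int(phi), normalizer_cq=25.0,
                    raw_cq=(25.0 + float(value)) if phi else None,
                )
            )
    return NormalizedDataset(target_id=target, c1=c1, observations=obs)


@pytest.fixture
def three_row_dataset():
    """Group 1 events {1, 3}; group 2 event {2} and a censoring bound 4."""
    return make_dataset([(1, 1), (3, 1)], [(2, 1), (4, 0)])


def random_censored_dataset(rng, max_per_group=6, tie_grid=0.5):
    """Random small dataset on a coarse value grid (so ties occur)."""
    n1 = int(rng.integers(2, max_per_group + 1))
    n2 = int(rng.integers(2, max_per_group + 1))
    g1 = [(tie_grid * int(rng.integers(1, 9)), int(rng.random() < 0.75))
          for _ in range(n1)]
    g2 = [(tie_grid * int(rng.integers(1, 9)), int(rng.random() < 0.75))
          for _ in range(n2)]
    return make_dataset(g1, g2)


# ---------------------------------------------------------------------------
# Independent oracle: weighted statistic by direct risk-table construction.
# ---------------------------------------------------------------------------

def oracle_statistic(values, phi, labels, fh_p=0.0, fh_q=0.0):
    """(U, V) by direct tabulation; labels are 1/2 per observation."""
    detection_points = sorted({v for v, e in zip(values, phi) if e})
    s = 1.0
    u = 0.0
    var = 0.0
    for d in detection_points:
        p1 = sum(1 for v, l in zip(values, labels) if v >= d and l == 1)
        p = sum(1 for v in values if v >= d)
        o1 = sum(1 for v, e, l in zip(values, phi, labels) if e and v == d and l == 1)
        o = sum(1 for v, e in zip(values, phi) if e and v == d)
        w = s ** fh_p * (1.0 - s) ** fh_q
        u += w * (o1 - o * p1 / p)
        if p > 1:
            frac = p1 / p
            var += w * w * o * frac * (1 - frac) * (p - o) / (p - 1)
        s *= 1.0 - o / p
    return u, var


def oracle_exact_pvalue(values, phi, n1, alternative="two_sided",
                        fh_p=0.0, fh_q=0.0, tol=1e-9):
    """Exact permutation p-value rebuilding the risk table per labeling.

    The observed group 1 is the first ``n1`` observations.
    """
    n = len(values)
    stats = []
    for subset in itertools.combinations(range(n), n1):
        chosen = set(subset)
        labels = [1 if i in chosen else 2 for i in range(n)]
        stats.append(oracle_statistic(values, phi, labels, fh_p, fh_q)[0])
    stats = np.array(stats)
    labels_obs = [1 if i < n1 else 2 for i in range(n)]
    u_obs = oracle_statistic(values, phi, labels_obs, fh_p, fh_q)[0]
    mu = stats.mean()
    if alternative == "two_sided":
        count = int(np.sum(np.abs(stats - mu) >= abs(u_obs - mu) - tol))
    elif alternative == "rate1_greater":
        count = int(np.sum(stats >= u_obs - tol))
    else:
        count = int(np.sum(stats <= u_obs + tol))
    return count / len(stats)


def dataset_arrays(data: NormalizedDataset):
    """(values, phi) with group-1 observations first, plus n1."""
    ordered = sorted(data.observations, key=lambda o: o.group)
    values = [o.delta_y for o in ordered]
    phi = [o.phi for o in ordered]
    n1 = sum(1 for o in ordered if o.group == 1)
    return values, phi, n1
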