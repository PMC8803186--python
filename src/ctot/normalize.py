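"""Normalization of Cq values with censoring propagation.

The normalized outcome for a sample is ΔY = Cq(target) − Cq(normalizer),
the familiar ΔCq of relative quantification.  When the target's Cq is
undetermined or at/above the quality cutoff C1, the true ΔY is only known
to satisfy ΔY ≥ C1 − Cq(normalizer): the observation is right-censored at
that per-sample bound.  The event indicator φ is 1 exactly when
Cq < C1 (strict inequality: a Cq equal to C1 is censored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .data import CqDataset
from .errors import ValidationError


@dataclass(frozen=True)
class NormalizedObservation:
    """One sample's (ΔY, φ) outcome for one target.

    When ``phi == 1``, ``delta_y`` is the observed ΔY; when ``phi == 0``
    it is the censoring bound C1 − Cq(normalizer), a lower bound on the
    true ΔY.
    """

    sample_id: str
    group: int  # 1 or 2
    delta_y: float
    phi: int  # event indicator: 1 = threshold reached before C1
    normalizer_cq: float
    raw_cq: float | None = None


@dataclass
class NormalizedDataset:
    """All (ΔY, φ) pairs for one target, split into exactly two groups."""

    target_id: str
    c1: float
    observations: list[NormalizedObservation] = field(default_factory=list)
    group_labels: tuple[str, str] = ("1", "2")

    def __post_init__(self) -> None:
        groups = {o.group for o in self.observations}
        if groups - {1, 2}:
            raise ValidationError(f"groups must be 1 or 2, got {groups}")
        if groups != {1, 2}:
            raise ValidationError("both groups must be nonempty")
        seen: set[str] = set()
        for o in self.observations:
            if o.sample_id in seen:
                raise ValidationError(f"duplicate sample {o.sample_id!r}")
            seen.add(o.sample_id)

    @property
    def n1(self) -> int:
        return sum(1 for o in self.observations if o.group == 1)

    @property
    def n2(self) -> int:
        return sum(1 for o in self.observations if o.group == 2)

    def group_values(self, group: int) -> list[float]:
        return [o.delta_y for o in self.observations if o.group == group]


def normalize_target(
    dataset: CqDataset,
    target: str,
    c1: float | None = None,
    *,
    group_order: tuple[str, str] | None = None,
) -> NormalizedDataset:
    """Compute (ΔY, φ) pairs for one target of a :class:`CqDataset`.

    Parameters
    ----------
    dataset
        Raw Cq records.
    target
        The target to normalize (must not be the normalizer itself).
    c1
        Quality cutoff in cycles; defaults to ``dataset.c1``.
    group_order
        Explicit mapping of group labels onto groups 1 and 2.  Defaults to
        the two distinct labels in sorted order.  Direction matters for
        one-sided tests.

    Notes
    -----
    Samples that have a record for the normalizer but none for ``target``
    are excluded with a warning: missingness is not censoring, which always
    comes with the auxiliary bound Cq ≥ C1.
    """
    if c1 is None:
        c1 = dataset.c1
    if target == dataset.normalizer_target:
        raise ValidationError("cannot analyze the normalizer against itself")
    records = dataset.records_for(target)
    if not records:
        raise ValidationError(f"no records for target {target!r}")

    labels = sorted({r.group_label for r in records})
    if group_order is not None:
        if sorted(group_order) != labels:
            raise ValidationError(
                f"group_order {group_order} does not match labels {labels}"
            )
        labels = list(group_order)
    if len(labels) != 2:
        raise ValidationError(f"exactly two group labels required, got {labels}")
    group_of = {labels[0]: 1, labels[1]: 2}

    all_samples = {
        r.sample_id
        for r in dataset.records
        if r.target_id == dataset.normalizer_target
    }
    covered = {r.sample_id for r in records}
    skipped = all_samples - covered
    if skipped:
        warnings.warn(
            f"samples missing a record for target {target!r} are excluded "
            f"(missingness, not censoring): {sorted(skipped)}",
            stacklevel=2,
        )

    observations: list[NormalizedObservation] = []
    for rec in records:
        norm = dataset.normalizer_record(rec.sample_id)
        if not norm.is_determined or norm.cq >= c1:
            raise ValidationError(
                f"sample {rec.sample_id!r}: the method requires a well-observed "
                f"Cq value of the normalizer (determined and < C1={c1}); got "
                f"{'undetermined' if not norm.is_determined else norm.cq}"
            )
        if rec.is_determined and rec.cq < c1:
            obs = NormalizedObservation(
                sample_id=rec.sample_id,
                group=group_of[rec.group_label],
                delta_y=rec.cq - norm.cq,
                phi=1,
                normalizer_cq=norm.cq,
                raw_cq=rec.cq,
            )
        else:
            # Censored: either instrument-undetermined (true Cq >= run length
            # >= c1) or reported at/above c1; bound is always c1 - normalizer.
            obs = NormalizedObservation(
                sample_id=rec.sample_id,
                group=group_of[rec.group_label],
                delta_y=c1 - norm.cq,
                phi=0,
                normalizer_cq=norm.cq,
                raw_cq=rec.cq if rec.is_determined else None,
            )
        observations.append(obs)

    return NormalizedDataset(
        target_id=target,
        c1=c1,
        observations=observations,
        group_labels=(labels[0], labels[1]),
    )
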