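"""Domain types and delimited-text I/O for raw qPCR Cq tables.

qPCR instruments export long-format tables with one row per (sample, target)
reaction.  The quantification cycle (Cq) is either a positive number of
cycles or an "Undetermined" token when the fluorescence threshold was never
reached within the run.  Parsing keeps undetermined reactions as explicit
records; censoring relative to the quality cutoff C1 is applied downstream
so that one file supports sensitivity analysis at different cutoffs
(e.g. C1 = 32 vs 40).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ConfigurationError, ParseError, ValidationError

#: Tokens commonly emitted by instrument software for reactions that never
#: crossed the fluorescence threshold.
DEFAULT_UNDETERMINED_TOKENS = ("Undetermined", "undetermined", "NA", "", "NaN")

DEFAULT_COLUMNS = {
    "sample": "sample",
    "group": "group",
    "target": "target",
    "cq": "cq",
}


@dataclass(frozen=True)
class CqRecord:
    """One qPCR reaction: a (sample, target) pair with its reported Cq.

    ``is_determined`` is False when the instrument reported no Cq; in that
    case ``cq`` is None.  A determined record always carries a finite,
    strictly positive Cq in cycles.
    """

    sample_id: str
    group_label: str
    target_id: str
    cq: float | None = None
    is_determined: bool = True

    def __post_init__(self) -> None:
        if self.is_determined:
            if self.cq is None:
                raise ValidationError(
                    f"determined record ({self.sample_id}, {self.target_id}) lacks a Cq"
                )
            if not (self.cq > 0 and self.cq == self.cq and self.cq != float("inf")):
                raise ValidationError(
                    f"Cq must be finite and > 0, got {self.cq!r} for "
                    f"({self.sample_id}, {self.target_id})"
                )
        elif self.cq is not None:
            raise ValidationError(
                f"undetermined record ({self.sample_id}, {self.target_id}) carries a Cq"
            )


@dataclass
class CqDataset:
    """A collection of CqRecords plus assay metadata.

    Parameters
    ----------
    records
        One record per (sample, target) pair.
    c1
        Assay-specific maximum quality cycle; Cq values at or above ``c1``
        are treated as right-censored downstream.
    normalizer_target
        The target used as the per-sample normalizer (reference assay).
    max_cycles
        Instrument run length in cycles (default 40).
    """

    records: list[CqRecord] = field(default_factory=list)
    c1: float = 40.0
    normalizer_target: str = "normalizer"
    max_cycles: int = 40

    def __post_init__(self) -> None:
        if not (0 < self.c1 <= self.max_cycles):
            raise ValidationError(
                f"require 0 < c1 <= max_cycles, got c1={self.c1}, max_cycles={self.max_cycles}"
            )
        seen: set[tuple[str, str]] = set()
        samples: set[str] = set()
        normalized: set[str] = set()
        for rec in self.records:
            key = (rec.sample_id, rec.target_id)
            if key in seen:
                raise ValidationError(f"duplicate (sample, target) pair {key}")
            seen.add(key)
            samples.add(rec.sample_id)
            if rec.target_id == self.normalizer_target:
                normalized.add(rec.sample_id)
        missing = samples - normalized
        if missing:
            raise ValidationError(
                f"samples without a normalizer ({self.normalizer_target!r}) record: "
                f"{sorted(missing)}"
            )

    @property
    def target_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.target_id != self.normalizer_target and rec.target_id not in out:
                out.append(rec.target_id)
        return out

    def records_for(self, target_id: str) -> list[CqRecord]:
        return [r for r in self.records if r.target_id == target_id]

    def normalizer_record(self, sample_id: str) -> CqRecord:
        for rec in self.records:
            if rec.sample_id == sample_id and rec.target_id == self.normalizer_target:
                return rec
        raise ValidationError(f"no normalizer record for sample {sample_id!r}")

    def with_c1(self, c1: float) -> "CqDataset":
        """Same data under a different quality cutoff (sensitivity analysis)."""
        ds = replace(self, c1=c1)
        return ds


def _parse_cq_cell(
    cell: str, tokens: Sequence[str], row_number: int
) -> tuple[float | None, bool]:
    text = cell.strip()
    if text in tokens:
        return None, False
    if "," in text:
        raise ParseError(
            f"row {row_number}: comma in Cq cell {cell!r}; use a decimal point "
            "(comma decimals are not accepted)"
        )
    try:
        return float(text), True
    except ValueError:
        raise ParseError(
            f"row {row_number}: cannot parse Cq cell {cell!r} "
            f"(not numeric and not one of the undetermined tokens {list(tokens)})"
        ) from None


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_cq_table(
    path: str | Path,
    *,
    c1: float = 40.0,
    normalizer_target: str = "normalizer",
    max_cycles: int = 40,
    columns: Mapping[str, str] | None = None,
    undetermined_tokens: Sequence[str] = DEFAULT_UNDETERMINED_TOKENS,
    delimiter: str | None = None,
) -> CqDataset:
    """Read a long-format delimited Cq table into a :class:`CqDataset`.

    ``columns`` maps the logical names ``sample``, ``group``, ``target``,
    ``cq`` onto the file's header names.  Cells matching an entry of
    ``undetermined_tokens`` become undetermined records.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)

    records: list[CqRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for logical, name in cols.items():
            if name not in header:
                raise ConfigurationError(
                    f"required column {name!r} (for {logical!r}) not in header {header}"
                )
        for i, row in enumerate(reader, start=2):
            cq, determined = _parse_cq_cell(row[cols["cq"]], undetermined_tokens, i)
            records.append(
                CqRecord(
                    sample_id=row[cols["sample"]].strip(),
                    group_label=row[cols["group"]].strip(),
                    target_id=row[cols["target"]].strip(),
                    cq=cq,
                    is_determined=determined,
                )
            )
    return CqDataset(
        records=records,
        c1=c1,
        normalizer_target=normalizer_target,
        max_cycles=max_cycles,
    )


def write_cq_table(
    dataset: CqDataset,
    path: str | Path,
    *,
    columns: Mapping[str, str] | None = None,
    delimiter: str = ",",
    undetermined_token: str = "Undetermined",
) -> None:
    """Write a :class:`CqDataset` back to a delimited table.

    Round-trips exactly with :func:`read_cq_table`: Cq values use
    ``repr(float)`` so no precision is lost, and undetermined records are
    written as ``undetermined_token``.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([cols["sample"], cols["group"], cols["target"], cols["cq"]])
        for rec in dataset.records:
            cell = repr(rec.cq) if rec.is_determined else undetermined_token
            writer.writerow([rec.sample_id, rec.group_label, rec.target_id, cell])
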