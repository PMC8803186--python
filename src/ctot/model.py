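"""Model/results objects presenting the cycle-to-threshold analysis.

`CTOTModel` is built from raw Cq data (a :class:`~ctot.data.CqDataset`, a
long-format pandas DataFrame, or a delimited file); ``fit()`` runs the
requested test and returns a :class:`CTOTResults` carrying the statistic,
p-value, interpretable summaries and a ``summary()`` table, in the spirit of
statsmodels model classes.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .comparators import run_method
from .data import DEFAULT_UNDETERMINED_TOKENS, CqDataset, CqRecord, read_cq_table
from .errors import ConfigurationError
from .normalize import NormalizedDataset, normalize_target
from .ranks import TestResult, ctot_test
from .summaries import SummaryStats, summarize


class CTOTModel:
    """Two-group comparison of one qPCR target with censored Cq values.

    Parameters
    ----------
    dataset
        Raw Cq records including the normalizer target.
    target
        The molecular target to analyze.
    c1
        Quality cutoff in cycles (defaults to the dataset's).
    group_order
        Optional explicit (group 1 label, group 2 label); defaults to
        sorted order.  Direction matters for one-sided alternatives.
    """

    def __init__(
        self,
        dataset: CqDataset,
        target: str,
        c1: float | None = None,
        group_order: tuple[str, str] | None = None,
    ) -> None:
        self.dataset = dataset
        self.target = target
        self.c1 = c1 if c1 is not None else dataset.c1
        self.group_order = group_order
        self.data: NormalizedDataset = normalize_target(
            dataset, target, self.c1, group_order=group_order
        )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        target: str,
        normalizer: str,
        c1: float = 40.0,
        columns: Mapping[str, str] | None = None,
        undetermined_tokens=DEFAULT_UNDETERMINED_TOKENS,
        group_order: tuple[str, str] | None = None,
        max_cycles: int = 40,
    ) -> "CTOTModel":
        """Build from a long-format DataFrame (sample, group, target, cq)."""
        cols = {"sample": "sample", "group": "group", "target": "target", "cq": "cq"}
        if columns:
            cols.update(columns)
        for logical, name in cols.items():
            if name not in frame.columns:
                raise ConfigurationError(
                    f"required column {name!r} (for {logical!r}) not in DataFrame"
                )
        records = []
        for _, row in frame.iterrows():
            raw = row[cols["cq"]]
            text = "" if pd.isna(raw) else str(raw).strip()
            if text in undetermined_tokens:
                records.append(CqRecord(str(row[cols["sample"]]), str(row[cols["group"]]),
                                        str(row[cols["target"]]), None, False))
            else:
                records.append(CqRecord(str(row[cols["sample"]]), str(row[cols["group"]]),
                                        str(row[cols["target"]]), float(raw), True))
        dataset = CqDataset(records=records, c1=c1, normalizer_target=normalizer,
                            max_cycles=max_cycles)
        return cls(dataset, target, c1=c1, group_order=group_order)

    @classmethod
    def from_csv(cls, path, target: str, normalizer: str, c1: float = 40.0,
                 group_order: tuple[str, str] | None = None, **read_kwargs) -> "CTOTModel":
        dataset = read_cq_table(path, c1=c1, normalizer_target=normalizer, **read_kwargs)
        return cls(dataset, target, c1=c1, group_order=group_order)

    def fit(
        self,
        method: str = "CTOT",
        fh_p: float = 0.0,
        fh_q: float = 0.0,
        alternative: str = "two_sided",
        pvalue_mode: str = "auto",
        seed: int | None = None,
        var_equal: bool = False,
        **kwargs,
    ) -> "CTOTResults":
        """Run the analysis and return a results object.

        ``method`` is ``CTOT`` (the exact weighted log-rank test) or one of
        the comparator strategies ``MC``, ``CO``, ``CNA``.
        """
        if method == "CTOT":
            result = ctot_test(self.data, fh_p=fh_p, fh_q=fh_q,
                               alternative=alternative, pvalue_mode=pvalue_mode,
                               seed=seed, **kwargs)
        elif method in ("MC", "CO", "CNA"):
            outcome = run_method(method, self.data, alternative=alternative,
                                 var_equal=var_equal)
            result = outcome.result or TestResult(
                statistic_u=0.0, variance_v=0.0, z=0.0, p_value=1.0,
                pvalue_mode="asymptotic", alternative=alternative,
                degenerate=True, degenerate_reason=outcome.degenerate_reason)
        else:
            raise ConfigurationError(f"unknown method {method!r}")
        return CTOTResults(self, method, result)


class CTOTResults:
    """Fitted results: test outcome plus interpretable summaries."""

    def __init__(self, model: CTOTModel, method: str, test: TestResult) -> None:
        self.model = model
        self.method = method
        self.test = test
        self.summaries: SummaryStats = summarize(model.data)

    @property
    def pvalue(self) -> float:
        return self.test.p_value

    @property
    def statistic(self) -> float:
        return self.test.statistic_u

    @property
    def ctot_ratio(self) -> float | None:
        return self.summaries.ctot_ratio

    def as_series(self) -> pd.Series:
        t = self.test
        s = self.summaries
        med = ["not reached" if m is None else m for m in s.km_median_delta_y]
        return pd.Series({
            "target": self.model.target,
            "method": self.method,
            "groups": "{} vs {}".format(*self.model.data.group_labels),
            "n1": s.n1, "n2": s.n2,
            "statistic_u": t.statistic_u, "variance_v": t.variance_v,
            "z": t.z, "p_value": t.p_value,
            "pvalue_mode": t.pvalue_mode, "alternative": t.alternative,
            "fh_p": t.fh_p, "fh_q": t.fh_q,
            "ctot_ratio_o_e": s.ctot_ratio,
            "km_median_dY_g1": med[0], "km_median_dY_g2": med[1],
            "prop_uncertain_g1": s.proportion_uncertain[0],
            "prop_uncertain_g2": s.proportion_uncertain[1],
            "degenerate": t.degenerate,
            "degenerate_reason": t.degenerate_reason,
        })

    def summary(self) -> str:
        """Human-readable analysis summary."""
        ser = self.as_series()
        width = max(len(str(k)) for k in ser.index)
        lines = [f"Cycle-to-threshold analysis ({self.method})",
                 "=" * 46]
        for key, val in ser.items():
            if isinstance(val, float):
                val = f"{val:.6g}"
            lines.append(f"{key:<{width}}  {val}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<CTOTResults {self.method} target={self.model.target!r} "
                f"p={self.test.p_value:.4g}>")
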