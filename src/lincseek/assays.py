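"""Quantification math for qPCR validation experiments.

Relative expression by the 2^-ddCt method, RIP enrichment by the
percent-input method, nuclear/cytoplasmic enrichment ratios, and the
two-sample t-test used to compare groups.  Dispersion is reported both
as SD and as SEM, clearly labelled.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import LincseekError


@dataclass(frozen=True)
class CtRecord:
    """One qPCR cycle-threshold measurement."""

    sample: str
    condition: str
    gene: str
    replicate: int
    ct: float
    input_dilution_factor: Optional[float] = None
    fraction: Optional[str] = None  # nuclear | cytoplasmic | whole

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct) and self.ct > 0):
            raise ValueError(f"Ct must be finite and > 0, got {self.ct}")
        if self.fraction is not None and self.fraction not in (
            "nuclear", "cytoplasmic", "whole"
        ):
            raise ValueError(f"unknown fraction label {self.fraction!r}")


class CtTable:
    """Ct measurements keyed by (sample, gene, replicate)."""

    def __init__(self, records: Iterable[CtRecord]):
        self.records = list(records)
        seen = set()
        for r in self.records:
            key = (r.sample, r.gene, r.replicate)
            if key in seen:
                raise ValueError(f"duplicate replicate {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [r.sample for r in self.records],
                "condition": [r.condition for r in self.records],
                "gene": [r.gene for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "ct": [r.ct for r in self.records],
                "input_dilution_factor": [
                    r.input_dilution_factor for r in self.records
                ],
                "fraction": [r.fraction for r in self.records],
            }
        )

    def shifted(self, delta: float) -> "CtTable":
        """A copy with *delta* added to every Ct (used for invariance checks)."""
        return CtTable(
            CtRecord(r.sample, r.condition, r.gene, r.replicate, r.ct + delta,
                     r.input_dilution_factor, r.fraction)
            for r in self.records
        )

    def write_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | os.PathLike) -> "CtTable":
        df = pd.read_csv(path)
        required = {"sample", "condition", "gene", "replicate", "ct"}
        missing = required - set(df.columns)
        if missing:
            raise LincseekError(f"Ct CSV lacks columns: {sorted(missing)}")
        records = []
        for row in df.itertuples(index=False):
            idf = getattr(row, "input_dilution_factor", None)
            frac = getattr(row, "fraction", None)
            records.append(
                CtRecord(
                    sample=str(row.sample),
                    condition=str(row.condition),
                    gene=str(row.gene),
                    replicate=int(row.replicate),
                    ct=float(row.ct),
                    input_dilution_factor=None if pd.isna(idf) else float(idf),
                    fraction=None if (frac is None or pd.isna(frac)) else str(frac),
                )
            )
        return cls(records)


@dataclass(frozen=True)
class QuantResult:
    """Per-condition fold-change summary for one target gene."""

    target_gene: str
    reference_gene: str
    calibrator: str
    per_condition: pd.DataFrame  # index condition; fold_mean, fold_sd, fold_sem, n
    replicate_folds: pd.DataFrame  # condition, replicate, delta_ct, fold

    def fold(self, condition: str) -> float:
        return float(self.per_condition.loc[condition, "fold_mean"])


def _delta_cts(table: CtTable, target_gene: str, reference_gene: str
               ) -> pd.DataFrame:
    """Per-(condition, sample, replicate) dCt = Ct_target - Ct_reference.

    Pairing is positional on (sample, replicate); a target measurement
    without its reference partner is an error naming the record.
    """
    df = table.to_frame()
    tgt = df[df.gene == target_gene]
    ref = df[df.gene == reference_gene].set_index(["sample", "replicate"])
    if tgt.empty:
        raise LincseekError(f"no Ct records for target gene {target_gene!r}")
    rows = []
    for row in tgt.itertuples(index=False):
        key = (row.sample, row.replicate)
        if key not in ref.index:
            raise LincseekError(
                f"missing reference-gene Ct for sample={row.sample!r} "
                f"replicate={row.replicate} (target {target_gene!r})"
            )
        rows.append(
            {
                "condition": row.condition,
                "sample": row.sample,
                "replicate": row.replicate,
                "fraction": row.fraction,
                "delta_ct": row.ct - float(ref.loc[key, "ct"]),
            }
        )
    return pd.DataFrame(rows)


def ddct_quantify(
    table: CtTable,
    target_gene: str,
    reference_gene: str,
    calibrator: str,
) -> QuantResult:
    """Relative expression by the 2^-ddCt method.

    Per replicate, dCt = Ct(target) - Ct(reference); ddCt subtracts the
    mean dCt of the calibrator condition; fold = 2^-ddCt.  Folds are
    aggregated per condition (mean, SD with ddof=1, SEM = SD/sqrt(n)).
    """
    d = _delta_cts(table, target_gene, reference_gene)
    cal = d[d.condition == calibrator]
    if cal.empty:
        raise LincseekError(f"calibrator condition {calibrator!r} absent")
    cal_mean = float(cal.delta_ct.mean())
    d = d.assign(
        ddct=d.delta_ct - cal_mean,
        fold=lambda x: np.power(2.0, -(x.delta_ct - cal_mean)),
    )
    per = (
        d.groupby("condition")["fold"]
        .agg(fold_mean="mean", fold_sd=lambda s: s.std(ddof=1), n="count")
    )
    per["fold_sem"] = per.fold_sd / np.sqrt(per.n)
    return QuantResult(
        target_gene=target_gene,
        reference_gene=reference_gene,
        calibrator=calibrator,
        per_condition=per[["fold_mean", "fold_sd", "fold_sem", "n"]],
        replicate_folds=d[["condition", "replicate", "delta_ct", "fold"]],
    )


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """RIP/ChIP enrichment as a percentage of the input signal.

    The input Ct is first adjusted for the fraction of lysate saved as
    input (``ct_input - log2(1/input_fraction)``); the result is
    ``100 * 2^(adjusted_input - ct_ip)``.
    """
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-tailed unpaired t-test (classical equal-variance Student's by default).

    Returns ``(t, p)`` with ``n1 + n2 - 2`` degrees of freedom in the
    pooled mode.  Groups of fewer than two values, or a zero pooled
    variance, are errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def fraction_enrichment(
    table: CtTable,
    gene: str,
    reference_gene: str,
    nuclear_label: str = "nuclear",
    cytoplasmic_label: str = "cytoplasmic",
) -> float:
    """Nuclear/cytoplasmic enrichment ratio for *gene*.

    ``ratio = 2^-(dCt_nuclear - dCt_cytoplasmic)`` with dCt taken
    against the reference gene and averaged over replicates per
    fraction; ratio > 1 means nuclear-enriched.
    """
    d = _delta_cts(table, gene, reference_gene)
    frac = d.fraction.fillna(d.condition)
    nuc = d[frac == nuclear_label]
    cyt = d[frac == cytoplasmic_label]
    if nuc.empty or cyt.empty:
        raise LincseekError(
            f"need both {nuclear_label!r} and {cytoplasmic_label!r} fractions"
        )
    return float(2.0 ** -(nuc.delta_ct.mean() - cyt.delta_ct.mean()))
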