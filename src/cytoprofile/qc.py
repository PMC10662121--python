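"""Per-cell quality-control filters, applied in a fixed order.

The pipeline removes cells with any missing parameter, then cells more
than k within-treatment SDs (default 5) from the treatment mean in any
parameter, then draws a balanced random subsample so every treatment
contributes the same number of cells to the ordination. Each step only
deletes rows — values are never edited — and the three steps always run
in this order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_table import parameter_columns

__all__ = [
    "QCReport",
    "drop_incomplete",
    "drop_outliers",
    "balanced_subsample",
    "apply_qc",
]


@dataclass
class QCReport:
    """Row counts removed per step, overall and per treatment."""

    n_input: int = 0
    n_incomplete: int = 0
    n_outliers: int = 0
    n_after_subsample: int = 0
    per_treatment: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            "QC report",
            f"  input cells:            {self.n_input}",
            f"  removed (missing data): {self.n_incomplete}",
            f"  removed (outliers):     {self.n_outliers}",
            f"  retained after subsample: {self.n_after_subsample}",
        ]
        for trt, counts in sorted(self.per_treatment.items()):
            lines.append(f"  {trt}: {counts}")
        return "\n".join(lines)


def drop_incomplete(
    table: pd.DataFrame, report: QCReport | None = None
) -> pd.DataFrame:
    """Remove cells with one or more missing parameter values."""
    params = parameter_columns(table)
    complete = table[params].notna().all(axis=1)
    removed = int((~complete).sum())
    if removed == len(table) and len(table) > 0:
        warnings.warn("every cell has missing data; table is now empty")
    if report is not None:
        report.n_incomplete = removed
        for trt, sub in table.groupby("treatment", observed=True):
            report.per_treatment.setdefault(str(trt), {})["missing"] = int(
                sub[params].isna().any(axis=1).sum()
            )
    return table.loc[complete].reset_index(drop=True)


def drop_outliers(
    table: pd.DataFrame, k: float = 5.0, report: QCReport | None = None
) -> pd.DataFrame:
    """Remove cells > k within-treatment sample SDs from the treatment mean
    in ANY parameter.

    Statistics are computed once from the pre-removal table (single pass,
    so the filter is not idempotent in general). Sample SD uses the n-1
    denominator; a zero-SD parameter removes no cell (every value sits at
    the mean), and a treatment with fewer than two cells is kept whole
    with a warning since its SD is undefined.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    params = parameter_columns(table)
    if table[params].isna().any().any():
        raise ValueError("drop_outliers requires a complete table; run drop_incomplete first")
    keep = pd.Series(True, index=table.index)
    for trt, sub in table.groupby("treatment", observed=True):
        if len(sub) < 2:
            warnings.warn(
                f"treatment {trt!r} has fewer than 2 cells; SD undefined, cells kept"
            )
            continue
        x = sub[params].to_numpy(dtype=float)
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(x - mean) / sd
        z[:, sd == 0] = 0.0
        outlier = (z > k).any(axis=1)
        keep.loc[sub.index[outlier]] = False
        if report is not None:
            report.per_treatment.setdefault(str(trt), {})["outliers"] = int(
                outlier.sum()
            )
    if report is not None:
        report.n_outliers = int((~keep).sum())
    return table.loc[keep].reset_index(drop=True)


def balanced_subsample(
    table: pd.DataFrame,
    n: int | None = None,
    seed: int = 0,
    report: QCReport | None = None,
) -> pd.DataFrame:
    """Sample exactly n cells per treatment, uniformly without replacement.

    ``n=None`` (auto) uses the smallest per-treatment count, so the most
    sparsely sampled treatment sets the common size. Output rows are
    ordered by treatment, then by sampled order; the draw is seeded.
    """
    counts = table.groupby("treatment", observed=True).size()
    if len(counts) == 0:
        return table.copy()
    if n is None:
        n = int(counts.min())
    if n <= 0:
        raise ValueError("subsample size must be positive")
    short = counts[counts < n]
    if len(short):
        raise ValueError(
            f"treatment {short.index[0]!r} has only {int(short.iloc[0])} cells, "
            f"fewer than the requested {n}"
        )
    rng = np.random.default_rng(seed)
    pieces = []
    for trt in counts.index:
        sub = table[table["treatment"] == trt]
        idx = rng.choice(len(sub), size=n, replace=False)
        pieces.append(sub.iloc[idx])
    out = pd.concat(pieces, ignore_index=True)
    if report is not None:
        report.n_after_subsample = len(out)
    return out


def apply_qc(
    table: pd.DataFrame,
    outlier_sd: float = 5.0,
    subsample_n: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, QCReport]:
    """Run the full QC sequence: incomplete -> outliers -> balanced subsample."""
    report = QCReport(n_input=len(table))
    table = drop_incomplete(table, report)
    table = drop_outliers(table, k=outlier_sd, report=report)
    table = balanced_subsample(table, n=subsample_n, seed=seed, report=report)
    report.n_after_subsample = len(table)
    return table, report
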