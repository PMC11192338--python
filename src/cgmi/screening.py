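"""Pearson screening of vegetation indices against growth indices.

Correlates every vegetation index with the four single indicators and the
two composite indices, and selects the model-input indices: those
significant at the chosen level against the target, ranked by |r|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .vegindex import INDEX_NAMES

__all__ = [
    "PAPER_PROTOCOL_INDICES",
    "CorrelationReport",
    "pearson_with_p",
    "correlation_report",
    "select_indices",
]

#: the five indices a practitioner screening chlorophyll/structure-sensitive
#: broadband indices against a composite growth target typically retains.
PAPER_PROTOCOL_INDICES = ("TCARI", "CIrededge", "OSAVI", "DVI", "MNVI")

TARGET_COLUMNS = ("spad", "ph", "lai", "agb", "CGMI1", "CGMI2")


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p-value (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationReport:
    """Index-vs-target correlations plus the index-index matrix."""

    r: pd.DataFrame  # indices x targets
    p: pd.DataFrame  # same shape, two-sided p-values
    index_r: pd.DataFrame  # indices x indices, symmetric, unit diagonal

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"index": idx, "target": tgt, "r": self.r.loc[idx, tgt], "p": self.p.loc[idx, tgt]}
            for idx in self.r.index
            for tgt in self.r.columns
        ]
        return pd.DataFrame(rows)


def correlation_report(
    index_table: pd.DataFrame, growth_table: pd.DataFrame
) -> CorrelationReport:
    """Correlate every vegetation index with every growth target.

    ``index_table`` holds the 12 index columns, ``growth_table`` the four
    raw indicators and the composite columns; rows are matched on
    ``plot_id``.
    """
    merged = index_table.merge(growth_table, on="plot_id", validate="one_to_one")
    targets = [t for t in TARGET_COLUMNS if t in merged.columns]
    r = pd.DataFrame(index=list(INDEX_NAMES), columns=targets, dtype=float)
    p = r.copy()
    for idx in INDEX_NAMES:
        for tgt in targets:
            r.loc[idx, tgt], p.loc[idx, tgt] = pearson_with_p(merged[idx], merged[tgt])
    idx_r = pd.DataFrame(
        np.corrcoef(merged[list(INDEX_NAMES)].to_numpy(), rowvar=False),
        index=list(INDEX_NAMES),
        columns=list(INDEX_NAMES),
    )
    return CorrelationReport(r=r, p=p, index_r=idx_r)


def select_indices(
    report: CorrelationReport,
    target: str = "CGMI2",
    k: int = 5,
    alpha: float = 0.01,
) -> list[str]:
    """Pick the k indices most correlated with the target among those
    significant at level alpha.

    Ties in |r| break by registry order.  If fewer than k indices pass the
    significance filter, all significant ones are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if target not in report.r.columns:
        raise ValueError(f"unknown target {target!r}; have {list(report.r.columns)}")
    significant = [idx for idx in report.r.index if report.p.loc[idx, target] < alpha]
    order = {name: i for i, name in enumerate(INDEX_NAMES)}
    ranked = sorted(
        significant, key=lambda idx: (-abs(report.r.loc[idx, target]), order[idx])
    )
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} indices significant at alpha={alpha} "
            f"against {target}; returning all of them",
            stacklevel=2,
        )
        return ranked
    return ranked[:k]
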