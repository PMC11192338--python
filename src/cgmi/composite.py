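"""Composite growth-index construction.

Four plot-level growth indicators (SPAD, plant height, leaf area index,
above-ground biomass) are min-max normalised to [0, 1] and combined into
two comprehensive growth monitoring indices:

* ``CGMI1`` — equal weights, the arithmetic mean of the four normalised
  indicators;
* ``CGMI2`` — coefficient-of-variation (CV) weights: each indicator's
  weight is its CV (standard deviation over mean, computed on the *raw*
  indicator column) normalised so the four weights sum to one.  More
  variable indicators carry more information about between-plot
  differences and therefore receive larger weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import INDICATOR_COLUMNS

__all__ = [
    "CVWeights",
    "normalize_minmax",
    "coefficient_of_variation",
    "cv_weights",
    "cgmi_equal",
    "cgmi_weighted",
    "build_composite",
]


@dataclass(frozen=True)
class CVWeights:
    """CV weighting breakdown for the four indicators, in SPAD/PH/LAI/AGB order."""

    sd: tuple[float, ...]
    mean: tuple[float, ...]
    cv: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        total = sum(self.weights)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {total!r}")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")


def normalize_minmax(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Min-max scale a column to [0, 1]; returns (scaled, (min, max)).

    The observed minimum maps to 0 and the maximum to 1.  A constant
    column has no scale and raises.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-D column with at least 2 values")
    lo, hi = float(np.min(arr)), float(np.max(arr))
    if hi == lo:
        raise ValueError("constant column: zero range, cannot normalise")
    return (arr - lo) / (hi - lo), (lo, hi)


def coefficient_of_variation(sd: float, mean: float) -> float:
    """CV = standard deviation / mean (mean must be nonzero)."""
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    return sd / mean


def cv_weights(indicators: pd.DataFrame, ddof: int = 0) -> CVWeights:
    """Coefficient-of-variation weights from the raw indicator columns.

    Parameters
    ----------
    indicators
        DataFrame holding the four indicator columns (``spad, ph, lai,
        agb``).  CVs are computed on these raw columns, not on the
        normalised ones: min-max scaling destroys the mean that the CV is
        relative to.
    ddof
        0 for the population SD convention (default), 1 for sample SD.
        The weights are almost insensitive to the choice at n = 66.
    """
    if len(indicators) < 2:
        raise ValueError("need at least 2 plots to compute dispersion")
    sds, means, cvs = [], [], []
    for name in INDICATOR_COLUMNS:
        col = indicators[name].to_numpy(dtype=float)
        mean = float(np.mean(col))
        sd = float(np.std(col, ddof=ddof))
        cvs.append(coefficient_of_variation(sd, mean))
        sds.append(sd)
        means.append(mean)
    total = sum(cvs)
    if total <= 0:
        raise ValueError("all indicator CVs are zero; weights undefined")
    weights = [v / total for v in cvs]
    # renormalise exactly against accumulated float error
    weights[-1] = 1.0 - sum(weights[:-1])
    return CVWeights(sd=tuple(sds), mean=tuple(means), cv=tuple(cvs), weights=tuple(weights))


def weights_from_cvs(cvs) -> tuple[float, ...]:
    """Normalise a sequence of CVs to unit-sum weights."""
    cvs = [float(v) for v in cvs]
    total = sum(cvs)
    if total <= 0:
        raise ValueError("CVs must have positive sum")
    weights = [v / total for v in cvs]
    weights[-1] = 1.0 - sum(weights[:-1])
    return tuple(weights)


def cgmi_equal(U: np.ndarray) -> np.ndarray:
    """Equal-weight composite: row mean of the normalised indicator matrix."""
    U = _check_U(U)
    return U.mean(axis=1)


def cgmi_weighted(U: np.ndarray, weights) -> np.ndarray:
    """CV-weighted composite: row-wise weighted sum of normalised indicators."""
    U = _check_U(U)
    w = np.asarray(
        weights.weights if isinstance(weights, CVWeights) else weights, dtype=float
    )
    if w.shape != (U.shape[1],):
        raise ValueError(f"expected {U.shape[1]} weights, got shape {w.shape}")
    return U @ w


def _check_U(U) -> np.ndarray:
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if np.any(U < -1e-9) or np.any(U > 1 + 1e-9):
        raise ValueError("normalised indicators must lie in [0, 1]")
    return U


def build_composite(
    records: pd.DataFrame, weighting: str = "both", ddof: int = 0
) -> tuple[pd.DataFrame, CVWeights, dict[str, tuple[float, float]]]:
    """Normalise indicators and build the composite index table.

    Returns ``(table, cv_weights, bounds)`` where *table* has columns
    ``plot_id, U1..U4`` plus ``CGMI1`` and/or ``CGMI2`` depending on
    *weighting* (``"equal"``, ``"cv"`` or ``"both"``), and *bounds* maps
    each indicator to the (min, max) used for scaling.  Normalisation
    bounds come from the full dataset, mirroring direct use of the
    observed extrema (a deliberate, documented leakage of the indicator
    range into any later train/test split).
    """
    if weighting not in ("equal", "cv", "both"):
        raise ValueError(f"weighting must be 'equal', 'cv' or 'both', got {weighting!r}")
    U_cols = {}
    bounds = {}
    for i, name in enumerate(INDICATOR_COLUMNS, start=1):
        U_cols[f"U{i}"], bounds[name] = normalize_minmax(records[name])
    table = pd.DataFrame({"plot_id": records["plot_id"].to_numpy(), **U_cols})
    U = table[[f"U{i}" for i in range(1, 5)]].to_numpy()
    w = cv_weights(records[list(INDICATOR_COLUMNS)], ddof=ddof)
    if weighting in ("equal", "both"):
        table["CGMI1"] = cgmi_equal(U)
    if weighting in ("cv", "both"):
        table["CGMI2"] = cgmi_weighted(U, w)
    return table, w, bounds
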