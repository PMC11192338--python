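"""Accuracy metrics, the train/test split, and comparative reporting.

Two R-squared conventions are computed side by side:

* ``r2_ratio`` — regression-sum-of-squares over total-sum-of-squares,
  sum((yhat - mean(y))^2) / sum((y - mean(y))^2).  This ratio equals the
  squared correlation only for least-squares fits and is *not* bounded by
  1 for arbitrary predictions.
* ``r2_conventional`` — 1 - SSE/SST, the usual coefficient of
  determination.

NRMSE normalises the RMSE by the *predicted* values' range by default
(a flag switches to the observed range for comparison with other work),
and MAPE is reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "r2_eq_ratio",
    "r2_conventional",
    "rmse",
    "nrmse",
    "mape",
    "split_data",
    "score_predictions",
    "EvalReport",
]


def _pair(pred, obs):
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("pred and obs must be equal-length with n >= 2")
    return pred, obs


def r2_eq_ratio(pred, obs) -> float:
    """SSR/SST ratio form of R-squared (can exceed 1 off the OLS fit)."""
    pred, obs = _pair(pred, obs)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant observations: R-squared undefined")
    return float(np.sum((pred - obs.mean()) ** 2)) / sst


def r2_conventional(pred, obs) -> float:
    """1 - SSE/SST coefficient of determination."""
    pred, obs = _pair(pred, obs)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant observations: R-squared undefined")
    return 1.0 - float(np.sum((pred - obs) ** 2)) / sst


def rmse(pred, obs) -> float:
    pred, obs = _pair(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def nrmse(pred, obs, normalize_by: str = "predicted") -> float:
    """RMSE over the predicted (default) or observed value range."""
    pred, obs = _pair(pred, obs)
    if normalize_by == "predicted":
        span = float(np.ptp(pred))
        if span == 0:
            raise ValueError("zero predicted range: NRMSE undefined")
    elif normalize_by == "observed":
        span = float(np.ptp(obs))
        if span == 0:
            raise ValueError("zero observed range: NRMSE undefined")
    else:
        raise ValueError("normalize_by must be 'predicted' or 'observed'")
    return rmse(pred, obs) / span


def mape(pred, obs) -> float:
    """Mean absolute percentage error, in percent."""
    pred, obs = _pair(pred, obs)
    zero = np.nonzero(obs == 0)[0]
    if zero.size:
        raise ValueError(f"zero observation at row {int(zero[0])}: MAPE undefined")
    return float(100.0 * np.mean(np.abs((pred - obs) / obs)))


def split_data(n_total: int, n_train: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform random partition into disjoint, exhaustive train/test ids."""
    if not (0 < n_train < n_total):
        raise ValueError(f"need 0 < n_train < n_total, got {n_train}/{n_total}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_total)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def score_predictions(
    pred, obs, nrmse_by: str = "predicted", strict: bool = True
) -> dict[str, float]:
    """All metrics for one prediction/observation pair.

    With ``strict=False``, metrics undefined for the supplied pair (MAPE
    with a zero observation, NRMSE with a degenerate range) are recorded
    as NaN instead of raising, so batch reports survive edge cases like a
    composite index that is exactly 0 at its defining minimum plot.
    """
    out = {
        "r2_ratio": r2_eq_ratio(pred, obs),
        "r2": r2_conventional(pred, obs),
        "rmse": rmse(pred, obs),
    }
    for key, func in (
        ("nrmse", lambda: nrmse(pred, obs, normalize_by=nrmse_by)),
        ("mape", lambda: mape(pred, obs)),
    ):
        if strict:
            out[key] = func()
        else:
            try:
                out[key] = func()
            except ValueError:
                out[key] = float("nan")
    return out


@dataclass
class EvalReport:
    """Per-model train/test metrics plus split metadata."""

    n_train: int
    n_test: int
    seed: int
    target: str = "CGMI2"
    rows: list[dict] = field(default_factory=list)

    def add(self, model: str, subset: str, metrics: dict[str, float]) -> None:
        self.rows.append({"model": model, "subset": subset, **metrics})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        df.insert(0, "target", self.target)
        return df

    def summary(self) -> pd.DataFrame:
        """Wide table, one row per model, percent columns rounded whole."""
        df = self.to_frame()
        wide = df.pivot(index="model", columns="subset", values=["r2", "nrmse", "mape"])
        wide.columns = [f"{m}_{s}" for m, s in wide.columns]
        for col in [c for c in wide.columns if c.startswith("mape")]:
            wide[col] = wide[col].round(0).astype(int).astype(str) + "%"
        return wide.round(4)
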