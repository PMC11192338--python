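"""Whale optimization algorithm (WOA) and its coupling to the BPNN.

WOA is a population metaheuristic modelled on the bubble-net hunting of
humpback whales.  Each of the ``pop`` agents is a candidate solution in a
bounded box.  Per iteration every agent takes one of three moves:

* **encircling** (p < 0.5, |A| < 1): step toward the best agent,
  ``x <- x_best - A * |2 r x_best - x|``, with ``A = 2 a r - a`` and the
  control parameter ``a`` decaying linearly from 2 to 0 over iterations;
* **exploration** (p < 0.5, |A| >= 1): the same step but around a random
  agent instead of the best, which keeps global search alive early on;
* **spiral** (p >= 0.5): a logarithmic-spiral approach to the best agent,
  ``x <- x_best + |x_best - x| * e^(b l) cos(2 pi l)`` with l ~ U(-1, 1).

The leader is updated greedily, so the best-fitness trace is monotone
non-increasing.  Positions are clamped to the box after every move.

``woa_bpnn`` uses WOA to pick the starting weights and thresholds of the
back-propagation network: the search space is the flattened parameter
vector in [-1, 1]^D, the fitness is the raw-network training MSE, and the
best position found then seeds Levenberg-Marquardt refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    ModelConfig,
    TrainedModel,
    _minmax_apply,
    _minmax_fit,
    bpnn_forward,
    bpnn_param_count,
    holdout_ids,
    train_bpnn,
)

__all__ = ["WOAConfig", "WOAResult", "woa_minimize", "woa_bpnn"]


@dataclass(frozen=True)
class WOAConfig:
    """Swarm size, iteration budget, box bounds and spiral shape."""

    pop: int = 10
    iterations: int = 60
    bounds: tuple[float, float] = (-1.0, 1.0)
    spiral_b: float = 1.0
    seed: int = 0
    random_agent_branch: bool = True  # disable for an exploitation-only ablation

    def __post_init__(self) -> None:
        if self.pop < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("need at least 1 iteration")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError(f"lower bound must be < upper bound, got {self.bounds}")


@dataclass
class WOAResult:
    """Best position/fitness and the per-iteration best-fitness trace."""

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray = field(repr=False)


def woa_minimize(objective, dim: int, config: WOAConfig | None = None) -> WOAResult:
    """Minimise ``objective`` over the box with the whale swarm.

    The trace has length ``iterations + 1`` (initial population included)
    and is monotone non-increasing.  Fully deterministic given the seed.
    """
    config = config or WOAConfig()
    lo, hi = config.bounds
    rng = np.random.default_rng(config.seed)
    T = config.iterations

    X = rng.uniform(lo, hi, size=(config.pop, dim))
    fitness = np.array([float(objective(x)) for x in X])
    if not np.all(np.isfinite(fitness)):
        bad = int(np.argmax(~np.isfinite(fitness)))
        raise ValueError(
            f"objective returned non-finite value at initial position {X[bad]}"
        )
    best_i = int(np.argmin(fitness))
    best_x = X[best_i].copy()
    best_f = float(fitness[best_i])
    trace = [best_f]

    for t in range(1, T + 1):
        a = 2.0 - 2.0 * t / T
        for i in range(config.pop):
            p = rng.uniform()
            r = rng.uniform(size=dim)
            A = 2.0 * a * r - a
            if p < 0.5:
                explore = config.random_agent_branch and np.max(np.abs(A)) >= 1.0
                target = X[rng.integers(config.pop)] if explore else best_x
                step = np.abs(2.0 * r * target - X[i])
                X[i] = target - A * step
            else:
                l = rng.uniform(-1.0, 1.0)
                dist = np.abs(best_x - X[i])
                X[i] = best_x + dist * np.exp(config.spiral_b * l) * np.cos(2.0 * np.pi * l)
            np.clip(X[i], lo, hi, out=X[i])
        for i in range(config.pop):
            f = float(objective(X[i]))
            if np.isfinite(f) and f < best_f:
                best_f = f
                best_x = X[i].copy()
        trace.append(best_f)

    return WOAResult(best_position=best_x, best_fitness=best_f, trace=np.asarray(trace))


def woa_bpnn(
    X_train: np.ndarray,
    y_train: np.ndarray,
    woa_config: WOAConfig | None = None,
    bpnn_config: ModelConfig | None = None,
) -> tuple[TrainedModel, WOAResult]:
    """WOA-initialised BPNN: search the weight/threshold vector, then refine.

    The swarm minimises the training MSE of the raw forward pass (no inner
    training during the search); the best position becomes the
    Levenberg-Marquardt starting point.  Architecture is fixed at
    n_in-hidden-1; only weights and thresholds are searched.
    """
    woa_config = woa_config or WOAConfig()
    bpnn_config = bpnn_config or ModelConfig("BPNN")
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    y = np.asarray(y_train, dtype=float).ravel()
    hidden = int(bpnn_config["hidden"])
    dim = bpnn_param_count(X.shape[1], hidden)

    scaler = _minmax_fit(X)
    Xs = _minmax_apply(X, scaler)

    # the rows L-M will hold out for early stopping stay out of the WOA
    # objective too, so no parameter selection ever sees them
    val_ids = holdout_ids(X.shape[0], bpnn_config)
    fit_mask = np.ones(X.shape[0], dtype=bool)
    fit_mask[val_ids] = False
    X_fit, y_fit = Xs[fit_mask], y[fit_mask]

    def fitness(position: np.ndarray) -> float:
        resid = bpnn_forward(position, X_fit, hidden) - y_fit
        return float(np.mean(resid**2))

    result = woa_minimize(fitness, dim, woa_config)
    model = train_bpnn(X, y, config=bpnn_config, init=result.best_position, val_ids=val_ids)
    model.name = "WOA-BPNN"
    return model, result
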