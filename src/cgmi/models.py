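"""Regression models for inverting the composite growth index from
vegetation indices.

Six regressors are exposed behind one ``fit_model``/``predict`` surface:

====== =========================================================
MLR    ordinary least squares with intercept
PLS    2-component partial least squares
SVR    epsilon-insensitive support vector regression, RBF kernel
       (penalty C = 20, kernel scale sigma = 30)
RF     random forest, 100 trees, minimum leaf size 4
RBFNN  radial-basis network, spread 100, incremental center addition
BPNN   5-12-1 feed-forward network, tanh hidden layer, trained by
       Levenberg-Marquardt (default) or mini-batch gradient descent
====== =========================================================

The linear and kernel baselines delegate to scikit-learn.  The two
networks are implemented natively: the BPNN exposes its flattened
weight/threshold vector so a metaheuristic can search it directly, and
the RBF network follows the classic "add a center at the worst-fit
point" construction controlled by a spread parameter.

Neural models min-max scale features (and, if needed, the target) to
[0, 1] internally; scaling parameters live in the trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR as _SkSVR

__all__ = [
    "MODEL_NAMES",
    "ModelConfig",
    "TrainedModel",
    "bpnn_param_count",
    "bpnn_forward",
    "train_bpnn",
    "fit_model",
    "predict",
]

MODEL_NAMES = ("MLR", "PLS", "SVR", "RF", "RBFNN", "BPNN")

_DEFAULT_HYPERPARAMS: dict[str, dict[str, Any]] = {
    "MLR": {},
    "PLS": {"n_components": 2},
    "SVR": {"penalty": 20.0, "kernel_scale": 30.0, "epsilon": 0.01},
    "RF": {"n_trees": 100, "min_leaf": 4},
    "RBFNN": {"spread": 100.0, "goal": 1e-4, "max_centers": 25},
    "BPNN": {
        "hidden": 12,
        "max_iter": 1000,
        "goal": 1e-4,
        "learning_rate": 0.1,
        "batch_size": 9,
        "algorithm": "lm",
        # fraction of training rows held out to stop L-M when the
        # held-out error rises (max_fail consecutive rises); 0 disables
        # and training runs purely to the goal / iteration budget
        "val_fraction": 0.15,
        "max_fail": 6,
    },
}


@dataclass(frozen=True)
class ModelConfig:
    """Model name, hyperparameters and seed.

    Unknown hyperparameter keys are rejected; omitted ones take the
    defaults above.
    """

    name: str
    hyperparams: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; valid: {MODEL_NAMES}")
        allowed = _DEFAULT_HYPERPARAMS[self.name]
        unknown = set(self.hyperparams) - set(allowed)
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.name}: {sorted(unknown)}")
        merged = {**allowed, **self.hyperparams}
        for key, val in merged.items():
            if key == "algorithm":
                if val not in ("lm", "gd"):
                    raise ValueError(f"algorithm must be 'lm' or 'gd', got {val!r}")
            elif key == "val_fraction":
                if not (isinstance(val, (int, float)) and 0 <= val < 1):
                    raise ValueError(f"val_fraction={val!r} must be in [0, 1)")
            elif key == "max_iter":
                if not (isinstance(val, int) and val >= 0):
                    raise ValueError(f"max_iter={val!r} must be a non-negative integer")
            elif not (isinstance(val, (int, float)) and val > 0):
                raise ValueError(f"hyperparameter {key}={val!r} must be positive")
        object.__setattr__(self, "hyperparams", merged)

    def __getitem__(self, key: str) -> Any:
        return self.hyperparams[key]


@dataclass
class TrainedModel:
    """Fitted model with opaque state and training metadata."""

    name: str
    state: Any
    scaler: dict[str, np.ndarray] | None = None
    iterations: int = 0
    final_loss: float = float("nan")
    loss_trace: np.ndarray | None = None


# ---------------------------------------------------------------------------
# BPNN: single hidden tanh layer, linear output


def bpnn_param_count(n_in: int, hidden: int = 12) -> int:
    """Length of the flattened parameter vector of an n_in-hidden-1 net."""
    return n_in * hidden + hidden + hidden + 1


def _unpack(params: np.ndarray, n_in: int, hidden: int):
    expected = bpnn_param_count(n_in, hidden)
    params = np.asarray(params, dtype=float).ravel()
    if params.size != expected:
        raise ValueError(f"expected {expected} parameters, got {params.size}")
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite network parameters")
    k = n_in * hidden
    W1 = params[:k].reshape(hidden, n_in)
    b1 = params[k : k + hidden]
    w2 = params[k + hidden : k + 2 * hidden]
    b2 = params[k + 2 * hidden]
    return W1, b1, w2, b2


def bpnn_forward(params: np.ndarray, X: np.ndarray, hidden: int = 12) -> np.ndarray:
    """Network output: w2 . tanh(W1 x + b1) + b2, per row of X.

    Parameter layout: input-to-hidden weights (row-major), hidden biases,
    hidden-to-output weights, output bias.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W1, b1, w2, b2 = _unpack(params, X.shape[1], hidden)
    return np.tanh(X @ W1.T + b1) @ w2 + b2


def _bpnn_jacobian(params: np.ndarray, X: np.ndarray, hidden: int):
    """Residual jacobian d(yhat)/d(params), shape (n, D)."""
    n, n_in = X.shape
    W1, b1, w2, b2 = _unpack(params, n_in, hidden)
    Z = np.tanh(X @ W1.T + b1)  # (n, hidden)
    dZ = 1.0 - Z**2
    J = np.empty((n, params.size))
    k = n_in * hidden
    # d/dW1[j, i] = w2_j * (1 - z_j^2) * x_i
    J[:, :k] = (dZ * w2).repeat(n_in, axis=1) * np.tile(X, hidden)
    J[:, k : k + hidden] = dZ * w2
    J[:, k + hidden : k + 2 * hidden] = Z
    J[:, k + 2 * hidden] = 1.0
    return J, Z @ w2 + b2


def _minmax_fit(X: np.ndarray) -> dict[str, np.ndarray]:
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return {"lo": lo, "span": span}


def _minmax_apply(X: np.ndarray, sc: dict[str, np.ndarray]) -> np.ndarray:
    return (X - sc["lo"]) / sc["span"]


def train_bpnn(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig | None = None,
    init: np.ndarray | None = None,
    scale: bool = True,
    val_ids: np.ndarray | None = None,
) -> TrainedModel:
    """Train the tanh network on (X, y) by Levenberg-Marquardt.

    Starts from ``init`` if given, else from seeded uniform [-1, 1]
    weights.  Stops when training MSE reaches the goal, the iteration
    budget is exhausted, or the damping factor saturates.  With
    ``algorithm='gd'`` a mini-batch gradient-descent fallback honours the
    configured batch size and learning rate instead.
    """
    config = config or ModelConfig("BPNN")
    if config.name != "BPNN":
        raise ValueError(f"expected a BPNN config, got {config.name!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    hidden = int(config["hidden"])
    D = bpnn_param_count(X.shape[1], hidden)
    if X.shape[0] < max(2 * D // 10, 2):
        import warnings

        warnings.warn(
            f"only {X.shape[0]} samples for {D} parameters; the network will "
            "likely memorise the training set",
            stacklevel=2,
        )

    scaler = _minmax_fit(X) if scale else None
    Xs = _minmax_apply(X, scaler) if scale else X

    rng = np.random.default_rng(config.seed)
    params = (
        np.asarray(init, dtype=float).ravel().copy()
        if init is not None
        else rng.uniform(-1.0, 1.0, size=D)
    )
    if params.size != D:
        raise ValueError(f"init has {params.size} parameters, expected {D}")

    goal = float(config["goal"])
    max_iter = int(config["max_iter"])
    if config["algorithm"] == "gd":
        params, trace, iters = _train_gd(
            params, Xs, y, hidden, max_iter, goal,
            float(config["learning_rate"]), int(config["batch_size"]), rng,
        )
    else:
        if val_ids is None:
            val_ids = holdout_ids(Xs.shape[0], config)
        if len(val_ids) > 0:
            fit_mask = np.ones(Xs.shape[0], dtype=bool)
            fit_mask[val_ids] = False
            params, trace, iters = _train_lm(
                params, Xs[fit_mask], y[fit_mask], hidden, max_iter, goal,
                X_val=Xs[val_ids], y_val=y[val_ids], max_fail=int(config["max_fail"]),
            )
        else:
            params, trace, iters = _train_lm(params, Xs, y, hidden, max_iter, goal)

    final = _mse(params, Xs, y, hidden)
    if not np.isfinite(final):
        raise FloatingPointError(f"training diverged: final loss {final}")
    return TrainedModel(
        name="BPNN",
        state={"params": params, "hidden": hidden},
        scaler=scaler,
        iterations=iters,
        final_loss=float(final),
        loss_trace=np.asarray(trace),
    )


def holdout_ids(n: int, config: ModelConfig) -> np.ndarray:
    """Row indices held out of L-M fitting for the early-stopping check.

    A pure function of (n, seed, val_fraction) so that any stage selecting
    parameters beforehand (e.g. a metaheuristic search) can exclude the
    same rows from its objective.
    """
    n_val = int(round(float(config["val_fraction"]) * n))
    if not 0 < n_val < n:
        return np.empty(0, dtype=int)
    rng = np.random.default_rng([config.seed, 0x5E1D])
    return np.sort(rng.permutation(n)[:n_val])


def _mse(params, X, y, hidden):
    r = bpnn_forward(params, X, hidden) - y
    return float(np.mean(r**2))


def _train_lm(params, X, y, hidden, max_iter, goal, X_val=None, y_val=None, max_fail=6):
    """Damped Gauss-Newton on the residual vector (full batch).

    When a validation set is supplied, training additionally stops after
    ``max_fail`` consecutive rises of the validation MSE and the
    parameters with the lowest validation error are returned (the early
    stopping the classic neural toolboxes apply by default).
    """
    n = X.shape[0]
    lam = 1e-3
    mse = _mse(params, X, y, hidden)
    trace = [mse]
    iters = 0
    use_val = X_val is not None and len(X_val) > 0
    if use_val:
        best_val = _mse(params, X_val, y_val, hidden)
        best_params = params.copy()
        fails = 0
    for _ in range(max_iter):
        if mse <= goal:
            break
        J, yhat = _bpnn_jacobian(params, X, hidden)
        r = yhat - y
        g = J.T @ r / n
        if np.max(np.abs(g)) < 1e-12:
            break
        H = J.T @ J / n
        accepted = False
        for _retry in range(25):
            try:
                step = np.linalg.solve(H + lam * np.eye(H.shape[0]), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = params + step
            cand_mse = _mse(cand, X, y, hidden)
            if np.isfinite(cand_mse) and cand_mse < mse:
                params, mse = cand, cand_mse
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
            if lam > 1e10:
                break
        iters += 1
        trace.append(mse)
        if not accepted:
            break
        if use_val:
            val_mse = _mse(params, X_val, y_val, hidden)
            if val_mse < best_val:
                best_val = val_mse
                best_params = params.copy()
                fails = 0
            else:
                fails += 1
                if fails >= max_fail:
                    break
    if use_val:
        params = best_params
    return params, trace, iters


def _train_gd(params, X, y, hidden, max_iter, goal, lr, batch_size, rng):
    """Seeded mini-batch gradient descent on the MSE."""
    n = X.shape[0]
    mse = _mse(params, X, y, hidden)
    trace = [mse]
    iters = 0
    for _ in range(max_iter):
        if mse <= goal:
            break
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            J, yhat = _bpnn_jacobian(params, X[idx], hidden)
            grad = 2.0 * J.T @ (yhat - y[idx]) / len(idx)
            params = params - lr * grad
        mse = _mse(params, X, y, hidden)
        iters += 1
        trace.append(mse)
        if not np.isfinite(mse):
            raise FloatingPointError("gradient descent diverged (non-finite loss)")
    return params, trace, iters


# ---------------------------------------------------------------------------
# RBFNN: incremental-center radial basis network


def _rbf_design(X, centers, spread):
    # exp(-(0.8326 d / spread)^2): activation 0.5 at distance = spread
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-(0.8326**2) * d2 / spread**2)


def _train_rbfnn(X, y, spread, goal, max_centers):
    """Add the worst-fit training point as a new center until the MSE goal
    or the center budget is reached; output weights by least squares."""
    n = X.shape[0]
    max_centers = int(min(max_centers, n))
    residual = y - np.mean(y)
    centers_idx: list[int] = []
    weights = np.array([np.mean(y)])
    centers = np.empty((0, X.shape[1]))
    for _ in range(max_centers):
        cand = int(np.argmax(np.abs(residual)))
        if cand in centers_idx:
            break
        centers_idx.append(cand)
        centers = X[centers_idx]
        Phi = np.column_stack([np.ones(n), _rbf_design(X, centers, spread)])
        weights, *_ = np.linalg.lstsq(Phi, y, rcond=None)
        residual = y - Phi @ weights
        if np.mean(residual**2) <= goal:
            break
    return {"centers": centers, "weights": weights, "spread": spread}


def _predict_rbfnn(state, X):
    Phi = np.column_stack(
        [np.ones(X.shape[0]), _rbf_design(X, state["centers"], state["spread"])]
    )
    return Phi @ state["weights"]


# ---------------------------------------------------------------------------
# dispatcher


def _check_mlr_rank(X: np.ndarray) -> None:
    design = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name columns whose removal restores full rank
        culprits = [
            str(j)
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) == rank
        ]
        raise ValueError(
            f"singular design for MLR; collinear feature column(s): {culprits}"
        )


def fit_model(
    name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Fit one of the six regressors with its standard hyperparameters."""
    config = config or ModelConfig(name)
    if config.name != name:
        raise ValueError(f"config is for {config.name!r}, not {name!r}")
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    y = np.asarray(y_train, dtype=float).ravel()
    if X.shape[0] < 5:
        raise ValueError("need at least 5 training rows")

    if name == "MLR":
        _check_mlr_rank(X)
        est = LinearRegression().fit(X, y)
        return TrainedModel(name, est, final_loss=float(np.mean((est.predict(X) - y) ** 2)))
    if name == "PLS":
        ncomp = min(int(config["n_components"]), X.shape[1])
        est = PLSRegression(n_components=ncomp).fit(X, y)
        return TrainedModel(
            name, est, final_loss=float(np.mean((est.predict(X).ravel() - y) ** 2))
        )
    if name == "SVR":
        # sigma-style kernel scale -> sklearn gamma = 1 / sigma^2
        est = _SkSVR(
            kernel="rbf",
            C=float(config["penalty"]),
            gamma=1.0 / float(config["kernel_scale"]) ** 2,
            epsilon=float(config["epsilon"]),
        ).fit(X, y)
        return TrainedModel(name, est, final_loss=float(np.mean((est.predict(X) - y) ** 2)))
    if name == "RF":
        est = RandomForestRegressor(
            n_estimators=int(config["n_trees"]),
            min_samples_leaf=int(config["min_leaf"]),
            random_state=config.seed,
        ).fit(X, y)
        return TrainedModel(name, est, final_loss=float(np.mean((est.predict(X) - y) ** 2)))
    if name == "RBFNN":
        scaler = _minmax_fit(X)
        Xs = _minmax_apply(X, scaler)
        state = _train_rbfnn(
            Xs, y, float(config["spread"]), float(config["goal"]), config["max_centers"]
        )
        loss = float(np.mean((_predict_rbfnn(state, Xs) - y) ** 2))
        return TrainedModel(name, state, scaler=scaler, final_loss=loss)
    # BPNN
    return train_bpnn(X, y, config=config)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Deterministic predictions of a fitted model."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.name in ("BPNN", "WOA-BPNN"):
        Xs = _minmax_apply(X, model.scaler) if model.scaler is not None else X
        return bpnn_forward(model.state["params"], Xs, model.state["hidden"])
    if model.name == "RBFNN":
        Xs = _minmax_apply(X, model.scaler) if model.scaler is not None else X
        return _predict_rbfnn(model.state, Xs)
    out = model.state.predict(X)
    return np.asarray(out).ravel()
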