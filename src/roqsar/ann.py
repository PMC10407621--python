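"""Back-propagation feedforward network for rejection regression.

Implements min-max scaling to [-1, 1], a (4, 4, 1) log-sigmoid /
linear-output network, Levenberg-Marquardt and plain gradient training
with the study's stopping rules, and Garson connection-weight importance.

Fit statistics are reported on the unscaled percent-rejection scale after
inverse transform of the network output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.special

from .dataset import QsarDataset
from .exceptions import ScalingError, TrainingError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# min-max scaling

@dataclass
class ScalerParams:
    """Per-variable linear map sending [x_min, x_max] to [r_min, r_max]."""

    x_min: np.ndarray
    x_max: np.ndarray
    r_min: float = -1.0
    r_max: float = 1.0

    @classmethod
    def fit(cls, values: np.ndarray, r_min: float = -1.0,
            r_max: float = 1.0) -> "ScalerParams":
        if r_min >= r_max:
            raise ScalingError(f"invalid target range [{r_min}, {r_max}]")
        arr = np.atleast_2d(np.asarray(values, dtype=float))
        x_min, x_max = arr.min(axis=0), arr.max(axis=0)
        degenerate = np.flatnonzero(x_max <= x_min)
        if degenerate.size:
            raise ScalingError(
                f"degenerate variable(s) at column(s) {degenerate.tolist()}: "
                "x_max == x_min (should have been filtered upstream)"
            )
        return cls(x_min=x_min, x_max=x_max, r_min=r_min, r_max=r_max)


def scale(values: np.ndarray, params: ScalerParams) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    span = params.x_max - params.x_min
    return (x - params.x_min) / span * (params.r_max - params.r_min) + params.r_min


def unscale(values: np.ndarray, params: ScalerParams) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    span = params.x_max - params.x_min
    return (a - params.r_min) / (params.r_max - params.r_min) * span + params.x_min


# ---------------------------------------------------------------------------
# network

def logsig(x: np.ndarray) -> np.ndarray:
    return scipy.special.expit(x)


@dataclass
class AnnWeights:
    """Weights of an (n_in, n_hidden, 1) network.

    ``W[i, j]`` connects input i to hidden node j; ``v[j]`` connects hidden
    node j to the linear output unit.
    """

    W: np.ndarray
    b_hidden: np.ndarray
    v: np.ndarray
    b_out: float

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        n_in, n_hidden = self.W.shape
        if self.b_hidden.shape != (n_hidden,) or self.v.shape != (n_hidden,):
            raise TrainingError("weight shapes inconsistent with topology")
        if not (np.isfinite(self.W).all() and np.isfinite(self.b_hidden).all()
                and np.isfinite(self.v).all() and np.isfinite(self.b_out)):
            raise TrainingError("non-finite weights")

    @property
    def topology(self) -> tuple[int, int, int]:
        return (self.W.shape[0], self.W.shape[1], 1)

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.W.ravel(), self.b_hidden, self.v, [self.b_out]])

    @classmethod
    def from_flat(cls, theta: np.ndarray, n_in: int, n_hidden: int) -> "AnnWeights":
        k = n_in * n_hidden
        return cls(W=theta[:k].reshape(n_in, n_hidden),
                   b_hidden=theta[k:k + n_hidden],
                   v=theta[k + n_hidden:k + 2 * n_hidden],
                   b_out=float(theta[-1]))

    def as_dict(self) -> dict:
        return {"W": self.W.tolist(), "b_hidden": self.b_hidden.tolist(),
                "v": self.v.tolist(), "b_out": self.b_out}

    @classmethod
    def from_dict(cls, d: dict) -> "AnnWeights":
        return cls(W=np.array(d["W"]), b_hidden=np.array(d["b_hidden"]),
                   v=np.array(d["v"]), b_out=float(d["b_out"]))


def forward(weights: AnnWeights, inputs: np.ndarray) -> np.ndarray:
    """Scaled network output: logsig hidden layer, linear output unit."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if not np.isfinite(X).all():
        raise TrainingError("non-finite network input")
    hidden = logsig(X @ weights.W + weights.b_hidden)
    out = hidden @ weights.v + weights.b_out
    return out if np.asarray(inputs).ndim > 1 else float(out[0])


@dataclass
class TrainConfig:
    topology: tuple[int, int, int] = (4, 4, 1)
    hidden_activation: str = "logsig"
    algorithm: str = "levenberg_marquardt"
    eta: float = 0.05
    max_validation_failures: int = 10
    min_gradient: float = 1e-7
    max_mu: float = 1e10
    max_epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("levenberg_marquardt", "gradient"):
            raise TrainingError(f"unknown algorithm {self.algorithm!r}")
        if not 0 < self.eta < 0.1:
            raise TrainingError("learning parameter eta must lie in (0, 0.1)")
        if min(self.max_validation_failures, self.max_epochs) <= 0 or \
                min(self.min_gradient, self.max_mu) <= 0:
            raise TrainingError("stopping thresholds must be positive")


@dataclass
class TrainResult:
    weights: AnnWeights
    scaler_x: ScalerParams
    scaler_y: ScalerParams
    epochs_run: int
    stop_reason: str
    history: pd.DataFrame
    config: TrainConfig = field(default=None)
    descriptor_names: list[str] = field(default_factory=list)


def _init_weights(config: TrainConfig) -> AnnWeights:
    n_in, n_hidden, _ = config.topology
    rng = np.random.default_rng(config.seed)
    theta = rng.uniform(-0.5, 0.5, size=n_in * n_hidden + 2 * n_hidden + 1)
    return AnnWeights.from_flat(theta, n_in, n_hidden)


def gradient_step(weights: AnnWeights, x: np.ndarray, target: float,
                  eta: float) -> AnnWeights:
    """One delta-rule update on a single sample.

    The output-layer change is exactly ``eta * (target - output) * input``
    for each output-layer connection; hidden-layer weights receive the
    backpropagated equivalent.
    """
    hidden = logsig(x @ weights.W + weights.b_hidden)
    out = float(hidden @ weights.v + weights.b_out)
    err = target - out
    dhid = err * weights.v * hidden * (1.0 - hidden)
    return AnnWeights(
        W=weights.W + eta * np.outer(x, dhid),
        b_hidden=weights.b_hidden + eta * dhid,
        v=weights.v + eta * err * hidden,
        b_out=weights.b_out + eta * err,
    )


def _jacobian(weights: AnnWeights, X: np.ndarray) -> np.ndarray:
    """d(output)/d(theta) for every sample; theta as in AnnWeights.flatten."""
    n = X.shape[0]
    hidden = logsig(X @ weights.W + weights.b_hidden)
    dh = hidden * (1.0 - hidden) * weights.v  # n x n_hidden
    J_W = X[:, :, None] * dh[:, None, :]      # n x n_in x n_hidden
    return np.concatenate(
        [J_W.reshape(n, -1), dh, hidden, np.ones((n, 1))], axis=1
    )


def _split_arrays(dataset: QsarDataset, scaler_x: ScalerParams,
                  scaler_y: ScalerParams, split: str) -> tuple[np.ndarray, np.ndarray]:
    sub = dataset.subset(split)
    Xs = scale(sub.X.to_numpy(dtype=float), scaler_x)
    ys = scale(sub.y.to_numpy(dtype=float)[:, None], scaler_y).ravel()
    return Xs, ys


def train(dataset: QsarDataset, config: TrainConfig) -> TrainResult:
    """Train the network on the training split with early stopping.

    Levenberg-Marquardt mode updates parameters by
    ``(J'J + mu I)^-1 J'e`` with mu multiplied by 10 on a rejected step and
    divided by 10 on an accepted one.  Training stops when the validation
    MSE has not improved for more than ``max_validation_failures``
    consecutive epochs (best-validation weights are restored), the gradient
    norm drops below ``min_gradient``, mu exceeds ``max_mu``, or
    ``max_epochs`` is reached.  Gradient mode applies per-sample
    delta-rule backpropagation with learning parameter eta.
    """
    counts = dataset.split_counts()
    for split_name in ("training", "validation"):
        if counts.get(split_name, 0) == 0:
            raise TrainingError(f"dataset has no {split_name} split")
    n_in, n_hidden, n_out = config.topology
    if dataset.X.shape[1] != n_in or n_out != 1:
        raise TrainingError(
            f"topology {config.topology} inconsistent with "
            f"{dataset.X.shape[1]} descriptors / 1 response"
        )
    train_split = dataset.subset("training")
    scaler_x = ScalerParams.fit(train_split.X.to_numpy(dtype=float))
    scaler_y = ScalerParams.fit(train_split.y.to_numpy(dtype=float)[:, None])
    X_tr, y_tr = _split_arrays(dataset, scaler_x, scaler_y, "training")
    X_va, y_va = _split_arrays(dataset, scaler_x, scaler_y, "validation")

    weights = _init_weights(config)
    theta = weights.flatten()
    n_params = theta.size

    def mse_of(th: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
        w = AnnWeights.from_flat(th, n_in, n_hidden)
        e = y - forward(w, X)
        return float(e @ e) / len(y)

    mu = 1e-3
    best_val = np.inf
    best_theta = theta.copy()
    val_failures = 0
    history_rows = []
    stop_reason = "max_epochs"
    epoch = 0

    for epoch in range(1, config.max_epochs + 1):
        w = AnnWeights.from_flat(theta, n_in, n_hidden)
        if config.algorithm == "levenberg_marquardt":
            e = y_tr - forward(w, X_tr)
            if not np.isfinite(e).all():
                raise TrainingError(f"divergence: non-finite loss at epoch {epoch}")
            J = _jacobian(w, X_tr)
            gradient = J.T @ e
            if np.linalg.norm(gradient) < config.min_gradient:
                stop_reason = "gradient"
                break
            JtJ = J.T @ J
            accepted = False
            current_sse = float(e @ e)
            while mu <= config.max_mu:
                try:
                    delta = np.linalg.solve(JtJ + mu * np.eye(n_params), gradient)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                candidate = theta + delta
                w_cand = AnnWeights.from_flat(candidate, n_in, n_hidden)
                e_cand = y_tr - forward(w_cand, X_tr)
                if np.isfinite(e_cand).all() and float(e_cand @ e_cand) < current_sse:
                    theta = candidate
                    mu = max(mu * 0.1, 1e-20)
                    accepted = True
                    break
                mu *= 10.0
            if not accepted:
                stop_reason = "mu"
                break
        else:  # per-sample delta-rule backpropagation (learning parameter eta)
            for i in range(len(y_tr)):
                w = AnnWeights.from_flat(theta, n_in, n_hidden)
                theta = gradient_step(w, X_tr[i], float(y_tr[i]),
                                      config.eta).flatten()

        train_mse = mse_of(theta, X_tr, y_tr)
        val_mse = mse_of(theta, X_va, y_va)
        history_rows.append({"epoch": epoch, "train_mse": train_mse,
                             "val_mse": val_mse, "mu": mu})
        if val_mse < best_val:
            best_val = val_mse
            best_theta = theta.copy()
            val_failures = 0
        else:
            val_failures += 1
            if val_failures > config.max_validation_failures:
                stop_reason = "validation"
                break

    theta = best_theta if stop_reason == "validation" else theta
    final = AnnWeights.from_flat(theta, n_in, n_hidden)
    logger.info("training stopped after %d epochs (%s)", epoch, stop_reason)
    return TrainResult(
        weights=final, scaler_x=scaler_x, scaler_y=scaler_y,
        epochs_run=epoch, stop_reason=stop_reason,
        history=pd.DataFrame(history_rows),
        config=config, descriptor_names=dataset.descriptor_names,
    )


def predict(result: TrainResult, X_raw) -> np.ndarray:
    """Predictions on the original (percent) scale."""
    X = np.atleast_2d(np.asarray(X_raw, dtype=float))
    out = forward(result.weights, scale(X, result.scaler_x))
    return unscale(np.atleast_1d(out)[:, None], result.scaler_y).ravel()


# ---------------------------------------------------------------------------
# interpretation

def garson_importance(weights: AnnWeights) -> np.ndarray:
    """Relative importance (%) of each input by connection-weight partitioning.

    ``Q_t = sum_n (|w_tn| / sum_k |w_kn|) * |v_n|`` normalised to 100%.
    Biases are ignored; hidden units with all-zero input weights contribute
    nothing.
    """
    absW = np.abs(weights.W)
    col_sums = absW.sum(axis=0)
    ok = col_sums > 0
    shares = np.zeros_like(absW)
    shares[:, ok] = absW[:, ok] / col_sums[ok]
    q = shares @ np.abs(weights.v)
    total = q.sum()
    if total == 0:
        raise TrainingError("all connection weights are zero")
    return 100.0 * q / total


def effective_weight_table(result: TrainResult | AnnWeights,
                           descriptor_names: list[str] | None = None) -> pd.DataFrame:
    """Report: hidden-neuron weight rows, hidden-to-output column, and a
    final relative-importance row (sums to 100)."""
    weights = result.weights if isinstance(result, TrainResult) else result
    if descriptor_names is None:
        descriptor_names = (result.descriptor_names
                            if isinstance(result, TrainResult) and result.descriptor_names
                            else [f"x{i + 1}" for i in range(weights.W.shape[0])])
    n_hidden = weights.W.shape[1]
    rows = {f"H{j + 1}": list(weights.W[:, j]) + [weights.v[j]]
            for j in range(n_hidden)}
    importance = garson_importance(weights)
    rows["Relative importance (%)"] = list(importance) + [np.nan]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(descriptor_names) + ["hidden_to_out"]
    )


def save_result(result: TrainResult, path) -> None:
    payload = {
        "weights": result.weights.as_dict(),
        "scaler_x": {"x_min": result.scaler_x.x_min.tolist(),
                     "x_max": result.scaler_x.x_max.tolist()},
        "scaler_y": {"x_min": result.scaler_y.x_min.tolist(),
                     "x_max": result.scaler_y.x_max.tolist()},
        "epochs_run": result.epochs_run,
        "stop_reason": result.stop_reason,
        "descriptor_names": result.descriptor_names,
        "config": asdict(result.config) if result.config else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_result(path) -> TrainResult:
    with open(path) as fh:
        payload = json.load(fh)
    config = TrainConfig(**{**payload["config"],
                            "topology": tuple(payload["config"]["topology"])}) \
        if payload.get("config") else None
    return TrainResult(
        weights=AnnWeights.from_dict(payload["weights"]),
        scaler_x=ScalerParams(np.array(payload["scaler_x"]["x_min"]),
                              np.array(payload["scaler_x"]["x_max"])),
        scaler_y=ScalerParams(np.array(payload["scaler_y"]["x_min"]),
                              np.array(payload["scaler_y"]["x_max"])),
        epochs_run=payload["epochs_run"],
        stop_reason=payload["stop_reason"],
        history=pd.DataFrame(),
        config=config,
        descriptor_names=payload.get("descriptor_names", []),
    )
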