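"""Shallow feedforward QSRR networks trained by back-propagation.

The network maps max-normalized molecular descriptors to a max-normalized
retention factor through logistic activations and is trained by full-batch
gradient descent on mean squared error. Two architectures are supported:

* ``direct`` — input layer wired straight to a single sigmoid output, one
  signed weight per descriptor. This is the default: thresholding scalar
  per-descriptor weights presupposes one weight per input.
* ``hidden`` — one logistic hidden layer; per-descriptor scores are then
  obtained by the connection-weights aggregation
  ``score_i = sum_j w_in[i, j] * w_out[j]``.

Input-layer weights are the quantity of interest throughout the pipeline:
a positive weight means the descriptor increases retention, a negative one
that it decreases retention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_tables import DescriptorTable


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class AnnConfig:
    """Training configuration.

    ``epochs`` defaults to 500 full passes ("learning cycles") over the
    training compounds; ``learning_rate`` and ``init_scale`` govern full-batch
    gradient descent from a Uniform(-init_scale, init_scale) start.
    """

    architecture: str = "direct"
    hidden_size: int = 5
    learning_rate: float = 0.05
    epochs: int = 500
    seed: int = 0
    init_scale: float = 0.1
    aggregation: str = "connection-weights"

    def __post_init__(self) -> None:
        if self.architecture not in ("direct", "hidden"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.architecture == "hidden" and self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.aggregation != "connection-weights":
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class TrainedModel:
    config: AnnConfig
    descriptor_names: tuple[str, ...]
    weights: dict[str, np.ndarray]
    loss_trace: np.ndarray
    condition: tuple[str, str, str] | None = None
    non_convergence: bool = False

    def save(self, path: str | Path) -> None:
        """Serialize to a diffable JSON text file."""
        payload = {
            "config": asdict(self.config),
            "descriptor_names": list(self.descriptor_names),
            "weights": {k: np.asarray(v).tolist() for k, v in self.weights.items()},
            "loss_trace": self.loss_trace.tolist(),
            "condition": list(self.condition) if self.condition else None,
            "non_convergence": self.non_convergence,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            config=AnnConfig(**payload["config"]),
            descriptor_names=tuple(payload["descriptor_names"]),
            weights={k: np.asarray(v, dtype=float) for k, v in payload["weights"].items()},
            loss_trace=np.asarray(payload["loss_trace"], dtype=float),
            condition=tuple(payload["condition"]) if payload["condition"] else None,
            non_convergence=payload["non_convergence"],
        )


@dataclass
class WeightVector:
    """Signed per-descriptor importance weights extracted from one trained net."""

    descriptor_names: tuple[str, ...]
    weights: np.ndarray
    condition: tuple[str, str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.descriptor_names) != self.weights.shape[0]:
            raise ValueError("weights length does not match descriptor names")

    def as_series(self):
        import pandas as pd

        return pd.Series(self.weights, index=list(self.descriptor_names))


def _as_matrix(X: DescriptorTable | np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, DescriptorTable):
        if not X.normalized:
            raise ValueError("descriptor table must be normalized before training")
        return X.values, tuple(X.descriptor_names)
    arr = np.asarray(X, dtype=float)
    return arr, tuple(f"d{j}" for j in range(arr.shape[1]))


def _forward(params: dict[str, np.ndarray], arch: str, X: np.ndarray):
    if arch == "direct":
        z = X @ params["w"] + params["b"]
        return _sigmoid(z), {}
    h = _sigmoid(X @ params["W1"] + params["b1"])
    yhat = _sigmoid(h @ params["w2"] + params["b2"])
    return yhat, {"h": h}


def gradients(
    params: dict[str, np.ndarray], arch: str, X: np.ndarray, y: np.ndarray
) -> dict[str, np.ndarray]:
    """Analytic gradients of mean squared error w.r.t. every parameter."""
    n = X.shape[0]
    yhat, cache = _forward(params, arch, X)
    delta = 2.0 * (yhat - y) * yhat * (1.0 - yhat) / n
    if arch == "direct":
        return {"w": X.T @ delta, "b": np.array(delta.sum())}
    h = cache["h"]
    gw2 = h.T @ delta
    gb2 = np.array(delta.sum())
    dh = np.outer(delta, params["w2"]) * h * (1.0 - h)
    return {"W1": X.T @ dh, "b1": dh.sum(axis=0), "w2": gw2, "b2": gb2}


def train(
    X: DescriptorTable | np.ndarray,
    y: Sequence[float],
    config: AnnConfig = AnnConfig(),
    condition: tuple[str, str, str] | None = None,
) -> TrainedModel:
    """Fit the network to normalized retention factors ``y`` in [0, 1].

    Deterministic given ``config.seed``. The per-epoch mean squared error is
    recorded before each update; a model whose final loss exceeds its initial
    loss is flagged ``non_convergence`` rather than rejected.
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    if yv.ndim != 1 or yv.shape[0] != Xm.shape[0]:
        raise ValueError("y must be one value per training compound")
    if np.any((yv < 0) | (yv > 1)):
        raise ValueError("y must be normalized into [0, 1]")
    if np.isnan(Xm).any():
        raise ValueError("descriptor matrix contains missing values")

    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    p = Xm.shape[1]
    if config.architecture == "direct":
        params = {"w": rng.uniform(-s, s, p), "b": np.array(rng.uniform(-s, s))}
    else:
        h = config.hidden_size
        params = {
            "W1": rng.uniform(-s, s, (p, h)),
            "b1": rng.uniform(-s, s, h),
            "w2": rng.uniform(-s, s, h),
            "b2": np.array(rng.uniform(-s, s)),
        }

    trace = np.empty(config.epochs)
    lr = config.learning_rate
    for epoch in range(config.epochs):
        yhat, _ = _forward(params, config.architecture, Xm)
        loss = float(np.mean((yhat - yv) ** 2))
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"training loss became non-finite at epoch {epoch} "
                f"(learning_rate={lr}); reduce the learning rate"
            )
        trace[epoch] = loss
        grads = gradients(params, config.architecture, Xm, yv)
        for k, g in grads.items():
            params[k] = params[k] - lr * g
            if not np.all(np.isfinite(params[k])):
                raise TrainingDivergedError(
                    f"parameter {k!r} became non-finite at epoch {epoch} "
                    f"(learning_rate={lr}); reduce the learning rate"
                )

    yhat, _ = _forward(params, config.architecture, Xm)
    final = float(np.mean((yhat - yv) ** 2))
    return TrainedModel(
        config=config,
        descriptor_names=names,
        weights={k: np.asarray(v, dtype=float) for k, v in params.items()},
        loss_trace=trace,
        condition=condition,
        non_convergence=bool(final > trace[0]),
    )


def predict(model: TrainedModel, X: DescriptorTable | np.ndarray) -> np.ndarray:
    """Normalized retention-factor predictions in (0, 1)."""
    if isinstance(X, DescriptorTable):
        missing = [n for n in model.descriptor_names if n not in X.descriptor_names]
        if missing:
            raise ValueError(f"descriptor(s) missing from table: {missing[:5]}")
        Xm = X.data[list(model.descriptor_names)].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.shape[1] != len(model.descriptor_names):
            raise ValueError(
                f"expected {len(model.descriptor_names)} descriptors, got {Xm.shape[1]}"
            )
    yhat, _ = _forward(model.weights, model.config.architecture, Xm)
    return yhat


def extract_weights(model: TrainedModel) -> WeightVector:
    """Per-descriptor signed importance weights.

    Direct architecture returns the input->output weights verbatim; the hidden
    architecture collapses paths by the sign-preserving connection-weights sum
    over hidden units.
    """
    if model.config.architecture == "direct":
        w = model.weights["w"].copy()
    else:
        w = model.weights["W1"] @ model.weights["w2"]
    return WeightVector(
        descriptor_names=model.descriptor_names,
        weights=w,
        condition=model.condition,
        seed=model.config.seed,
    )
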