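"""Feed-forward interval network in plain numpy.

The network maps a feature vector to two linear outputs — the lower and
upper prediction-interval bound.  It is deliberately small (the search
space caps layers at 4 and widths at 150), so a hand-rolled forward /
backward pass is fast, dependency-free and bit-reproducible on one
thread.  The flat-weight view exists for the genetic-algorithm trainer,
which treats the parameter vector as a chromosome.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .metrics import IntervalBatch, crossing_fraction

__all__ = ["IntervalNet", "predict_intervals"]

log = logging.getLogger(__name__)

_ACTIVATIONS = ("relu", "tanh", "linear")


class IntervalNet:
    """Fully connected network with ``n_outputs`` linear output neurons.

    Parameters
    ----------
    input_dim : int
        Number of input features (22 for the pain cohort).
    hidden_layers : sequence of int
        Hidden-layer widths; 1-4 layers of 10-150 neurons is the tuned
        range.
    activation : {"relu", "tanh", "linear"}
        Hidden activation; outputs are always linear.
    n_outputs : int
        2 for (lower, upper) interval heads; 1 for a point regressor used
        by the bootstrap baseline.
    seed : int
        Seed for the small-uniform (Glorot-scaled) weight initialisation.
    """

    def __init__(self, input_dim: int, hidden_layers=(32, 32),
                 activation: str = "relu", n_outputs: int = 2,
                 seed: int = 0) -> None:
        if activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if input_dim <= 0 or n_outputs <= 0:
            raise ValueError("input_dim and n_outputs must be positive")
        hidden_layers = tuple(int(h) for h in hidden_layers)
        if any(h <= 0 for h in hidden_layers):
            raise ValueError("hidden layer widths must be positive")
        self.input_dim = int(input_dim)
        self.hidden_layers = hidden_layers
        self.activation = activation
        self.n_outputs = int(n_outputs)
        self.seed = int(seed)
        self.init_weights(seed)

    # -- parameters -------------------------------------------------------
    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = (self.input_dim, *self.hidden_layers, self.n_outputs)
        return [(dims[i], dims[i + 1]) for i in range(len(dims) - 1)]

    def init_weights(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in self.layer_dims:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def get_flat_weights(self) -> np.ndarray:
        parts = []
        for w, b in zip(self.weights, self.biases):
            parts.append(w.ravel())
            parts.append(b.ravel())
        return np.concatenate(parts)

    def set_flat_weights(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters, "
                             f"got {theta.shape}")
        pos = 0
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[i] = theta[pos:pos + w.size].reshape(w.shape).copy()
            pos += w.size
            self.biases[i] = theta[pos:pos + b.size].copy()
            pos += b.size

    # -- forward / backward ----------------------------------------------
    def _act(self, z: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            return np.maximum(z, 0.0)
        if self.activation == "tanh":
            return np.tanh(z)
        return z

    def _act_grad(self, z: np.ndarray, a: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            return (z > 0).astype(float)
        if self.activation == "tanh":
            return 1.0 - a * a
        return np.ones_like(z)

    def forward(self, X: np.ndarray, cache: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} input features, got {X.shape[1]}")
        a = X
        caches = []
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            a_next = z if i == last else self._act(z)
            if cache:
                caches.append((a, z, a_next))
            a = a_next
        if not np.isfinite(a).all():
            raise FloatingPointError("non-finite network output")
        return (a, caches) if cache else a

    def backward(self, caches, dout: np.ndarray):
        """Gradients of a scalar loss w.r.t. all weights and biases.

        ``dout`` is dLoss/d(output), shape (n, n_outputs); ``caches`` is the
        cache list from ``forward(..., cache=True)``.
        """
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = np.asarray(dout, dtype=float)
        last = len(self.weights) - 1
        for i in range(last, -1, -1):
            a_prev, z, a = caches[i]
            if i != last:
                delta = delta * self._act_grad(z, a)
            grads_w[i] = a_prev.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
        return grads_w, grads_b

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(path, meta=np.array([
            self.input_dim, self.n_outputs, self.seed], dtype=np.int64),
            hidden=np.array(self.hidden_layers, dtype=np.int64),
            activation=np.array(self.activation), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "IntervalNet":
        data = np.load(path, allow_pickle=False)
        meta = data["meta"]
        net = cls(int(meta[0]), tuple(int(h) for h in data["hidden"]),
                  str(data["activation"]), int(meta[1]), int(meta[2]))
        for i in range(len(net.weights)):
            net.weights[i] = data[f"w{i}"]
            net.biases[i] = data[f"b{i}"]
        return net


def predict_intervals(net: IntervalNet, X: np.ndarray,
                      target: np.ndarray | None = None) -> IntervalBatch:
    """Per-row (lower, upper) bounds from the two output heads.

    ``target`` defaults to NaN-free zeros when the labels are unknown; the
    crossing fraction of the produced bounds is logged at DEBUG level.
    """
    if net.n_outputs != 2:
        raise ValueError("predict_intervals requires a 2-output network")
    out = net.forward(X)
    t = np.zeros(out.shape[0]) if target is None else target
    batch = IntervalBatch(lower=out[:, 0], upper=out[:, 1], target=t)
    frac = crossing_fraction(batch) if len(batch) else 0.0
    if frac > 0:
        log.debug("crossed bounds on %.1f%% of rows", 100 * frac)
    return batch
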