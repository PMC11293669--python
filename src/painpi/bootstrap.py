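"""Bootstrap-ensemble prediction intervals.

B point-regression networks are trained on bootstrap resamples of the
training data.  The ensemble mean estimates the regression function; the
ensemble variance estimates model (epistemic) uncertainty; the residual
variance of the out-of-bag ensemble mean on the training data, minus the
mean model variance and floored at zero, estimates the irreducible noise
(aleatoric) variance.  The predictive variance is their sum,

    sigma_y^2 = sigma_model^2 + sigma_noise^2,

and bounds are the Gaussian central interval
mean +/- z_{1-alpha/2} sqrt(sigma_y^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .metrics import IntervalBatch
from .network import IntervalNet

__all__ = ["BootstrapParams", "BootstrapResult", "bootstrap_pi"]


@dataclass(frozen=True)
class BootstrapParams:
    """Settings of the bootstrap-ensemble interval constructor."""

    B: int = 30
    nominal: float = 0.9
    hidden_layers: tuple = (32, 32)
    activation: str = "relu"
    epochs: int = 150
    batch_size: int = 128
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2 for a nonzero model variance")
        if not 0 < self.nominal < 1:
            raise ValueError("nominal must lie in (0, 1)")


@dataclass
class BootstrapResult:
    """Ensemble mean, uncertainty components, and interval bounds."""

    mean: np.ndarray
    sigma_model: np.ndarray
    sigma_noise: float
    lower: np.ndarray
    upper: np.ndarray
    nominal: float

    def as_batch(self, target: np.ndarray) -> IntervalBatch:
        return IntervalBatch(self.lower, self.upper, target)


def _train_point_net(net: IntervalNet, X: np.ndarray, y: np.ndarray,
                     epochs: int, batch_size: int, lr: float,
                     rng: np.random.Generator) -> IntervalNet:
    """Minibatch Adam on mean squared error for a 1-output network."""
    m_w = [np.zeros_like(w) for w in net.weights]
    v_w = [np.zeros_like(w) for w in net.weights]
    m_b = [np.zeros_like(b) for b in net.biases]
    v_b = [np.zeros_like(b) for b in net.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            out, caches = net.forward(X[idx], cache=True)
            resid = out[:, 0] - y[idx]
            dout = (2.0 * resid / idx.size)[:, None]
            gw, gb = net.backward(caches, dout)
            step += 1
            for i in range(len(net.weights)):
                for grads, params, m, v in ((gw[i], net.weights, m_w, v_w),
                                            (gb[i], net.biases, m_b, v_b)):
                    m[i] = beta1 * m[i] + (1 - beta1) * grads
                    v[i] = beta2 * v[i] + (1 - beta2) * grads * grads
                    mhat = m[i] / (1 - beta1 ** step)
                    vhat = v[i] / (1 - beta2 ** step)
                    params[i] -= lr * mhat / (np.sqrt(vhat) + eps)
    return net


def bootstrap_pi(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    p: BootstrapParams,
) -> BootstrapResult:
    """Construct bootstrap-ensemble prediction intervals on test inputs."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    X_test = np.asarray(X_test, dtype=float)
    n = X_train.shape[0]
    rng = np.random.default_rng(p.seed)

    preds_test = np.empty((p.B, X_test.shape[0]))
    preds_train = np.empty((p.B, n))
    in_bag = np.zeros((p.B, n), dtype=bool)
    for b in range(p.B):
        idx = rng.integers(0, n, size=n)
        in_bag[b, idx] = True
        net = IntervalNet(X_train.shape[1], p.hidden_layers, p.activation,
                          n_outputs=1, seed=int(rng.integers(0, 2**31 - 1)))
        net.biases[-1] = np.array([float(y_train[idx].mean())])
        _train_point_net(net, X_train[idx], y_train[idx],
                         p.epochs, p.batch_size, p.learning_rate, rng)
        preds_test[b] = net.forward(X_test)[:, 0]
        preds_train[b] = net.forward(X_train)[:, 0]

    mean_test = preds_test.mean(axis=0)
    var_model_test = preds_test.var(axis=0, ddof=1)
    var_model_train = preds_train.var(axis=0, ddof=1)
    # noise variance from out-of-bag residuals: for each training point,
    # average only the models whose resample excluded it, so the residual
    # is not deflated by in-sample overfitting; then subtract the mean
    # model variance (variance decomposition rearranged) and floor at 0.
    oob_mask = ~in_bag
    has_oob = oob_mask.any(axis=0)
    with np.errstate(invalid="ignore"):
        oob_mean = np.where(
            has_oob,
            (preds_train * oob_mask).sum(axis=0) / oob_mask.sum(axis=0),
            preds_train.mean(axis=0))
    var_noise = max(0.0, float(np.mean((y_train - oob_mean) ** 2)
                               - np.mean(var_model_train)))

    z = stats.norm.ppf(0.5 + p.nominal / 2.0)
    half = z * np.sqrt(var_model_test + var_noise)
    return BootstrapResult(
        mean=mean_test,
        sigma_model=np.sqrt(var_model_test),
        sigma_noise=float(np.sqrt(var_noise)),
        lower=mean_test - half,
        upper=mean_test + half,
        nominal=p.nominal,
    )
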