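"""Coverage-width loss functions for interval networks.

``loss_L`` is the LUBE-style objective: normalized mean width inflated by
an exponential penalty on the coverage shortfall,

    loss_L = (MPIW / R) * (1 + gamma * exp(-eta * (PICP - mu))),

with gamma fixed at 1 during training and, at evaluation, gamma = 0 once
PICP reaches the confidence level mu = 1 - alpha.  The hard coverage
indicator makes it non-differentiable, hence the evolutionary trainer.

``loss_S`` is the differentiable softening: captured-only mean width plus
a quadratic penalty on the soft-coverage shortfall,

    loss_S = MPIW_S + lam * (eta / (alpha (1 - alpha)))
                    * max(0, (1 - alpha) - PICP_S)^2,

where PICP_S softens the indicator with logistic sigmoids of steepness
``s`` and MPIW_S averages widths over captured points (hard selector).
``eta`` is a free constant on the scale of a batch size.  When a batch
captures no points, MPIW_S falls back to the plain mean width so the loss
stays defined early in training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .metrics import IntervalBatch, mpiw, mpiw_captured, picp, picp_soft

__all__ = ["LossLParams", "LossSParams", "loss_L", "loss_S",
           "loss_S_bound_grads"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LossLParams:
    """Hyperparameters of the LUBE loss.

    ``eta`` amplifies small coverage shortfalls (tuned range [25, 100]);
    ``mu`` is the confidence level 1 - alpha (tuned range [0.5, 0.95]);
    ``target_range`` is R, the target span (4 on the pain scale).
    """

    eta: float = 50.0
    mu: float = 0.9
    target_range: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.mu < 1:
            raise ValueError("mu must lie in (0, 1)")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.target_range <= 0:
            raise ValueError("target range R must be positive")


@dataclass(frozen=True)
class LossSParams:
    """Hyperparameters of the soft loss.

    ``lam`` balances width against the coverage penalty (tuned [5, 30]);
    ``eta`` is the batch-size-scale constant in the penalty (tuned
    [35, 240]); ``alpha`` is the miscoverage rate, mu = 1 - alpha;
    ``s`` is the sigmoid softening factor (tuned [10, 220]).
    """

    lam: float = 10.0
    eta: float = 50.0
    alpha: float = 0.1
    s: float = 60.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.s <= 0:
            raise ValueError("softening factor s must be positive")
        if self.eta <= 0:
            raise ValueError("eta must be positive")

    @property
    def mu(self) -> float:
        return 1.0 - self.alpha

    @property
    def penalty_scale(self) -> float:
        return self.lam * self.eta / (self.alpha * (1.0 - self.alpha))


def loss_L(batch: IntervalBatch, p: LossLParams, training: bool = True) -> float:
    """LUBE loss; gamma = 1 when training, else the step function of PICP."""
    cov = picp(batch)
    gamma = 1.0 if training else (0.0 if cov >= p.mu else 1.0)
    width = mpiw(batch) / p.target_range
    return float(width * (1.0 + gamma * np.exp(-p.eta * (cov - p.mu))))


def _mpiw_s(batch: IntervalBatch) -> tuple[float, bool]:
    """Captured-only mean width with the zero-capture guard.

    With no captured point the captured-width ratio is undefined; the
    width term is then dropped (contributes 0) so the loss reduces to the
    coverage penalty alone.  A signed-width fallback is ruled out: crossed
    bounds capture nothing and have negative mean width, so minimising it
    would reward driving the bounds apart the wrong way without limit.
    """
    try:
        return mpiw_captured(batch), False
    except ZeroDivisionError:
        log.debug("zero captured points: width term dropped from loss_S")
        return 0.0, True


def loss_S(batch: IntervalBatch, p: LossSParams) -> float:
    """Soft loss value on a batch."""
    width, _ = _mpiw_s(batch)
    shortfall = max(0.0, (1.0 - p.alpha) - picp_soft(batch, p.s))
    return float(width + p.penalty_scale * shortfall ** 2)


def loss_S_bound_grads(batch: IntervalBatch, p: LossSParams):
    """Soft loss with its analytic gradients w.r.t. the bounds.

    Returns ``(loss, d_lower, d_upper, info)``.  The hard-capture selector
    inside MPIW_S is held fixed (it is piecewise constant in the bounds),
    so the gradient is exact except on the measure-zero capture boundary.
    """
    y, L, U = batch.target, batch.lower, batch.upper
    n = len(batch)
    k = batch.covered
    n_cap = k.sum()

    if n_cap > 0:
        width = float((k * (U - L)).sum() / n_cap)
        dmpiw_dL = -k / n_cap
        dmpiw_dU = k / n_cap
        fallback = False
    else:
        width = 0.0
        dmpiw_dL = np.zeros(n)
        dmpiw_dU = np.zeros(n)
        fallback = True

    sig_lo = expit(p.s * (y - L))
    sig_hi = expit(p.s * (U - y))
    cov_soft = float((sig_lo * sig_hi).mean())
    shortfall = (1.0 - p.alpha) - cov_soft

    dL = dmpiw_dL.copy()
    dU = dmpiw_dU.copy()
    if shortfall > 0:
        # d picp_soft / dL_i = -(s/n) sig_lo' sig_hi ; sig' = sig (1 - sig)
        dcov_dL = -(p.s / n) * sig_lo * (1.0 - sig_lo) * sig_hi
        dcov_dU = (p.s / n) * sig_hi * (1.0 - sig_hi) * sig_lo
        coef = -2.0 * p.penalty_scale * shortfall
        dL += coef * dcov_dL
        dU += coef * dcov_dU
        value = width + p.penalty_scale * shortfall ** 2
    else:
        value = width
    info = {"mpiw_s": width, "picp_s": cov_soft,
            "zero_capture_fallback": fallback}
    return float(value), dL, dU, info
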