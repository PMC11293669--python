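"""Prediction-interval quality measures.

Hard measures:

* PICP — prediction interval coverage probability, the fraction of targets
  falling inside their interval (bounds inclusive).
* MPIW — mean prediction interval width; NMPIW = MPIW / R where R is the
  target range (R = 4 for a 0-4 pain scale).

Soft measures used inside the differentiable loss:

* ``picp_soft`` replaces the coverage indicator with a product of logistic
  sigmoids steered by a softening factor ``s``; it converges to the hard
  PICP as ``s`` grows.
* ``mpiw_captured`` averages widths over captured points only (hard
  indicator), so uncovered points cannot shrink the width term.

Crossed bounds (upper < lower) are legal inputs — training can transiently
produce them — and are reported via ``crossing_fraction`` rather than
silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "IntervalBatch",
    "PIQuality",
    "picp",
    "mpiw",
    "nmpiw",
    "picp_soft",
    "mpiw_captured",
    "crossing_fraction",
]


@dataclass
class IntervalBatch:
    """Per-observation interval bounds with the realised targets."""

    lower: np.ndarray
    upper: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float).ravel()
        self.upper = np.asarray(self.upper, dtype=float).ravel()
        self.target = np.asarray(self.target, dtype=float).ravel()
        n = self.lower.shape[0]
        if self.upper.shape[0] != n or self.target.shape[0] != n:
            raise ValueError("lower, upper and target must have equal length")
        for name in ("lower", "upper", "target"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"{name} contains non-finite values")

    def __len__(self) -> int:
        return self.lower.shape[0]

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def covered(self) -> np.ndarray:
        """Hard coverage indicators k_i (bounds inclusive)."""
        return ((self.lower <= self.target)
                & (self.target <= self.upper)).astype(float)


def _require_nonempty(batch: IntervalBatch) -> None:
    if len(batch) == 0:
        raise ValueError("empty interval batch")


def picp(batch: IntervalBatch) -> float:
    """Coverage probability: mean of the inclusive-bounds indicators."""
    _require_nonempty(batch)
    return float(batch.covered.mean())


def mpiw(batch: IntervalBatch) -> float:
    """Mean interval width; negative if bounds cross on average."""
    _require_nonempty(batch)
    return float(batch.widths.mean())


def nmpiw(mpiw_value: float, target_range: float) -> float:
    """Width normalized by the target range R (R = 4 on the pain scale)."""
    if target_range <= 0:
        raise ValueError("target range R must be positive")
    return float(mpiw_value) / float(target_range)


def picp_soft(batch: IntervalBatch, s: float) -> float:
    """Sigmoid-softened coverage.

    Mean over observations of sigma(s (y - L)) * sigma(s (U - y)); lies in
    (0, 1) and approaches the hard PICP as the softening factor s grows
    (for targets not exactly on a bound, where each factor is 1/2).
    """
    _require_nonempty(batch)
    if s <= 0:
        raise ValueError("softening factor s must be positive")
    soft = (expit(s * (batch.target - batch.lower))
            * expit(s * (batch.upper - batch.target)))
    return float(soft.mean())


def mpiw_captured(batch: IntervalBatch) -> float:
    """Mean width over captured points only (hard indicator selector).

    Raises if no point is captured: the ratio is undefined there.  The
    training loss applies its own fallback for that degenerate case.
    """
    _require_nonempty(batch)
    k = batch.covered
    total = k.sum()
    if total == 0:
        raise ZeroDivisionError(
            "no captured points: captured mean width is undefined")
    return float((k * batch.widths).sum() / total)


def crossing_fraction(batch: IntervalBatch) -> float:
    """Fraction of observations whose bounds cross (upper < lower)."""
    _require_nonempty(batch)
    return float((batch.upper < batch.lower).mean())


@dataclass(frozen=True)
class PIQuality:
    """The (PICP, MPIW, NMPIW) triple for a bound set at a nominal level."""

    picp: float
    mpiw: float
    nmpiw: float
    nominal: float
    crossing_fraction: float = 0.0

    @classmethod
    def from_batch(cls, batch: IntervalBatch, nominal: float,
                   target_range: float = 4.0) -> "PIQuality":
        w = mpiw(batch)
        return cls(picp=picp(batch), mpiw=w,
                   nmpiw=nmpiw(w, target_range), nominal=nominal,
                   crossing_fraction=crossing_fraction(batch))

    def as_row(self) -> dict:
        return {"nominal": self.nominal, "picp": self.picp,
                "mpiw": self.mpiw, "nmpiw": self.nmpiw,
                "crossing_fraction": self.crossing_fraction}
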