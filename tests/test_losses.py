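"""The LUBE loss, its differentiable softening, and their gradients."""

import numpy as np
import pytest

import painpi as pp
from painpi.losses import (LossLParams, LossSParams, loss_L, loss_S,
                           loss_S_bound_grads)


def batch_with(picp_target, width, n=100):
    """A batch whose hard PICP and MPIW are exactly the requested values."""
    y = np.full(n, 2.0)
    lo = np.full(n, 2.0 - width / 2)
    hi = np.full(n, 2.0 + width / 2)
    n_out = round(n * (1 - picp_target))
    y[:n_out] = 100.0  # far outside: not captured
    return pp.IntervalBatch(lo, hi, y)


class TestLossL:
    def test_evaluation_mode_drops_penalty_when_covered(self):
        b = batch_with(0.95, width=2.0)
        p = LossLParams(eta=50, mu=0.9)
        assert loss_L(b, p, training=False) == pytest.approx(2.0 / 4.0)

    def test_training_at_exact_target_doubles_width_term(self):
        b = batch_with(0.9, width=2.0)
        p = LossLParams(eta=50, mu=0.9)
        assert loss_L(b, p, training=True) == pytest.approx(2 * 2.0 / 4.0)

    def test_derived_arithmetic(self):
        # MPIW=2, R=4, PICP=0.8, mu=0.9, eta=50 -> 0.5 (1 + e^5)
        b = batch_with(0.8, width=2.0)
        p = LossLParams(eta=50, mu=0.9)
        expected = 0.5 * (1 + np.exp(5.0))
        assert loss_L(b, p, training=True) == pytest.approx(expected,
                                                            rel=1e-9)
        assert expected == pytest.approx(74.71, abs=0.01)

    def test_monotone_in_picp_and_mpiw(self):
        p = LossLParams(eta=50, mu=0.9)
        losses = [loss_L(batch_with(c, width=2.0), p) for c in
                  (0.5, 0.7, 0.9, 1.0)]
        assert all(a > b for a, b in zip(losses, losses[1:]))
        widths = [loss_L(batch_with(0.8, width=w), p) for w in
                  (0.5, 1.0, 2.0, 3.0)]
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            LossLParams(mu=1.5)
        with pytest.raises(ValueError):
            LossLParams(target_range=0.0)


class TestLossS:
    def test_reduces_to_captured_width_when_covered(self, rng):
        y = rng.uniform(1, 3, 50)
        b = pp.IntervalBatch(y - 2.0, y + 2.0, y)  # huge margins
        p = LossSParams(lam=10, eta=100, alpha=0.1, s=60)
        assert loss_S(b, p) == pytest.approx(pp.mpiw_captured(b), abs=1e-6)

    def test_lambda_zero_drops_penalty(self):
        b = batch_with(0.5, width=1.0)
        p = LossSParams(lam=0.0, eta=100, alpha=0.1, s=60)
        assert loss_S(b, p) == pytest.approx(pp.mpiw_captured(b))

    def test_derived_arithmetic_of_penalty(self):
        # MPIW_S=2, PICP_S=0.8, alpha=0.1, lam=10, eta=100
        # -> 2 + 10 (100 / 0.09) 0.1^2 = 113.11
        p = LossSParams(lam=10, eta=100, alpha=0.1, s=60)
        value = 2.0 + p.penalty_scale * max(0.0, 0.9 - 0.8) ** 2
        assert value == pytest.approx(113.11, abs=0.01)

    def test_loss_matches_metric_composition(self, rng):
        # dual route: loss_S equals the composition of the public metric
        # functions on the same batch
        for _ in range(10):
            y = rng.uniform(0, 4, 40)
            b = pp.IntervalBatch(y - rng.uniform(-0.3, 1.0, 40),
                                 y + rng.uniform(-0.3, 1.0, 40), y)
            p = LossSParams(lam=12, eta=80, alpha=0.15, s=45)
            try:
                width = pp.mpiw_captured(b)
            except ZeroDivisionError:
                width = 0.0
            expected = width + p.penalty_scale * max(
                0.0, (1 - p.alpha) - pp.picp_soft(b, p.s)) ** 2
            assert loss_S(b, p) == pytest.approx(expected, rel=1e-12)

    def test_penalty_zero_above_target_positive_decreasing_below(self):
        p = LossSParams(lam=10, eta=100, alpha=0.1, s=200)
        # soft coverage above 1 - alpha: loss equals width term
        covered = batch_with(1.0, width=1.0)
        assert loss_S(covered, p) == pytest.approx(1.0, abs=1e-3)
        below = [loss_S(batch_with(c, width=1.0), p)
                 for c in (0.85, 0.7, 0.5)]
        assert all(a < b for a, b in zip(below, below[1:]))

    def test_zero_capture_drops_width_term(self):
        b = pp.IntervalBatch([2.0], [3.0], [0.0])
        p = LossSParams(lam=10, eta=100, alpha=0.1, s=60)
        value, dL, dU, info = loss_S_bound_grads(b, p)
        assert info["zero_capture_fallback"]
        assert value == pytest.approx(
            p.penalty_scale * max(0.0, 0.9 - pp.picp_soft(b, 60.0)) ** 2)


class TestLossSGradients:
    def test_matches_central_differences(self, rng):
        maxerr = 0.0
        for _ in range(10):
            n = int(rng.integers(5, 25))
            y = rng.uniform(0, 4, n)
            b = pp.IntervalBatch(y - rng.uniform(-0.5, 1.5, n),
                                 y + rng.uniform(-0.5, 1.5, n), y)
            p = LossSParams(lam=float(rng.uniform(5, 30)),
                            eta=float(rng.uniform(35, 240)),
                            alpha=float(rng.uniform(0.05, 0.5)),
                            s=float(rng.uniform(10, 220)))
            _, dL, dU, _ = loss_S_bound_grads(b, p)
            eps, k0 = 1e-5, b.covered
            for which, grad in (("L", dL), ("U", dU)):
                for i in rng.choice(n, size=min(3, n), replace=False):
                    lo_p, hi_p = b.lower.copy(), b.upper.copy()
                    lo_m, hi_m = b.lower.copy(), b.upper.copy()
                    if which == "L":
                        lo_p[i] += eps
                        lo_m[i] -= eps
                    else:
                        hi_p[i] += eps
                        hi_m[i] -= eps
                    bp = pp.IntervalBatch(lo_p, hi_p, y)
                    bm = pp.IntervalBatch(lo_m, hi_m, y)
                    if not (np.array_equal(bp.covered, k0)
                            and np.array_equal(bm.covered, k0)):
                        continue  # capture selector flipped: held fixed
                    fd = (loss_S(bp, p) - loss_S(bm, p)) / (2 * eps)
                    rel = abs(fd - grad[i]) / max(1e-2, abs(fd) + abs(grad[i]))
                    maxerr = max(maxerr, rel)
        assert maxerr < 1e-4
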