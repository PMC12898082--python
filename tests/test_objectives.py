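"""Loss-function oracles: closed-form and brute-force hand evaluations."""

import numpy as np
import pytest

from eimspec import (LossConfig, cosine_diagnostic, reconstruction_loss,
                     retrieval_loss, total_loss)
from eimspec.autodiff import Tensor


def brute_force_reconstruction(P, T, eps):
    """Direct per-term evaluation of the mass-weighted sqrt loss."""
    P, T = np.atleast_2d(P), np.atleast_2d(T)
    B, D = T.shape
    m = np.arange(1, D + 1)
    vals = []
    for i in range(B):
        p = np.maximum(P[i], 0.0)
        num = sum(m[k] * (np.sqrt(T[i, k] + eps) - np.sqrt(p[k] + eps)) ** 2
                  for k in range(D))
        den = sum((m[k] * np.sqrt(T[i, k] + eps)) ** 2 for k in range(D))
        vals.append(num / den)
    return float(np.mean(vals))


class TestReconstructionLoss:
    def test_zero_at_identity(self):
        T = np.zeros((2, 500))
        T[0, 10] = 0.6
        T[0, 20] = 0.4
        T[1, 99] = 1.0
        assert float(reconstruction_loss(T, T).data) == pytest.approx(0.0, abs=1e-12)

    def test_three_term_hand_oracle(self):
        cfg = LossConfig(epsilon=1e-8)
        t = np.array([[0.0, 1.0, 0.0]])
        p = np.array([[0.0, 0.5, 0.5]])
        got = float(reconstruction_loss(p, t, cfg=cfg).data)
        assert got == pytest.approx(brute_force_reconstruction(p, t, cfg.epsilon),
                                    rel=1e-12)

    def test_clamping_invariance_for_negative_predictions(self):
        t = np.zeros((1, 500))
        t[0, 5] = 1.0
        p = np.random.default_rng(0).normal(size=(1, 500))
        p_clamped = np.maximum(p, 0.0)
        assert float(reconstruction_loss(p, t).data) == pytest.approx(
            float(reconstruction_loss(p_clamped, t).data), rel=1e-12)

    def test_denominator_uses_targets_only(self):
        """Scaling the prediction must not rescale the loss denominator."""
        t = np.zeros((1, 100))
        t[0, 40] = 1.0
        p = np.zeros((1, 100))
        p[0, 50] = 1.0
        big = p * 100.0
        eps = LossConfig().epsilon
        assert float(reconstruction_loss(big, t).data) == pytest.approx(
            brute_force_reconstruction(big, t, eps), rel=1e-10)

    def test_unnormalized_target_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.ones((1, 10)), np.ones((1, 10)))

    def test_monotone_decrease_toward_target(self):
        r = np.random.default_rng(1)
        t = r.dirichlet(np.ones(50)).reshape(1, -1)
        p = r.random((1, 50))
        losses = [float(reconstruction_loss(p + a * (t - p), t).data)
                  for a in np.linspace(0, 1, 8)]
        assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))


def _unit_rows(X):
    return X / np.linalg.norm(X, axis=1, keepdims=True)


class TestRetrievalLoss:
    def test_single_candidate_is_zero(self):
        u = _unit_rows(np.array([[1.0, 2.0, 3.0]]))
        cfg = LossConfig(tau=1.0)
        assert float(retrieval_loss(u, u, cfg).data) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_pair_closed_form(self):
        """B=2, diagonal similarity 1, off-diagonal 0, tau=1:
        per-row loss log(1 + e^-1) ~ 0.313262."""
        U = np.eye(2)
        V = np.eye(2)
        got = float(retrieval_loss(U, V, LossConfig(tau=1.0)).data)
        assert got == pytest.approx(np.log(1 + np.exp(-1.0)), abs=1e-9)
        assert got == pytest.approx(0.313262, abs=1e-6)

    def test_uniform_logits_give_log_b(self):
        B, d = 5, 3
        u = np.tile(_unit_rows(np.ones((1, d))), (B, 1))
        assert float(retrieval_loss(u, u, LossConfig(tau=0.7)).data) == (
            pytest.approx(np.log(B), rel=1e-12))

    def test_non_unit_rows_rejected(self):
        with pytest.raises(ValueError):
            retrieval_loss(np.ones((2, 3)), _unit_rows(np.ones((2, 3))))

    def test_invariance_under_common_rotation(self, rng):
        U = _unit_rows(rng.normal(size=(6, 8)))
        V = _unit_rows(rng.normal(size=(6, 8)))
        Q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        cfg = LossConfig(tau=0.04)
        a = float(retrieval_loss(U, V, cfg).data)
        b = float(retrieval_loss(U @ Q, V @ Q, cfg).data)
        assert a == pytest.approx(b, rel=1e-9)


class TestTotalLoss:
    def test_hand_arithmetic(self):
        got = total_loss(Tensor(0.4), Tensor(0.2), LossConfig(lambda_ret=0.5))
        assert float(got.data) == pytest.approx(0.5)

    def test_lambda_zero(self):
        got = total_loss(Tensor(0.7), Tensor(123.0), LossConfig(lambda_ret=0.0))
        assert float(got.data) == pytest.approx(0.7)

    def test_zero_case(self):
        assert float(total_loss(Tensor(0.0), Tensor(0.0)).data) == 0.0


class TestCosineDiagnostic:
    def test_identical(self):
        X = np.random.default_rng(0).random((3, 10))
        assert cosine_diagnostic(X, X) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal(self):
        p = np.array([[1.0, 0.0]])
        t = np.array([[0.0, 1.0]])
        assert cosine_diagnostic(p, t) == pytest.approx(1.0)

    def test_scale_invariance(self):
        t = np.random.default_rng(1).random((2, 20))
        assert cosine_diagnostic(2.0 * t, t) == pytest.approx(0.0, abs=1e-12)


def test_config_validation():
    with pytest.raises(ValueError):
        LossConfig(tau=0.0)
    with pytest.raises(ValueError):
        LossConfig(lambda_ret=-0.1)
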