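"""Training objectives: reconstruction, retrieval, total, and the cosine
diagnostic.

The reconstruction loss is a mass-weighted squared difference of
square-root intensities,

    L_rec = (1/B) sum_i  sum_k m_k (sqrt(t_ik + eps) - sqrt(p~_ik + eps))^2
                         -----------------------------------------------
                         sum_k (m_k sqrt(t_ik + eps))^2

with p~ = max(p, 0) and m_k = k + 1 the m/z at bin k.  Only the true
spectrum appears in the denominator, so the magnitude of the prediction
cannot dilute its own error.  The small eps keeps the square root away
from zero.

The retrieval loss is a temperature-scaled cross-entropy over the batch
similarity matrix of unit-norm spectrum embeddings, with the diagonal as
the positive pairs (an InfoNCE-style objective).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, logsumexp, maximum


@dataclass
class LossConfig:
    epsilon: float = 1e-8    # guards sqrt(0) in the reconstruction loss
    tau: float = 0.04        # retrieval softmax temperature
    lambda_ret: float = 0.5  # retrieval weight in the total loss

    def __post_init__(self):
        if self.epsilon <= 0 or self.tau <= 0 or self.lambda_ret < 0:
            raise ValueError("epsilon, tau must be > 0 and lambda_ret >= 0")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def reconstruction_loss(P, T, masses: np.ndarray | None = None,
                        cfg: LossConfig = LossConfig()) -> Tensor:
    """Mass-weighted square-root reconstruction loss (batch mean).

    ``P``: predicted spectra (B, D), sign-unconstrained (clamped inside);
    ``T``: L1-normalized target spectra (B, D); ``masses``: the m/z value at
    each bin (defaults to k+1).
    """
    P, T = _as_tensor(P), _as_tensor(T)
    B, D = T.shape
    row_sums = T.data.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("target spectra must be L1-normalized")
    m = (np.arange(1, D + 1, dtype=np.float64) if masses is None
         else np.asarray(masses, dtype=np.float64))
    p_clamped = maximum(P, 0.0)
    sqrt_t = (T + cfg.epsilon) ** 0.5
    sqrt_p = (p_clamped + cfg.epsilon) ** 0.5
    num = ((sqrt_t - sqrt_p) ** 2 * m).sum(axis=1)
    den = ((sqrt_t * m) ** 2).sum(axis=1)       # true spectrum only
    return (num / den).mean()


def retrieval_loss(U, V, cfg: LossConfig = LossConfig()) -> Tensor:
    """Temperature-scaled cross-entropy with diagonal positives.

    ``U``: embeddings of predicted spectra, ``V``: of targets; rows must be
    unit-norm.  s_ij = (u_i . v_j) / tau; loss = -(1/B) sum_i log softmax
    row i at column i.
    """
    U, V = _as_tensor(U), _as_tensor(V)
    for name, X in (("U", U), ("V", V)):
        norms = np.linalg.norm(X.data, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-5):
            raise ValueError(f"rows of {name} must be unit-norm")
    S = (U @ V.transpose()) * (1.0 / cfg.tau)
    diag = (S * Tensor(np.eye(S.shape[0]))).sum(axis=1)
    return (logsumexp(S, axis=1) - diag).mean()


def total_loss(rec: Tensor, ret: Tensor,
               cfg: LossConfig = LossConfig()) -> Tensor:
    """Total objective: reconstruction + lambda * retrieval."""
    return rec + cfg.lambda_ret * ret


def cosine_diagnostic(P, T, eps: float = 1e-12) -> float:
    """Batch mean of 1 - cosine(p_i, t_i); test-set diagnostic only.

    Never differentiated — returns a plain float.
    """
    P = P.data if isinstance(P, Tensor) else np.asarray(P, dtype=np.float64)
    T = T.data if isinstance(T, Tensor) else np.asarray(T, dtype=np.float64)
    pn = np.linalg.norm(P, axis=1)
    tn = np.linalg.norm(T, axis=1)
    denom = np.where(pn * tn > 0, pn * tn, eps)
    cos = (P * T).sum(axis=1) / denom
    return float(np.mean(1.0 - cos))


def mean_cosine_similarity(P, T) -> float:
    """Batch mean cosine similarity between paired spectra."""
    return 1.0 - cosine_diagnostic(P, T)
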