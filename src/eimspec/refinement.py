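"""Refinement stack for the initial spectrum prediction.

Three stages, each individually ablatable:

* **Cross-attention** — each m/z bin of the initial spectrum becomes a token
  (its scalar intensity modulating a learned per-bin positional embedding);
  the graph embedding is the query and attends over all 500 tokens; the
  attended context is projected back to 500-d and added residually.
* **Bidirectional prediction** — forward and reverse heads; the reverse
  spectrum is indexed from the molecular-ion bin downwards (fragment at
  m/z M−x mirrors a neutral loss of x), with no mass shift, so no reverse
  contribution lands above the molecular ion.  A learned per-bin gate
  blends the two directions.
* **Probabilistic mask** — multiplicative position-dependent probabilities
  and mass-relative scaling, plus additive non-normalized Gaussian boosts
  centred at the m/z of each expected neutral-loss peak (M − loss), with
  amplitude in (0,1) and width ≥ 1 predicted from the graph embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (Tensor, logsumexp, maximum, sigmoid, softplus,
                       take_per_row, where_mask)
from .nn import MLP, Linear, Module


@dataclass
class AttentionConfig:
    n_heads: int = 4
    qkv_dim: int = 256      # queries, keys and values all project to this
    spectrum_dim: int = 500

    def __post_init__(self):
        if self.qkv_dim % self.n_heads != 0:
            raise ValueError("qkv_dim must be divisible by n_heads")


@dataclass(frozen=True)
class NeutralLossTable:
    """Common neutral losses (label, integer mass in Da).

    Defaults cover the frequent EI losses (water, ammonia, methyl, CO, ...);
    the table is configuration and can be loaded from YAML.
    """

    entries: tuple[tuple[str, int], ...] = (
        ("H2O", 18), ("NH3", 17), ("CH3", 15), ("CO", 28), ("CHO", 29),
        ("OCH3", 31), ("CO2", 44), ("C2H5", 29), ("Cl", 35), ("NO2", 46),
    )

    def __post_init__(self):
        labels = [label for label, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("neutral-loss labels must be unique")
        for label, mass in self.entries:
            if not (0 < int(mass) <= 100):
                raise ValueError(f"neutral-loss mass out of range: {label}={mass}")

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for _, m in self.entries], dtype=np.intp)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_yaml(cls, path) -> "NeutralLossTable":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(entries=tuple((str(e["label"]), int(e["mass"])) for e in raw))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump([{"label": l, "mass": int(m)} for l, m in self.entries], fh)


def _rounded_mass(masses: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(masses, dtype=np.float64) + 0.5).astype(np.intp)


class CrossAttention(Module):
    """Graph-embedding query attending over per-bin spectrum tokens."""

    def __init__(self, cfg: AttentionConfig, embed_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        D, q = cfg.spectrum_dim, cfg.qkv_dim
        self.pos_scale = Tensor(rng.uniform(-0.1, 0.1, size=(D, q)),
                                requires_grad=True)
        self.pos_bias = Tensor(rng.uniform(-0.1, 0.1, size=(D, q)),
                               requires_grad=True)
        self.Wq = Linear(embed_dim, q, rng)
        self.Wk = Linear(q, q, rng)
        self.Wv = Linear(q, q, rng)
        self.Wo = Linear(q, D, rng)

    def __call__(self, z: Tensor, s0: Tensor) -> Tensor:
        cfg = self.cfg
        B = s0.shape[0]
        D, q, h = cfg.spectrum_dim, cfg.qkv_dim, cfg.n_heads
        dh = q // h
        if s0.shape[-1] != D:
            raise ValueError(f"expected spectrum dim {D}, got {s0.shape[-1]}")
        # tokens: scalar bin intensity modulates a learned positional embedding
        tok = s0.reshape(B, D, 1) * self.pos_scale + self.pos_bias   # (B,D,q)
        K = self.Wk(tok).reshape(B, D, h, dh).transpose(0, 2, 1, 3)  # (B,h,D,dh)
        V = self.Wv(tok).reshape(B, D, h, dh).transpose(0, 2, 1, 3)
        Q = self.Wq(z).reshape(B, 1, h, dh).transpose(0, 2, 1, 3)    # (B,h,1,dh)
        scores = (Q @ K.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))  # (B,h,1,D)
        attn = (scores - logsumexp(scores, axis=-1, keepdims=True)).exp()
        ctx = (attn @ V).transpose(0, 2, 1, 3).reshape(B, q)
        return s0 + self.Wo(ctx)


def cross_attend(z: Tensor, s0: Tensor, module: CrossAttention | None) -> Tensor:
    """Apply cross-attention; with the module disabled the input passes
    through untouched (exact ablation identity)."""
    if module is None:
        return s0
    return module(z, s0)


def reverse_spectrum(g: Tensor, masses: np.ndarray) -> Tensor:
    """Index-reverse a spectrum around each molecule's molecular-ion bin.

    With M = round(mono_mass) and molecular-ion bin m* = M − 1 (capped at
    D − 1): ``r_k = g_{m*−k}`` for 0 ≤ k ≤ m*, else 0.  Bins above the
    molecular ion receive no reverse contribution (no mass shift).
    """
    D = g.shape[-1]
    m_star = np.minimum(_rounded_mass(masses) - 1, D - 1)
    k = np.arange(D)
    idx = m_star[:, None] - k[None, :]
    valid = idx >= 0
    return where_mask(valid, take_per_row(g, np.clip(idx, 0, D - 1)))


class BidirectionalGate(Module):
    """Forward/reverse spectrum heads blended by a learned per-bin gate."""

    def __init__(self, spectrum_dim: int, rng: np.random.Generator):
        super().__init__()
        self.spectrum_dim = spectrum_dim
        self.gate_logits = Tensor(np.zeros(spectrum_dim), requires_grad=True)
        self.forward_head = Linear(spectrum_dim, spectrum_dim, rng)
        self.reverse_head = Linear(spectrum_dim, spectrum_dim, rng)

    def __call__(self, s: Tensor, masses: np.ndarray,
                 forward_only: bool = False) -> Tensor:
        if np.any(np.asarray(masses) <= 0):
            raise ValueError("mono_mass must be positive")
        f = self.forward_head(s)
        if forward_only:
            return f
        g = self.reverse_head(s)
        r = reverse_spectrum(g, masses)
        alpha = sigmoid(self.gate_logits)
        return alpha * f + (1.0 - alpha) * r


def bidirectional(s: Tensor, masses: np.ndarray, gate: BidirectionalGate,
                  forward_only: bool = False) -> Tensor:
    return gate(s, masses, forward_only=forward_only)


class ProbabilisticMask(Module):
    """Chemistry-informed mask applied multiplicatively to the spectrum.

    mask_k = sigmoid(position_logits_k) * mass_scale(k / M)
             + sum_l A_l * exp(-(k - c_l)^2 / (2 w_l^2)),

    with c_l the bin of m/z (M - loss_l).  Gaussians are deliberately not
    normalized: the boost at the centre equals the amplitude, so a wide
    (uncertain) loss does not contribute the same total mass as a sharp one.
    """

    def __init__(self, spectrum_dim: int, embed_dim: int,
                 loss_table: NeutralLossTable, rng: np.random.Generator,
                 hidden: int = 16):
        super().__init__()
        self.spectrum_dim = spectrum_dim
        self.loss_table = loss_table
        self.position_logits = Tensor(np.zeros(spectrum_dim), requires_grad=True)
        self.mass_scale_net = MLP([1, hidden, 1], rng)
        self.amp_net = MLP([embed_dim, hidden, len(loss_table)], rng)
        self.width_net = MLP([embed_dim, hidden, len(loss_table)], rng)

    def gaussian_params(self, z: Tensor) -> tuple[Tensor, Tensor]:
        """Per-loss amplitude in (0,1) (sigmoid) and width >= 1 (softplus+1)."""
        amps = sigmoid(self.amp_net(z))
        widths = softplus(self.width_net(z)) + 1.0
        return amps, widths

    def __call__(self, s: Tensor, z: Tensor, masses: np.ndarray) -> Tensor:
        B, D = s.shape[0], self.spectrum_dim
        if np.any(np.asarray(masses) <= 0):
            raise ValueError("mono_mass must be positive")
        k = np.arange(D, dtype=np.float64)
        ratio = (k[None, :] / np.asarray(masses, dtype=np.float64)[:, None])
        scale = softplus(
            self.mass_scale_net(Tensor(ratio.reshape(B * D, 1)))
        ).reshape(B, D)
        base = sigmoid(self.position_logits).reshape(1, D) * scale

        M = _rounded_mass(masses)
        centers = (M[:, None] - self.loss_table.masses[None, :]) - 1  # (B, L)
        applicable = (centers >= 0) & (centers < D)
        diff2 = (k[None, None, :] - centers[:, :, None].astype(np.float64)) ** 2
        amps, widths = self.gaussian_params(z)                        # (B, L)
        L = len(self.loss_table)
        w2 = (widths * widths).reshape(B, L, 1)
        gauss = (Tensor(-diff2) / (2.0 * w2)).exp()
        amp_masked = (amps * Tensor(applicable.astype(np.float64))).reshape(B, L, 1)
        boost = (amp_masked * gauss).sum(axis=1)                      # (B, D)
        mask = base + boost
        return maximum(s, 0.0) * mask


def apply_mask(s: Tensor, z: Tensor, masses: np.ndarray,
               mask_module: ProbabilisticMask | None) -> Tensor:
    """Apply the probabilistic mask; disabled, only the nonnegativity clamp
    remains."""
    if mask_module is None:
        return maximum(s, 0.0)
    return mask_module(s, z, masses)
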