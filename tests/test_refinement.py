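"""Refinement-stack contracts: ablation identities, index reversal,
Gaussian boost geometry, mask constraint ranges."""

import numpy as np
import pytest

from eimspec import NeutralLossTable
from eimspec.autodiff import Tensor
from eimspec.refinement import (AttentionConfig, BidirectionalGate,
                                CrossAttention, ProbabilisticMask,
                                apply_mask, cross_attend, reverse_spectrum)


@pytest.fixture()
def small_attention(rng):
    cfg = AttentionConfig(n_heads=1, qkv_dim=2, spectrum_dim=3)
    return CrossAttention(cfg, embed_dim=2, rng=rng)


class TestCrossAttention:
    def test_disabled_attention_is_bitwise_identity(self):
        s0 = Tensor(np.random.default_rng(0).normal(size=(2, 500)))
        out = cross_attend(Tensor(np.zeros((2, 8))), s0, None)
        assert out is s0

    def test_output_length_matches_spectrum(self, rng):
        cfg = AttentionConfig(n_heads=4, qkv_dim=16, spectrum_dim=500)
        att = CrossAttention(cfg, embed_dim=8, rng=rng)
        out = att(Tensor(np.random.default_rng(1).normal(size=(3, 8))),
                  Tensor(np.random.default_rng(2).normal(size=(3, 500))))
        assert out.shape == (3, 500)

    def test_single_head_matches_hand_softmax(self, small_attention):
        """3-bin toy: softmax-weighted values plus residual, by hand."""
        att = small_attention
        z = np.array([[0.3, -0.7]])
        s0 = np.array([[0.5, -1.0, 2.0]])
        out = att(Tensor(z), Tensor(s0)).data

        W = {k: v.data for k, v in att.parameters().items()}
        tok = s0[0][:, None] * W["pos_scale"] + W["pos_bias"]       # (3, 2)
        K = tok @ W["Wk.W"] + W["Wk.b"]
        V = tok @ W["Wv.W"] + W["Wv.b"]
        q = z[0] @ W["Wq.W"] + W["Wq.b"]
        scores = K @ q / np.sqrt(2.0)
        weights = np.exp(scores - scores.max())
        weights /= weights.sum()
        ctx = weights @ V
        expected = s0[0] + (ctx @ W["Wo.W"] + W["Wo.b"])
        np.testing.assert_allclose(out[0], expected, atol=1e-10)


class TestBidirectional:
    def test_forward_only_equals_forward_head(self, rng):
        gate = BidirectionalGate(10, rng)
        s = Tensor(np.random.default_rng(0).normal(size=(2, 10)))
        masses = np.array([8.0, 5.0])
        out = gate(s, masses, forward_only=True).data
        np.testing.assert_array_equal(out, gate.forward_head(s).data)

    def test_reverse_index_oracle_d5(self):
        """D=5, M=4 so m*=3: r = [g3, g2, g1, g0, 0]."""
        g = Tensor(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]))
        r = reverse_spectrum(g, np.array([4.0])).data
        np.testing.assert_array_equal(r, [[4.0, 3.0, 2.0, 1.0, 0.0]])

    def test_no_reverse_mass_above_molecular_ion(self):
        g = Tensor(np.arange(20, dtype=float).reshape(1, 20))
        r = reverse_spectrum(g, np.array([10.0])).data
        assert np.all(r[0, 10:] == 0.0)

    def test_saturated_gate_returns_forward(self, rng):
        gate = BidirectionalGate(10, rng)
        gate.gate_logits.data = np.full(10, 50.0)   # sigmoid -> 1
        s = Tensor(np.random.default_rng(1).normal(size=(2, 10)))
        out = gate(s, np.array([8.0, 5.0])).data
        np.testing.assert_allclose(out, gate.forward_head(s).data, atol=1e-12)

    def test_nonpositive_mass_rejected(self, rng):
        gate = BidirectionalGate(10, rng)
        with pytest.raises(ValueError):
            gate(Tensor(np.zeros((1, 10))), np.array([0.0]))


class TestProbabilisticMask:
    @pytest.fixture()
    def mask(self, rng):
        return ProbabilisticMask(spectrum_dim=500, embed_dim=8,
                                 loss_table=NeutralLossTable(), rng=rng)

    def test_disabled_mask_is_clamp_only(self):
        s = Tensor(np.random.default_rng(0).normal(size=(2, 500)))
        out = apply_mask(s, Tensor(np.zeros((2, 8))), np.array([100.0, 90.0]),
                         None).data
        np.testing.assert_array_equal(out, np.maximum(s.data, 0.0))

    def test_water_loss_gaussian_centred_at_index_81(self, rng):
        """M = 100, H2O loss 18: peak at m/z 82 lives at index 81."""
        table = NeutralLossTable(entries=(("H2O", 18),))
        mask = ProbabilisticMask(500, 8, table, rng)
        z = Tensor(np.random.default_rng(1).normal(size=(1, 8)))
        amps, widths = mask.gaussian_params(z)
        ones = Tensor(np.ones((1, 500)))
        with_boost = mask(ones, z, np.array([100.0])).data[0]
        mask.amp_net.layers[-1].b.data -= 1e3     # amplitude -> 0
        base_only = mask(ones, z, np.array([100.0])).data[0]
        boost = with_boost - base_only
        assert boost.argmax() == 81
        # non-normalized Gaussian: the value at the centre is the amplitude
        assert boost[81] == pytest.approx(float(amps.data[0, 0]), abs=1e-6)

    def test_zero_amplitude_leaves_base_mask(self, rng):
        mask = ProbabilisticMask(500, 8, NeutralLossTable(), rng)
        mask.amp_net.layers[-1].b.data -= 1e3
        z = Tensor(np.random.default_rng(2).normal(size=(1, 8)))
        s = Tensor(np.ones((1, 500)))
        out = mask(s, z, np.array([250.0])).data
        # reconstruct base term independently
        from eimspec.autodiff import sigmoid, softplus
        ratio = np.arange(500) / 250.0
        scale = softplus(mask.mass_scale_net(
            Tensor(ratio.reshape(-1, 1)))).data.reshape(-1)
        base = sigmoid(mask.position_logits).data * scale
        np.testing.assert_allclose(out[0], base, atol=1e-9)

    def test_constraint_ranges_for_random_embeddings(self, mask):
        z = Tensor(np.random.default_rng(3).normal(size=(40, 8), scale=3.0))
        amps, widths = mask.gaussian_params(z)
        assert np.all((amps.data > 0) & (amps.data < 1))
        assert np.all(widths.data >= 1.0)

    def test_output_nonnegative(self, mask):
        r = np.random.default_rng(4)
        s = Tensor(r.normal(size=(5, 500)))
        z = Tensor(r.normal(size=(5, 8)))
        out = mask(s, z, np.array([120.0, 77.0, 500.0, 18.5, 300.0])).data
        assert np.all(out >= 0.0)

    def test_losses_below_zero_index_skipped(self, rng):
        """A molecule lighter than the loss gets no boost from it."""
        table = NeutralLossTable(entries=(("CO2", 44),))
        mask = ProbabilisticMask(500, 8, table, rng)
        z = Tensor(np.random.default_rng(5).normal(size=(1, 8)))
        out1 = mask(Tensor(np.ones((1, 500))), z, np.array([30.0])).data
        mask.amp_net.layers[-1].b.data -= 1e3
        out2 = mask(Tensor(np.ones((1, 500))), z, np.array([30.0])).data
        np.testing.assert_allclose(out1, out2, atol=1e-9)


def test_loss_table_validation():
    with pytest.raises(ValueError):
        NeutralLossTable(entries=(("A", 18), ("A", 17)))
    with pytest.raises(ValueError):
        NeutralLossTable(entries=(("big", 150),))


def test_loss_table_yaml_round_trip(tmp_path):
    table = NeutralLossTable()
    path = tmp_path / "losses.yaml"
    table.to_yaml(path)
    assert NeutralLossTable.from_yaml(path).entries == table.entries
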