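"""Encoder/decoder/projection contracts: permutation invariance, shapes,
hand-computed message passing, homogeneity of the bias-free projection."""

import numpy as np
import pytest

from eimspec import featurize
from eimspec.autodiff import Tensor
from eimspec.network import (DecoderConfig, EncoderConfig, GraphBatch,
                             MPNNEncoder, MPNNLayer, PoolMLPEncoder,
                             ProjectionConfig, ProjectionHead, ResNetDecoder)

SMALL_ENC = dict(n_layers=2, hidden_dim=16, dropout=0.0, out_dim=8)


def _encoder(rng, **over):
    cfg = EncoderConfig(**{**SMALL_ENC, **over})
    return MPNNEncoder(cfg, rng)


def test_encoder_permutation_invariance(rng):
    enc = _encoder(rng)
    enc.set_training(False)
    za = enc(GraphBatch([featurize("CC(=O)Oc1ccccc1C(=O)O")])).data
    zb = enc(GraphBatch([featurize("OC(=O)c1ccccc1OC(C)=O")])).data
    np.testing.assert_allclose(za, zb, atol=1e-5)


def test_encoder_edge_order_invariance(rng):
    g = featurize("CCO")
    enc = _encoder(rng)
    enc.set_training(False)
    base = enc(GraphBatch([g])).data
    perm = np.random.default_rng(0).permutation(g.n_edges)
    g.edge_index = g.edge_index[perm]
    g.edge_features = g.edge_features[perm]
    np.testing.assert_allclose(enc(GraphBatch([g])).data, base, atol=1e-10)


def test_single_node_graph_aggregates_zero(rng):
    """With no neighbours the message sum is exactly the zero vector, so the
    update acts on (x, 0)."""
    g = featurize("C")
    layer = MPNNLayer(hidden_dim=4, edge_dim=10, dropout=0.0, rng=rng)
    layer.set_training(False)
    x = np.random.default_rng(0).normal(size=(1, 4))
    out = layer(Tensor(x), GraphBatch([g])).data
    W = {k: v.data for k, v in layer.parameters().items()}
    inp = np.concatenate([x, np.zeros((1, 4))], axis=1)
    h = np.maximum(inp @ W["update_mlp.layer0.W"] + W["update_mlp.layer0.b"], 0)
    h = h @ W["update_mlp.layer1.W"] + W["update_mlp.layer1.b"]
    np.testing.assert_allclose(out, x + np.maximum(h, 0), atol=1e-12)


def test_message_passing_matches_hand_computation(rng):
    """One round on a 2-node path equals the formula evaluated by hand:
    x_i + update(x_i, sum_j message(x_i, x_j) * gate(e_ji))."""
    g = featurize("CO")
    layer = MPNNLayer(hidden_dim=4, edge_dim=10, dropout=0.0, rng=rng)
    layer.set_training(False)
    X = np.random.default_rng(1).normal(size=(2, 4))
    out = layer(Tensor(X), GraphBatch([g])).data

    W = {k: v.data for k, v in layer.parameters().items()}

    def mlp(x, name):
        h = np.maximum(x @ W[f"{name}.layer0.W"] + W[f"{name}.layer0.b"], 0)
        return h @ W[f"{name}.layer1.W"] + W[f"{name}.layer1.b"]

    expected = np.zeros_like(out)
    for i in range(2):
        agg = np.zeros(4)
        for (src, tgt), e in zip(g.edge_index, g.edge_features):
            if tgt != i:
                continue
            raw = mlp(np.concatenate([X[tgt], X[src]]), "message_mlp")
            gate = 1 / (1 + np.exp(-(e @ W["edge_gate.W"] + W["edge_gate.b"])))
            agg += raw * gate
        expected[i] = X[i] + np.maximum(
            mlp(np.concatenate([X[i], agg]), "update_mlp"), 0)
    np.testing.assert_allclose(out, expected, atol=1e-10)


def test_batch_composition_independence(rng):
    graphs = [featurize(s) for s in ("CCO", "c1ccccc1", "CC(C)=O")]
    enc = _encoder(rng)
    enc.set_training(False)
    together = enc(GraphBatch(graphs)).data
    alone = np.concatenate([enc(GraphBatch([g])).data for g in graphs])
    np.testing.assert_allclose(together, alone, atol=1e-10)


class TestDecoder:
    CFG = DecoderConfig(input_dim=8, block_hidden_dim=16, head1_dim=16,
                        head2_dim=8, output_dim=500)

    def test_output_length_500(self, rng):
        dec = ResNetDecoder(self.CFG, rng)
        dec.set_training(False)
        out = dec(Tensor(np.random.default_rng(0).normal(size=(3, 8))))
        assert out.shape == (3, 500)

    def test_zero_weights_give_final_bias(self, rng):
        dec = ResNetDecoder(self.CFG, rng)
        state = {k: np.zeros_like(v) for k, v in dec.state_dict().items()}
        bias = np.linspace(-1, 1, 500)
        state["head_out.b"] = bias.copy()
        dec.load_state_dict(state)
        dec.set_training(False)
        out = dec(Tensor(np.zeros((2, 8)))).data
        np.testing.assert_allclose(out, np.tile(bias, (2, 1)), atol=1e-12)

    def test_batch_row_independence(self, rng):
        dec = ResNetDecoder(self.CFG, rng)
        dec.set_training(False)
        X = np.random.default_rng(1).normal(size=(4, 8))
        full = dec(Tensor(X)).data
        for i in range(4):
            np.testing.assert_allclose(dec(Tensor(X[i:i + 1])).data, full[i:i + 1],
                                       atol=1e-10)

    def test_dimension_mismatch_raises(self, rng):
        dec = ResNetDecoder(self.CFG, rng)
        with pytest.raises(ValueError):
            dec(Tensor(np.zeros((2, 5))))


class TestProjectionHead:
    CFG = ProjectionConfig(input_dim=500, hidden_dim=32, embedding_dim=16)

    def test_unit_norm_output(self, rng):
        head = ProjectionHead(self.CFG, rng)
        out = head(Tensor(np.random.default_rng(0).random((6, 500)))).data
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-6)

    def test_positive_homogeneity_without_biases(self, rng):
        head = ProjectionHead(self.CFG, rng)
        state = head.state_dict()
        state["lin1.b"] = np.zeros_like(state["lin1.b"])
        state["lin2.b"] = np.zeros_like(state["lin2.b"])
        head.load_state_dict(state)
        s = np.random.default_rng(2).random((3, 500))
        np.testing.assert_allclose(head(Tensor(s)).data,
                                   head(Tensor(2.0 * s)).data, atol=1e-10)

    def test_distinct_spectra_distinct_embeddings(self, rng):
        head = ProjectionHead(self.CFG, rng)
        r = np.random.default_rng(3)
        out = head(Tensor(r.random((2, 500)))).data
        assert not np.allclose(out[0], out[1])


def test_pool_mlp_encoder_ignores_bonds(rng):
    """The ablation encoder pools atom features only, so it is trivially
    permutation invariant."""
    enc = PoolMLPEncoder(EncoderConfig(**SMALL_ENC), rng)
    enc.set_training(False)
    za = enc(GraphBatch([featurize("CCO")])).data
    zb = enc(GraphBatch([featurize("OCC")])).data
    np.testing.assert_allclose(za, zb, atol=1e-10)
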