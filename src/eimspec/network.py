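"""Graph encoder, spectrum decoder, and projection head.

The encoder is a message-passing neural network: at each round every atom
aggregates (by summation, hence permutation-invariantly) messages computed
by an MLP from its own state, each neighbor's state, and the connecting
bond's features, and updates its state through a second MLP.  A sum readout
followed by a linear map yields one graph-level embedding per molecule.

The decoder is a shallow residual network: one residual block (hidden width
1024) followed by three projection layers 256 → 512 → 256 → 500 with layer
normalization between linear layers.  Index ``k`` of the 500-d output
corresponds to m/z ``k + 1``.

The projection head maps any 500-bin spectrum to a 128-d L2-normalized
embedding used for retrieval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, gather_rows, relu, segment_sum
from .chemgraph import DEFAULT_SCHEMA, MoleculeGraph
from .nn import MLP, Dropout, LayerNorm, Linear, Module


@dataclass
class EncoderConfig:
    n_layers: int = 3
    hidden_dim: int = 256
    dropout: float = 0.25
    readout: str = "sum"
    out_dim: int = 256
    node_feature_dim: int = DEFAULT_SCHEMA.atom_width
    edge_feature_dim: int = DEFAULT_SCHEMA.bond_width

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.readout != "sum":
            raise ValueError(f"unsupported readout: {self.readout!r}")


@dataclass
class DecoderConfig:
    input_dim: int = 256
    n_blocks: int = 1
    block_hidden_layers: int = 1
    block_hidden_dim: int = 1024
    block_dropout: float = 0.2
    head1_dim: int = 512
    head2_dim: int = 256
    output_dim: int = 500


@dataclass
class ProjectionConfig:
    input_dim: int = 500
    hidden_dim: int = 256
    embedding_dim: int = 128


class GraphBatch:
    """Padding-free sparse batch of molecular graphs.

    Node/edge matrices of all graphs are concatenated; ``node_graph`` maps
    each node to its graph index so per-graph quantities are recovered by
    segment sums.  Per-molecule outputs are therefore independent of batch
    composition.
    """

    def __init__(self, graphs: list[MoleculeGraph]):
        if not graphs:
            raise ValueError("empty graph batch")
        self.graphs = graphs
        self.n_graphs = len(graphs)
        offsets = np.cumsum([0] + [g.n_atoms for g in graphs])
        self.node_features = np.concatenate([g.node_features for g in graphs])
        self.edge_index = np.concatenate(
            [g.edge_index + off for g, off in zip(graphs, offsets)]
        ) if any(g.n_edges for g in graphs) else np.zeros((0, 2), dtype=np.intp)
        self.edge_features = np.concatenate([g.edge_features for g in graphs])
        self.node_graph = np.concatenate(
            [np.full(g.n_atoms, i, dtype=np.intp) for i, g in enumerate(graphs)]
        )
        self.masses = np.array([g.mono_mass for g in graphs])
        self.keys = [g.structure_key for g in graphs]


class MPNNLayer(Module):
    """One message-passing round at constant width, with a residual update.

    The message φ(x_i, x_j, e_ji) is an MLP on the concatenated endpoint
    states, gated elementwise by a linear network on the bond features; the
    update γ adds the MLP of (state, aggregated message) back onto the
    state, so repeated rounds refine rather than replace node features.
    """

    def __init__(self, hidden_dim: int, edge_dim: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.message_mlp = MLP([2 * hidden_dim, hidden_dim, hidden_dim], rng)
        self.edge_gate = Linear(edge_dim, hidden_dim, rng)
        self.update_mlp = MLP([2 * hidden_dim, hidden_dim, hidden_dim], rng)
        self.dropout = Dropout(dropout, rng)

    def __call__(self, x: Tensor, batch: GraphBatch) -> Tensor:
        from .autodiff import sigmoid

        n_nodes = batch.node_features.shape[0]
        hidden = self.edge_gate.W.shape[1]
        if batch.edge_index.shape[0] > 0:
            src = gather_rows(x, batch.edge_index[:, 0])
            tgt = gather_rows(x, batch.edge_index[:, 1])
            raw = self.message_mlp(concat([tgt, src], axis=-1))
            gate = sigmoid(self.edge_gate(Tensor(batch.edge_features)))
            messages = raw * gate
            agg = segment_sum(messages, batch.edge_index[:, 1], n_nodes)
        else:
            agg = Tensor(np.zeros((n_nodes, hidden)))
        return x + self.dropout(
            relu(self.update_mlp(concat([x, agg], axis=-1))))


class MPNNEncoder(Module):
    """Message-passing encoder producing one embedding per molecule.

    Raw one-hot node features are projected once to the hidden width; the
    configured number of residual message-passing rounds follows; a sum
    readout over node states and a linear map yield the graph embedding.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.input_proj = Linear(cfg.node_feature_dim, cfg.hidden_dim, rng)
        self.mp_layers = []
        for i in range(cfg.n_layers):
            layer = MPNNLayer(cfg.hidden_dim, cfg.edge_feature_dim,
                              cfg.dropout, rng)
            setattr(self, f"mp{i}", layer)
            self.mp_layers.append(layer)
        self.readout_lin = Linear(cfg.hidden_dim, cfg.out_dim, rng)

    def __call__(self, batch: GraphBatch) -> Tensor:
        x = relu(self.input_proj(Tensor(batch.node_features)))
        for layer in self.mp_layers:
            x = layer(x, batch)
        pooled = segment_sum(x, batch.node_graph, batch.n_graphs)
        return self.readout_lin(pooled)


class PoolMLPEncoder(Module):
    """Ablation encoder: sum-pool raw atom features, then an MLP.

    Replaces message passing entirely (`replace_gnn_with_pool_mlp`); bond
    information is discarded.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.mlp = MLP([cfg.node_feature_dim, cfg.hidden_dim, cfg.out_dim], rng)

    def __call__(self, batch: GraphBatch) -> Tensor:
        pooled = segment_sum(Tensor(batch.node_features), batch.node_graph,
                             batch.n_graphs)
        return self.mlp(pooled)


class ResNetDecoder(Module):
    """One residual block plus three projection layers → 500-bin spectrum."""

    def __init__(self, cfg: DecoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.input_dim
        self.blocks = []
        for b in range(cfg.n_blocks):
            lins = [Linear(d, cfg.block_hidden_dim, rng)]
            norms = [LayerNorm(cfg.block_hidden_dim)]
            for _ in range(cfg.block_hidden_layers - 1):
                lins.append(Linear(cfg.block_hidden_dim, cfg.block_hidden_dim, rng))
                norms.append(LayerNorm(cfg.block_hidden_dim))
            lins.append(Linear(cfg.block_hidden_dim, d, rng))
            drop = Dropout(cfg.block_dropout, rng)
            for i, (l, n) in enumerate(zip(lins[:-1], norms)):
                setattr(self, f"block{b}_lin{i}", l)
                setattr(self, f"block{b}_norm{i}", n)
            setattr(self, f"block{b}_out", lins[-1])
            setattr(self, f"block{b}_drop", drop)
            self.blocks.append((lins, norms, drop))
        self.head1 = Linear(d, cfg.head1_dim, rng)
        self.norm1 = LayerNorm(cfg.head1_dim)
        self.head2 = Linear(cfg.head1_dim, cfg.head2_dim, rng)
        self.norm2 = LayerNorm(cfg.head2_dim)
        self.head_out = Linear(cfg.head2_dim, cfg.output_dim, rng)

    def __call__(self, z: Tensor) -> Tensor:
        if z.shape[-1] != self.cfg.input_dim:
            raise ValueError(
                f"decoder expects input dim {self.cfg.input_dim}, "
                f"got {z.shape[-1]}")
        h = z
        for lins, norms, drop in self.blocks:
            inner = h
            for lin, norm in zip(lins[:-1], norms):
                inner = drop(relu(norm(lin(inner))))
            h = h + lins[-1](inner)          # residual connection
        h = relu(self.norm1(self.head1(h)))
        h = relu(self.norm2(self.head2(h)))
        return self.head_out(h)              # sign-unconstrained initial spectrum


class LinearDecoder(Module):
    """Ablation decoder (`replace_resnet_with_linear`): one linear map."""

    def __init__(self, cfg: DecoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.lin = Linear(cfg.input_dim, cfg.output_dim, rng)

    def __call__(self, z: Tensor) -> Tensor:
        return self.lin(z)


class ProjectionHead(Module):
    """500 → 256 → 128 MLP with L2 output normalization.

    Applied identically to predicted and target spectra: the input is
    first clamped nonnegative and L1-normalized (targets already are, so
    this makes the treatment of predictions genuinely identical and the
    embedding scale-invariant).  Trained only by the retrieval loss — the
    reconstruction loss never touches it.
    """

    def __init__(self, cfg: ProjectionConfig, rng: np.random.Generator,
                 eps: float = 1e-12):
        super().__init__()
        self.cfg = cfg
        self.eps = eps
        self.lin1 = Linear(cfg.input_dim, cfg.hidden_dim, rng)
        self.lin2 = Linear(cfg.hidden_dim, cfg.embedding_dim, rng)

    def __call__(self, s: Tensor) -> Tensor:
        from .autodiff import maximum

        s = maximum(s, 0.0)
        s = s / (s.sum(axis=-1, keepdims=True) + self.eps)
        h = self.lin2(relu(self.lin1(s)))
        norm = ((h * h).sum(axis=-1, keepdims=True) + self.eps) ** 0.5
        return h / norm
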