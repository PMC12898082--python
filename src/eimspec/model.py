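"""End-to-end spectrum predictor: encoder → decoder → refinement stack,
wrapped as a scikit-learn style estimator.

:class:`SpectrumPredictor` follows the fit/predict convention (parameters in
``__init__``, fitted state in trailing-underscore attributes, ``get_params``
/ ``set_params`` via :class:`sklearn.base.BaseEstimator`), so it composes
with sklearn model selection.  The heavy lifting lives in
:class:`SpectrumModel`, a pure network module.

Six architecture variants are supported: the full model (``baseline``) and
five single-component knockouts used by the ablation harness.
"""

from __future__ import annotations

import json
import logging

import numpy as np
from sklearn.base import BaseEstimator

from .autodiff import Tensor, maximum
from .chemgraph import MoleculeGraph, featurize
from .network import (DecoderConfig, EncoderConfig, GraphBatch, LinearDecoder,
                      MPNNEncoder, PoolMLPEncoder, ProjectionConfig,
                      ProjectionHead, ResNetDecoder)
from .nn import Adam, Module, ReduceLROnPlateau
from .objectives import (LossConfig, mean_cosine_similarity,
                         reconstruction_loss, retrieval_loss, total_loss)
from .refinement import (AttentionConfig, BidirectionalGate, CrossAttention,
                         NeutralLossTable, ProbabilisticMask, apply_mask,
                         bidirectional, cross_attend)
from .spectra_io import Spectrum

logger = logging.getLogger(__name__)

VARIANTS = (
    "baseline",
    "disable_attention",
    "replace_resnet_with_linear",
    "fix_alpha_forward",
    "replace_gnn_with_pool_mlp",
    "disable_mask",
)


class SpectrumModel(Module):
    """The assembled network for one ablation variant."""

    def __init__(self, variant: str, enc_cfg: EncoderConfig,
                 dec_cfg: DecoderConfig, attn_cfg: AttentionConfig,
                 proj_cfg: ProjectionConfig, loss_table: NeutralLossTable,
                 rng: np.random.Generator):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; "
                             f"expected one of {VARIANTS}")
        self.variant = variant
        self.encoder = (PoolMLPEncoder(enc_cfg, rng)
                        if variant == "replace_gnn_with_pool_mlp"
                        else MPNNEncoder(enc_cfg, rng))
        self.decoder = (LinearDecoder(dec_cfg, rng)
                        if variant == "replace_resnet_with_linear"
                        else ResNetDecoder(dec_cfg, rng))
        if variant != "disable_attention":
            self.attention = CrossAttention(attn_cfg, enc_cfg.out_dim, rng)
        else:
            self.attention = None
        self.gate = BidirectionalGate(dec_cfg.output_dim, rng)
        if variant != "disable_mask":
            self.mask = ProbabilisticMask(dec_cfg.output_dim, enc_cfg.out_dim,
                                          loss_table, rng)
        else:
            self.mask = None
        self.projection = ProjectionHead(proj_cfg, rng)

    def forward(self, batch: GraphBatch) -> tuple[Tensor, Tensor]:
        """Return (refined nonnegative spectra (B, D), graph embeddings)."""
        z = self.encoder(batch)
        s0 = self.decoder(z)
        s1 = cross_attend(z, s0, self.attention)
        s2 = bidirectional(s1, batch.masses, self.gate,
                           forward_only=(self.variant == "fix_alpha_forward"))
        return apply_mask(s2, z, batch.masses, self.mask), z

    def project(self, spectra: Tensor) -> Tensor:
        return self.projection(spectra)


def _as_graphs(X) -> list[MoleculeGraph]:
    return [x if isinstance(x, MoleculeGraph) else featurize(x) for x in X]


def _as_target_matrix(y, spectrum_dim: int) -> np.ndarray:
    if isinstance(y, np.ndarray):
        T = np.asarray(y, dtype=np.float64)
    else:
        T = np.stack([s.intensities if isinstance(s, Spectrum)
                      else np.asarray(s, dtype=np.float64) for s in y])
    if T.shape[1] != spectrum_dim:
        raise ValueError(f"targets must have {spectrum_dim} bins, "
                         f"got {T.shape[1]}")
    sums = T.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("all-zero target spectrum")
    return T / sums[:, None]


class SpectrumPredictor(BaseEstimator):
    """GNN-encoder / ResNet-decoder EI-MS spectrum predictor.

    Parameters mirror the model hyperparameter table (encoder 3×256 with
    dropout 0.25, one ResNet block of width 1024, heads 512/256, 4-head
    cross-attention at projection dim 256, projection head 500→256→128,
    τ = 0.04, λ = 0.5, Adam at lr 0.001 with plateau scheduling and early
    stopping with patience 50).

    ``fit(X, y, validation_data=...)`` trains on (SMILES, binned spectrum)
    pairs; targets are L1-normalized internally.  ``predict`` returns the
    refined nonnegative 500-bin spectra; ``embed_spectra`` maps any batch
    of spectra through the trained projection head.
    """

    def __init__(self, variant: str = "baseline", *,
                 encoder_layers: int = 3, hidden_dim: int = 256,
                 dropout: float = 0.25, embedding_dim: int = 256,
                 block_hidden_dim: int = 1024, block_dropout: float = 0.2,
                 head1_dim: int = 512, head2_dim: int = 256,
                 spectrum_dim: int = 500, n_heads: int = 4,
                 qkv_dim: int | None = None, proj_hidden_dim: int = 256,
                 proj_embedding_dim: int = 128, tau: float = 0.04,
                 lambda_ret: float = 0.5, epsilon: float = 1e-8,
                 batch_size: int = 256, lr: float = 0.001,
                 max_epochs: int = 500, early_stop_patience: int = 50,
                 scheduler_factor: float = 0.1, scheduler_patience: int = 5,
                 neutral_losses: NeutralLossTable | None = None,
                 eval_mass_window: float = 5.0, random_state: int = 0):
        self.variant = variant
        self.encoder_layers = encoder_layers
        self.hidden_dim = hidden_dim
        self.dropout = dropout
        self.embedding_dim = embedding_dim
        self.block_hidden_dim = block_hidden_dim
        self.block_dropout = block_dropout
        self.head1_dim = head1_dim
        self.head2_dim = head2_dim
        self.spectrum_dim = spectrum_dim
        self.n_heads = n_heads
        self.qkv_dim = qkv_dim
        self.proj_hidden_dim = proj_hidden_dim
        self.proj_embedding_dim = proj_embedding_dim
        self.tau = tau
        self.lambda_ret = lambda_ret
        self.epsilon = epsilon
        self.batch_size = batch_size
        self.lr = lr
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.scheduler_factor = scheduler_factor
        self.scheduler_patience = scheduler_patience
        self.neutral_losses = neutral_losses
        self.eval_mass_window = eval_mass_window
        self.random_state = random_state

    # -- config assembly ------------------------------------------------------
    def _configs(self):
        enc = EncoderConfig(n_layers=self.encoder_layers,
                            hidden_dim=self.hidden_dim, dropout=self.dropout,
                            out_dim=self.embedding_dim)
        dec = DecoderConfig(input_dim=self.embedding_dim,
                            block_hidden_dim=self.block_hidden_dim,
                            block_dropout=self.block_dropout,
                            head1_dim=self.head1_dim, head2_dim=self.head2_dim,
                            output_dim=self.spectrum_dim)
        attn = AttentionConfig(n_heads=self.n_heads,
                               qkv_dim=(self.qkv_dim if self.qkv_dim is not None
                                        else self.embedding_dim),
                               spectrum_dim=self.spectrum_dim)
        proj = ProjectionConfig(input_dim=self.spectrum_dim,
                                hidden_dim=self.proj_hidden_dim,
                                embedding_dim=self.proj_embedding_dim)
        loss = LossConfig(epsilon=self.epsilon, tau=self.tau,
                          lambda_ret=self.lambda_ret)
        table = (self.neutral_losses if self.neutral_losses is not None
                 else NeutralLossTable())
        return enc, dec, attn, proj, loss, table

    def _build_model(self, rng: np.random.Generator) -> SpectrumModel:
        enc, dec, attn, proj, _, table = self._configs()
        return SpectrumModel(self.variant, enc, dec, attn, proj, table, rng)

    # -- training -------------------------------------------------------------
    def _batch_losses(self, model: SpectrumModel, graphs, T: np.ndarray,
                      loss_cfg: LossConfig):
        batch = GraphBatch(graphs)
        pred, _ = model.forward(batch)
        target = Tensor(T)
        rec = reconstruction_loss(pred, target, cfg=loss_cfg)
        U = model.project(maximum(pred, 0.0))
        V = model.project(target)
        ret = retrieval_loss(U, V, cfg=loss_cfg)
        return total_loss(rec, ret, loss_cfg), rec, ret, pred

    def fit(self, X, y, validation_data=None):
        """Train on molecule/spectrum pairs.

        ``validation_data=(X_val, y_val)`` drives the plateau scheduler,
        early stopping, and the per-epoch retrieval metrics; without it the
        model trains for ``max_epochs`` on the training loss alone.
        """
        graphs = _as_graphs(X)
        T = _as_target_matrix(y, self.spectrum_dim)
        if len(graphs) != T.shape[0]:
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.random_state)
        _, _, _, _, loss_cfg, _ = self._configs()
        model = self._build_model(rng)
        optimizer = Adam(model.parameters(), lr=self.lr)
        scheduler = ReduceLROnPlateau(optimizer,
                                      factor=self.scheduler_factor,
                                      patience=self.scheduler_patience)
        val = None
        if validation_data is not None:
            val_graphs = _as_graphs(validation_data[0])
            val_T = _as_target_matrix(validation_data[1], self.spectrum_dim)
            val = (val_graphs, val_T)

        n = len(graphs)
        history: list[dict] = []
        best_loss, best_state, best_epoch = np.inf, None, 0
        bad_epochs = 0
        for epoch in range(1, self.max_epochs + 1):
            model.set_training(True)
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                if idx.size < 2:      # retrieval loss needs >= 2 candidates
                    continue
                model.zero_grad()
                loss, rec, ret, _ = self._batch_losses(
                    model, [graphs[i] for i in idx], T[idx], loss_cfg)
                value = float(loss.data)
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={value}")
                loss.backward()
                optimizer.step()
                epoch_losses.append(value)
            record = {"epoch": epoch, "lr": optimizer.lr,
                      "train_loss": float(np.mean(epoch_losses))}
            monitored = record["train_loss"]
            if val is not None:
                record.update(self._evaluate(model, val[0], val[1], loss_cfg))
                monitored = record["test_loss"]
            history.append(record)
            scheduler.step(monitored)
            if monitored < best_loss - 1e-12:
                best_loss, best_epoch = monitored, epoch
                best_state = model.state_dict()
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= self.early_stop_patience:
                    logger.info("early stopping at epoch %d (best %d)",
                                epoch, best_epoch)
                    break
        if best_state is not None:
            model.load_state_dict(best_state)
        model.set_training(False)
        self.model_ = model
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.n_epochs_ = len(history)
        self.loss_config_ = loss_cfg
        return self

    def _evaluate(self, model: SpectrumModel, graphs, T: np.ndarray,
                  loss_cfg: LossConfig, eval_batch: int = 512) -> dict:
        from .matching import LibraryIndex, query_topk, recall_at_k

        model.set_training(False)
        preds, zs = [], []
        for start in range(0, len(graphs), eval_batch):
            chunk = graphs[start:start + eval_batch]
            pred, z = model.forward(GraphBatch(chunk))
            preds.append(pred.data)
            zs.append(z.data)
        P = np.concatenate(preds)
        rec = reconstruction_loss(Tensor(P), Tensor(T), cfg=loss_cfg)
        U = model.project(Tensor(np.maximum(P, 0.0))).data
        V = model.project(Tensor(T)).data
        ret = retrieval_loss(Tensor(U), Tensor(V), cfg=loss_cfg)
        test_loss = float(rec.data) + loss_cfg.lambda_ret * float(ret.data)

        index = LibraryIndex()
        masses = [g.mono_mass for g in graphs]
        for g, u in zip(graphs, U):
            index.add(g.structure_key, g.mono_mass, u, provenance="predicted")
        results = [
            query_topk(v, m, index, k=10, mass_window=self.eval_mass_window,
                       query_key=g.structure_key)
            for v, m, g in zip(V, masses, graphs)
        ]
        out = {"test_loss": test_loss,
               "test_rec_loss": float(rec.data),
               "test_ret_loss": float(ret.data),
               "test_cosine": mean_cosine_similarity(P, T)}
        for k in (1, 5, 10):
            out[f"recall@{k}"] = recall_at_k(results, k)
        model.set_training(True)
        return out

    # -- inference ------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("SpectrumPredictor is not fitted")

    def predict(self, X, batch_size: int = 512) -> np.ndarray:
        """Refined nonnegative spectra, one 500-bin row per molecule."""
        self._check_fitted()
        graphs = _as_graphs(X)
        self.model_.set_training(False)
        out = []
        for start in range(0, len(graphs), batch_size):
            pred, _ = self.model_.forward(
                GraphBatch(graphs[start:start + batch_size]))
            out.append(pred.data)
        return np.concatenate(out)

    def encode(self, X, batch_size: int = 512) -> np.ndarray:
        """Graph-level molecular embeddings."""
        self._check_fitted()
        graphs = _as_graphs(X)
        self.model_.set_training(False)
        out = []
        for start in range(0, len(graphs), batch_size):
            _, z = self.model_.forward(
                GraphBatch(graphs[start:start + batch_size]))
            out.append(z.data)
        return np.concatenate(out)

    def embed_spectra(self, S) -> np.ndarray:
        """Unit-norm retrieval embeddings of spectra (predicted or true)."""
        self._check_fitted()
        S = np.asarray(S, dtype=np.float64)
        self.model_.set_training(False)
        return self.model_.project(Tensor(S)).data

    def score(self, X, y) -> float:
        """Mean cosine similarity between predictions and targets."""
        P = self.predict(X)
        T = _as_target_matrix(y, self.spectrum_dim)
        return mean_cosine_similarity(P, T)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: parameters plus embedded config."""
        self._check_fitted()
        state = self.model_.state_dict()
        params = self.get_params()
        params["neutral_losses"] = (
            list(params["neutral_losses"].entries)
            if params["neutral_losses"] is not None else None)
        payload = {f"param::{k}": v for k, v in state.items()}
        payload["__config__"] = np.frombuffer(
            json.dumps(params).encode(), dtype=np.uint8)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "SpectrumPredictor":
        with np.load(path) as data:
            config = json.loads(bytes(data["__config__"].tobytes()).decode())
            state = {k[len("param::"):]: data[k] for k in data.files
                     if k.startswith("param::")}
        if config.get("neutral_losses") is not None:
            config["neutral_losses"] = NeutralLossTable(
                entries=tuple((str(l), int(m))
                              for l, m in config["neutral_losses"]))
        est = cls(**config)
        model = est._build_model(np.random.default_rng(est.random_state))
        model.load_state_dict(state)
        model.set_training(False)
        est.model_ = model
        est.history_ = []
        est.best_epoch_ = 0
        est.n_epochs_ = 0
        return est


class LibraryMatcher(BaseEstimator):
    """Thin retrieval front-end over a fitted :class:`SpectrumPredictor`.

    ``fit`` builds the augmented library index (reference spectra plus, via
    the predictor, predicted spectra); ``query`` runs mass-filtered top-k
    retrieval.
    """

    def __init__(self, predictor: SpectrumPredictor,
                 mass_window: float = 5.0):
        self.predictor = predictor
        self.mass_window = mass_window

    def fit(self, spectra, keys, masses, provenance: str = "reference"):
        from .matching import LibraryIndex

        if not hasattr(self, "index_"):
            self.index_ = LibraryIndex()
        embeddings = self.predictor.embed_spectra(spectra)
        for key, mass, e in zip(keys, masses, embeddings):
            self.index_.add(key, mass, e, provenance=provenance)
        return self

    def add_predictions(self, smiles_list):
        """Predict spectra for molecules and add them to the index."""
        from .chemgraph import featurize

        graphs = [featurize(s) for s in smiles_list]
        P = self.predictor.predict(graphs)
        return self.fit(np.maximum(P, 0.0),
                        [g.structure_key for g in graphs],
                        [g.mono_mass for g in graphs],
                        provenance="predicted")

    def query(self, spectra, keys, masses, k: int = 10):
        from .matching import query_topk

        embeddings = self.predictor.embed_spectra(spectra)
        return [query_topk(e, m, self.index_, k=k,
                           mass_window=self.mass_window, query_key=key)
                for e, m, key in zip(embeddings, masses, keys)]
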