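# eimspec

Electron-ionization mass spectrometry (EI-MS, 70 eV) produces highly
reproducible fragmentation spectra, and compounds are identified by
searching those spectra against reference libraries.  Library coverage is
the bottleneck: a molecule without a reference spectrum is easily
misidentified.  `eimspec` addresses this by *predicting* EI-MS spectra
directly from molecular structure, so predicted spectra can augment a
library, and by evaluating predictions the way libraries are used — by
retrieval.

It is aimed at mass-spectrometry and cheminformatics practitioners who
want a compact, fully inspectable structure-to-spectrum model with an
honest retrieval-based evaluation, and at method developers who want a
clean reference implementation of the hybrid architecture.

## The model

Input is an isomeric SMILES string.  A message-passing graph neural
network encodes the hydrogen-suppressed molecular graph,

x_i^(k) = γ( x_i^(k−1), ⊕_{j∈N(i)} φ(x_i^(k−1), x_j^(k−1), e_{j,i}) ),  ⊕ = Σ,

into a 256-d embedding z.  A shallow ResNet decoder (one residual block,
projections 256→512→256→500) proposes an initial spectrum on the integer
m/z grid (index k ↔ m/z k+1, up to 500 Da).  A refinement stack then
applies:

* **cross-attention** — z queries the 500 per-bin tokens of the initial
  spectrum (4 heads, dim 256), residual output;
* **bidirectional prediction** — forward head f and reverse head g with
  r_k = g_{m*−k} below the molecular-ion bin m*, blended by a learned
  per-bin gate σ(α); neutral losses become forward structure in r;
* **probabilistic mask** — σ(position)·scale(k/M) plus unnormalized
  Gaussian boosts at the bins of expected neutral-loss peaks (M−18 for
  water, M−17 for ammonia, ...), amplitudes and widths predicted from z.

Training minimizes L = L_rec + λ·L_ret (λ = 0.5): a mass-weighted
square-root reconstruction loss against L1-normalized targets, normalized
by the true spectrum only, plus an InfoNCE-style retrieval loss (τ = 0.04)
over 128-d unit-norm projection-head embeddings of predicted and true
spectra.  Evaluation is mass-filtered (±5 Da) cosine retrieval from an
augmented library: Recall@k is the fraction of query molecules whose
predicted spectrum ranks in the top k.

Everything runs on a compact NumPy reverse-mode autodiff engine
(`eimspec.autodiff`) — no GPU or deep-learning framework required; all
operator gradients are finite-difference tested.

Commercial spectral libraries cannot be redistributed, so the package
ships a synthetic molecule–spectrum generator (`eimspec.synthfrag`): random
valence-legal molecules in structural families with a rule-based
fragmentation simulator (bond cleavages, heteroatom-biased intensities,
molecular ion, SMARTS-gated neutral losses, log-normal noise).  See
`docs/methods.md` for what this does and does not demonstrate.

## Worked example

```python
import numpy as np
from eimspec import (SimConfig, TrainConfig, generate_pairs, train,
                     library_matching_evaluation, split_dataset)

smiles, spectra = generate_pairs(SimConfig(n_molecules=400, seed=3))
cfg = TrainConfig(run_seed=0, max_epochs=10, batch_size=64)
desk = dict(hidden_dim=64, embedding_dim=64, qkv_dim=64,
            block_hidden_dim=128, head1_dim=128, head2_dim=64,
            proj_hidden_dim=256, proj_embedding_dim=128, dropout=0.0)

est, history = train(smiles, spectra, variant="baseline",
                     train_cfg=cfg, model_params=desk)
print(history[["epoch", "train_loss", "test_loss",
               "test_cosine", "recall@10"]].iloc[[0, 4, 9]])

pairs = list(zip(smiles, spectra))
train_pairs, test_pairs = split_dataset(pairs, cfg)
rep = library_matching_evaluation(est, train_pairs, test_pairs)
print({k: round(v, 3) for k, v in rep.items()
       if isinstance(v, float)})
```

prints (exactly, for these seeds):

```
   epoch  train_loss  test_loss  test_cosine  recall@10
0      1    2.064895   2.016105     0.459343        1.0
4      5    0.261818   0.730023     0.469851        1.0
9     10    0.093235   0.494981     0.508290        1.0
{'recall@1': 0.29, 'random_recall@1': 0.079, 'recall@5': 0.913,
 'random_recall@5': 0.397, 'recall@10': 0.986, 'random_recall@10': 0.748,
 'raw_cosine_mean': 0.508, 'raw_fraction_above_0.6': 0.275,
 'embedding_cosine_mean': 0.768}
```

Reading this: the composite loss falls as the model learns the
structure→spectrum map; `recall@10` in the history is the in-training
retrieval diagnostic (true-spectrum queries against the predicted test-set
library), which saturates at this tiny scale.  The final dictionary is
the stricter augmented-library task — reference spectra of all training
molecules plus predicted spectra of the held-out molecules, ±5 Da mass
filter — compared against the recall a random ranker would get on the
same candidate sets: the model retrieves the right molecule in the top 5
for 91% of held-out queries, against a 40% random floor.

A command-line interface covers the same flow
(`eimspec simulate | train | match | profile`); see `--help` on each.

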