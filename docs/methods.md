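# Methods

`eimspec` predicts electron-ionization (EI, 70 eV) mass spectra directly
from molecular structure and evaluates the predictions the way spectral
libraries are actually used: by retrieval.  This note records the model,
its assumptions, the synthetic data it is tested on, and the numerical and
design choices that were genuinely open.

## Model

**Input representation.**  The only input is an isomeric SMILES string.
Molecules are hydrogen-suppressed attributed graphs: heavy atoms are nodes,
bonds are pairs of directed edges with identical features.  Atom features
are one-hot blocks — atomic number (61 slots: 60 common elements plus a
fallback), degree (0–6), explicit valence (0–6), formal charge
({−2,−1,0,+1,+2}), a raw radical-electron count, hybridization (6
categories), an aromaticity flag, and attached-hydrogen count (0–5) — for a
node width of 94.  Bond features are bond type
(single/double/triple/aromatic), conjugation, ring membership, and stereo
configuration (width 10).  Every categorical block clamps
out-of-vocabulary values to its last slot, so each block always sums to 1.
Three-dimensional coordinates are deliberately not used: the same SMILES
can correspond to different measured geometries, and nominal-mass EI
fragmentation is modeled here as a function of the bond graph.

**Encoder.**  A message-passing neural network,

x_i^(k) = γ( x_i^(k−1), Σ_{j∈N(i)} φ(x_i^(k−1), x_j^(k−1), e_{j,i}) ),

with sum aggregation, three rounds, hidden width 256 and dropout 0.25.
Raw one-hot features are projected once to the hidden width; each round's
φ is an MLP on the concatenated endpoint states, gated elementwise by a
linear network on the bond features (a diagonal per-edge transformation of
the neighbor state; a full per-edge weight matrix at width 256 is
prohibitively expensive on CPU and adds nothing at this width); γ adds the
MLP of (state, aggregated message) residually onto the state — without the
skip connections the encoder is measurably optimization-bound at small
step budgets.  The readout is a sum over node states followed by a linear
map to a 256-d graph embedding; summation (rather than mean) preserves
molecule size, which correlates with fragment counts.

**Decoder.**  A shallow residual network: one residual block
(256 → 1024 → 256, dropout 0.2) whose input is added to its output,
followed by projections 256 → 512 → 256 → 500 with layer normalization
between linear layers (none after the final layer).  Output index k is the
intensity at m/z k+1; the initial prediction is sign-unconstrained.

**Refinement.**  Three stages, each independently ablatable:

1. *Cross-attention.*  Each of the 500 bins becomes a token — the scalar
   intensity modulates a learned per-bin positional embedding — and the
   graph embedding, projected to the key/value dimension (256, 4 heads),
   attends over all tokens.  The attended context is projected back to
   500-d and added residually.
2. *Bidirectional prediction.*  A forward head and a reverse head (two
   separate 500 → 500 linear maps) produce f and g; the reverse spectrum is
   r_k = g_{m*−k} for k ≤ m* (m* = round(M)−1, the molecular-ion bin) and 0
   above it — fragments at m/z M−x encode neutral losses of x, and no mass
   shift is applied, so nothing is predicted above the molecular ion by the
   reverse path.  A learned per-bin gate α blends them:
   o = σ(α)⊙f + (1−σ(α))⊙r.  α is per-bin rather than scalar so the model
   can trust the reverse path only in the mass region where neutral-loss
   structure is strong.
3. *Probabilistic mask.*  mask_k = σ(pos_k)·scale(k/M) + Σ_l A_l·
   exp(−(k−c_l)²/2w_l²), applied multiplicatively to the clamped spectrum.
   The position term learns which mass regions carry peaks in general; the
   scale term is a small MLP on the *relative* position k/M (softplus
   output), letting molecular weight concentrate or spread intensity; the
   Gaussian boosts sit at c_l = (M−loss_l)−1, the bin of each expected
   neutral-loss peak, with amplitude (sigmoid, in (0,1)) and width
   (softplus + 1, ≥ 1) predicted from the graph embedding.  The Gaussians
   are deliberately unnormalized so a wide, uncertain loss does not
   contribute the same total mass as a sharp one.  The multiplicative base
   acts as a probability; the boosts are additive because they *raise*
   neighboring intensities.  The default loss table (H2O 18, NH3 17, CH3
   15, CO 28, CHO 29, OCH3 31, CO2 44, C2H5 29, Cl 35, NO2 46) is an
   editable YAML config.

**Objectives.**  Targets are L1-normalized (discrete distributions over
fragment mass).  The reconstruction loss is a mass-weighted squared
difference of square-root intensities, normalized per sample by the true
spectrum only (Σ_k m_k(√(t_k+ε)−√(p̃_k+ε))² / Σ_k(m_k√(t_k+ε))², with
p̃ = max(p,0), m_k = k+1, ε = 10⁻⁸).  Normalizing by the target alone keeps
the prediction's own magnitude from diluting its error; ε guards the square
root at zero.  The retrieval loss is an InfoNCE-style temperature-scaled
cross-entropy (τ = 0.04) over the batch similarity matrix of 128-d
unit-norm projection-head embeddings of predicted and true spectra, with
diagonal positives.  The total loss is rec + λ·ret with λ = 0.5.  The
projection head (500 → 256 → 128, L2-normalized output) receives gradient
only from the retrieval loss by construction.  A cosine similarity between
raw predicted and true spectra is logged for the held-out set as a
diagnostic only.

**Optimization.**  Adam at lr 0.001, batch 256, up to 500 epochs, early
stopping with patience 50 on the held-out loss, and learning-rate reduction
on plateau (factor 0.1, patience 5).  There is no third validation split —
the held-out set drives both early stopping and the reported metrics, which
is optimistically biased and is accepted here as the protocol being
studied.  Splitting is 80/20 by a dedicated split seed (42), reused across
run seeds; shuffling, initialization and dropout vary with the run seed.
Initialization is uniform fan-in.  Standard deviations across seeds use the
sample convention (ddof = 1).

**Numerical backend.**  All neural components run on a compact
reverse-mode automatic-differentiation engine over float64 NumPy arrays
(`eimspec.autodiff`), with sparse graph batching via gather/segment-sum
primitives.  Every operator's gradient is verified against central finite
differences in the test suite.  Computation is deterministic given the run
seed; dropout is active only in training mode.

## Library matching

Evaluation mirrors library practice: the library holds reference (true)
spectra of the training molecules plus the model's *predicted* spectra for
held-out molecules; each held-out molecule's true spectrum is a query, and
only its predicted entry counts as a hit (identity = canonical isomeric
SMILES).  Similarity is the dot product of unit embeddings (= cosine);
candidates are restricted to ±5 Da of the query's integer-rounded
monoisotopic mass; ties break by insertion order.  Recall@k is reported
overall and in three mass bins — small (1–175 Da), medium (176–324 Da),
large (325–500 Da) — alongside the recall of a random ranker over the same
filtered candidate sets (per query, min(k, n_c)/n_c), which is the floor
any learned ranking must clear.

## Synthetic data

Commercial EI libraries cannot ship with a package, so training and
evaluation run on a synthetic generator (`eimspec.synthfrag`) designed to
emulate the *shape* of the problem, not its chemistry:

* molecules: random valence-legal acyclic/monocyclic structures over
  C/N/O/F/S/Cl, 3–20 heavy atoms, monoisotopic mass ≤ 500 Da, generated in
  structural families (one random base plus up to three single-edit
  analogs) the way real libraries contain homologous series — without
  families, nearest-neighbour structure carries almost no spectral
  information and retrieval is vacuous.  Half of the edits are
  *relocations* of a terminal atom to an element-matched anchor whose
  degree compensates the move: the result is a positional isomer with an
  exactly identical multiset of per-atom features but different fragment
  masses, i.e. a molecule pair only connectivity can tell apart;
* spectra: every acyclic single bond is cleaved once (deeper recursive
  cleavage behind a flag); each fragment peaks at its integer mass
  (hydrogens travel with their heavy atom, and the fragment gains one
  hydrogen when the complementary fragment's cut atom can donate one — a
  simplified rearrangement rule that ties peak positions to the local
  environment of the cut); cleavage weight is Boltzmann, exp(score/T) with
  T = 1, where the score rewards heteroatom-adjacent cuts and cuts at
  branched centres (carbocation stability); a molecular-ion peak is always
  present; applicable neutral losses (detected by SMARTS, e.g. hydroxyl →
  H2O) add peaks at M − loss; each peak intensity is perturbed by
  multiplicative log-normal noise (σ = 0.1); the spectrum is binned and
  L1-normalized.

The map is deterministic per (molecule, seed) and verifiably informative: a
fingerprint nearest-neighbour baseline beats the mean-spectrum baseline on
held-out molecules.  What passing tests on this generator shows is that the
architecture, objectives, and retrieval pipeline can learn a
structure→spectrum dependence end-to-end and beat chance retrieval by a
wide margin.  What it does not show: chemical realism (no rearrangements,
no isotope clusters, no charge-site chemistry), NIST-scale difficulty, or
the recall levels attainable with commercial reference libraries two
orders of magnitude larger.

## Problem sizes used in the shipped experiments

The acceptance script and end-to-end tests train at desk scale, chosen
for a single CPU: 2,000 synthetic molecules (80/20 split, split seed 42),
30 epochs of the baseline variant, with reduced encoder/decoder widths
(hidden 64, embedding 64, attention dim 64, residual block 128) and batch
size 128 — the dataset is two orders of magnitude smaller than a
commercial library, so the batch is scaled down with it to keep a
meaningful number of optimizer steps (12/epoch) inside the fixed epoch
budget while retaining enough in-batch negatives for the contrastive
retrieval loss.  The projection head keeps its full-scale size
(500 → 256 → 128): it is computationally cheap and retrieval
discrimination lives there.  Encoder dropout is 0 in the desk runs — at
width 64 with a few hundred optimizer steps the default 0.25 is a large
handicap that the dropout-free pooled ablation encoder would not share.
The ablation harness (baseline + five knockouts × 3 seeds) runs on 800
molecules for 12 epochs and reports Recall@k from the augmented-library
task, because the in-training retrieval diagnostic saturates on small
test libraries.  Config-dataclass *defaults* remain the full-scale values (batch 256, widths 256/1024/4-head/128-d, dropout 0.25,
τ = 0.04, λ = 0.5); the desk-scale overrides are explicit arguments at
the call sites.

A caveat the harness makes visible: with ±5 Da candidate sets of only
~30–60 entries, Recall@10 has limited resolution for ranking encoder
variants — the pooled-features encoder trails the message-passing encoder
on average, but within seed noise.  A full-scale regime (a 200k-entry
library, thousands of candidates per window) is far from this saturation
point, which is where the encoder choice becomes decisive.

## Known limitations

* Nominal (integer) mass only; no isotope fine structure above 500 Da.
* Bond-graph features only; stereochemistry enters through bond stereo
  flags, not geometry.
* The held-out set is reused for early stopping and reporting (see above).
* The ablation directional check (pooled-MLP encoder worse than the
  message-passing encoder) is a statement about means over a few seeds at
  desk scale, not a significance test.
* The MSP dialect is the plain Name/MW/Num Peaks record form; exotic
  metadata fields round-trip as opaque strings.
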