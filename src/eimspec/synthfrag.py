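"""Synthetic molecule–spectrum pairs for training and evaluation at desk
scale.

Two parts:

* a random generator of small, valence-legal, acyclic or monocyclic
  molecules over a configurable atom alphabet (C, N, O, F, S, Cl by
  default, 3–20 heavy atoms), and
* a rule-based fragmentation simulator that turns a molecule into an
  electron-ionization-like spectrum: every acyclic single bond is cleaved,
  each fragment contributes a peak at its integer mass (hydrogens travel
  with their heavy atom), cleavages adjacent to heteroatoms are rewarded
  through a Boltzmann-style weight, a molecular-ion peak is always present,
  and applicable neutral losses (water from hydroxyls, ammonia from amines,
  ...) add peaks at M − loss.  Multiplicative log-normal noise is applied
  per peak, then the spectrum is binned and L1-normalized.

The structure → spectrum map is deterministic per (molecule, seed) and
carries enough learnable signal that a graph model trained on it beats
trivial baselines; it makes no claim of chemical accuracy.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chemgraph import canonical_dedup, mol_from_smiles
from .refinement import NeutralLossTable
from .spectra_io import Spectrum, bin_peaks, l1_normalize

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2, "Cl": 1, "Br": 1, "P": 3}

_MONO_MASS = {
    "H": 1.007825, "C": 12.0, "N": 14.003074, "O": 15.994915,
    "F": 18.998403, "S": 31.972071, "Cl": 34.968853, "Br": 78.918338,
    "P": 30.973762,
}

# which substructure makes each default neutral loss applicable
LOSS_SMARTS: dict[str, tuple[str, ...]] = {
    "H2O": ("[OX2H]",),
    "NH3": ("[NX3;H2]", "[NX4;H3]"),
    "CH3": ("[CX4H3]",),
    "CO": ("[CX3]=[OX1]",),
    "CHO": ("[CX3H1]=[OX1]",),
    "OCH3": ("[OX2][CH3]",),
    "CO2": ("[CX3](=[OX1])[OX2]",),
    "C2H5": ("[CX4H2][CX4H3]",),
    "Cl": ("[Cl]",),
    "NO2": ("[NX3](=O)=O", "[NX3+](=O)[O-]"),
}


@dataclass
class SimConfig:
    """Knobs of the synthetic data generator (all serialized with outputs)."""

    n_molecules: int = 2000
    atom_alphabet: tuple[str, ...] = ("C", "N", "O", "F", "S", "Cl")
    atom_weights: tuple[float, ...] = (0.60, 0.12, 0.12, 0.06, 0.05, 0.05)
    size_range: tuple[int, int] = (3, 20)
    family_size: int = 4           # one random base plus single-edit analogs
    fragmentation_depth: int = 1
    loss_table: NeutralLossTable = field(default_factory=NeutralLossTable)
    temperature: float = 1.0       # Boltzmann scale of the cleavage scores
    noise_sd: float = 0.1          # sd of the per-peak log-normal noise
    max_mass: float = 500.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_molecules": self.n_molecules,
            "atom_alphabet": list(self.atom_alphabet),
            "atom_weights": list(self.atom_weights),
            "size_range": list(self.size_range),
            "fragmentation_depth": self.fragmentation_depth,
            "neutral_losses": [list(e) for e in self.loss_table.entries],
            "temperature": self.temperature,
            "noise_sd": self.noise_sd,
            "max_mass": self.max_mass,
            "seed": self.seed,
        }


# -- molecule generation ------------------------------------------------------

def _random_molecule(rng: np.random.Generator, cfg: SimConfig) -> str | None:
    n = int(rng.integers(cfg.size_range[0], cfg.size_range[1] + 1))
    symbols = list(rng.choice(cfg.atom_alphabet, size=n,
                              p=np.asarray(cfg.atom_weights) /
                              np.sum(cfg.atom_weights)))
    # univalent atoms cannot seed a chain
    if _MAX_VALENCE[symbols[0]] < 2:
        symbols[0] = "C"
    mol = Chem.RWMol()
    free = []
    mol.AddAtom(Chem.Atom(symbols[0]))
    free.append(_MAX_VALENCE[symbols[0]])
    for sym in symbols[1:]:
        candidates = [i for i, f in enumerate(free) if f >= 1]
        if not candidates:
            break
        anchor = int(rng.choice(candidates))
        new_idx = mol.AddAtom(Chem.Atom(sym))
        order = Chem.BondType.SINGLE
        used = 1
        if (rng.random() < 0.15 and free[anchor] >= 2
                and _MAX_VALENCE[sym] >= 2):
            order = Chem.BondType.DOUBLE
            used = 2
        mol.AddBond(anchor, new_idx, order)
        free[anchor] -= used
        free.append(_MAX_VALENCE[sym] - used)
    # optional single ring closure (monocyclic at most)
    if rng.random() < 0.3:
        open_atoms = [i for i, f in enumerate(free) if f >= 1]
        rng.shuffle(open_atoms)
        done = False
        for a in open_atoms:
            if done:
                break
            for b in open_atoms:
                if b <= a or mol.GetBondBetweenAtoms(a, b) is not None:
                    continue
                path = Chem.GetShortestPath(mol, a, b)
                if len(path) >= 3:            # ring size >= 3
                    mol.AddBond(a, b, Chem.BondType.SINGLE)
                    done = True
                    break
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    smiles = Chem.MolToSmiles(mol)
    if _exact_mass(Chem.MolFromSmiles(smiles)) > cfg.max_mass:
        return None
    return smiles


def _mutate(smiles: str, rng: np.random.Generator,
            cfg: SimConfig) -> str | None:
    """One structural edit: swap an atom's element, append a substituent,
    or relocate a terminal atom.

    Produces close structural analogs of the base molecule, so the dataset
    contains families of related structures the way real spectral libraries
    contain homologous series.  The relocation edit yields positional
    isomers — identical composition and mass, different connectivity and
    hence different fragment masses — which is exactly the regime where
    bond topology, not atom composition, determines the spectrum.
    """
    base = Chem.MolFromSmiles(smiles)
    if base is None:
        return None
    mol = Chem.RWMol(base)
    choice = rng.random()
    if choice < 0.5:
        # relocate a terminal atom to an element-matched anchor whose degree
        # is exactly deg(parent) - 1: the move swaps the two degrees, so the
        # multiset of per-atom features is exactly preserved -> a positional
        # isomer indistinguishable by pooled features but with different
        # fragment masses
        leaves = [a.GetIdx() for a in mol.GetAtoms()
                  if a.GetDegree() == 1 and
                  a.GetBonds()[0].GetBondType() == Chem.BondType.SINGLE]
        rng.shuffle(leaves)
        for leaf in leaves:
            parent = mol.GetAtomWithIdx(int(leaf)).GetNeighbors()[0]
            anchors = [
                a.GetIdx() for a in mol.GetAtoms()
                if a.GetIdx() not in (int(leaf), parent.GetIdx())
                and a.GetSymbol() == parent.GetSymbol()
                and a.GetDegree() == parent.GetDegree() - 1
                and a.GetImplicitValence() >= 1
                and not a.GetIsAromatic()
            ]
            if anchors:
                anchor = int(anchors[int(rng.integers(len(anchors)))])
                mol.RemoveBond(int(leaf), parent.GetIdx())
                mol.AddBond(int(leaf), anchor, Chem.BondType.SINGLE)
                break
        else:
            return None
    elif choice < 0.75:
        # element swap respecting the atom's current explicit valence
        idx = int(rng.integers(mol.GetNumAtoms()))
        atom = mol.GetAtomWithIdx(idx)
        valence = atom.GetExplicitValence()
        options = [s for s in cfg.atom_alphabet
                   if _MAX_VALENCE[s] >= max(valence, 1)
                   and s != atom.GetSymbol() and not atom.GetIsAromatic()]
        if not options:
            return None
        atom.SetAtomicNum(Chem.Atom(options[int(rng.integers(len(options)))])
                          .GetAtomicNum())
    else:
        # append a small substituent at an atom with a free valence
        open_atoms = [a.GetIdx() for a in mol.GetAtoms()
                      if a.GetImplicitValence() >= 1]
        if not open_atoms:
            return None
        anchor = int(open_atoms[int(rng.integers(len(open_atoms)))])
        sym = str(rng.choice(cfg.atom_alphabet))
        new_idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(anchor, new_idx, Chem.BondType.SINGLE)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    out = Chem.MolToSmiles(mol)
    if _exact_mass(Chem.MolFromSmiles(out)) > cfg.max_mass:
        return None
    return out


def generate_molecules(cfg: SimConfig) -> list[str]:
    """Random valence-legal molecules in structural families, canonicalized
    and deduplicated.

    Each family is one random base molecule plus up to ``family_size - 1``
    single-edit analogs.  Deterministic per seed; the returned count can
    fall slightly short of ``n_molecules`` because duplicates are dropped.
    """
    rng = np.random.default_rng(cfg.seed)
    raw: list[str] = []
    attempts = 0
    while len(raw) < cfg.n_molecules and attempts < 20 * cfg.n_molecules:
        attempts += 1
        smi = _random_molecule(rng, cfg)
        if smi is None:
            continue
        raw.append(smi)
        for _ in range(cfg.family_size - 1):
            if len(raw) >= cfg.n_molecules:
                break
            analog = _mutate(smi, rng, cfg)
            if analog is not None:
                raw.append(analog)
    return canonical_dedup(raw)[: cfg.n_molecules]


# -- fragmentation simulation -------------------------------------------------

def _exact_mass(mol: Chem.Mol) -> float:
    from rdkit.Chem.Descriptors import ExactMolWt

    return float(ExactMolWt(mol))


def _atom_mass_with_h(atom: Chem.Atom) -> float:
    return (_MONO_MASS[atom.GetSymbol()]
            + atom.GetTotalNumHs() * _MONO_MASS["H"])


def _components(n_atoms: int, bonds: list[tuple[int, int]],
                atoms_subset: set[int]) -> list[set[int]]:
    """Connected components of the subset under the given bonds."""
    adj: dict[int, list[int]] = {a: [] for a in atoms_subset}
    for i, j in bonds:
        if i in atoms_subset and j in atoms_subset:
            adj[i].append(j)
            adj[j].append(i)
    seen: set[int] = set()
    comps = []
    for start in sorted(atoms_subset):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            a = stack.pop()
            if a in comp:
                continue
            comp.add(a)
            stack.extend(adj[a])
        seen |= comp
        comps.append(comp)
    return comps


def enumerate_fragments(
        mol: Chem.Mol, depth: int = 1
) -> list[tuple[frozenset, float, bool]]:
    """All fragments reachable by up to ``depth`` acyclic single-bond cuts.

    Returns (atom-index set, weight, hydrogen-donor flag) triples; the
    weight rewards cleavage next to heteroatoms and at branched centres and
    shrinks geometrically with cut depth; the flag records whether the cut
    atom on the *other* side carries a hydrogen it can transfer.
    """
    cleavable = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
    ]
    all_bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]

    def cleavage_score(i: int, j: int) -> float:
        # heteroatom-adjacent cuts are favoured, and so are cuts at branched
        # centres (carbocation stability: tertiary > secondary > primary)
        hetero = sum(mol.GetAtomWithIdx(a).GetSymbol() != "C"
                     for a in (i, j))
        branching = sum(mol.GetAtomWithIdx(a).GetDegree() - 1
                        for a in (i, j)) / 4.0
        return float(hetero + branching)

    out: list[tuple[frozenset, float, bool]] = []

    def recurse(atoms: frozenset, level: int, weight: float):
        if level > depth:
            return
        for (i, j) in cleavable:
            if i not in atoms or j not in atoms:
                continue
            remaining = [b for b in all_bonds if b != (i, j)]
            for comp in _components(mol.GetNumAtoms(), remaining, set(atoms)):
                w = weight * np.exp(cleavage_score(i, j)) * 0.5 ** (level - 1)
                frag = frozenset(comp)
                # the cut atom left on the other side; it donates an H to
                # this fragment if it carries one
                other = j if i in frag else i
                donor = mol.GetAtomWithIdx(other).GetTotalNumHs() >= 1
                out.append((frag, w, donor))
                if level < depth:
                    recurse(frag, level + 1, w * 0.5)

    recurse(frozenset(range(mol.GetNumAtoms())), 1, 1.0)
    return out


def _applicable_losses(mol: Chem.Mol, table: NeutralLossTable) -> list[int]:
    masses = []
    for label, mass in table.entries:
        patterns = LOSS_SMARTS.get(label)
        if patterns is None:
            masses.append(int(mass))
            continue
        for pattern in patterns:
            patt = Chem.MolFromSmarts(pattern)
            if patt is not None and mol.HasSubstructMatch(patt):
                masses.append(int(mass))
                break
    return masses


def simulate_spectrum(smiles: str, cfg: SimConfig) -> Spectrum:
    """Rule-based EI-like spectrum for one molecule (deterministic per
    (molecule, seed))."""
    mol = mol_from_smiles(smiles)
    M = _exact_mass(mol)
    n_total = mol.GetNumAtoms()
    temperature = cfg.temperature

    peaks: list[tuple[float, float]] = []
    molecular_ion_weight = float(np.exp(1.0 / temperature))
    peaks.append((M, molecular_ion_weight))

    if n_total > 1:
        for frag, base_weight, donor in enumerate_fragments(
                mol, cfg.fragmentation_depth):
            frag_mass = sum(_atom_mass_with_h(mol.GetAtomWithIdx(a))
                            for a in frag)
            # hydrogen rearrangement: the fragment picks up one hydrogen
            # when the complementary fragment's cut atom can donate one, so
            # the observed m/z depends on the local environment of the cut
            if donor:
                frag_mass += _MONO_MASS["H"]
            size_frac = len(frag) / n_total
            # hetero reward is already in base_weight; temperature rescales it
            weight = base_weight ** (1.0 / temperature) * size_frac
            peaks.append((frag_mass, float(weight)))

    for loss in _applicable_losses(mol, cfg.loss_table):
        if loss < M:
            peaks.append((M - loss, 0.7 * molecular_ion_weight))

    if cfg.noise_sd > 0:
        noise_seed = (zlib.crc32(smiles.encode()) ^ (cfg.seed * 2654435761)) % (2**31)
        noise_rng = np.random.default_rng(noise_seed)
        peaks = [(mz, w * float(np.exp(noise_rng.normal(0.0, cfg.noise_sd))))
                 for mz, w in peaks]

    spectrum = bin_peaks(peaks, max_mz=int(cfg.max_mass),
                         mono_mass=M, structure_key=Chem.MolToSmiles(mol))
    return l1_normalize(spectrum)


def generate_pairs(cfg: SimConfig) -> tuple[list[str], list[Spectrum]]:
    """Full synthetic dataset: canonical SMILES plus simulated spectra."""
    smiles = generate_molecules(cfg)
    spectra = [simulate_spectrum(s, cfg) for s in smiles]
    return smiles, spectra
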