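"""Dataset diversity profiling.

Two views of chemical diversity: (i) the fraction of one molecule set whose
nearest neighbour in another set reaches a Tanimoto similarity threshold on
ECFP4 (radius-2, 2048-bit circular) fingerprints, and (ii) a pluggable
first-match-wins SMARTS rule set assigning each molecule a coarse
superclass / class label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chemgraph import SmilesParseError, mol_from_smiles

logger = logging.getLogger(__name__)

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

# minimal default taxonomy (label, superclass, SMARTS); order matters:
# the first matching rule wins
DEFAULT_CLASS_RULES: tuple[tuple[str, str, str], ...] = (
    ("carboxylic acid", "organic acids", "[CX3](=O)[OX2H1]"),
    ("ester", "organic acids", "[CX3](=O)[OX2H0][#6]"),
    ("amide", "organic acids", "[CX3](=O)[NX3]"),
    ("aldehyde", "carbonyl compounds", "[CX3H1]=O"),
    ("ketone", "carbonyl compounds", "[#6][CX3](=O)[#6]"),
    ("nitrile", "nitrogen compounds", "[NX1]#[CX2]"),
    ("nitro compound", "nitrogen compounds", "[NX3](=O)=O"),
    ("amine", "nitrogen compounds", "[NX3;!$(N=*);!$(NC=O)]"),
    ("phenol", "benzenoids", "[OX2H][cX3]"),
    ("aromatic hydrocarbon", "benzenoids", "c1ccccc1"),
    ("alcohol", "alcohols and ethers", "[OX2H][CX4]"),
    ("ether", "alcohols and ethers", "[OX2]([#6])[#6]"),
    ("thiol", "sulfur compounds", "[SX2H]"),
    ("sulfide", "sulfur compounds", "[SX2]([#6])[#6]"),
    ("organohalide", "halogen compounds", "[F,Cl,Br,I]"),
    ("alkene", "hydrocarbons", "[CX3]=[CX3]"),
    ("alkane", "hydrocarbons", "[CX4]"),
)


@dataclass
class ClassRuleSet:
    """Ordered (class, superclass, SMARTS) rules, first match wins."""

    rules: tuple[tuple[str, str, str], ...] = DEFAULT_CLASS_RULES
    first_match_wins: bool = True

    def __post_init__(self):
        self._compiled = []
        for label, superclass, smarts in self.rules:
            if not label or not superclass:
                raise ValueError("rule labels must be nonempty")
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"invalid SMARTS for {label!r}: {smarts!r}")
            self._compiled.append((label, superclass, patt))

    @classmethod
    def from_yaml(cls, path) -> "ClassRuleSet":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(rules=tuple(
            (r["class"], r["superclass"], r["smarts"]) for r in raw))


def fingerprint(smiles: str):
    return _FP_GEN.GetFingerprint(mol_from_smiles(smiles))


def nn_overlap(set_a, set_b, threshold: float = 0.8) -> float:
    """Fraction of ``set_a`` with a nearest neighbour in ``set_b`` at
    Tanimoto similarity >= threshold (ECFP4, 2048 bits).

    A similarity exactly equal to the threshold counts as a hit.  Invalid
    SMILES are skipped with a warning.
    """
    def valid_fps(smiles_list):
        fps = []
        n_bad = 0
        for smi in smiles_list:
            try:
                fps.append(fingerprint(smi))
            except SmilesParseError:
                n_bad += 1
        if n_bad:
            logger.warning("nn_overlap skipped %d invalid SMILES", n_bad)
        return fps

    fps_a, fps_b = valid_fps(set_a), valid_fps(set_b)
    if not fps_a or not fps_b:
        raise ValueError("both sets must contain at least one valid molecule")
    hits = 0
    for fp in fps_a:
        sims = DataStructs.BulkTanimotoSimilarity(fp, fps_b)
        if max(sims) >= threshold:
            hits += 1
    return hits / len(fps_a)


def classify(smiles: str,
             rules: ClassRuleSet | None = None) -> tuple[str, str]:
    """Assign (superclass, class) by the first matching SMARTS rule."""
    rules = rules if rules is not None else ClassRuleSet()
    mol = mol_from_smiles(smiles)
    for label, superclass, patt in rules._compiled:
        if mol.HasSubstructMatch(patt):
            return superclass, label
    return "unclassified", "unclassified"


def class_table(smiles_list, rules: ClassRuleSet | None = None):
    """Percentage of molecules per (superclass, class) as a DataFrame."""
    import pandas as pd

    rules = rules if rules is not None else ClassRuleSet()
    counts: dict[tuple[str, str], int] = {}
    n = 0
    for smi in smiles_list:
        try:
            key = classify(smi, rules)
        except SmilesParseError:
            continue
        counts[key] = counts.get(key, 0) + 1
        n += 1
    rows = [{"superclass": sc, "class": c,
             "count": v, "percent": 100.0 * v / n}
            for (sc, c), v in sorted(counts.items())]
    return pd.DataFrame(rows)
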