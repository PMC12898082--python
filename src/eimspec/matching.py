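"""Embedding-based spectral library matching.

A library index holds (structure key, monoisotopic mass, unit-norm spectrum
embedding) entries; augmentation adds predicted spectra alongside reference
ones, so a structure key can appear more than once.  A query is answered by
cosine similarity (dot product of unit embeddings) over the candidates
whose mass lies within ±5 Da of the query mass; Recall@k is the fraction of
queries whose own molecule appears in the top k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MASS_BINS = (("small", 1, 175), ("medium", 176, 324), ("large", 325, 500))


@dataclass
class LibraryEntry:
    structure_key: str
    mono_mass: float
    embedding: np.ndarray
    provenance: str = "reference"     # "reference" | "predicted"


@dataclass
class LibraryIndex:
    entries: list[LibraryEntry] = field(default_factory=list)

    def add(self, structure_key: str, mono_mass: float, embedding: np.ndarray,
            provenance: str = "reference") -> None:
        embedding = np.asarray(embedding, dtype=np.float64)
        norm = np.linalg.norm(embedding)
        if not np.isclose(norm, 1.0, atol=1e-5):
            raise ValueError(f"embedding must be unit-norm, got |e|={norm:.6f}")
        self.entries.append(LibraryEntry(structure_key, float(mono_mass),
                                         embedding, provenance))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def masses(self) -> np.ndarray:
        return np.array([e.mono_mass for e in self.entries])

    @property
    def embedding_matrix(self) -> np.ndarray:
        return np.stack([e.embedding for e in self.entries])


@dataclass
class MatchResult:
    query_key: str
    candidate_keys: list[str]
    scores: list[float]
    hit_rank: int | None      # 1-based rank of the first correct candidate
    query_mass: float | None = None


def query_topk(q: np.ndarray, q_mass: float, index: LibraryIndex, k: int,
               mass_window: float = 5.0,
               query_key: str = "") -> MatchResult:
    """Mass-filtered top-k cosine retrieval.

    Candidates are restricted to entries with ``|mass - q_mass| <=
    mass_window`` (integer-rounded masses on both sides); ties break by
    library insertion order.  An empty candidate set yields an empty,
    logged result.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    q = np.asarray(q, dtype=np.float64)
    if len(index) == 0:
        logger.warning("query against an empty library")
        return MatchResult(query_key, [], [], None, q_mass)
    lib_mass = np.round(index.masses)
    candidates = np.nonzero(np.abs(lib_mass - round(q_mass))
                            <= mass_window)[0]
    if candidates.size == 0:
        logger.warning("no candidates within ±%g Da of mass %g",
                       mass_window, q_mass)
        return MatchResult(query_key, [], [], None, q_mass)
    sims = index.embedding_matrix[candidates] @ q
    # stable sort on -similarity keeps insertion order among ties
    order = np.argsort(-sims, kind="stable")
    ranked = candidates[order]
    hit_rank = None
    if query_key:
        for rank, idx in enumerate(ranked, start=1):
            if index.entries[idx].structure_key == query_key:
                hit_rank = rank
                break
    top = ranked[:k]
    return MatchResult(
        query_key=query_key,
        candidate_keys=[index.entries[i].structure_key for i in top],
        scores=[float(sims[order[r]]) for r in range(min(k, len(ranked)))],
        hit_rank=hit_rank,
        query_mass=q_mass,
    )


def recall_at_k(results, k: int) -> float:
    """Fraction of queries whose correct molecule ranks within the top k."""
    results = list(results)
    if not results:
        raise ValueError("no match results")
    hits = sum(1 for r in results if r.hit_rank is not None and r.hit_rank <= k)
    return hits / len(results)


def binned_metrics(results, ks=(1, 5, 10)) -> dict[str, dict]:
    """Recall@k separately for the small/medium/large mass bins."""
    out: dict[str, dict] = {}
    for name, lo, hi in MASS_BINS:
        in_bin = [r for r in results
                  if r.query_mass is not None and lo <= round(r.query_mass) <= hi]
        out[name] = {"n": len(in_bin)}
        for k in ks:
            out[name][f"recall@{k}"] = (recall_at_k(in_bin, k) if in_bin
                                        else float("nan"))
    return out


def expected_random_recall(index: LibraryIndex, query_masses, k: int,
                           mass_window: float = 5.0) -> float:
    """Recall@k of a random ranker over the same mass-filtered candidate
    sets: per query min(k, n_c) / n_c, assuming the correct molecule is one
    of the n_c candidates; averaged over queries."""
    lib_mass = np.round(index.masses)
    vals = []
    for m in query_masses:
        n_c = int(np.sum(np.abs(lib_mass - round(m)) <= mass_window))
        vals.append(min(k, n_c) / n_c if n_c else 0.0)
    return float(np.mean(vals))


def similarity_distributions(P: np.ndarray, T: np.ndarray,
                             embed=None, threshold: float = 0.6) -> dict:
    """Cosine-similarity distributions between paired predicted/true spectra.

    Returns raw-spectrum cosines, optional embedding cosines (via the
    provided ``embed`` callable), their means, and the fraction above the
    threshold.
    """
    P = np.asarray(P, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    pn = np.linalg.norm(P, axis=1)
    tn = np.linalg.norm(T, axis=1)
    denom = np.where(pn * tn > 0, pn * tn, 1e-12)
    raw = (P * T).sum(axis=1) / denom
    out = {
        "raw_cosines": raw,
        "raw_mean": float(raw.mean()),
        "raw_fraction_above": float((raw > threshold).mean()),
    }
    if embed is not None:
        U = np.asarray(embed(P))
        V = np.asarray(embed(T))
        emb = (U * V).sum(axis=1)
        out.update({
            "embedding_cosines": emb,
            "embedding_mean": float(emb.mean()),
            "embedding_fraction_above": float((emb > threshold).mean()),
        })
    return out
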