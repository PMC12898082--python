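"""Library matching: brute-force ranking oracle, mass filter semantics,
Recall@k properties, weight-binned metrics."""

import numpy as np
import pytest

from eimspec import (LibraryIndex, MatchResult, binned_metrics, query_topk,
                     recall_at_k, similarity_distributions)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _random_index(rng, n, dim=8, mass_range=(50, 450)):
    index = LibraryIndex()
    for i in range(n):
        index.add(f"mol{i}", rng.uniform(*mass_range),
                  _unit(rng.normal(size=dim)))
    return index


def test_self_retrieval_scores_one(rng):
    index = _random_index(rng, 10)
    e = index.entries[4]
    res = query_topk(e.embedding, e.mono_mass, index, k=1,
                     query_key=e.structure_key)
    assert res.candidate_keys[0] == "mol4"
    assert res.scores[0] == pytest.approx(1.0)
    assert res.hit_rank == 1


def test_topk_matches_brute_force_sort(rng):
    """No mass filter, k = index size: full ranking equals argsort."""
    index = _random_index(rng, 100)
    q = _unit(rng.normal(size=8))
    res = query_topk(q, 250.0, index, k=100, mass_window=np.inf)
    sims = index.embedding_matrix @ q
    expected = [index.entries[i].structure_key
                for i in np.argsort(-sims, kind="stable")]
    assert res.candidate_keys == expected
    assert all(a >= b - 1e-12 for a, b in zip(res.scores, res.scores[1:]))


def test_three_entry_hand_oracle():
    index = LibraryIndex()
    index.add("a", 100.0, _unit([1.0, 0.0]))
    index.add("b", 100.0, _unit([1.0, 1.0]))
    index.add("c", 100.0, _unit([0.0, 1.0]))
    q = _unit([2.0, 1.0])
    res = query_topk(q, 100.0, index, k=2)
    dots = sorted([("a", q @ _unit([1, 0])), ("b", q @ _unit([1, 1])),
                   ("c", q @ _unit([0, 1]))], key=lambda kv: -kv[1])
    assert res.candidate_keys == [dots[0][0], dots[1][0]]


def test_mass_filter_window_inclusive():
    index = LibraryIndex()
    for key, mass in [("in_low", 95.0), ("in_high", 105.0),
                      ("out_low", 94.0), ("out_high", 106.0)]:
        index.add(key, mass, _unit([1.0, 0.0]))
    res = query_topk(_unit([1.0, 0.0]), 100.0, index, k=10, mass_window=5.0)
    assert set(res.candidate_keys) == {"in_low", "in_high"}


def test_empty_candidate_set_returns_empty_result(rng):
    index = _random_index(rng, 5, mass_range=(400, 450))
    res = query_topk(_unit(rng.normal(size=8)), 50.0, index, k=3)
    assert res.candidate_keys == [] and res.hit_rank is None


def test_tie_break_by_insertion_order():
    index = LibraryIndex()
    e = _unit([1.0, 1.0])
    index.add("first", 100.0, e)
    index.add("second", 100.0, e)
    res = query_topk(e, 100.0, index, k=2)
    assert res.candidate_keys == ["first", "second"]


class TestRecall:
    def test_perfect_index(self, rng):
        index = _random_index(rng, 20)
        results = [query_topk(e.embedding, e.mono_mass, index, k=10,
                              query_key=e.structure_key)
                   for e in index.entries]
        assert recall_at_k(results, 1) == 1.0

    def test_absent_target(self, rng):
        index = _random_index(rng, 5)
        results = [query_topk(_unit(rng.normal(size=8)), 250.0, index, k=5,
                              mass_window=np.inf, query_key="missing")
                   for _ in range(4)]
        assert recall_at_k(results, 5) == 0.0

    def test_hand_counted_ranks(self):
        results = [MatchResult("q", [], [], rank) for rank in (1, 3, 7, None)]
        assert recall_at_k(results, 5) == 0.5
        assert recall_at_k(results, 1) == 0.25
        assert recall_at_k(results, 10) == 0.75

    def test_monotone_in_k_and_window(self, rng):
        index = _random_index(rng, 50)
        queries = [( _unit(e.embedding + rng.normal(size=8, scale=0.5)),
                     e.mono_mass, e.structure_key) for e in index.entries]
        for window in (5.0, 50.0, np.inf):
            results = [query_topk(q, m, index, k=50, mass_window=window,
                                  query_key=key) for q, m, key in queries]
            recalls = [recall_at_k(results, k) for k in (1, 2, 5, 10, 50)]
            assert all(a <= b + 1e-12 for a, b in zip(recalls, recalls[1:]))
        # at full depth a wider window can only keep or gain the true hit
        small = [query_topk(q, m, index, k=50, mass_window=5.0, query_key=key)
                 for q, m, key in queries]
        wide = [query_topk(q, m, index, k=50, mass_window=np.inf,
                           query_key=key) for q, m, key in queries]
        assert recall_at_k(wide, 50) >= recall_at_k(small, 50) - 1e-12


class TestBinnedMetrics:
    @staticmethod
    def _result(mass, rank=1):
        return MatchResult("q", [], [], rank, query_mass=mass)

    def test_single_bin_population(self):
        out = binned_metrics([self._result(100.0) for _ in range(3)])
        assert out["small"]["n"] == 3
        assert out["medium"]["n"] == 0 and out["large"]["n"] == 0
        assert out["small"]["recall@1"] == 1.0

    def test_boundary_masses(self):
        out = binned_metrics([self._result(175.0), self._result(176.0),
                              self._result(324.0), self._result(325.0)])
        assert out["small"]["n"] == 1
        assert out["medium"]["n"] == 2
        assert out["large"]["n"] == 1

    def test_bins_recombine_to_overall_recall(self, rng):
        results = [self._result(float(rng.uniform(10, 490)),
                                rank=int(rng.integers(1, 12)))
                   for _ in range(40)]
        out = binned_metrics(results)
        overall = recall_at_k(results, 5)
        weighted = sum(out[b]["recall@5"] * out[b]["n"] for b in out
                       if out[b]["n"]) / len(results)
        assert weighted == pytest.approx(overall)


class TestSimilarityDistributions:
    def test_identity_pairs(self):
        P = np.random.default_rng(0).random((4, 30))
        out = similarity_distributions(P, P)
        np.testing.assert_allclose(out["raw_cosines"], 1.0)
        assert out["raw_fraction_above"] == 1.0

    def test_orthogonal_pairs(self):
        P = np.array([[1.0, 0.0], [0.0, 1.0]])
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = similarity_distributions(P, T)
        np.testing.assert_allclose(out["raw_cosines"], 0.0)
        assert out["raw_fraction_above"] == 0.0

    def test_hand_built_mixed_set(self):
        P = np.array([[1, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        T = np.array([[1, 0], [0, 1], [1, 1], [0, 1]], dtype=float)
        out = similarity_distributions(P, T)
        expected = np.mean([1.0, 0.0, 1.0, 1.0])
        assert out["raw_mean"] == pytest.approx(expected)
        assert out["raw_fraction_above"] == pytest.approx(0.75)


def test_non_unit_embedding_rejected():
    index = LibraryIndex()
    with pytest.raises(ValueError):
        index.add("x", 100.0, np.array([1.0, 1.0]))
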