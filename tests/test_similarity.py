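"""Combined probability/identity scoring, WPGMA clustering and placement."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from phageneck.detection import DetectionEntry, DetectionTable, ProteinClass
from phageneck.homology import HomologyHit, HomologyProvider
from phageneck.similarity import (
    MAX_SCORE,
    SimilarityMatrix,
    assign_cluster,
    build_similarity_matrix,
    component_score,
    phage_pair_similarity,
    wpgma_tree,
)
from phageneck.synthetic import generate_planted_similarity

P = ProteinClass

percent = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)


def _table(rows):
    t = DetectionTable()
    for phage, cls, pid in rows:
        t.add(phage, cls, DetectionEntry(pid, 95.0, "strict90"))
    return t


def _both(a, b, prob, ident):
    return [HomologyHit(a, b, prob, ident), HomologyHit(b, a, prob, ident)]


class TestComponentScore:
    @pytest.mark.parametrize("prob,ident,expected", [
        (0.0, 0.0, 0.0),
        (100.0, 100.0, 110.0),
        (98.0, 20.0, 100.0),
    ])
    def test_known_values(self, prob, ident, expected):
        assert component_score(HomologyHit("a", "b", prob, ident)) == expected

    def test_uncompared_pair_scores_zero(self):
        assert component_score(None) == 0.0

    @given(percent, percent)
    @settings(max_examples=50, derandomize=True)
    def test_bounds(self, prob, ident):
        s = component_score(HomologyHit("a", "b", prob, ident))
        assert 0.0 <= s <= MAX_SCORE
        assert s >= prob  # identity can only add

    @given(percent, percent, percent, percent)
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_both_factors(self, p1, p2, i1, i2):
        lo = component_score(HomologyHit("a", "b", min(p1, p2), min(i1, i2)))
        hi = component_score(HomologyHit("a", "b", max(p1, p2), max(i1, i2)))
        assert hi >= lo


class TestPairSimilarity:
    def test_hand_computed_mean(self):
        # Portal (98,20) -> 100.0 ; Hc1 (80,15) -> 81.5 ; mean 90.75
        t = _table([("A", P.Portal, "a_po"), ("A", P.Hc1, "a_hc"),
                    ("A", P.MCP, "a_mcp"),
                    ("B", P.Portal, "b_po"), ("B", P.Hc1, "b_hc")])
        provider = HomologyProvider(
            _both("a_po", "b_po", 98.0, 20.0) + _both("a_hc", "b_hc", 80.0, 15.0)
        )
        score, shared = phage_pair_similarity("A", "B", t, provider)
        assert shared == 2  # MCP seen in A only is ignored
        assert score == pytest.approx(90.75)

    def test_self_similarity_maximal(self):
        t = _table([("A", c, f"p{i}") for i, c in enumerate(
            [P.Portal, P.MCP, P.TermL, P.Hc1, P.Tc1])])
        score, shared = phage_pair_similarity("A", "A", t, HomologyProvider())
        assert (score, shared) == (MAX_SCORE, 5)

    def test_disjoint_components_missing(self):
        t = _table([("A", P.Portal, "a_po"), ("B", P.MCP, "b_mcp")])
        assert phage_pair_similarity("A", "B", t, HomologyProvider()) == (None, 0)

    def test_portal_only_mode_equals_full_when_only_portal_shared(self):
        t = _table([("A", P.Portal, "a_po"), ("A", P.MCP, "a_mcp"),
                    ("B", P.Portal, "b_po"), ("B", P.Tc1, "b_tc")])
        provider = HomologyProvider(_both("a_po", "b_po", 90.0, 30.0))
        full = phage_pair_similarity("A", "B", t, provider, "all")
        portal = phage_pair_similarity("A", "B", t, provider, "portal")
        assert full == portal == (93.0, 1)


class TestSimilarityMatrix:
    def test_identical_phage_pair_scores_110(self):
        t = _table([("A", P.Portal, "a_po"), ("B", P.Portal, "b_po")])
        provider = HomologyProvider(_both("a_po", "b_po", 100.0, 100.0))
        m = build_similarity_matrix(["A", "B"], t, provider)
        assert m.value("A", "B") == MAX_SCORE

    def test_three_phage_toy_against_cell_oracle(self):
        t = _table([("A", P.Portal, "a_po"), ("A", P.Hc1, "a_hc"),
                    ("B", P.Portal, "b_po"), ("B", P.Hc1, "b_hc"),
                    ("C", P.Portal, "c_po")])
        provider = HomologyProvider(
            _both("a_po", "b_po", 98.0, 20.0) + _both("a_hc", "b_hc", 80.0, 15.0)
            + _both("a_po", "c_po", 60.0, 10.0) + _both("b_po", "c_po", 50.0, 12.0)
        )
        m = build_similarity_matrix(["A", "B", "C"], t, provider)
        for x, y in [("A", "B"), ("A", "C"), ("B", "C")]:
            expected, _ = phage_pair_similarity(x, y, t, provider)
            assert m.value(x, y) == pytest.approx(expected)
            assert m.value(y, x) == pytest.approx(expected)  # symmetry
        assert np.allclose(np.diag(m.scores), MAX_SCORE)

    def test_missing_cell_is_nan_not_zero(self):
        t = _table([("A", P.Portal, "a_po"), ("B", P.Portal, "b_po"),
                    ("C", P.MCP, "c_mcp")])
        provider = HomologyProvider(_both("a_po", "b_po", 90.0, 10.0))
        m = build_similarity_matrix(["A", "B", "C"], t, provider)
        assert np.isnan(m.value("A", "C"))
        assert m.value("A", "B") > 0

    def test_asymmetric_input_rejected(self):
        bad = np.array([[MAX_SCORE, 1.0], [2.0, MAX_SCORE]])
        with pytest.raises(ValueError, match="symmetric"):
            SimilarityMatrix(["A", "B"], bad, np.ones((2, 2), dtype=int))


def _matrix_from_scores(ids, cells):
    n = len(ids)
    scores = np.full((n, n), np.nan)
    np.fill_diagonal(scores, MAX_SCORE)
    for (a, b), v in cells.items():
        i, j = ids.index(a), ids.index(b)
        scores[i, j] = scores[j, i] = v
    return SimilarityMatrix(ids, scores, np.ones((n, n), dtype=int))


class TestWPGMA:
    def test_three_leaf_hand_oracle(self):
        # dissimilarities d(A,B)=2, d(A,C)=4, d(B,C)=6 (110 - score):
        # WPGMA merges (A,B) at height 2/2 = 1, then C at ((4+6)/2)/2 = 2.5
        m = _matrix_from_scores(
            ["A", "B", "C"],
            {("A", "B"): 108.0, ("A", "C"): 106.0, ("B", "C"): 104.0},
        )
        tree = wpgma_tree(m, distance="score")
        assert tree.heights == pytest.approx([1.0, 2.5])
        assert set(tree.cut_k(2)) == {"A", "B", "C"}
        labels = tree.cut_k(2)
        assert labels["A"] == labels["B"] != labels["C"]

    def test_identical_rows_merge_first_at_zero(self):
        m = _matrix_from_scores(
            ["A", "B", "C"],
            {("A", "B"): 110.0, ("A", "C"): 40.0, ("B", "C"): 40.0},
        )
        tree = wpgma_tree(m)  # rows of A and B are identical
        assert tree.heights[0] == pytest.approx(0.0)
        labels = tree.cut_k(2)
        assert labels["A"] == labels["B"] != labels["C"]

    def test_heights_never_invert(self):
        for seed in range(5):
            m, _ = generate_planted_similarity([4, 3, 5], seed=seed)
            tree = wpgma_tree(m)
            assert np.all(np.diff(tree.heights) >= -1e-9)

    def test_phage_with_missing_pairs_pruned(self):
        m = _matrix_from_scores(
            ["A", "B", "C", "D"],
            {("A", "B"): 100.0, ("A", "C"): 90.0, ("B", "C"): 95.0,
             ("A", "D"): 80.0},  # D misses pairs with B and C
        )
        tree = wpgma_tree(m)
        assert tree.pruned == ["D"]
        assert sorted(tree.ids) == ["A", "B", "C"]

    def test_too_few_phages_error(self):
        m = _matrix_from_scores(["A", "B"], {})  # off-diagonal all missing
        with pytest.raises(ValueError, match="fewer than 2"):
            wpgma_tree(m)

    def test_newick_is_parseable_with_matching_leaves(self):
        from Bio import Phylo

        m, _ = generate_planted_similarity([3, 4], seed=0)
        tree = wpgma_tree(m)
        parsed = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        leaves = sorted(t.name for t in parsed.get_terminals())
        assert leaves == sorted(tree.ids)
        # ultrametric: root-to-leaf path lengths all equal
        root_depths = [round(parsed.distance(t), 4) for t in parsed.get_terminals()]
        assert len(set(root_depths)) == 1

    def test_planted_blocks_recovered_by_largest_gap_cut(self):
        m, truth = generate_planted_similarity([5, 4, 6], seed=1)
        labels = wpgma_tree(m).cut_largest_gap()
        truth_vec = [truth[i] for i in sorted(labels)]
        label_vec = [labels[i] for i in sorted(labels)]
        assert adjusted_rand_score(truth_vec, label_vec) == 1.0


class TestAssignCluster:
    def _reference(self):
        # two clusters of reference phages with a shared Portal class
        t = _table([(p, P.Portal, f"{p}_po") for p in ["R1", "R2", "R3", "R4", "Q"]])
        hits = []
        for ref, prob in [("R1", 99.0), ("R2", 98.0), ("R3", 45.0), ("R4", 40.0)]:
            hits += _both("Q_po", f"{ref}_po", prob, 20.0)
        labels = {"R1": 1, "R2": 1, "R3": 2, "R4": 2}
        return t, HomologyProvider(hits), labels

    def test_query_joins_most_similar_cluster(self):
        t, provider, labels = self._reference()
        cluster, means, warnings = assign_cluster("Q", t, provider, labels)
        assert cluster == 1
        assert means[1] > means[2]
        assert warnings == []

    def test_tie_goes_to_lowest_cluster_with_warning(self):
        t = _table([(p, P.Portal, f"{p}_po") for p in ["R1", "R2", "Q"]])
        provider = HomologyProvider(
            _both("Q_po", "R1_po", 80.0, 10.0) + _both("Q_po", "R2_po", 80.0, 10.0)
        )
        cluster, _, warnings = assign_cluster("Q", t, provider, {"R1": 2, "R2": 3})
        assert cluster == 2
        assert any("equidistant" in w for w in warnings)

    def test_no_shared_component_unplaced(self):
        t = _table([("R1", P.Portal, "r_po"), ("Q", P.MCP, "q_mcp")])
        cluster, means, warnings = assign_cluster(
            "Q", t, HomologyProvider(), {"R1": 1}
        )
        assert cluster is None and means == {}
        assert any("unplaced" in w for w in warnings)

    @pytest.mark.parametrize("k", [2, 4])
    def test_planted_query_recovered_for_every_cluster(self, k):
        rng = np.random.default_rng(k)
        refs = [f"R{i}" for i in range(k * 3)]
        labels = {r: i % k + 1 for i, r in enumerate(refs)}
        t = _table([(p, P.Portal, f"{p}_po") for p in refs + ["Q"]])
        for target in range(1, k + 1):
            hits = []
            for r in refs:
                prob = rng.uniform(92, 100) if labels[r] == target else rng.uniform(20, 50)
                hits += _both("Q_po", f"{r}_po", round(prob, 2), 10.0)
            cluster, _, _ = assign_cluster("Q", t, HomologyProvider(hits), labels)
            assert cluster == target
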