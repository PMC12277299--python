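"""From-scratch agglomeration against brute-force and independent oracles."""

import itertools

import dendropy
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.cluster.hierarchy import linkage as scipy_linkage

from anxclust import (
    Dendrogram,
    Partition,
    agglomerate,
    cut_at_fraction,
    cut_to_k,
    distance_matrix,
    export_dendrogram,
)
from anxclust.hierarchy import ClusteringError, Merge, dendrogram_from_json, pairwise_euclidean

floats_1d = st.lists(
    st.floats(min_value=0, max_value=100, allow_nan=False), min_size=3, max_size=12
)


def _dist_1d(values):
    return distance_matrix(np.asarray(values, float).reshape(-1, 1))


class TestDistanceMatrix:
    def test_one_feature_distance_is_absolute_difference(self):
        d = _dist_1d([82, 35])
        assert d.values[0, 1] == 47  # Brazil vs Czech Republic, low stratum

    def test_zero_diagonal(self, low_data):
        d = distance_matrix(low_data)
        assert np.all(np.diag(d.values) == 0)

    def test_matches_brute_force_double_loop(self, rng):
        X = rng.normal(size=(5, 3))
        d = distance_matrix(X, labels=list("abcde"))
        for i in range(5):
            for j in range(5):
                expected = np.sqrt(sum((X[i, f] - X[j, f]) ** 2 for f in range(3)))
                assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ClusteringError):
            pairwise_euclidean(np.array([[0.0], [np.nan]]))


def exhaustive_agglomerate(values, linkage):
    """Oracle: rescan all cluster pairs at every step, computing the linkage
    distance directly from the raw pairwise distances (same tie-break)."""
    values = np.asarray(values, float)
    d0 = np.abs(np.subtract.outer(values, values))
    clusters = [frozenset([i]) for i in range(len(values))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            pair_d = [d0[i, j] for i in a for j in b]
            d = {"complete": max, "average": np.mean, "single": min}[linkage](pair_d)
            ca, cb = np.mean(values[list(a)]), np.mean(values[list(b)])
            key = (d, tuple(sorted(((ca,), (cb,)))), (min(min(a), min(b)), max(min(a), min(b))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
        merges.append((a | b, float(d)))
    return merges


@pytest.mark.parametrize("linkage", ["complete", "average", "single"])
def test_merge_sequence_matches_exhaustive_rescan_oracle(rng, linkage):
    for _ in range(10):
        n = int(rng.integers(3, 8))
        values = rng.uniform(0, 100, size=n)
        dendro = agglomerate(_dist_1d(values), linkage)
        oracle = exhaustive_agglomerate(values, linkage)
        n_leaves = dendro.n
        for t, (members, height) in enumerate(oracle):
            got = frozenset(dendro.members(n_leaves + t))
            assert got == members, f"step {t}: {got} != {members}"
            assert dendro.merges[t].height == pytest.approx(height, abs=1e-9)


@pytest.mark.parametrize("linkage", ["ward", "complete", "average", "single"])
def test_matches_scipy_on_tie_free_data(rng, linkage):
    """Independent cross-check: identical merge heights and member sets."""
    for _ in range(5):
        n = int(rng.integers(4, 15))
        X = rng.normal(size=(n, int(rng.integers(1, 4))))
        dendro = agglomerate(distance_matrix(X), linkage)
        Z = scipy_linkage(X, method=linkage)
        assert np.allclose(sorted(m.height for m in dendro.merges), sorted(Z[:, 2]), rtol=1e-8)
        mem = {i: frozenset([i]) for i in range(n)}
        theirs = set()
        for t, (a, b, h, _) in enumerate(Z):
            mem[n + t] = mem[int(a)] | mem[int(b)]
            theirs.add((mem[n + t], round(h, 8)))
        mine = {
            (frozenset(dendro.members(n + t)), round(m.height, 8))
            for t, m in enumerate(dendro.merges)
        }
        assert mine == theirs


class TestAgglomerateBasics:
    @pytest.mark.parametrize("linkage", ["ward", "complete", "average", "single"])
    def test_two_points_merge_at_their_distance(self, linkage):
        dendro = agglomerate(_dist_1d([3, 8]), linkage)
        assert len(dendro.merges) == 1
        assert dendro.merges[0].height == pytest.approx(5)

    def test_forced_merge_order_complete_linkage(self):
        dendro = agglomerate(_dist_1d([0, 1, 10]), "complete")
        heights = [m.height for m in dendro.merges]
        assert heights == pytest.approx([1, 10])
        assert frozenset(dendro.members(3)) == frozenset({0, 1})

    def test_unknown_linkage(self):
        with pytest.raises(ClusteringError):
            agglomerate(_dist_1d([0, 1]), "centroid")

    @given(floats_1d)
    def test_heights_monotone_nondecreasing(self, values):
        for linkage in ("ward", "complete", "average"):
            dendro = agglomerate(_dist_1d(values), linkage)
            heights = [m.height for m in dendro.merges]
            assert all(a <= b + 1e-9 for a, b in zip(heights, heights[1:]))

    def test_deterministic_under_record_permutation(self, rng):
        values = rng.uniform(0, 100, size=10)
        labels = [f"c{i}" for i in range(10)]
        base = agglomerate(distance_matrix(values.reshape(-1, 1), labels=labels))
        order = rng.permutation(10)
        perm = agglomerate(
            distance_matrix(values[order].reshape(-1, 1), labels=[labels[i] for i in order])
        )
        for k in (2, 3, 5):
            assert cut_to_k(base, k).same_clusters(cut_to_k(perm, k))


class TestCuts:
    def test_k_equals_one_and_n(self, low_model):
        dendro = low_model.dendrogram
        assert cut_to_k(dendro, 1).k == 1
        assert cut_to_k(dendro, 56).k == 56

    def test_k_out_of_range(self, low_model):
        with pytest.raises(ClusteringError):
            cut_to_k(low_model.dendrogram, 0)
        with pytest.raises(ClusteringError):
            cut_to_k(low_model.dendrogram, 57)

    def test_fraction_bounds(self, low_model):
        for bad in (0.0, -0.1, 1.01):
            with pytest.raises(ClusteringError):
                cut_at_fraction(low_model.dendrogram, bad)

    def test_fraction_one_gives_two_clusters(self, low_model):
        # the top merge is not strictly below its own height
        assert cut_at_fraction(low_model.dendrogram, 1.0).k == 2

    def test_tiny_fraction_gives_singletons(self, rng):
        values = rng.uniform(0, 100, size=8)
        dendro = agglomerate(distance_matrix(values.reshape(-1, 1)))
        min_h = min(m.height for m in dendro.merges)
        frac = 0.5 * min_h / dendro.max_height
        assert cut_at_fraction(dendro, frac).k == 8

    @given(floats_1d, st.integers(min_value=1, max_value=12))
    def test_fraction_and_count_cuts_agree(self, values, k):
        """Any threshold yielding k clusters gives the same partition as cut_to_k."""
        if len(set(values)) < len(values):
            values = list(np.asarray(values) + np.linspace(0, 1e-6, len(values)))
        k = min(k, len(values))
        dendro = agglomerate(_dist_1d(values))
        by_k = cut_to_k(dendro, k)
        heights = sorted(m.height for m in dendro.merges)
        # threshold strictly between the (n-k)th and (n-k+1)th merge heights
        lo = heights[len(values) - k - 1] if len(values) - k >= 1 else 0.0
        hi = heights[len(values) - k] if len(values) - k < len(heights) else None
        if hi is None or np.isclose(lo, hi):
            return
        frac = (lo + hi) / 2 / dendro.max_height
        if not 0 < frac <= 1:
            return
        assert cut_at_fraction(dendro, frac).same_clusters(by_k)

    @given(floats_1d)
    def test_one_dimensional_clusters_are_value_intervals(self, values):
        values = list(np.asarray(values) + np.linspace(0, 1e-6, len(values)))  # break ties
        arr = np.asarray(values)
        for linkage in ("ward", "complete", "average"):
            dendro = agglomerate(_dist_1d(values), linkage)
            for k in range(1, len(values) + 1):
                part = cut_to_k(dendro, k)
                spans = []
                for members in part.clusters().values():
                    idx = [int(m[1:]) for m in members]  # default labels P0..Pn
                    spans.append((arr[idx].min(), arr[idx].max()))
                for (lo1, hi1), (lo2, hi2) in itertools.combinations(spans, 2):
                    assert not (lo2 < hi1 and lo1 < hi2), f"overlap at k={k}"


class TestExport:
    def test_two_leaf_newick(self):
        dendro = Dendrogram(("A", "B"), (Merge(0, 1, 4.0, 2),))
        assert export_dendrogram(dendro, "newick") == "(A:4,B:4);"

    def test_json_round_trip(self, low_model):
        text = export_dendrogram(low_model.dendrogram, "json")
        again = dendrogram_from_json(text)
        assert again == low_model.dendrogram

    def test_newick_parses_with_56_leaves(self, high_model):
        """Quoted country names survive a standard Newick parser."""
        tree = dendropy.Tree.get(
            data=export_dendrogram(high_model.dendrogram, "newick"), schema="newick"
        )
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        assert len(leaves) == 56
        assert "Hong Kong (China)" in leaves

    def test_unknown_format(self, low_model):
        with pytest.raises(ClusteringError):
            export_dendrogram(low_model.dendrogram, "xml")


class TestPartition:
    def test_same_clusters_up_to_relabelling(self):
        p1 = Partition({"a": 1, "b": 1, "c": 2})
        p2 = Partition({"a": "x", "b": "x", "c": "y"})
        p3 = Partition({"a": 1, "b": 2, "c": 2})
        assert p1.same_clusters(p2)
        assert not p1.same_clusters(p3)
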