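"""Constrained Ward agglomeration: adjacency, optimality, contiguity."""

import itertools

import numpy as np
import pytest

from mvbc.data_model import BrainMask, SubjectRecord, ViewDataset
from mvbc.parcellate import (
    AdjacencyGraph,
    build_adjacency,
    extract_features,
    fit_parcelation,
    load_parcelation,
    save_parcelation,
    ward_linkage,
)

from conftest import box_mask


def view_from_matrix(data, mask, prefix="s"):
    subs = tuple(SubjectRecord(f"{prefix}{i}", "x") for i in range(len(data)))
    return ViewDataset("v", np.asarray(data, float), mask, subs)


# ---------------------------------------------------------------- adjacency
class TestAdjacency:
    def test_full_2x2x2_has_12_face_edges(self):
        g = build_adjacency(box_mask(2, 2, 2), 6)
        assert g.n_edges == 12

    def test_single_voxel_has_no_edges(self):
        g = build_adjacency(box_mask(1, 1, 1), 6)
        assert g.n_edges == 0

    def test_in_plane_diagonal_needs_18_connectivity(self):
        vol = np.zeros((2, 2, 1), bool)
        vol[0, 0, 0] = vol[1, 1, 0] = True
        mask = BrainMask.from_volume(vol, np.eye(4))
        assert build_adjacency(mask, 6).n_edges == 0
        assert build_adjacency(mask, 18).n_edges == 1

    def test_corner_diagonal_needs_26_connectivity(self):
        vol = np.zeros((2, 2, 2), bool)
        vol[0, 0, 0] = vol[1, 1, 1] = True
        mask = BrainMask.from_volume(vol, np.eye(4))
        assert build_adjacency(mask, 18).n_edges == 0
        assert build_adjacency(mask, 26).n_edges == 1

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            build_adjacency(box_mask(2, 2, 2), 7)

    def test_no_self_loops_allowed(self):
        with pytest.raises(ValueError):
            AdjacencyGraph(3, [[1, 1]])


# ---------------------------------------------------- brute-force oracle
def wcss(X, labels):
    """Total within-cluster sum of squares (the Ward objective)."""
    total = 0.0
    for c in np.unique(labels):
        sub = X[labels == c]
        total += ((sub - sub.mean(0)) ** 2).sum()
    return total


def is_connected(members, nbr_sets):
    members = set(members)
    seen = {next(iter(members))}
    stack = list(seen)
    while stack:
        v = stack.pop()
        for w in nbr_sets[v] & members:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen == members


def best_connected_partition(X, graph, k):
    """Exhaustive minimum-WCSS connected k-partition (oracle)."""
    n = len(X)
    nbrs = graph.neighbor_sets()
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        labels = np.asarray(assign)
        if len(set(assign)) != k:
            continue
        if not all(
            is_connected(np.flatnonzero(labels == c), nbrs) for c in range(k)
        ):
            continue
        best = min(best, wcss(X, labels))
    return best


class TestWardOracle:
    def test_chain_two_cluster_example(self, chain_mask):
        data = np.array([[0.0, 0.1, 5.0, 5.1], [0.0, 0.1, 5.0, 5.1]])
        view = view_from_matrix(data, chain_mask)
        g = build_adjacency(chain_mask, 6)
        parc = fit_parcelation(view, g, 2)
        assert np.array_equal(parc.labels, [0, 0, 1, 1])

    def test_k_equals_n_gives_singletons(self, chain_mask):
        data = np.random.default_rng(0).normal(size=(2, 4))
        parc = fit_parcelation(
            view_from_matrix(data, chain_mask), build_adjacency(chain_mask, 6), 4
        )
        assert np.array_equal(parc.labels, np.arange(4))

    def test_duplicated_subject_row_preserves_partition(self, chain_mask):
        g = build_adjacency(chain_mask, 6)
        data = np.array([[0.0, 0.3, 4.0, 4.2], [1.0, 1.1, -2.0, -2.2]])
        p1 = fit_parcelation(view_from_matrix(data, chain_mask), g, 2)
        dup = np.vstack([data, data[0]])
        p2 = fit_parcelation(view_from_matrix(dup, chain_mask), g, 2)
        # same grouping up to renaming (relabelling is canonical here)
        assert np.array_equal(p1.labels, p2.labels)

    def test_optimum_attained_on_block_structured_data(self):
        # well-separated contiguous blocks: greedy agglomeration recovers
        # the exhaustively optimal connected partition
        mask = box_mask(1, 1, 6)
        g = build_adjacency(mask, 6)
        rng = np.random.default_rng(9)
        centers = np.array([0.0, 0.0, 5.0, 5.0, -5.0, -5.0])
        X = centers[:, None] + 0.1 * rng.normal(size=(6, 3))
        tree = ward_linkage(X, g)
        assert wcss(X, tree.cut(3)) == pytest.approx(
            best_connected_partition(X, g, 3), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_each_merge_is_locally_optimal(self, seed):
        # the defining Ward property: every merge joins the admissible
        # (adjacent) cluster pair with the smallest variance increase
        mask = box_mask(1, 2, 4)
        g = build_adjacency(mask, 6)
        X = np.random.default_rng(seed).normal(size=(mask.n_voxels, 3))
        tree = ward_linkage(X, g)
        nbrs = g.neighbor_sets()
        clusters = {i: [i] for i in range(mask.n_voxels)}

        def ward_d(a, b):
            xa, xb = X[clusters[a]], X[clusters[b]]
            na, nb = len(xa), len(xb)
            diff = xa.mean(0) - xb.mean(0)
            return na * nb / (na + nb) * float(diff @ diff)

        def adjacent(a, b):
            return any(v in nbrs[u] for u in clusters[a] for v in clusters[b])

        for a, b, new, height in tree.merges:
            best = min(
                ward_d(u, v)
                for u in clusters
                for v in clusters
                if u < v and adjacent(u, v)
            )
            assert height == pytest.approx(best, abs=1e-12)
            clusters[new] = clusters.pop(a) + clusters.pop(b)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_sklearn_constrained_ward(self, seed):
        from sklearn.cluster import AgglomerativeClustering

        mask = box_mask(3, 3, 3)
        g = build_adjacency(mask, 6)
        X = np.random.default_rng(seed).normal(size=(mask.n_voxels, 4))
        ours = ward_linkage(X, g).cut(5)
        sk = AgglomerativeClustering(
            n_clusters=5, linkage="ward", connectivity=g.to_sparse()
        ).fit_predict(X)
        # identical partitions up to label names (bijective relabelling)
        mapping = {}
        for a, b in zip(ours, sk):
            assert mapping.setdefault(a, b) == b
        assert len(set(mapping.values())) == 5


class TestTreeStructure:
    def _tree(self, seed=0, shape=(2, 3, 3)):
        mask = box_mask(*shape)
        X = np.random.default_rng(seed).normal(size=(mask.n_voxels, 3))
        return ward_linkage(X, build_adjacency(mask, 6)), mask

    def test_nesting_changes_exactly_one_pair_of_clusters(self):
        tree, _ = self._tree()
        for k in range(3, tree.n_voxels):
            fine = tree.cut(k)
            coarse = tree.cut(k - 1)
            # each coarse cluster is a union of fine clusters; exactly one
            # coarse cluster contains two fine clusters
            merged = 0
            for c in range(k - 1):
                fine_ids = set(fine[coarse == c].tolist())
                assert len(fine_ids) in (1, 2)
                merged += len(fine_ids) - 1
            assert merged == 1

    def test_contiguity_under_bfs_audit(self):
        tree, mask = self._tree(seed=3, shape=(3, 3, 3))
        g = build_adjacency(mask, 6)
        nbrs = g.neighbor_sets()
        for k in (2, 5, 9):
            labels = tree.cut(k)
            for c in range(k):
                assert is_connected(np.flatnonzero(labels == c), nbrs)

    def test_multi_component_mask_requires_k_at_least_components(self):
        vol = np.zeros((1, 1, 5), bool)
        vol[0, 0, [0, 1, 3, 4]] = True  # two 2-voxel components
        mask = BrainMask.from_volume(vol, np.eye(4))
        g = build_adjacency(mask, 6)
        X = np.random.default_rng(0).normal(size=(4, 2))
        tree = ward_linkage(X, g)
        assert tree.n_components == 2
        with pytest.raises(ValueError):
            tree.cut(1)
        labels = tree.cut(2)  # exactly the components
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_fit_depends_only_on_training_subjects(self, chain_mask):
        g = build_adjacency(chain_mask, 6)
        rng = np.random.default_rng(11)
        data = rng.normal(size=(5, 4))
        train = [0, 2, 4]
        v1 = view_from_matrix(data, chain_mask)
        p1 = fit_parcelation(v1.restrict(train), g, 2)
        altered = data.copy()
        altered[[1, 3]] = 99.0  # mutate held-out rows only
        p2 = fit_parcelation(
            view_from_matrix(altered, chain_mask).restrict(train), g, 2
        )
        assert np.array_equal(p1.labels, p2.labels)


class TestFeatures:
    def test_median_aggregation_examples(self, chain_mask):
        # clusters {v0,v1,v2}, {v3}; subject values 1,2,9 and 7
        from mvbc.parcellate import Parcelation

        parc = Parcelation("v", [0, 0, 0, 1], 2, ("s0",))
        view = view_from_matrix([[1.0, 2.0, 9.0, 7.0]], chain_mask)
        fm = extract_features(view, parc)
        assert fm.data[0, 0] == 2.0  # odd-count median
        assert fm.data[0, 1] == 7.0
        parc2 = Parcelation("v", [0, 0, 1, 1], 2, ("s0",))
        fm2 = extract_features(
            view_from_matrix([[1.0, 3.0, 0.0, 1.0]], chain_mask), parc2
        )
        assert fm2.data[0, 0] == 2.0  # even-count midpoint

    def test_singleton_clusters_reproduce_input(self, chain_mask):
        from mvbc.parcellate import Parcelation

        data = np.random.default_rng(2).normal(size=(3, 4))
        parc = Parcelation("v", [0, 1, 2, 3], 4, ("s",))
        fm = extract_features(view_from_matrix(data, chain_mask), parc)
        np.testing.assert_array_equal(fm.data, data)

    def test_geometry_mismatch_errors(self, chain_mask):
        from mvbc.parcellate import Parcelation

        parc = Parcelation("v", [0, 1, 0], 2, ("s",))
        with pytest.raises(ValueError):
            extract_features(
                view_from_matrix(np.zeros((1, 4)), chain_mask), parc
            )


def test_parcelation_nifti_roundtrip(tmp_path, chain_mask):
    g = build_adjacency(chain_mask, 6)
    view = view_from_matrix(np.random.default_rng(1).normal(size=(3, 4)), chain_mask)
    parc = fit_parcelation(view, g, 2)
    save_parcelation(parc, chain_mask, tmp_path / "parc")
    back, mask = load_parcelation(tmp_path / "parc")
    assert np.array_equal(back.labels, parc.labels)
    assert back.k == parc.k and back.fit_subjects == parc.fit_subjects
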