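import numpy as np
import pandas as pd
import pytest

from gsinv import simreduce
from gsinv.dataio import ExpressionMatrix, GeneSet
from gsinv.resample import build_null
from gsinv.simreduce import Embedding
from gsinv.synthio import BulkSimConfig, simulate_bulk


def _matrix(values, n_normal, n_tumor):
    n = values.shape[1]
    samples = [f"N{i}" for i in range(n_normal)] + \
              [f"T{i}" for i in range(n_tumor)]
    assert len(samples) == n
    cond = pd.Series(["normal"] * n_normal + ["tumor"] * n_tumor, index=samples)
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            cond)


ADDITIVE = pd.DataFrame(
    [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
    index=list("ABCD"), columns=list("ABCD"), dtype=float)


class TestPCA:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.lognormal(0, 1, size=(5, 4)), 2, 2)
        emb = simreduce.pca_embed(m, log_transform=False)
        X = m.values.T
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        scores = Xc @ v[:, :2]
        for j in range(2):
            assert (np.allclose(emb.coordinates[:, j], scores[:, j], atol=1e-8)
                    or np.allclose(emb.coordinates[:, j], -scores[:, j],
                                   atol=1e-8))
        np.testing.assert_allclose(emb.explained_variance,
                                   (w[:2] / w.sum()), atol=1e-8)

    def test_duplicated_samples_identical_coordinates(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0, 1, size=(8, 4))
        vals[:, 1] = vals[:, 0]
        emb = simreduce.pca_embed(_matrix(vals, 2, 2))
        np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[1],
                                   atol=1e-10)

    def test_rank_one_data_explains_everything_on_pc1(self):
        t = np.array([0.0, 1.0, 2.0, 5.0])
        vals = np.outer(np.array([1.0, 2.0, 3.0]), t) + 1.0
        emb = simreduce.pca_embed(_matrix(vals, 2, 2), log_transform=False)
        assert emb.explained_variance[0] == pytest.approx(1.0, abs=1e-9)
        assert emb.explained_variance[1] == pytest.approx(0.0, abs=1e-9)


class TestConditionDistance:
    def test_coincident_samples(self):
        e = Embedding(["N1", "T1", "T2"], np.zeros((3, 2)),
                      (1.0, 0.0))
        cond = pd.Series(["normal", "tumor", "tumor"],
                         index=["N1", "T1", "T2"])
        assert simreduce.condition_distance(e, cond) == 0.0

    def test_three_four_five(self):
        e = Embedding(["N1", "T1"], np.array([[0.0, 0.0], [3.0, 4.0]]),
                      (1.0, 0.0))
        cond = pd.Series(["normal", "tumor"], index=["N1", "T1"])
        assert simreduce.condition_distance(e, cond) == pytest.approx(5.0)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(9)]
        coords = rng.normal(size=(9, 2))
        cond = pd.Series(["normal"] * 4 + ["tumor"] * 5, index=ids)
        e = Embedding(ids, coords, (0.7, 0.3))
        brute = np.mean([np.linalg.norm(coords[i] - coords[j])
                         for i in range(4) for j in range(4, 9)])
        assert simreduce.condition_distance(e, cond) == pytest.approx(
            brute, abs=1e-12)


def test_sample_distance_matrix_properties(small_matrix):
    d = simreduce.sample_distance_matrix(small_matrix)
    D = d.to_numpy()
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0)
    assert (D >= 0).all()


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        tree = simreduce.nj_tree(ADDITIVE)
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    assert tree.leaf_distance(a, b) == pytest.approx(
                        ADDITIVE.loc[a, b], abs=1e-9)
        # topology AB|CD: A and B share an internal neighbor
        na = next(iter(tree.graph.neighbors("A")))
        nb = next(iter(tree.graph.neighbors("B")))
        assert na == nb
        assert tree.is_fully_resolved()
        assert tree.total_branch_length == pytest.approx(11.0)

    def test_three_leaves_closed_form(self):
        d = pd.DataFrame([[0, 4, 6], [4, 0, 8], [6, 8, 0]],
                         index=list("XYZ"), columns=list("XYZ"), dtype=float)
        tree = simreduce.nj_tree(d)
        center = next(iter(tree.graph.neighbors("X")))
        assert tree.graph["X"][center]["length"] == pytest.approx(1.0)
        assert tree.graph["Y"][center]["length"] == pytest.approx(3.0)
        assert tree.graph["Z"][center]["length"] == pytest.approx(5.0)

    def test_leaf_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        ref = simreduce.nj_tree(ADDITIVE).distance_matrix()
        for _ in range(10):
            perm = rng.permutation(4)
            labels = [list("ABCD")[i] for i in perm]
            d = ADDITIVE.loc[labels, labels]
            got = simreduce.nj_tree(d).distance_matrix()
            for a in "ABCD":
                for b in "ABCD":
                    if a < b:
                        assert got[a][b] == pytest.approx(ref[a][b], abs=1e-9)

    def test_matches_reference_implementation(self):
        """Cross-check leaf path lengths against scikit-bio's NJ."""
        skbio = pytest.importorskip("skbio")
        dm = skbio.DistanceMatrix(ADDITIVE.to_numpy(), ids=list("ABCD"))
        ref = skbio.tree.nj(dm)
        ours = simreduce.nj_tree(ADDITIVE)
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    assert ours.leaf_distance(a, b) == pytest.approx(
                        ref.find(a).distance(ref.find(b)), abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            simreduce.nj_tree(np.array([[0, 1.0], [2.0, 0]]))
        bad = ADDITIVE.copy()
        bad.iloc[0, 1] = bad.iloc[1, 0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            simreduce.nj_tree(bad)
        with pytest.raises(ValueError, match="3 leaves"):
            simreduce.nj_tree(np.zeros((2, 2)))

    def test_subset_tree_shorter_than_whole(self):
        """Euclidean distances shrink on a gene subset, and so does the NJ
        tree's total branch length."""
        m, focal = simulate_bulk(BulkSimConfig(n_genes=500, focal_size=50,
                                               seed=5))
        whole = simreduce.nj_tree(simreduce.sample_distance_matrix(m))
        sub = simreduce.nj_tree(simreduce.sample_distance_matrix(m, focal))
        assert sub.total_branch_length <= whole.total_branch_length


class TestClustering:
    def test_merge_heights_non_decreasing(self, small_matrix):
        Z, _ = simreduce.hierarchical_cluster(
            simreduce.sample_distance_matrix(small_matrix))
        heights = Z[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_perfect_separation_scores_one(self):
        coords = np.vstack([np.zeros((3, 5)), np.full((3, 5), 10.0)])
        coords += np.random.default_rng(0).normal(0, 0.01, coords.shape)
        m = _matrix(np.abs(coords.T) + 1.0, 3, 3)
        d = simreduce.sample_distance_matrix(m, log_transform=False)
        score = simreduce.separation_score(simreduce.hierarchical_cluster(d),
                                           m.condition)
        assert score == pytest.approx(1.0)
        tree_score = simreduce.separation_score(simreduce.nj_tree(d),
                                                m.condition)
        assert tree_score == pytest.approx(1.0)

    def test_random_labels_center_on_zero(self):
        rng = np.random.default_rng(4)
        scores = []
        ids = [f"s{i}" for i in range(12)]
        for _ in range(200):
            vals = rng.lognormal(0, 1, size=(20, 12))
            labels = rng.permutation(["normal"] * 6 + ["tumor"] * 6)
            genes = [f"g{i}" for i in range(20)]
            m = ExpressionMatrix(
                pd.DataFrame(vals, index=genes, columns=ids),
                pd.Series(labels, index=ids))
            d = simreduce.sample_distance_matrix(m)
            scores.append(simreduce.separation_score(
                simreduce.hierarchical_cluster(d), m.condition))
        assert abs(np.mean(scores)) < 0.05

    def test_single_condition_undefined(self, small_matrix):
        cond = pd.Series(["normal"] * 6, index=small_matrix.sample_ids)
        m = ExpressionMatrix(small_matrix.data, cond)
        d = simreduce.sample_distance_matrix(m)
        with pytest.warns(UserWarning, match="one condition"):
            score = simreduce.separation_score(
                simreduce.hierarchical_cluster(d), cond)
        assert np.isnan(score)


def test_invariant_focal_condition_distance_typical_of_null():
    """Under an exchangeable focal set, the PCA condition distance of the
    focal subset should be statistically indistinguishable from size-matched
    random subsets (central 90% of the null in most seeds)."""
    def stat(m, genes):
        emb = simreduce.pca_embed(m, GeneSet("sub", tuple(genes)))
        return simreduce.condition_distance(emb, m.condition)

    inside = 0
    for seed in range(10):
        m, focal = simulate_bulk(BulkSimConfig(n_genes=300, focal_size=30,
                                               seed=seed))
        null = build_null(m, focal, stat, n_reps=60, seed=seed + 500)
        inside += 0.05 <= null.percentile <= 0.95
    assert inside >= 7
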