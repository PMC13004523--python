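import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from priornmf import (
    Embedding,
    adjusted_rand_index,
    cbdir,
    clustering_accuracy,
    correlation_structure_agreement,
    gene_pearson,
    knn_graph,
    leakage_ratio,
    macro_auc_ovr,
    macro_f1,
    silhouette_mean,
)
from priornmf.metrics import _gene_corr, contingency


# --- independent oracles -----------------------------------------------------

def ari_oracle(a, b):
    """Pair-counting ARI computed directly from all unordered pairs."""
    a, b = list(a), list(b)
    n = len(a)
    pairs = list(itertools.combinations(range(n), 2))
    n11 = sum(1 for i, j in pairs if a[i] == a[j] and b[i] == b[j])
    n00 = sum(1 for i, j in pairs if a[i] != a[j] and b[i] != b[j])
    n10 = sum(1 for i, j in pairs if a[i] == a[j] and b[i] != b[j])
    n01 = sum(1 for i, j in pairs if a[i] != a[j] and b[i] == b[j])
    total = len(pairs)
    index = n11
    expected = (n11 + n10) * (n11 + n01) / total
    maximum = ((n11 + n10) + (n11 + n01)) / 2
    if maximum == expected:
        return 0.0
    return (index - expected) / (maximum - expected)


def accuracy_oracle(truth, pred):
    """Exhaustive max over all injective cluster-to-class assignments."""
    t = np.asarray([list(dict.fromkeys(truth)).index(x) for x in truth])
    p = np.asarray([list(dict.fromkeys(pred)).index(x) for x in pred])
    kt, kp = t.max() + 1, p.max() + 1
    size = max(kt, kp)
    best = 0
    for perm in itertools.permutations(range(size)):
        correct = sum(1 for i in range(len(t)) if perm[p[i]] == t[i])
        best = max(best, correct)
    return best / len(t)


def silhouette_oracle(X, labels):
    """Double-loop silhouette with Euclidean distances; singletons get 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    scores = []
    for i in range(n):
        own = (labels == labels[i]) & (np.arange(n) != i)
        if not own.any():
            scores.append(0.0)
            continue
        a = d[i, own].mean()
        b = min(d[i, labels == other].mean() for other in set(labels) if other != labels[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


# --- tests -------------------------------------------------------------------

class TestAri:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 3], [9, 9, 8, 7]) == pytest.approx(1.0)

    def test_single_cluster_vs_anything_is_zero(self):
        assert adjusted_rand_index([0, 0, 0, 0], [1, 2, 1, 2]) == pytest.approx(0.0)

    def test_three_item_hand_case_matches_pair_enumeration(self):
        a, b = [1, 1, 2], [1, 2, 2]
        assert adjusted_rand_index(a, b) == pytest.approx(ari_oracle(a, b))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_oracle_on_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        a = rng.integers(0, 4, n)
        b = rng.integers(0, 4, n)
        assert adjusted_rand_index(a, b) == pytest.approx(ari_oracle(a, b), abs=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 20)
        b = rng.integers(0, 3, 20)
        remap = {0: "x", 1: "y", 2: "z"}
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_index([remap[v] for v in a], b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])


class TestClusteringAccuracy:
    def test_permuted_ids_score_one(self):
        truth = [0, 0, 1, 1, 2, 2]
        pred = [2, 2, 0, 0, 1, 1]
        assert clustering_accuracy(truth, pred) == pytest.approx(1.0)

    def test_constant_prediction_balanced_truth(self):
        truth = [0, 1, 2] * 4
        assert clustering_accuracy(truth, [7] * 12) == pytest.approx(1 / 3)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_permutation_max(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        truth = rng.integers(0, 4, n)
        pred = rng.integers(0, 5, n)
        assert clustering_accuracy(truth, pred) == pytest.approx(
            accuracy_oracle(truth, pred), abs=1e-9)

    def test_hungarian_at_least_any_fixed_mapping(self):
        rng = np.random.default_rng(9)
        truth = rng.integers(0, 3, 30)
        pred = rng.integers(0, 3, 30)
        identity_acc = np.mean(truth == pred)
        assert clustering_accuracy(truth, pred) >= identity_acc - 1e-12


class TestMacroF1:
    def test_perfect_prediction(self):
        assert macro_f1([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)

    def test_never_predicted_class_contributes_zero(self):
        truth = [0, 0, 1, 1]
        pred = [0, 0, 0, 0]
        # class 1 has recall 0 -> F1 = 0; macro mean < 1
        assert macro_f1(truth, pred, mapping="identity") < 1.0

    def test_printed_confusion_counts(self):
        # one class with TP=2, FP=1, FN=1 -> F1 = 2/3
        truth = [0, 0, 0, 1, 1, 1]
        pred = [0, 0, 1, 0, 1, 1]
        per_class = 2 * (2 / 3) * (2 / 3) / ((2 / 3) + (2 / 3))
        assert macro_f1(truth, pred, mapping="identity") == pytest.approx(per_class)


class TestMacroAuc:
    def test_one_hot_scores_are_perfect(self):
        truth = [0, 1, 2, 1]
        scores = np.eye(3)[truth]
        assert macro_auc_ovr(truth, scores) == pytest.approx(1.0)

    def test_constant_scores_are_chance(self):
        truth = [0, 1, 0, 1]
        assert macro_auc_ovr(truth, np.ones((4, 2))) == pytest.approx(0.5)

    def test_sign_reversal_mirrors_auc(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 30)
        scores = rng.normal(size=(30, 2))
        a = macro_auc_ovr(truth, scores)
        b = macro_auc_ovr(truth, -scores)
        assert a + b == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 3, 40)
        scores = rng.uniform(size=(40, 3))
        assert macro_auc_ovr(truth, scores) == pytest.approx(
            macro_auc_ovr(truth, np.exp(5 * scores)))


class TestSilhouette:
    def test_two_tight_clusters_hand_case(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = [0, 0, 1, 1]
        # point 0: a=1, b=10.5 -> s = 9.5/10.5; point 1: a=1, b=9.5 -> 8.5/9.5
        expected = (9.5 / 10.5 + 8.5 / 9.5) / 2  # symmetric cluster pair
        assert silhouette_mean(X, labels) == pytest.approx(expected, abs=1e-9)
        assert silhouette_oracle(X, labels) == pytest.approx(expected, abs=1e-9)

    def test_coincident_clusters_score_nonpositive(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        assert silhouette_mean(X, [0, 0, 1, 1]) <= 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        X = rng.normal(size=(n, 3))
        labels = rng.integers(0, 3, n)
        if np.unique(labels).size < 2:
            labels[0] = (labels[0] + 1) % 3
        ours = silhouette_mean(X, labels)
        assert ours == pytest.approx(silhouette_oracle(X, labels), abs=1e-9)
        assert -1.0 <= ours <= 1.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_mean(np.zeros((3, 2)), [0, 0, 0])


class TestCbdir:
    def _embedding(self, coords, velocity, neighbors):
        return Embedding(np.asarray(coords, float), np.asarray(velocity, float), neighbors)

    def test_aligned_velocity_scores_one(self):
        emb = self._embedding([[0, 0], [1, 0]], [[1, 0], [0, 0]], {0: {1}, 1: {0}})
        assert cbdir(emb, ["src", "tgt"], "src", "tgt") == pytest.approx(1.0)

    def test_antiparallel_velocity_scores_minus_one(self):
        emb = self._embedding([[0, 0], [1, 0]], [[-1, 0], [0, 0]], {0: {1}, 1: {0}})
        assert cbdir(emb, ["src", "tgt"], "src", "tgt") == pytest.approx(-1.0)

    def test_mixed_parallel_and_orthogonal_neighbors(self):
        emb = self._embedding(
            [[0, 0], [1, 0], [0, 1]], [[1, 0], [0, 0], [0, 0]],
            {0: {1, 2}, 1: set(), 2: set()})
        assert cbdir(emb, ["src", "tgt", "tgt"], "src", "tgt") == pytest.approx(0.5)

    def test_no_boundary_cells_reports_missing(self):
        emb = self._embedding([[0, 0], [5, 5]], [[1, 0], [0, 1]], {0: set(), 1: set()})
        assert cbdir(emb, ["src", "tgt"], "src", "tgt") is None

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(12, 2))
        vel = rng.normal(size=(12, 2))
        labels = ["a"] * 6 + ["b"] * 6
        graph = knn_graph(coords, 4)
        base = cbdir(Embedding(coords, vel, graph), labels, "a", "b")
        phi = 1.1
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        rotated = cbdir(Embedding(coords @ R.T, vel @ R.T, graph), labels, "a", "b")
        assert rotated == pytest.approx(base, abs=1e-9)


class TestGenePearson:
    def test_identity_gives_unit_correlations(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(size=(10, 5))
        res = gene_pearson(M, M)
        np.testing.assert_allclose(res.r, 1.0, atol=1e-12)
        assert res.mean == pytest.approx(1.0)

    def test_positive_affine_per_gene_gives_one(self):
        rng = np.random.default_rng(1)
        M = rng.uniform(size=(10, 4))
        res = gene_pearson(M, 3.0 * M + 2.0)
        np.testing.assert_allclose(res.r, 1.0, atol=1e-9)

    def test_constant_gene_excluded_from_summary(self):
        rng = np.random.default_rng(2)
        M = rng.uniform(size=(8, 3))
        M[:, 1] = 5.0
        res = gene_pearson(M, M)
        assert np.isnan(res.r[1]) and res.n_undefined == 1
        assert res.mean == pytest.approx(1.0)


class TestLeakage:
    def _M(self):
        M = np.zeros((4, 2))
        M[:2, :] = 4.0  # correct cells
        return M

    def test_zero_wrong_expression(self):
        assert leakage_ratio(self._M(), ["g0", "g1"], ["g0", "g1"], [0, 1], [2, 3]) == 0.0

    def test_equal_expression_is_one(self):
        M = np.full((4, 2), 3.0)
        assert leakage_ratio(M, ["g0", "g1"], ["g0", "g1"], [0, 1], [2, 3]) == pytest.approx(1.0)

    def test_quarter_ratio(self):
        M = self._M()
        M[2:, :] = 1.0
        assert leakage_ratio(M, ["g0", "g1"], ["g0", "g1"], [0, 1], [2, 3]) == pytest.approx(0.25)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            leakage_ratio(np.zeros((4, 2)), ["g0", "g1"], ["g0"], [0, 1], [2, 3])


class TestCorrelationStructure:
    def test_full_sample_of_matching_matrix(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(40, 5))
        ref = _gene_corr(M)
        sims, dists = correlation_structure_agreement(ref, M, 1.0, 5, seed=0)
        np.testing.assert_allclose(sims, 1.0, atol=1e-9)
        np.testing.assert_allclose(dists, 0.0, atol=1e-9)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(50, 4))
        ref = _gene_corr(M)
        a = correlation_structure_agreement(ref, M, 0.2, 10, seed=3)
        b = correlation_structure_agreement(ref, M, 0.2, 10, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_duplicated_gene_always_perfectly_correlated(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(60, 3))
        M[:, 2] = M[:, 1]
        sub_rng = np.random.default_rng(5)
        for _ in range(5):
            idx = sub_rng.choice(60, size=12, replace=False)
            corr = _gene_corr(M[idx])
            assert corr[1, 2] == pytest.approx(1.0)

    def test_too_small_subsample_rejected(self):
        M = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            correlation_structure_agreement(_gene_corr(M), M, 0.1, 5, seed=0)


def test_contingency_counts():
    table = contingency([0, 0, 1, 1], [0, 1, 1, 1])
    np.testing.assert_array_equal(table, [[1, 1], [0, 2]])
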