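"""Weighted KNN, weighted naive Bayes and multi-level SVM."""

import math

import numpy as np
import pytest

from epu import pu_classifiers as pc
from epu.exceptions import ValidationError


class TestWknn:
    def test_all_positive_neighbors_give_certainty(self):
        V = np.array([[0.0], [0.1], [0.2], [5.0]])
        scores = np.array([0.5, 0.3, 0.2, -1.0])
        p_pos, p_neg = pc.wknn_posterior([0.05], V, scores, k=3)
        assert (p_pos, p_neg) == (1.0, 0.0)

    def test_mixed_neighbors_mass_ratio(self):
        """Neighbour scores {+0.6, +0.2, -0.2}: positive mass 0.8 of total 1.0."""
        V = np.array([[0.0], [0.1], [0.2]])
        scores = np.array([0.6, 0.2, -0.2])
        p_pos, p_neg = pc.wknn_posterior([0.05], V, scores, k=3)
        assert p_pos == pytest.approx(0.8)
        assert p_pos + p_neg == pytest.approx(1.0)

    def test_zero_mass_neighbors_are_uninformative(self):
        V = np.array([[0.0], [1.0], [2.0]])
        scores = np.zeros(3)
        assert pc.wknn_posterior([0.5], V, scores, k=3) == (0.5, 0.5)

    def test_k_out_of_range_rejected(self):
        V = np.array([[0.0], [1.0]])
        with pytest.raises(ValidationError):
            pc.wknn_posterior([0.5], V, np.zeros(2), k=0)
        with pytest.raises(ValidationError):
            pc.wknn_posterior([0.5], V, np.zeros(2), k=3)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_exhaustive_neighbor_oracle(self, k):
        rng = np.random.default_rng(k)
        n = 100
        ids = [f"g{i:03d}" for i in range(n)]
        V = rng.normal(size=(n, 5))
        scores = rng.normal(size=n)
        model = pc.WeightedKNN(k=k).fit(ids, V, scores)
        for _ in range(20):
            x = rng.normal(size=5)
            # oracle: full sort by (distance, id), explicit mass accumulation
            order = sorted(range(n), key=lambda i: (float(np.linalg.norm(V[i] - x)), ids[i]))
            top = order[:k]
            pos = sum(scores[i] for i in top if scores[i] >= 0)
            neg = sum(-scores[i] for i in top if scores[i] < 0)
            expected = (0.5, 0.5) if pos + neg == 0 else (pos / (pos + neg), neg / (pos + neg))
            assert model.posterior(x) == pytest.approx(expected)
            assert model.posteriors(x[None, :])[0] == pytest.approx(expected)


class TestWnb:
    def test_symmetric_pools_give_half(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        model = pc.WeightedNaiveBayes().fit(V, [1.0, 1.0], V, [1.0, 1.0])
        p_pos, p_neg = model.posterior([0.5, 0.5])
        assert p_pos == pytest.approx(0.5)

    def test_positive_only_feature_pushes_posterior_up(self):
        V_pos = np.array([[1.0, 0.0], [1.0, 0.0]])
        V_neg = np.array([[0.0, 1.0], [0.0, 1.0]])
        model = pc.WeightedNaiveBayes().fit(V_pos, [1, 1], V_neg, [1, 1])
        p_pos, _ = model.posterior([1.0, 0.0])
        assert p_pos > 0.5

    def test_matches_hand_log_space_oracle(self):
        """4-gene, 3-feature fixture against explicit Bayes arithmetic."""
        V_pos = np.array([[1.0, 0.0, 0.5], [0.5, 0.5, 0.0]])
        w_pos = np.array([1.0, 0.8])
        V_neg = np.array([[0.0, 1.0, 1.0], [0.0, 0.5, 1.0]])
        w_neg = np.array([1.0, 0.4])
        x = np.array([0.5, 1.0, 0.0])
        lam, m = 1.0, 3

        def likelihoods(V, w):
            counts = [lam + sum(wi * V[i, k] for i, wi in enumerate(w)) for k in range(m)]
            total = sum(counts)
            return [c / total for c in counts]

        lp = math.log(0.5) + sum(x[k] * math.log(likelihoods(V_pos, w_pos)[k]) for k in range(m))
        ln = math.log(0.5) + sum(x[k] * math.log(likelihoods(V_neg, w_neg)[k]) for k in range(m))
        z = math.exp(lp) + math.exp(ln)
        expected = (math.exp(lp) / z, math.exp(ln) / z)

        model = pc.WeightedNaiveBayes(laplace=lam).fit(V_pos, w_pos, V_neg, w_neg)
        got = model.posterior(x)
        assert got[0] == pytest.approx(expected[0], abs=1e-9)
        assert got[1] == pytest.approx(expected[1], abs=1e-9)

    def test_empty_pool_error_names_side(self):
        V = np.array([[1.0]])
        with pytest.raises(ValidationError, match="positive"):
            pc.WeightedNaiveBayes().fit(np.zeros((0, 1)), [], V, [1.0])
        with pytest.raises(ValidationError, match="negative"):
            pc.WeightedNaiveBayes().fit(V, [1.0], np.zeros((0, 1)), [])

    def test_negative_features_rejected(self):
        with pytest.raises(ValidationError):
            pc.WeightedNaiveBayes().fit(np.array([[-0.1]]), [1.0], np.array([[1.0]]), [1.0])

    def test_pool_construction_from_scores(self):
        pos_ids, pos_w, neg_ids, neg_w = pc.wnb_pools(
            ["p"], ["n"], ["u1", "u2", "u3"], {"u1": 0.4, "u2": -0.2, "u3": 0.0}
        )
        assert pos_ids == ["p", "u1"] and pos_w == [1.0, 0.4]
        assert neg_ids == ["n", "u2"] and neg_w == [1.0, 0.2]


class TestLevelPartition:
    def test_hand_example(self):
        scores = {"a": 0.9, "b": 0.1, "c": -0.1, "d": -0.9}
        lv = pc.partition_levels(scores.keys(), scores)
        assert lv.LP == {"a"} and lv.LN == {"d"} and lv.WN == {"b", "c"}
        assert lv.mu_pos == pytest.approx(0.5) and lv.mu_neg == pytest.approx(-0.5)

    def test_uniform_positive_scores_fill_lp(self):
        scores = {g: 0.3 for g in "abc"}
        lv = pc.partition_levels("abc", scores)
        assert lv.LP == {"a", "b", "c"} and not lv.LN and not lv.WN

    def test_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(30)]
        scores = {g: float(rng.normal()) for g in genes}
        lv1 = pc.partition_levels(genes, scores)
        lv2 = pc.partition_levels(genes, {g: 7.0 * s for g, s in scores.items()})
        assert (lv1.LP, lv1.LN, lv1.WN) == (lv2.LP, lv2.LN, lv2.WN)

    def test_partition_covers_input(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(20)]
        scores = {g: float(rng.normal()) for g in genes}
        lv = pc.partition_levels(genes, scores)
        assert lv.LP | lv.LN | lv.WN == set(genes)
        assert not (lv.LP & lv.LN) and not (lv.LP & lv.WN) and not (lv.LN & lv.WN)


def _separable(n=20, seed=0):
    rng = np.random.default_rng(seed)
    X_pos = rng.normal(loc=2.0, scale=0.3, size=(n, 3))
    X_neg = rng.normal(loc=-2.0, scale=0.3, size=(n, 3))
    X = np.vstack([X_pos, X_neg])
    y = np.array([1] * n + [-1] * n)
    return X, y


class TestMsvm:
    def test_separable_fixture_perfect_training_accuracy(self):
        X, y = _separable()
        model = pc.MultiLevelSVM(cost_grid=(100.0,)).fit(X, y, np.ones(len(y)))
        pred = np.where(model.decision_values(X) > 0, 1, -1)
        assert np.all(pred == y)

    def test_zero_weight_points_equivalent_to_removal(self):
        """Zero slack cost removes a point from the objective: the fitted
        model must match a refit without those points."""
        X, y = _separable(seed=3)
        w = np.ones(len(y))
        w[-5:] = 0.0
        m1 = pc.MultiLevelSVM(cost_grid=(1.0,)).fit(X, y, w)
        m2 = pc.MultiLevelSVM(cost_grid=(1.0,)).fit(X[:-5], y[:-5], w[:-5])
        grid = np.random.default_rng(0).normal(size=(10, 3))
        np.testing.assert_allclose(
            m1.decision_values(grid), m2.decision_values(grid), atol=1e-8
        )

    def test_duplicated_point_equals_doubled_weight(self):
        """A training point listed twice at weight w behaves as one point
        at weight 2w (weighted-loss identity)."""
        X = np.array([[1.0, 0.0], [0.5, 1.0], [-1.0, 0.0], [-0.5, -1.0]])
        y = np.array([1, 1, -1, -1])
        X_dup = np.vstack([X, X[:1]])
        y_dup = np.append(y, 1)
        w_dup = np.ones(5)
        w_single = np.array([2.0, 1.0, 1.0, 1.0])
        m1 = pc.MultiLevelSVM(cost_grid=(1.0,)).fit(X_dup, y_dup, w_dup)
        m2 = pc.MultiLevelSVM(cost_grid=(1.0,)).fit(X, y, w_single)
        grid = np.random.default_rng(1).normal(size=(10, 2))
        np.testing.assert_allclose(
            m1.decision_values(grid), m2.decision_values(grid), atol=1e-6
        )

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValidationError):
            pc.MultiLevelSVM().fit(X, np.ones(5, dtype=int), np.ones(5))

    def test_training_arrays_strata(self):
        lv = pc.LevelPartition(
            LP=frozenset({"lp"}), LN=frozenset({"ln"}), WN=frozenset({"wn"}),
            mu_pos=0.5, mu_neg=-0.5,
        )
        rows = {g: np.array([float(i)]) for i, g in enumerate(["p", "lp", "rn", "ln", "wn"])}
        ids, X, y, w = pc.msvm_training_arrays(["p"], ["rn"], lv, rows=rows)
        assert ids == ["p", "lp", "rn", "ln", "wn"]
        np.testing.assert_array_equal(y, [1, 1, -1, -1, -1])
        np.testing.assert_allclose(w, [1.0, 0.5, 1.0, 0.5, 0.25])


class TestPosteriorValidity:
    @pytest.mark.parametrize("seed", range(3))
    def test_all_models_emit_normalized_posteriors(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        ids = [f"g{i:02d}" for i in range(n)]
        V = rng.random((n, 4))
        scores = rng.normal(size=n)
        y = np.where(scores > 0, 1, -1)
        queries = rng.random((10, 4))

        wknn = pc.WeightedKNN(k=3).fit(ids, V, scores)
        pools = pc.wnb_pools(ids[:5], ids[5:10], ids[10:], dict(zip(ids, scores)))
        id_row = {g: V[i] for i, g in enumerate(ids)}
        wnb = pc.WeightedNaiveBayes().fit(
            np.array([id_row[g] for g in pools[0]]), pools[1],
            np.array([id_row[g] for g in pools[2]]), pools[3],
        )
        msvm = pc.MultiLevelSVM(cost_grid=(1.0,)).fit(V, y, np.ones(n))
        for model in (wknn, wnb, msvm):
            post = model.posteriors(queries)
            assert np.all(post >= 0)
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_score_separated_instance_ranks_positives_first(self):
        """When the integrated score separates the hidden classes, every
        base model ranks held-out positives above negatives (AUC > 0.8)."""
        rng = np.random.default_rng(42)
        n = 40
        half = n // 2

        def draw(n_rows, positive):
            # class-specific feature pattern: positives load on features
            # 0-2, negatives on 3-4 (like clade vs background GO anchors)
            hi = rng.normal(0.7, 0.15, size=(n_rows, 5)).clip(0, 1)
            lo = rng.normal(0.1, 0.05, size=(n_rows, 5)).clip(0, 1)
            mask = np.array([1, 1, 1, 0, 0] if positive else [0, 0, 1, 1, 1], bool)
            return np.where(mask, hi, lo)

        V = np.vstack([draw(half, True), draw(half, False)])
        ids = [f"g{i:02d}" for i in range(n)]
        scores = np.concatenate([rng.uniform(0.2, 1.0, half), rng.uniform(-1.0, -0.2, half)])
        test = np.vstack([draw(15, True), draw(15, False)])
        truth = np.array([1] * 15 + [0] * 15)

        def auc(p):
            pos, neg = p[truth == 1], p[truth == 0]
            return np.mean(pos[:, None] > neg[None, :]) + 0.5 * np.mean(pos[:, None] == neg[None, :])

        wknn = pc.WeightedKNN(k=3).fit(ids, V, scores)
        wnb = pc.WeightedNaiveBayes().fit(V[:half], scores[:half], V[half:], -scores[half:])
        msvm = pc.MultiLevelSVM(cost_grid=(1.0,)).fit(
            V, np.where(scores > 0, 1, -1), np.ones(n)
        )
        for model in (wknn, wnb, msvm):
            assert auc(model.posteriors(test)[:, 0]) > 0.8
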