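"""Cross-validation protocol, ranking metrics and parameter search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from slnpm import (
    CVConfig,
    InteractionMatrix,
    LNSConfig,
    PredictionMatrix,
    PropagationConfig,
    auc_score,
    average_precision,
    compute_metrics,
    cross_validate,
    grid_search,
    split_folds,
    topk_recall,
)


def make_interactions(mat):
    mat = np.asarray(mat, dtype=float)
    l, m = mat.shape
    return InteractionMatrix(mat, [f"l{i}" for i in range(l)], [f"m{j}" for j in range(m)])


class TestSplitFolds:
    def random_interactions(self, n_pos, shape=(8, 6), seed=0):
        rng = np.random.default_rng(seed)
        Y = np.zeros(shape)
        flat = rng.choice(shape[0] * shape[1], size=n_pos, replace=False)
        Y[np.unravel_index(flat, shape)] = 1.0
        return make_interactions(Y)

    @pytest.mark.parametrize("n_pos,sizes", [(10, [2] * 5), (11, [2, 2, 2, 2, 3])])
    def test_near_equal_sizes(self, n_pos, sizes):
        folds = split_folds(self.random_interactions(n_pos), 5, seed=1)
        assert sorted(len(f) for f in folds) == sorted(sizes)

    def test_deterministic_given_seed(self):
        Y = self.random_interactions(12)
        a = split_folds(Y, 5, seed=7)
        b = split_folds(Y, 5, seed=7)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_exact_partition(self):
        Y = self.random_interactions(13)
        folds = split_folds(Y, 4, seed=2)
        pairs = sorted(map(tuple, np.vstack(folds)))
        expected = sorted(map(tuple, np.argwhere(Y.Y == 1)))
        assert pairs == expected

    def test_too_few_positives(self):
        with pytest.raises(ValueError, match="positive"):
            split_folds(self.random_interactions(3), 5, seed=0)


class TestMetrics:
    def test_perfect_ranking(self):
        m = compute_metrics([0.9, 0.8, 0.1], [1, 1, 0])
        assert m.auc == 1.0
        assert m.aupr == 1.0
        assert m.rec == m.pr == m.f1 == 1.0

    def test_half_auc_by_pair_enumeration(self):
        # one concordant, one discordant positive-negative pair
        m = compute_metrics([0.9, 0.5, 0.1], [0, 1, 0])
        assert m.auc == pytest.approx(0.5)

    def test_all_ties_give_half_auc(self):
        m = compute_metrics([0.3, 0.3, 0.3, 0.3], [1, 0, 1, 0])
        assert m.auc == pytest.approx(0.5)

    def test_auc_matches_brute_force(self, auc_oracle):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(5, 50))
            scores = rng.choice(rng.random(max(2, n // 3)), size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            assert auc_score(scores, labels) == pytest.approx(
                auc_oracle(scores, labels)
            )

    def test_auc_and_ap_match_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(10, 120))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            assert auc_score(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores)
            )
            assert average_precision(scores, labels) == pytest.approx(
                average_precision_score(labels, scores)
            )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 10.0))
    def test_invariant_under_monotone_transform(self, seed, scale):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        if labels.sum() in (0, 30):
            labels[0], labels[-1] = 0, 1
        m1 = compute_metrics(scores, labels)
        m2 = compute_metrics(np.exp(scale * scores), labels)
        for name in ("auc", "aupr", "rec", "sp", "pr", "acc", "f1"):
            assert getattr(m1, name) == pytest.approx(getattr(m2, name))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0.1, 0.2], [1, 1])

    def test_rank_cutoff_thresholded_metrics(self):
        # 2 positives -> top-2 predicted positive: one hit, one miss
        m = compute_metrics([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        assert m.rec == pytest.approx(0.5)
        assert m.pr == pytest.approx(0.5)
        assert m.sp == pytest.approx(0.5)
        assert m.acc == pytest.approx(0.5)
        assert m.f1 == pytest.approx(0.5)


class TestTopkRecall:
    def test_counts_match_manual_ranking(self):
        P = PredictionMatrix(
            np.array([[0.9, 0.1], [0.8, 0.7]]), ["l0", "l1"], ["m0", "m1"]
        )
        held = {(0, 0), (1, 1)}
        counts = topk_recall(P, held, {(1, 0)}, [1, 2, 3])
        # candidates ranked: (0,0)=0.9, (1,1)=0.7, (0,1)=0.1
        assert counts == {1: 1, 2: 2, 3: 2}

    def test_non_decreasing_in_k(self):
        rng = np.random.default_rng(2)
        P = PredictionMatrix(rng.random((5, 5)), [f"l{i}" for i in range(5)], [f"m{j}" for j in range(5)])
        held = {(0, 0), (2, 3), (4, 4)}
        counts = topk_recall(P, held, set(), [1, 5, 10, 25])
        values = [counts[k] for k in (1, 5, 10, 25)]
        assert values == sorted(values)
        assert counts[25] == 3

    def test_k_exceeding_candidates_rejected(self):
        P = PredictionMatrix(np.ones((2, 2)), ["l0", "l1"], ["m0", "m1"])
        with pytest.raises(ValueError, match="exceeds"):
            topk_recall(P, set(), set(), [5])


class TestCrossValidate:
    def test_mean_is_average_of_folds(self, small_dataset, small_features):
        X_lnc, X_mir = small_features
        cfg = CVConfig(n_folds=3, n_runs=2, seed=5)
        table, means = cross_validate(
            small_dataset.interactions, X_lnc, X_mir, "profile", cv_cfg=cfg
        )
        assert len(table) == 6
        assert means.auc == pytest.approx(table["auc"].mean())
        assert means.aupr == pytest.approx(table["aupr"].mean())

    def test_above_chance_on_planted_structure(self, small_dataset, small_features):
        X_lnc, X_mir = small_features
        table, means = cross_validate(
            small_dataset.interactions,
            X_lnc,
            X_mir,
            "sc",
            cv_cfg=CVConfig(n_folds=5, n_runs=2, seed=1),
        )
        se = table["auc"].std(ddof=1) / np.sqrt(len(table))
        assert means.auc > 0.5 + 3 * se

    def test_deterministic_given_seed(self, small_dataset, small_features):
        X_lnc, X_mir = small_features
        kw = dict(cv_cfg=CVConfig(n_folds=3, n_runs=1, seed=9))
        _, m1 = cross_validate(small_dataset.interactions, X_lnc, X_mir, "sc", **kw)
        _, m2 = cross_validate(small_dataset.interactions, X_lnc, X_mir, "sc", **kw)
        assert m1.as_dict() == m2.as_dict()


class TestGridSearch:
    def test_singleton_grid_equals_direct_cv(self, small_dataset, small_features):
        X_lnc, X_mir = small_features
        Y = small_dataset.interactions
        cv_cfg = CVConfig(n_folds=3, n_runs=1, seed=4)
        table, best = grid_search(
            Y, X_lnc, X_mir, "sc", [0.8], [0.4], [0.25], cv_cfg
        )
        assert len(table) == 1
        _, direct = cross_validate(
            Y, X_lnc, X_mir, "sc",
            LNSConfig(neighbor_ratio=0.8),
            PropagationConfig(alpha=0.4, beta=0.25),
            cv_cfg,
        )
        assert table.iloc[0]["aupr"] == pytest.approx(direct.aupr)
        assert best["neighbor_ratio"] == 0.8

    def test_argmax_dominates_table(self, small_dataset, small_features):
        X_lnc, X_mir = small_features
        table, best = grid_search(
            small_dataset.interactions, X_lnc, X_mir, "profile",
            [0.5, 0.9], [0.2, 0.6], [0.25],
            CVConfig(n_folds=3, n_runs=1, seed=4),
        )
        assert best["aupr"] == pytest.approx(table["aupr"].max())

    def test_empty_grid_rejected(self, small_dataset, small_features):
        X_lnc, X_mir = small_features
        with pytest.raises(ValueError, match="nonempty"):
            grid_search(small_dataset.interactions, X_lnc, X_mir, "sc", [], [0.4], [0.25])
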