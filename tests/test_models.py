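"""Classifier primitives, scoring, evaluation, ranking and explanation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geneprio._nn import CNNClassifier
from geneprio.models import (
    FittedModel,
    LinearModelParams,
    aggregate_importance,
    cross_validate,
    evaluate,
    explain,
    logistic_probability,
    prioritize,
    rank_sum_compare,
    select_eval_groups,
    softmax_score,
    svc_decision,
    train_model,
)
from geneprio.synthetic import simulate_labeled_features
from geneprio.types import ScoredGene


class TestClosedForms:
    def test_zero_weights_give_half(self):
        p = LinearModelParams(np.zeros(3), 0.0)
        assert logistic_probability(p, np.array([1.0, 2, 3])) == 0.5

    def test_log3_margin_gives_three_quarters(self):
        p = LinearModelParams(np.array([np.log(3.0)]), 0.0)
        assert logistic_probability(p, np.array([1.0])) == pytest.approx(0.75)

    def test_class_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = LinearModelParams(rng.normal(size=5), float(rng.normal()))
            x = rng.normal(size=5)
            p1 = logistic_probability(p, x)
            assert p1 + (1 - p1) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("margin,expected", [(2.3, 1), (-0.1, -1), (0.0, 0)])
    def test_svc_signum(self, margin, expected):
        p = LinearModelParams(np.array([1.0]), 0.0)
        assert svc_decision(p, np.array([margin])) == expected

    def test_softmax_score_midpoint_and_log3(self):
        assert softmax_score(1.7, 1.7) == 50.0
        assert softmax_score(0.0, np.log(3.0)) == pytest.approx(75.0)

    def test_softmax_score_stable_at_extremes(self):
        assert softmax_score(0.0, 10_000.0) == 100.0
        assert softmax_score(10_000.0, 0.0) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-500, 500), st.floats(-500, 500))
    def test_score_symmetry_sums_to_100(self, z1, z2):
        assert softmax_score(z1, z2) + softmax_score(z2, z1) == pytest.approx(
            100.0, abs=1e-9)

    def test_logistic_equals_two_class_softmax(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            w, b = rng.normal(size=4), float(rng.normal())
            x = rng.normal(size=4)
            p = logistic_probability(LinearModelParams(w, b), x)
            assert softmax_score(0.0, float(w @ x + b)) / 100 == pytest.approx(
                p, abs=1e-12)


class TestTrainModel:
    def test_separable_toy_is_learned_by_lr(self):
        X = np.array([[0.0, 0], [0, 1], [5, 5], [5, 6]])
        y = np.array([0, 0, 1, 1])
        m = train_model("lr", X, y, fit_scaler=True)
        assert (m.predict(X) == y).all()

    def test_constant_features_warn_and_sit_at_chance(self, caplog):
        X = np.ones((20, 3))
        y = np.array([0, 1] * 10)
        with caplog.at_level("WARNING"):
            m = train_model("lr", X, y, fit_scaler=True)
        assert "constant" in caplog.text.lower()
        assert np.allclose(m.scores(X), m.scores(X)[0])

    def test_nan_rejected(self):
        X = np.array([[1.0, np.nan], [0, 1]])
        with pytest.raises(ValueError, match="NaN"):
            train_model("lr", X, np.array([0, 1]))

    def test_non_binary_labels_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="binary"):
            train_model("lr", X, np.array([0, 1, 2]))

    def test_every_kind_learns_strong_planted_signal(self):
        w = np.zeros(14)
        w[[4, 10, 12]] = 3.0  # nonsynonymous SNPs, expression, QTALs
        X, y, _ = simulate_labeled_features(800, w, seed=0)
        Xtr, ytr, Xte, yte = X[:600], y[:600], X[600:], y[600:]
        for kind in ("lr", "svc", "mlp"):
            m = train_model(kind, Xtr, ytr, seed=0, fit_scaler=True)
            assert evaluate(m, Xte, yte).accuracy >= 0.85, kind


class TestCNN:
    def test_architecture_shrinks_14_to_flat_256(self):
        net = CNNClassifier(n_features=14)
        assert net.flat_width == 256

    def test_learns_well_separated_classes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 14))
        y = rng.integers(0, 2, 400)
        X[y == 1, 3] += 4.0
        X[y == 1, 7] -= 4.0
        m = train_model("cnn", X[:320], y[:320], seed=0, fit_scaler=True,
                        config={"max_epochs": 60})
        assert evaluate(m, X[320:], y[320:]).accuracy >= 0.9

    def test_seeded_training_reproducible(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 14))
        y = (X[:, 0] > 0).astype(int)
        cfg = {"max_epochs": 5}
        a = train_model("cnn", X, y, seed=3, fit_scaler=True, config=cfg)
        b = train_model("cnn", X, y, seed=3, fit_scaler=True, config=cfg)
        assert np.allclose(a.scores(X), b.scores(X), atol=1e-9)


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate(None, None, [0, 1, 1, 0], y_pred=[0, 1, 1, 0])
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1, 1, 1, 1)

    def test_all_positive_on_balanced_labels(self):
        m = evaluate(None, None, [0, 1] * 5, y_pred=[1] * 10)
        assert (m.accuracy, m.precision, m.recall) == (0.5, 0.5, 1.0)

    def test_hand_confusion_matrix(self):
        y = [1] * 3 + [0] * 1 + [1] * 2 + [0] * 4  # TP=3 FP=1 FN=2 TN=4
        yp = [1] * 3 + [1] * 1 + [0] * 2 + [0] * 4
        m = evaluate(None, None, y, y_pred=yp)
        assert m.precision == 0.75
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_matches_confusion_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            y, yp = rng.integers(0, 2, n), rng.integers(0, 2, n)
            m = evaluate(None, None, y, y_pred=yp)
            tp = np.sum((y == 1) & (yp == 1))
            fp = np.sum((y == 0) & (yp == 1))
            fn = np.sum((y == 1) & (yp == 0))
            assert m.accuracy == pytest.approx(np.mean(y == yp))
            assert m.precision == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
            assert m.recall == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
            if m.precision + m.recall:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall))


class TestCrossValidate:
    def test_eight_samples_four_folds_of_two(self):
        X = np.arange(16, dtype=float).reshape(8, 2)
        y = np.array([0, 1] * 4)
        report = cross_validate("lr", X, y, folds=4, seed=0)
        assert len(report.fold_metrics[0]) == 4

    def test_single_setting_grid_equals_plain_cv(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        a = cross_validate("lr", X, y, folds=4, seed=1)
        b = cross_validate("lr", X, y, grid=[{}], folds=4, seed=1)
        assert a.mean_f1 == b.mean_f1

    def test_planted_signal_beats_chance_by_wide_margin(self):
        w = np.zeros(14)
        w[4] = 3.0
        X, y, _ = simulate_labeled_features(400, w, seed=2)
        report = cross_validate("lr", X, y, grid=[{}, {"max_iter": 50}],
                                folds=4, seed=0)
        assert report.mean_f1[report.best_index] >= 0.5 + 0.3

    def test_fold_count_larger_than_class_errors(self):
        X = np.zeros((6, 2))
        y = np.array([0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="folds|class"):
            cross_validate("lr", X, y, folds=4)


class TestPrioritize:
    def _model_scoring(self, scores):
        class Fake(FittedModel):
            def __init__(self):
                super().__init__(kind="lr", estimator=None)

            def scores(self, X):
                return np.asarray(scores)

        return Fake()

    def test_rank_and_credible_flags(self):
        ranked = prioritize(self._model_scoring([30.0, 70.0]), ["a", "b"],
                            np.zeros((2, 14)))
        assert [(g.gene_id, g.rank, g.credible) for g in ranked] == [
            ("b", 1, True), ("a", 2, False)]

    def test_exact_50_is_non_credible(self):
        ranked = prioritize(self._model_scoring([50.0, 50.0]), ["b", "a"],
                            np.zeros((2, 14)))
        assert all(not g.credible for g in ranked)
        # ties broken lexicographically
        assert [g.gene_id for g in ranked] == ["a", "b"]

    def test_empty_candidates(self):
        assert prioritize(self._model_scoring([]), [], np.zeros((0, 14))) == []


class TestSelectEvalGroups:
    def _ranked(self, scores):
        return [ScoredGene(f"g{i}", s, i + 1)
                for i, s in enumerate(sorted(scores, reverse=True))]

    def test_disjoint_full_groups(self):
        ranked = self._ranked(list(np.linspace(99, 51, 30))
                              + list(np.linspace(49, 1, 15)))
        ct, cl, nt = select_eval_groups(ranked, k=10)
        assert len(ct) == len(cl) == len(nt) == 10
        assert not {g.gene_id for g in ct} & {g.gene_id for g in cl}
        assert all(g.credible for g in ct + cl)
        assert all(not g.credible for g in nt)

    def test_few_credible_overlap_documented(self):
        ranked = self._ranked(list(np.linspace(99, 51, 12))
                              + list(np.linspace(49, 1, 15)))
        ct, cl, _ = select_eval_groups(ranked, k=10)
        assert len({g.gene_id for g in ct} & {g.gene_id for g in cl}) == 8

    def test_truncated_non_credible(self):
        ranked = self._ranked(list(np.linspace(99, 51, 30))
                              + list(np.linspace(49, 40, 5)))
        _, _, nt = select_eval_groups(ranked, k=10)
        assert len(nt) == 5


class TestRankSum:
    def test_identical_samples_p_near_one(self):
        _, p = rank_sum_compare([1.0, 2, 3, 4, 5] * 3, [1.0, 2, 3, 4, 5] * 3)
        assert p > 0.9

    def test_complete_separation_u_zero(self):
        u, _ = rank_sum_compare([1.0, 2, 3], [10.0, 11, 12])
        assert u == 0.0

    def test_exact_enumeration_two_vs_two(self):
        # all C(4,2)=6 assignments of ranks to group a; U(a)=0 only once,
        # two-sided exact p = 2/6
        a, b = [1.0, 2.0], [3.0, 4.0]
        _, p = rank_sum_compare(a, b)
        us = []
        vals = [1, 2, 3, 4]
        for combo in itertools.combinations(range(4), 2):
            ga = [vals[i] for i in combo]
            gb = [vals[i] for i in range(4) if i not in combo]
            us.append(sum(1 for x in ga for y in gb if x > y))
        observed = 0
        extreme = sum(1 for u in us if min(u, 4 - u) <= min(observed, 4 - observed)) / len(us)
        assert p == pytest.approx(extreme)  # = 1/3


class TestExplain:
    def test_pure_linear_model_concentrates_on_its_feature(self):
        rng = np.random.default_rng(0)
        background = rng.normal(size=(200, 5))

        def score_fn(X):
            return 10.0 * X[:, 3]

        w = explain(score_fn, background[0], background, n_perturb=500, seed=1)
        assert abs(w[3]) > 5 * max(abs(w[i]) for i in range(5) if i != 3)

    def test_constant_model_gives_zero_weights(self):
        rng = np.random.default_rng(1)
        background = rng.normal(size=(100, 4))
        w = explain(lambda X: np.full(len(X), 42.0), background[0], background,
                    n_perturb=200, seed=0)
        assert np.allclose(w, 0.0, atol=1e-8)

    def test_fixed_seed_identical_weights(self):
        rng = np.random.default_rng(2)
        background = rng.normal(size=(100, 4))

        def f(X):
            return X @ np.array([1.0, -2, 0, 3])

        a = explain(f, background[0], background, n_perturb=300, seed=9)
        b = explain(f, background[0], background, n_perturb=300, seed=9)
        assert np.array_equal(a, b)


class TestAggregateImportance:
    def test_single_explanation_scales_to_100(self):
        out = aggregate_importance([np.array([2.0, 1.0])])
        assert out.tolist() == [100.0, 50.0]

    def test_all_zero_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            out = aggregate_importance([np.zeros(3)])
        assert out.tolist() == [0, 0, 0]
        assert "zero" in caplog.text

    def test_planted_linear_model_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        background = rng.normal(size=(300, 6))

        def f(X):
            return 5.0 * X[:, 2] + 0.5 * X[:, 4]

        ws = [explain(f, background[i], background, n_perturb=200, seed=i)
              for i in range(50)]
        imp = aggregate_importance(ws)
        assert imp.argmax() == 2
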