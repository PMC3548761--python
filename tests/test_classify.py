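import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epiccapo import classify
from epiccapo.classify import ClassifierSpec, ConfusionCounts, TrainingError

from conftest import brute_force_auc


def separable_toy(n=20, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 0.3, size=(n // 2, 2))
    X1 = rng.normal(gap, 0.3, size=(n // 2, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestFitClassifier:
    def test_separable_data_perfect_training_auc(self):
        X, y = separable_toy()
        model = classify.fit_classifier(X, y, ClassifierSpec(seed=0))
        assert classify.auc(y, model.decision_scores(X)) == 1.0

    def test_deterministic_given_seed(self):
        X, y = separable_toy()
        s1 = classify.fit_classifier(X, y, ClassifierSpec(seed=7)).decision_scores(X)
        s2 = classify.fit_classifier(X, y, ClassifierSpec(seed=7)).decision_scores(X)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(TrainingError, match="single class"):
            classify.fit_classifier(X, np.ones(10, dtype=int), ClassifierSpec())

    def test_nan_features_rejected(self):
        X, y = separable_toy()
        X[0, 0] = np.nan
        with pytest.raises(TrainingError, match="non-finite"):
            classify.fit_classifier(X, y, ClassifierSpec())

    def test_training_sign_agreement(self):
        X, y = separable_toy(gap=3.0)
        model = classify.fit_classifier(X, y, ClassifierSpec())
        assert np.mean((model.decision_scores(X) > 0) == (y == 1)) >= 0.9

    def test_fixed_kernel_width(self):
        X, y = separable_toy()
        spec = ClassifierSpec(kernel_width_mode="fixed", kernel_width=0.5)
        model = classify.fit_classifier(X, y, spec)
        assert classify.auc(y, model.decision_scores(X)) == 1.0

    def test_spec_validation(self):
        with pytest.raises(TrainingError):
            ClassifierSpec(cost=-1.0)
        with pytest.raises(TrainingError):
            ClassifierSpec(kernel_width=1.0)  # width without fixed mode
        with pytest.raises(TrainingError):
            ClassifierSpec(kernel="linear")

    def test_save_load_identical_scores(self, tmp_path):
        X, y = separable_toy()
        model = classify.fit_classifier(X, y, ClassifierSpec(seed=3))
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = classify.TrainedModel.load(path)
        np.testing.assert_array_equal(loaded.decision_scores(X), model.decision_scores(X))


class TestDecisionScores:
    def test_permuted_rows_give_permuted_scores(self):
        X, y = separable_toy()
        model = classify.fit_classifier(X, y, ClassifierSpec())
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_array_equal(
            model.decision_scores(X[perm]), model.decision_scores(X)[perm]
        )

    def test_single_row(self):
        X, y = separable_toy()
        model = classify.fit_classifier(X, y, ClassifierSpec())
        assert model.decision_scores(X[0]).shape == (1,)

    def test_dimension_mismatch(self):
        X, y = separable_toy()
        model = classify.fit_classifier(X, y, ClassifierSpec())
        with pytest.raises(ValueError, match="features"):
            model.decision_scores(np.zeros((3, 5)))


class TestConfusion:
    @pytest.mark.parametrize(
        "y, s, expected",
        [
            ([1, 1, 0, 0], [1, 1, -1, -1], (2, 0, 2, 0)),
            ([1, 1, 0, 0], [-1, -1, -1, -1], (0, 0, 2, 2)),
            ([1, 0, 1, 0], [1, 1, -1, -1], (1, 1, 1, 1)),
        ],
    )
    def test_enumerated_counts(self, y, s, expected):
        c = classify.confusion(y, s)
        assert (c.tp, c.fp, c.tn, c.fn) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify.confusion([], [])

    def test_total_matches_input_length(self):
        c = classify.confusion([1, 0, 1], [0.5, 0.5, -0.5])
        assert c.total == 3


class TestComputeMetrics:
    def test_hand_evaluated_formulas(self):
        m = classify.compute_metrics(ConfusionCounts(tp=8, fn=2, tn=6, fp=4))
        assert m.sens == pytest.approx(0.8)
        assert m.spec == pytest.approx(0.6)
        assert m.acc == pytest.approx(0.7)
        assert m.f1 == pytest.approx(16 / 22)

    def test_perfect_counts(self):
        m = classify.compute_metrics(ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
        assert (m.acc, m.sens, m.spec, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_all_positives_missed(self):
        m = classify.compute_metrics(ConfusionCounts(tp=0, fn=5, tn=5, fp=0))
        assert (m.sens, m.spec, m.f1) == (0.0, 1.0, 0.0)

    def test_undefined_sensitivity_raises(self):
        with pytest.raises(ValueError, match="sens"):
            classify.compute_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=1))

    def test_undefined_specificity_raises(self):
        with pytest.raises(ValueError, match="spec"):
            classify.compute_metrics(ConfusionCounts(tp=3, fn=1, tn=0, fp=0))

    @given(
        tp=st.integers(0, 30), fn=st.integers(0, 30),
        tn=st.integers(0, 30), fp=st.integers(0, 30),
    )
    @settings(derandomize=True, max_examples=60)
    def test_accuracy_decomposition(self, tp, fn, tn, fp):
        # acc == (sens*P + spec*N) / (P + N)
        if tp + fn == 0 or tn + fp == 0:
            return
        m = classify.compute_metrics(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))
        P, N = tp + fn, tn + fp
        assert m.acc == pytest.approx((m.sens * P + m.spec * N) / (P + N))


class TestAuc:
    @pytest.mark.parametrize(
        "y, s, expected",
        [
            ([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], 1.0),
            ([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1], 0.75),
            ([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5], 0.5),
        ],
    )
    def test_known_values(self, y, s, expected):
        assert classify.auc(y, s) == pytest.approx(expected)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            classify.auc([1, 1, 1], [0.1, 0.2, 0.3])

    @given(st.data())
    @settings(derandomize=True, max_examples=80)
    def test_matches_pair_counting_oracle(self, data):
        n = data.draw(st.integers(2, 8))
        y = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda v: 0 < sum(v) < len(v)
            )
        )
        s = data.draw(st.lists(st.integers(-3, 3), min_size=n, max_size=n))
        assert classify.auc(y, s) == pytest.approx(brute_force_auc(y, s))

    @given(st.data())
    @settings(derandomize=True, max_examples=40)
    def test_invariant_under_monotone_transform(self, data):
        n = data.draw(st.integers(4, 10))
        y = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda v: 0 < sum(v) < len(v)
            )
        )
        s = np.array(data.draw(st.lists(st.integers(-50, 50), min_size=n, max_size=n)), dtype=float)
        # cubic map: strictly increasing, exact on small integers
        assert classify.auc(y, s**3 + 7.0) == pytest.approx(classify.auc(y, s))


class TestCrossValidate:
    def planted(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 4))
        X[:, 0] += 2.0 * y
        return X, y

    def test_fold_sizes(self):
        X, y = self.planted(100)
        res = classify.cross_validate(X, y, ClassifierSpec(), folds=5, iterations=1, seed=0)
        assert res.fold_count == 5  # n=100 / 5 folds = 20 per fold, checked below via stratification

    def test_iteration_count(self):
        X, y = self.planted(60)
        res = classify.cross_validate(X, y, ClassifierSpec(), folds=5, iterations=20, seed=0)
        assert len(res.per_iteration_auc) == 20
        assert res.mean_auc == pytest.approx(np.mean(res.per_iteration_auc))
        assert res.sd_auc == pytest.approx(np.std(res.per_iteration_auc, ddof=1))

    def test_stratified_fold_balance(self):
        # 30/70 class mix: per-fold class counts differ from n_class/folds by <= 1
        rng = np.random.default_rng(1)
        n = 100
        y = np.array([1] * 30 + [0] * 70)
        X = rng.normal(size=(n, 3))
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, test_idx in skf.split(X, y):
            assert abs(y[test_idx].sum() - 30 / 5) <= 1
            assert abs((y[test_idx] == 0).sum() - 70 / 5) <= 1

    def test_reproducible_with_same_seed(self):
        X, y = self.planted(80)
        r1 = classify.cross_validate(X, y, ClassifierSpec(), folds=5, iterations=3, seed=5)
        r2 = classify.cross_validate(X, y, ClassifierSpec(), folds=5, iterations=3, seed=5)
        assert r1.per_iteration_auc == r2.per_iteration_auc

    def test_seed_changes_folds_but_not_signal(self):
        X, y = self.planted(200)
        r1 = classify.cross_validate(X, y, ClassifierSpec(), folds=5, iterations=5, seed=1)
        r2 = classify.cross_validate(X, y, ClassifierSpec(), folds=5, iterations=5, seed=2)
        assert r1.per_iteration_auc != r2.per_iteration_auc
        spread = 3 * max(r1.sd_auc, 1e-3)
        assert abs(r1.mean_auc - r2.mean_auc) < spread

    def test_too_small_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(TrainingError, match="stratify"):
            classify.cross_validate(X, y, ClassifierSpec(), folds=5)


class TestPairedTtest:
    def test_identical_vectors_p_one(self):
        res = classify.paired_ttest([0.9, 0.8, 0.7], [0.9, 0.8, 0.7])
        assert res.p == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        res = classify.paired_ttest([1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 0.0, 0.0])
        assert res.degenerate
        assert res.p == 0.0 and res.t == np.inf

    def test_regular_path_matches_closed_form(self):
        a = np.array([0.9, 0.8, 0.7])
        b = np.array([0.6, 0.55, 0.35])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy import stats

        p_expected = 2 * stats.t.sf(abs(t_expected), df=len(d) - 1)
        res = classify.paired_ttest(a, b, tails="two")
        assert res.t == pytest.approx(t_expected)
        assert res.p == pytest.approx(p_expected)
        assert not res.degenerate

    def test_one_tailed_halves_symmetric_p(self):
        a, b = [0.9, 0.8, 0.7], [0.6, 0.55, 0.35]
        two = classify.paired_ttest(a, b, tails="two")
        one = classify.paired_ttest(a, b, tails="one")
        assert one.p == pytest.approx(two.p / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify.paired_ttest([0.9], [0.8])
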