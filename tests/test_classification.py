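"""ROC/AUC with brute-force oracle, CV aggregation, DeLong, classifiers."""

import numpy as np
import pandas as pd
import pytest

from dwigrade.classification import (
    CLASSIFIERS,
    FEATURES,
    aggregate_fold_aucs,
    assemble_features,
    cross_validate,
    delong_test,
    parameter_roc,
    roc_curve_auc,
    stratified_kfold,
    train_predict,
    youden_optimal,
)
from dwigrade.synthetic_data import GroupDistributionSpec, sample_cohort_parameters


def brute_force_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(0.5 for p in pos for n in neg if p == n)
    return (wins + ties) / (len(pos) * len(neg))


class TestAssembleFeatures:
    def test_cohort_table_gives_fixed_order_feature_matrix(self):
        c = sample_cohort_parameters(GroupDistributionSpec(), 53, 32, seed=0)
        feats = assemble_features(c)
        assert feats.shape == (85, 4)
        assert tuple(feats.columns[:3]) == FEATURES
        assert feats["label"].sum() == 32

    def test_missing_feature_raises(self):
        df = pd.DataFrame({"d": [1, 2], "kapp": [1, 2], "grade": ["low", "high"]})
        with pytest.raises(ValueError, match="f"):
            assemble_features(df)

    def test_column_order_independent_of_input_order(self):
        df = pd.DataFrame({"kapp": [1.0, 2.0], "f": [0.1, 0.2],
                           "d": [1.0, 1.1], "label": [0, 1]})
        assert tuple(assemble_features(df).columns[:3]) == ("d", "f", "kapp")


class TestStratifiedKfold:
    def test_cohort_fold_counts(self):
        y = np.array([0] * 53 + [1] * 32)
        folds = stratified_kfold(y, k=5, seed=3)
        for _, test_idx in folds:
            assert (y[test_idx] == 0).sum() in (10, 11)
            assert (y[test_idx] == 1).sum() in (6, 7)
        all_test = np.sort(np.concatenate([t for _, t in folds]))
        np.testing.assert_array_equal(all_test, np.arange(85))

    def test_same_seed_reproducible(self):
        y = np.array([0] * 20 + [1] * 15)
        a = stratified_kfold(y, k=5, seed=9)
        b = stratified_kfold(y, k=5, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(te1, te2)

    def test_class_smaller_than_k_raises(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([0] * 10 + [1] * 3), k=5)


class TestTrainPredict:
    def _separable(self, rng, n=40):
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(0, 0.3, (n, 3)) + y[:, None] * 5.0
        return x, y

    @pytest.mark.parametrize("kind", CLASSIFIERS)
    def test_separable_clusters_reach_auc_one(self, kind, rng):
        x, y = self._separable(rng)
        scores = train_predict(kind, x, y, x, seed=0)
        assert roc_curve_auc(scores, y).auc == 1.0

    @pytest.mark.parametrize("kind", CLASSIFIERS)
    def test_permuted_labels_near_chance(self, kind, rng):
        x = rng.normal(0, 1, (200, 3))
        y = rng.permutation(np.repeat([0, 1], 100))
        x_test = rng.normal(0, 1, (200, 3))
        y_test = rng.permutation(np.repeat([0, 1], 100))
        scores = train_predict(kind, x, y, x_test, seed=1)
        assert roc_curve_auc(scores, y_test).auc == pytest.approx(0.5, abs=0.1)

    def test_logistic_on_label_feature(self):
        x = np.array([[0.0], [1.0]] * 20)
        y = np.tile([0, 1], 20)
        probs = train_predict("LG", x, y, np.array([[0.0], [1.0]]), seed=0)
        assert probs[0] < 0.5 < probs[1]

    def test_single_class_training_fold_raises(self):
        with pytest.raises(ValueError):
            train_predict("LG", np.ones((5, 2)), np.zeros(5), np.ones((2, 2)))


class TestRoc:
    def test_perfectly_separated(self):
        roc = roc_curve_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auc == 1.0
        assert roc.youden_index == 1.0

    def test_partially_inverted_quartet(self):
        # pairwise: only (0.8 > 0.2) of 4 positive-negative pairs
        roc = roc_curve_auc([0.9, 0.2, 0.8, 0.1], [0, 0, 1, 1])
        assert roc.auc == 0.25

    def test_all_tied_scores_give_half(self):
        roc = roc_curve_auc([0.5] * 6, [0, 0, 0, 1, 1, 1])
        assert roc.auc == 0.5

    def test_auc_equals_brute_force_concordance(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = np.round(rng.normal(0, 1, n) + 0.8 * y, 1)  # induces ties
            roc = roc_curve_auc(scores, y)
            assert roc.auc == pytest.approx(brute_force_auc(scores, y),
                                            rel=1e-12)

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = rng.normal(0, 1, 60)
        assert roc_curve_auc(s, y).auc == pytest.approx(
            roc_auc_score(y, s), rel=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_auc([0.1, 0.9], [1, 1])


class TestYouden:
    def test_identity_holds_exactly(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, 30)
            y[:2] = [0, 1]
            roc = roc_curve_auc(rng.normal(0, 1, 30), y)
            assert roc.youden_index == roc.sens_at_youden + roc.spec_at_youden - 1

    def test_random_scores_low_youden(self, rng):
        y = np.repeat([0, 1], 500)
        roc = roc_curve_auc(rng.normal(0, 1, 1000), y)
        assert roc.youden_index < 0.15

    def test_tie_broken_toward_higher_specificity(self):
        # thresholds 0.3 and 0.7 both give J = 0.5; 0.7 is more specific
        roc = roc_curve_auc([0.1, 0.3, 0.7, 0.9], [0, 1, 0, 1])
        assert roc.spec_at_youden == 1.0


class TestCvAggregation:
    def test_mean_is_exact_arithmetic_mean(self):
        mean, lo, hi = aggregate_fold_aucs([0.962, 0.933, 0.917, 0.766, 0.933])
        assert mean == pytest.approx(np.mean([0.962, 0.933, 0.917, 0.766, 0.933]))
        assert round(mean, 3) == 0.902
        assert 0 <= lo <= mean <= hi <= 1

    def test_equal_folds_give_degenerate_interval(self):
        mean, lo, hi = aggregate_fold_aucs([0.8] * 5)
        assert mean == lo == hi == 0.8

    def test_cross_validate_contract(self):
        c = sample_cohort_parameters(GroupDistributionSpec(), 30, 20, seed=4)
        cv = cross_validate(assemble_features(c), "LG", k=5, seed=4)
        assert len(cv.fold_aucs) == 5
        assert cv.mean_auc == pytest.approx(np.mean(cv.fold_aucs), rel=1e-15)
        assert cv.youden_index == pytest.approx(
            cv.sens_at_youden + cv.spec_at_youden - 1, abs=1e-12)

    def test_cross_validate_deterministic(self):
        c = sample_cohort_parameters(GroupDistributionSpec(), 15, 10, seed=6)
        feats = assemble_features(c)
        a = cross_validate(feats, "RF", k=5, seed=6)
        b = cross_validate(feats, "RF", k=5, seed=6)
        assert a.fold_aucs == b.fold_aucs


class TestDelong:
    def test_identical_scores_give_p_one(self, rng):
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        s = rng.normal(0, 1, 20)
        res = delong_test(s, s.copy(), y)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_placement_auc_matches_roc_auc(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        sa, sb = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
        res = delong_test(sa, sb, y)
        assert res.auc_a == pytest.approx(roc_curve_auc(sa, y).auc, rel=1e-12)
        assert res.auc_b == pytest.approx(roc_curve_auc(sb, y).auc, rel=1e-12)

    def test_variance_agrees_with_jackknife_on_small_instance(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        sa = rng.normal(0, 1, 8) + y
        sb = 0.7 * sa + rng.normal(0, 0.5, 8)
        res = delong_test(sa, sb, y)

        thetas = []
        for i in range(8):
            idx = np.delete(np.arange(8), i)
            thetas.append(roc_curve_auc(sa[idx], y[idx]).auc
                          - roc_curve_auc(sb[idx], y[idx]).auc)
        thetas = np.asarray(thetas)
        jack = (len(thetas) - 1) / len(thetas) * np.sum(
            (thetas - thetas.mean()) ** 2)
        assert res.var_diff == pytest.approx(jack, rel=0.2)


class TestNullBehaviour:
    def test_all_classifiers_near_chance_on_permuted_labels(self):
        rng = np.random.default_rng(77)
        n = 500
        table = pd.DataFrame({
            "d": rng.normal(1.3, 0.2, n), "f": rng.normal(0.22, 0.06, n),
            "kapp": rng.normal(0.75, 0.13, n),
            "label": rng.permutation(np.repeat([0, 1], n // 2)),
        })
        feats = assemble_features(table)
        for kind in CLASSIFIERS:
            cv = cross_validate(feats, kind, k=5, seed=77)
            assert 0.35 <= cv.mean_auc <= 0.65, kind

    def test_lg_beats_single_f_feature_on_synthetic_cohort(self):
        c = sample_cohort_parameters(GroupDistributionSpec(), 53, 32, seed=2024)
        feats = assemble_features(c)
        lg = cross_validate(feats, "LG", k=5, seed=2024)
        f_auc = parameter_roc(c["f"].to_numpy(),
                              feats["label"].to_numpy())[0].auc
        assert lg.mean_auc > f_auc

    def test_parameter_roc_auto_orientation(self, rng):
        y = np.repeat([0, 1], 50)
        v = rng.normal(0, 1, 100) - 1.5 * y  # lower value in class 1
        roc, sign = parameter_roc(v, y)
        assert sign == -1 and roc.auc > 0.5
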