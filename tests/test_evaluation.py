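import numpy as np
import pytest
from scipy.stats import rankdata

import aophmm
from aophmm import (
    ConfusionCounts,
    FeatureTable,
    HyperParams,
    PipelineConfig,
    auc,
    independent_test,
    jackknife_cv,
    kfold_cv,
    make_separable_table,
    metrics,
)


def rank_statistic_auc(y, scores):
    """Tie-corrected Mann-Whitney estimator of the AUC."""
    ranks = rankdata(scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert (m.sen, m.spe, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_perfectly_wrong_classifier(self):
        m = metrics(ConfusionCounts(tp=0, tn=0, fp=10, fn=10))
        assert m.acc == 0.0
        assert m.mcc == -1.0

    def test_hand_computed_case(self):
        # TP=50 TN=40 FP=10 FN=0:
        # MCC = (50*40 - 0*10) / sqrt(50 * 50 * 60 * 40)
        m = metrics(ConfusionCounts(tp=50, tn=40, fp=10, fn=0))
        expected = 2000.0 / np.sqrt(50 * 50 * 60 * 40)
        assert m.mcc == pytest.approx(expected, abs=1e-12)
        assert m.sen == 1.0
        assert m.spe == pytest.approx(0.8)
        assert m.acc == pytest.approx(0.9)

    def test_mcc_symmetry_under_class_swap(self):
        a = metrics(ConfusionCounts(tp=30, tn=12, fp=5, fn=8))
        b = metrics(ConfusionCounts(tp=12, tn=30, fp=8, fn=5))
        assert a.mcc == pytest.approx(b.mcc)
        assert a.acc == pytest.approx(b.acc)
        assert a.sen == pytest.approx(b.spe)

    def test_zero_denominator_conventions(self):
        m = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m.mcc == 0.0
        assert not m.sen_defined and m.sen == 0.0
        assert m.spe_defined and m.spe == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(tp=0, tn=0, fp=0, fn=0))

    def test_mcc_bounded(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert -1.0 <= m.mcc <= 1.0
            assert 0.0 <= m.acc <= 1.0


class TestAuc:
    def test_perfect_ranking(self):
        labels = np.array(["AOP"] * 3 + ["non-AOP"] * 3)
        value, roc = auc(labels, np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0]))
        assert value == 1.0
        np.testing.assert_array_equal(roc[0], [0, 0])
        np.testing.assert_array_equal(roc[-1], [1, 1])

    def test_constant_scores_give_half(self):
        labels = np.array(["AOP"] * 4 + ["non-AOP"] * 4)
        value, _ = auc(labels, np.zeros(8))
        assert value == pytest.approx(0.5)

    def test_matches_rank_statistic(self, rng):
        labels = np.where(rng.uniform(size=200) < 0.4, "AOP", "non-AOP")
        scores = rng.standard_normal(200)
        scores[rng.uniform(size=200) < 0.3] = 0.0  # force ties
        value, _ = auc(labels, scores)
        y = (labels == "AOP").astype(int)
        assert value == pytest.approx(rank_statistic_auc(y, scores), abs=1e-12)

    def test_roc_monotone(self, rng):
        labels = np.where(rng.uniform(size=80) < 0.5, "AOP", "non-AOP")
        _, roc = auc(labels, rng.standard_normal(80))
        assert np.all(np.diff(roc[:, 0]) >= 0)
        assert np.all(np.diff(roc[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array(["AOP", "AOP"]), np.array([1.0, 2.0]))


FIXED = PipelineConfig(params=HyperParams(C=8.0, gamma=0.1))


class TestKfoldCv:
    def test_separable_data_high_accuracy(self):
        table = make_separable_table(n=60, d=4, margin=8.0, seed=0)
        report = kfold_cv(FIXED, table, k=5, seed=0)
        assert report.acc == 1.0
        assert report.auc == 1.0

    def test_pooled_acc_identity(self):
        table = make_separable_table(n=50, d=4, margin=1.0, seed=1)
        report = kfold_cv(FIXED, table, k=5, seed=1)
        c = report.counts
        assert report.acc == (c.tp + c.tn) / c.n
        assert c.n == table.n_samples
        fold_counts = [f["counts"] for f in report.per_fold]
        assert sum(fc["tp"] + fc["tn"] for fc in fold_counts) == c.tp + c.tn

    def test_determinism(self):
        table = make_separable_table(n=40, d=3, margin=1.5, seed=2)
        r1 = kfold_cv(FIXED, table, k=4, seed=9)
        r2 = kfold_cv(FIXED, table, k=4, seed=9)
        assert r1.to_dict() == r2.to_dict()

    def test_k_equals_n_matches_jackknife(self):
        table = make_separable_table(n=16, d=3, margin=2.0, seed=3)
        # non-stratifiable at k=n; compare the underlying leave-one-out
        jk = jackknife_cv(FIXED, table, seed=0)
        assert jk.counts.n == 16
        assert len(jk.per_fold) == 16
        assert all(f["test_size"] == 1 for f in jk.per_fold)

    def test_more_folds_than_samples_rejected(self):
        table = make_separable_table(n=6, d=2, margin=2.0, seed=4)
        with pytest.raises(ValueError):
            kfold_cv(FIXED, table, k=10, seed=0)

    def test_presplit_smote_warns_about_leakage(self):
        table = make_separable_table(n=40, d=3, margin=2.0, seed=5)
        table.labels[:14] = "non-AOP"  # imbalance to 6 AOP / 34 non-AOP
        cfg = PipelineConfig(
            params=HyperParams(C=8.0, gamma=0.1),
            smote_k=3,
            resample_before_split=True,
        )
        with pytest.warns(UserWarning, match="leak"):
            report = kfold_cv(cfg, table, k=4, seed=0)
        assert report.counts.n > table.n_samples  # synthetic rows evaluated


class TestJackknife:
    def test_three_sample_protocol_structure(self):
        table = make_separable_table(n=12, d=2, margin=10.0, seed=6)
        report = jackknife_cv(FIXED, table, seed=0)
        assert len(report.per_fold) == 12
        assert report.acc == 1.0

    def test_separable_accuracy_perfect(self):
        table = make_separable_table(n=20, d=3, margin=10.0, seed=7)
        report = jackknife_cv(FIXED, table, seed=0)
        assert report.acc == 1.0


class TestIndependentTest:
    def test_resubstitution_on_separable_fit(self):
        table = make_separable_table(n=40, d=4, margin=8.0, seed=8)
        with pytest.warns(UserWarning, match="train and test"):
            report = independent_test(FIXED, table, table, seed=0)
        assert report.acc == 1.0

    def test_train_test_generalization(self):
        train_t = make_separable_table(n=80, d=4, margin=6.0, seed=9)
        test_t = make_separable_table(n=40, d=4, margin=6.0, seed=10)
        test_t = FeatureTable(
            X=test_t.X, names=test_t.names,
            ids=[f"t_{i}" for i in range(40)], labels=test_t.labels,
        )
        report = independent_test(FIXED, train_t, test_t, seed=0)
        assert report.acc > 0.9
        assert report.protocol == "independent"

    def test_registry_mismatch_rejected(self):
        train_t = make_separable_table(n=20, d=3, margin=3.0, seed=11)
        test_t = make_separable_table(n=20, d=4, margin=3.0, seed=12)
        with pytest.raises(aophmm.RegistryMismatchError):
            independent_test(FIXED, train_t, test_t, seed=0)


class TestLeakageCanary:
    def test_test_fold_sentinel_never_reaches_training_state(self):
        """Plant an extreme sentinel in rows of exactly one test fold and
        verify every training-time fitted statistic of that fold's model
        (ANOVA selection, SMOTE count, scaler moments) is unchanged."""
        from sklearn.model_selection import StratifiedKFold

        rng = np.random.default_rng(0)
        n, d = 60, 12
        X = rng.standard_normal((n, d))
        X[: n // 3, :4] += 2.5
        labels = np.array(["AOP"] * (n // 3) + ["non-AOP"] * (n - n // 3))
        table = FeatureTable(
            X=X, names=[f"f{i}" for i in range(d)],
            ids=[f"s{i}" for i in range(n)], labels=labels,
        )
        cfg = PipelineConfig(
            select_k=6, smote=True, smote_k=3,
            params=HyperParams(C=2.0, gamma=0.1),
        )
        k, seed = 4, 3
        y = table.binary_labels()
        folds = list(StratifiedKFold(k, shuffle=True, random_state=seed).split(X, y))
        target_fold, (_, test_idx) = 1, folds[1]

        clean = kfold_cv(cfg, table, k=k, seed=seed)
        poisoned_X = X.copy()
        poisoned_X[test_idx] = 1e6  # sentinel visible only in fold 1's test set
        poisoned = FeatureTable(
            X=poisoned_X, names=table.names, ids=table.ids, labels=labels
        )
        dirty = kfold_cv(cfg, poisoned, k=k, seed=seed)

        f_clean = clean.per_fold[target_fold]
        f_dirty = dirty.per_fold[target_fold]
        assert f_clean["selected_names"] == f_dirty["selected_names"]
        assert f_clean["f_scores_sum"] == f_dirty["f_scores_sum"]
        assert f_clean["n_synthetic"] == f_dirty["n_synthetic"]
        np.testing.assert_array_equal(
            f_clean["scaler_mean"], f_dirty["scaler_mean"]
        )
        np.testing.assert_array_equal(
            f_clean["scaler_scale"], f_dirty["scaler_scale"]
        )
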