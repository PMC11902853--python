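"""Normality-gated tests, Mann-Whitney feature screen, stratified split
and SVM metrics against closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from grangernet.stats import (
    Partition,
    classify_features,
    group_test_table,
    normality_gated_test,
    order_sweep,
    select_features,
    split_stratified,
    train_eval_svm,
)


class TestNormalityGatedTest:
    def test_identical_samples_p_one(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        r = normality_gated_test(a, a.copy())
        assert r.p_value == pytest.approx(1.0)
        assert r.direction == 0

    def test_complete_separation_exact_u_tail(self):
        # forced U branch (one sample constant); complete separation of
        # 10 vs 10 has exact two-sided p = 2 / C(20, 10)
        a = np.ones(10)
        b = np.linspace(2.0, 3.0, 10)
        r = normality_gated_test(a, b)
        assert r.test_used == "mann-whitney"
        assert r.warnings
        assert r.p_value == pytest.approx(2 / comb(20, 10), rel=1e-6)
        assert r.direction == 1

    def test_gaussian_samples_take_t_branch(self):
        rng = np.random.default_rng(0)
        r = normality_gated_test(rng.standard_normal(40), rng.standard_normal(40))
        assert r.test_used == "t-test"

    def test_type_i_rate_near_alpha(self):
        """Equal-mean Gaussian samples: rejection rate ~ alpha."""
        n_sig = 0
        n_rep = 200
        rng = np.random.default_rng(1)
        for _ in range(n_rep):
            a, b = rng.standard_normal(30), rng.standard_normal(30)
            if normality_gated_test(a, b).p_value < 0.05:
                n_sig += 1
        assert 0.02 <= n_sig / n_rep <= 0.09

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            normality_gated_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSelectFeatures:
    def test_null_selection_fraction_near_alpha(self):
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((40, 100))
            labels = np.array(["a"] * 20 + ["b"] * 20)
            sel = select_features(x, labels, alpha=0.05)
            rates.append(sel.mask.mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.03)

    def test_separated_feature_always_selected(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 5))
        labels = np.array(["a"] * 15 + ["b"] * 15)
        x[labels == "b", 3] += 10
        sel = select_features(x, labels)
        assert sel.mask[3]

    def test_alpha_zero_selects_nothing_and_pipeline_aborts(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.standard_normal((20, 4)))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        assert select_features(x.to_numpy(), labels, alpha=0.0).n_selected == 0
        with pytest.raises(ValueError, match="no feature passed"):
            classify_features(x, labels, alpha=0.0, split_seed=0)


class TestSplit:
    def test_cohort_arithmetic_34_14(self):
        labels = np.array(["TLE"] * 34 + ["HC"] * 14)
        part = split_stratified(labels, 0.7, seed=0)
        tr, va = labels[part.train_idx], labels[part.val_idx]
        assert (tr == "TLE").sum() == 24 and (tr == "HC").sum() == 10
        assert (va == "TLE").sum() == 10 and (va == "HC").sum() == 4

    def test_partition_disjoint_exhaustive(self):
        labels = np.array(["a"] * 9 + ["b"] * 7)
        part = split_stratified(labels, 0.6, seed=1)
        joined = np.concatenate([part.train_idx, part.val_idx])
        assert sorted(joined) == list(range(16))

    def test_full_train_frac_rejected(self):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError):
            split_stratified(labels, 1.0, seed=0)
        with pytest.raises(ValueError, match="empty on one side"):
            split_stratified(labels, 0.95, seed=0)

    def test_seeded_determinism(self):
        labels = np.array(["a"] * 10 + ["b"] * 10)
        p1 = split_stratified(labels, 0.7, seed=5)
        p2 = split_stratified(labels, 0.7, seed=5)
        assert np.array_equal(p1.train_idx, p2.train_idx)


class TestSVM:
    def _toy(self, seed=0, n=40, sep=3.0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, 2)) * 0.1
        labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        x[labels == "b"] += sep
        return x, labels

    def test_perfect_separation_all_metrics_one(self):
        x, labels = self._toy()
        part = split_stratified(labels, 0.7, seed=0)
        rep = train_eval_svm(x, labels, part, seed=0)
        assert rep.accuracy == rep.kappa == rep.roc_auc == 1.0

    def test_permuted_labels_auc_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((40, 5))
            labels = np.array(["a"] * 20 + ["b"] * 20)
            part = split_stratified(labels, 0.7, seed=seed)
            aucs.append(train_eval_svm(x, labels, part, seed=seed).roc_auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_metric_identities_against_confusion_matrix(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((60, 4))
        labels = np.array(["a"] * 30 + ["b"] * 30)
        x[labels == "b", 0] += 1.2
        part = split_stratified(labels, 0.7, seed=2)
        rep = train_eval_svm(x, labels, part, seed=2)
        # recompute kappa and f1 from an explicit confusion matrix
        from sklearn.svm import SVC

        tr, va = part.train_idx, part.val_idx
        mu, sd = x[tr].mean(0), x[tr].std(0)
        xs = (x - mu) / sd
        y = (labels == "b").astype(int)
        clf = SVC(kernel="linear", C=1.0, random_state=2).fit(xs[tr], y[tr])
        pred = clf.predict(xs[va])
        tp = int(((pred == 1) & (y[va] == 1)).sum())
        fp = int(((pred == 1) & (y[va] == 0)).sum())
        fn = int(((pred == 0) & (y[va] == 1)).sum())
        tn = int(((pred == 0) & (y[va] == 0)).sum())
        n = tp + fp + fn + tn
        po = (tp + tn) / n
        pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
        assert rep.kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-12)
        p = tp / (tp + fp) if tp + fp else 0
        r = tp / (tp + fn) if tp + fn else 0
        assert rep.f1 == pytest.approx(2 * p * r / (p + r) if p + r else 0, abs=1e-12)
        assert rep.precision == pytest.approx(p) and rep.recall == pytest.approx(r)

    def test_no_leakage_from_validation_rows(self):
        """Poisoning validation rows must not change training-side feature
        selection or standardization (leakage-free default protocol)."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal((40, 20))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        x[labels == "b", :3] += 2.0
        part = split_stratified(labels, 0.7, seed=3)
        sel_clean = select_features(x[part.train_idx], labels[part.train_idx])
        x_poison = x.copy()
        x_poison[part.val_idx] = 1e6  # absurd values, training rows untouched
        sel_poison = select_features(x_poison[part.train_idx], labels[part.train_idx])
        assert np.array_equal(sel_clean.mask, sel_poison.mask)
        assert np.allclose(sel_clean.p_values, sel_poison.p_values)
        mu_clean = x[part.train_idx].mean(0)
        mu_poison = x_poison[part.train_idx].mean(0)
        assert np.array_equal(mu_clean, mu_poison)


class TestOrderSweep:
    def _feature_fn(self, seed=6):
        rng = np.random.default_rng(seed)
        labels = np.array(["a"] * 14 + ["b"] * 20)

        def fn(order):
            rng_o = np.random.default_rng(seed * 100 + order)
            x = rng_o.standard_normal((34, 10))
            x[labels == "b", 0] += 4.0 / order
            x[labels == "b", 1] += 2.0
            return pd.DataFrame(x)

        return fn, labels

    def test_single_order_single_row(self):
        fn, labels = self._feature_fn()
        tab = order_sweep(fn, labels, orders=[3], split_seed=0)
        assert len(tab) == 1 and tab.loc[0, "order"] == 3
        assert {"accuracy", "roc_auc", "kappa", "n_features_selected"} <= set(tab.columns)

    def test_fixed_seeds_bitwise_reproducible(self):
        fn, labels = self._feature_fn()
        t1 = order_sweep(fn, labels, orders=[1, 2, 3], split_seed=4)
        t2 = order_sweep(fn, labels, orders=[1, 2, 3], split_seed=4)
        pd.testing.assert_frame_equal(t1, t2)


def test_group_test_table_layout():
    rng = np.random.default_rng(7)
    feats = pd.DataFrame(rng.standard_normal((20, 3)), columns=["f1", "f2", "f3"])
    labels = ["a"] * 10 + ["b"] * 10
    tab = group_test_table(feats, labels, "a", "b")
    assert list(tab["feature"]) == ["f1", "f2", "f3"]
    assert set(tab["test"]) <= {"t-test", "mann-whitney"}
    assert ((0 <= tab["p_value"]) & (tab["p_value"] <= 1)).all()
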