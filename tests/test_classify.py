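import numpy as np
import pytest
from sklearn.naive_bayes import BernoulliNB, GaussianNB

from hetmix.classify import (
    MixedNaiveBayes,
    ModelSpec,
    cross_validate,
    lasso_select,
    pooled_metrics,
    select_for_combined,
)
from hetmix.prep import EXPRESSION, MUTATION, combine_features

from conftest import make_planted_dataset

FAST = dict(cv=3, n_cs=6)


class TestLassoSelect:
    def test_planted_support_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            ds = make_planted_dataset(n_samples=80, n_features=100, n_informative=5, effect=3.0, seed=seed)
            X = np.log2(ds.X + 1)
            sel, coefs = lasso_select(X, ds.y, np.random.default_rng(seed), feature_ids=ds.feature_ids, **FAST)
            assert set(sel) <= set(ds.feature_ids)
            assert len(coefs) == len(sel)
            hits += set(ds.feature_ids[:5]) <= set(sel)
        assert hits >= 9

    def test_null_labels_shrink_selection(self):
        sizes = []
        for seed in range(10):
            g = np.random.default_rng(seed)
            X = g.normal(size=(60, 100))
            y = np.repeat([0, 1], 30)
            g.shuffle(y)
            sel, _ = lasso_select(X, y, g, fallback_k=None, **FAST)
            sizes.append(len(sel))
        assert np.median(sizes) <= 5

    def test_empty_selection_falls_back_to_univariate_topk(self):
        g = np.random.default_rng(0)
        X = g.normal(size=(40, 20)) * 1e-3  # no usable signal
        y = np.repeat([0, 1], 20)
        sel, _ = lasso_select(X, y, g, fallback_k=7, **FAST)
        assert 0 < len(sel) <= 7

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            lasso_select(np.ones((10, 3)), np.zeros(10, dtype=int), np.random.default_rng(0))


class TestCombinedSelection:
    def test_both_datatypes_represented_when_both_carry_signal(self):
        hits = 0
        for seed in range(10):
            m = make_planted_dataset(n_samples=100, n_features=40, n_informative=4, effect=3.0, set_kind="M", seed=seed)
            e = make_planted_dataset(
                n_features=40, n_informative=4, effect=3.0, set_kind="E", seed=seed + 500, labels=m.y
            )
            em = combine_features(m, e)
            X = em.X.copy()
            expr = em.feature_types == EXPRESSION
            X[:, expr] = np.log2(X[:, expr] + 1)
            sel, _ = select_for_combined(
                X, em.y, em.feature_types, np.random.default_rng(seed), feature_ids=em.feature_ids, **FAST
            )
            types = {t for f, t in zip(em.feature_ids, em.feature_types) if f in sel}
            hits += types == {MUTATION, EXPRESSION}
        assert hits >= 9

    def test_union_of_disjoint_blocks(self):
        g = np.random.default_rng(1)
        y = np.repeat([0, 1], 20)
        X = np.hstack([np.tile(y[:, None], (1, 2)).astype(float), g.normal(size=(40, 3))])
        types = np.array([MUTATION, MUTATION, EXPRESSION, EXPRESSION, EXPRESSION], dtype=object)
        ids = ["m1", "m2", "e1", "e2", "e3"]
        sel, _ = select_for_combined(X, y, types, g, feature_ids=ids, **FAST, fallback_k=None)
        assert set(sel) <= set(ids)
        assert {"m1", "m2"} & set(sel)


class TestMixedNaiveBayes:
    def test_reduces_to_gaussian_nb_on_pure_expression(self):
        ds = make_planted_dataset(n_samples=60, n_features=8, seed=4)
        clf = MixedNaiveBayes(ds.feature_types).fit(ds.X, ds.y)
        ref = GaussianNB().fit(ds.X, ds.y)
        assert np.allclose(clf.predict_proba(ds.X), ref.predict_proba(ds.X), atol=1e-9)

    def test_reduces_to_bernoulli_nb_on_pure_mutation(self):
        ds = make_planted_dataset(n_samples=60, n_features=8, set_kind="M", seed=4)
        clf = MixedNaiveBayes(ds.feature_types).fit(ds.X, ds.y)
        ref = BernoulliNB(alpha=1.0).fit(ds.X, ds.y)
        assert np.allclose(clf.predict_proba(ds.X), ref.predict_proba(ds.X), atol=1e-9)

    def test_mixed_blocks_combine_both_likelihoods(self):
        m = make_planted_dataset(n_samples=80, n_features=6, n_informative=3, set_kind="M", seed=5)
        e = make_planted_dataset(n_features=6, n_informative=3, set_kind="E", seed=6, labels=m.y)
        em = combine_features(m, e)
        clf = MixedNaiveBayes(em.feature_types).fit(em.X, em.y)
        acc = (clf.predict(em.X) == em.y).mean()
        assert acc > 0.8


class TestPooledMetrics:
    def test_confusion_matrix_identity(self, rng):
        y = rng.integers(0, 2, 200)
        pred = rng.integers(0, 2, 200)
        m = pooled_metrics(y, pred, rng.random(200))
        assert m["accuracy"] == pytest.approx(100 * (m["tp"] + m["tn"]) / 200)
        assert m["sensitivity"] == pytest.approx(m["tp"] / (m["tp"] + m["fn"]))
        assert m["specificity"] == pytest.approx(m["tn"] / (m["tn"] + m["fp"]))

    def test_constant_classifier_on_balanced_labels(self):
        y = np.repeat([0, 1], 25)
        m = pooled_metrics(y, np.zeros(50, dtype=int), np.zeros(50))
        assert m["accuracy"] == pytest.approx(50.0)
        assert m["auc"] == pytest.approx(0.5)

    def test_auc_invariant_under_monotone_score_rescaling(self, rng):
        y = rng.integers(0, 2, 100)
        scores = rng.normal(size=100) + y
        a = pooled_metrics(y, y, scores)["auc"]
        b = pooled_metrics(y, y, np.exp(3 * scores + 7))["auc"]
        assert a == pytest.approx(b)


class TestCrossValidate:
    SPECS = [
        ModelSpec(method="naive_bayes", lasso_cv=3, lasso_n_cs=6),
        ModelSpec(method="svm_rbf", svm_C=(10,), svm_gamma=(0.01, 0.25), lasso_cv=3, lasso_n_cs=6),
        ModelSpec(method="random_forest", rf_n_trees=(200,), rf_min_node=(2, 5), lasso_cv=3, lasso_n_cs=6),
    ]

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.method)
    def test_overwhelming_signal_is_learned(self, spec):
        ds = make_planted_dataset(n_samples=150, n_features=30, n_informative=5, effect=6.0, seed=1)
        res = cross_validate(ds, spec, n_folds=5, n_runs=1, rng=0)
        assert res.accuracy >= 95.0
        assert res.auc >= 0.98

    def test_same_seed_reproduces_results(self):
        ds = make_planted_dataset(n_samples=60, n_features=15, seed=2)
        spec = ModelSpec(method="naive_bayes", lasso_cv=3, lasso_n_cs=6)
        a = cross_validate(ds, spec, n_folds=5, n_runs=2, rng=7)
        b = cross_validate(ds, spec, n_folds=5, n_runs=2, rng=7)
        assert a.per_run.equals(b.per_run)
        assert a.selected.equals(b.selected)

    def test_selected_features_recorded_per_fold(self):
        ds = make_planted_dataset(n_samples=60, n_features=15, seed=3)
        spec = ModelSpec(method="naive_bayes", lasso_cv=3, lasso_n_cs=6)
        res = cross_validate(ds, spec, n_folds=5, n_runs=1, rng=1)
        assert set(res.selected["fold"]) == set(range(5))
        assert set(res.selected["feature"]) <= set(ds.feature_ids)

    def test_single_class_dataset_rejected(self):
        ds = make_planted_dataset(n_samples=40, n_features=10, seed=4)
        ds.y[:] = 1
        with pytest.raises(ValueError):
            cross_validate(ds, ModelSpec(method="naive_bayes"), rng=0)
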