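"""Yeo-Johnson scaling, RMI forward selection, classifiers, rankings."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.preprocessing import PowerTransformer

from saccadometry.classify import (
    CohortDataset,
    ResidualMIForwardSelector,
    YeoJohnsonScaler,
    make_forest,
    make_logistic_pipeline,
    mutual_information,
    rank_features,
    train_forest,
    train_logistic,
)


def xor_cohort(rng, n=200, n_noise=6, parent_prevalence=0.3):
    """Binary XOR label with one marginally visible parent.

    x2 ~ Bernoulli(parent_prevalence) makes P(y|x1) differ from 1/2 (x1
    carries marginal signal) while P(y=1|x2) = 1/2 exactly: the second
    parent is invisible to marginal screening and only reachable through
    the model residual.
    """
    x1 = (rng.uniform(size=n) < 0.5).astype(float)
    x2 = (rng.uniform(size=n) < parent_prevalence).astype(float)
    y = np.logical_xor(x1, x2).astype(int)
    noise = rng.normal(size=(n, n_noise))
    X = np.column_stack([x1, x2, noise])
    return X, y


class TestYeoJohnson:
    def test_training_columns_standardized_exactly(self):
        z = YeoJohnsonScaler().fit_transform(np.array([[1.0], [2.0], [3.0]]))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.var() == pytest.approx(1.0, abs=1e-12)

    def test_normal_data_keeps_lambda_near_identity(self, rng):
        x = rng.normal(loc=2.0, size=(2000, 1))
        sc = YeoJohnsonScaler().fit(x)
        assert abs(sc.lambdas_[0] - 1.0) < 0.25
        # near-affine: transformed values correlate ~1 with the input
        z = sc.transform(x)
        assert np.corrcoef(x[:, 0], z[:, 0])[0, 1] > 0.999

    def test_symmetrizes_lognormal_and_matches_reference_mle(self, rng):
        x = rng.lognormal(size=(10000, 1))
        sc = YeoJohnsonScaler().fit(x)
        ref = PowerTransformer(method="yeo-johnson").fit(x)
        assert sc.lambdas_[0] == pytest.approx(ref.lambdas_[0], abs=0.02)
        raw_skew = sps.skew(x[:, 0])
        z_skew = sps.skew(sc.fit_transform(x)[:, 0])
        assert raw_skew > 3.0 and abs(z_skew) < 0.2

    def test_constant_column_guard(self, rng):
        X = np.column_stack([np.full(50, 3.0), rng.normal(size=50)])
        sc = YeoJohnsonScaler().fit(X)
        assert list(sc.dropped_features_) == [0]
        z = sc.transform(X)
        assert np.all(z[:, 0] == 0.0)

    def test_apply_uses_training_parameters(self, rng):
        train = rng.lognormal(size=(500, 2))
        other = rng.lognormal(size=(100, 2)) * 3.0
        sc = YeoJohnsonScaler().fit(train)
        z = sc.transform(other)
        # shifted data transformed with train parameters is NOT centered
        assert abs(z.mean()) > 0.1


class TestMutualInformation:
    def test_label_copy_has_maximal_mi(self, rng):
        y = rng.integers(0, 2, size=200)
        X = np.column_stack([rng.normal(size=(200, 4)), y.astype(float)])
        scores = [mutual_information(X[:, j], y) for j in range(5)]
        assert int(np.argmax(scores)) == 4


class TestForwardSelection:
    def test_label_feature_selected_first(self, rng):
        y = rng.integers(0, 2, size=100)
        X = np.column_stack([rng.normal(size=(100, 5)), y.astype(float)])
        sel = ResidualMIForwardSelector(random_state=0).fit(X, y)
        assert sel.path_[0] == 5
        assert 5 in sel.selected_

    def test_xor_parents_enter_path_through_residual_step(self, rng):
        hits = 0
        for rep in range(20):
            X, y = xor_cohort(np.random.default_rng(100 + rep))
            sel = ResidualMIForwardSelector(random_state=rep).fit(X, y)
            if {0, 1} <= set(sel.path_[:3]):
                hits += 1
        assert hits >= 16

    def test_all_noise_selection_stops_early(self, rng):
        sizes = []
        for rep in range(50):
            r = np.random.default_rng(rep)
            X = r.normal(size=(80, 10))
            y = r.integers(0, 2, size=80)
            sel = ResidualMIForwardSelector(random_state=rep).fit(X, y)
            sizes.append(len(sel.selected_))
        assert np.median(sizes) <= 2

    def test_transform_subsets_columns(self, rng):
        y = rng.integers(0, 2, size=60)
        X = np.column_stack([y.astype(float), rng.normal(size=(60, 3))])
        sel = ResidualMIForwardSelector(random_state=0).fit(X, y)
        assert sel.transform(X).shape[1] == len(sel.selected_)


class TestClassifiers:
    def test_separable_data_reaches_training_auc_one(self, rng):
        X = np.vstack([rng.normal(-2, 0.2, size=(20, 2)),
                       rng.normal(2, 0.2, size=(20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        pipe = train_logistic(CohortDataset(X, y, ("a", "b")))
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, pipe.predict_proba(X)[:, 1]) == 1.0

    def test_infinite_penalty_shrinks_to_prior(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        pipe = train_logistic(CohortDataset(X, y, ("a", "b", "c")),
                              l2_strength=1e8, with_selection=False)
        coefs = pipe.named_steps["logistic"].coef_
        assert np.max(np.abs(coefs)) < 1e-3
        p = pipe.predict_proba(X)[:, 1]
        assert np.allclose(p, 0.5, atol=1e-3)

    def test_duplicated_rows_leave_optimum_unchanged(self, rng):
        # duplicating every row doubles the log-likelihood term, so the
        # optimum is invariant exactly when the L2 penalty is doubled too
        # (constant per-sample regularization)
        X = rng.normal(size=(30, 4))
        y = np.array([0, 1] * 15)
        ds1 = CohortDataset(X, y, tuple("abcd"))
        ds2 = CohortDataset(np.vstack([X, X]), np.concatenate([y, y]), tuple("abcd"))
        p1 = train_logistic(ds1, l2_strength=1.0,
                            with_selection=False).predict_proba(X)[:, 1]
        p2 = train_logistic(ds2, l2_strength=2.0,
                            with_selection=False).predict_proba(X)[:, 1]
        assert np.allclose(p1, p2, atol=1e-4)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            train_logistic(CohortDataset(X, np.zeros(10, dtype=int), ("a", "b")))
        with pytest.raises(ValueError):
            train_forest(CohortDataset(X, np.ones(10, dtype=int), ("a", "b")))

    def test_forest_seeded_determinism_and_perfect_split(self, rng):
        y = rng.integers(0, 2, size=60)
        X = np.column_stack([rng.normal(size=(60, 4)), y.astype(float)])
        ds = CohortDataset(X, y, tuple("abcde"))
        f1 = train_forest(ds, n_trees=100, random_state=3)
        f2 = train_forest(ds, n_trees=100, random_state=3)
        assert np.array_equal(f1.predict_proba(X), f2.predict_proba(X))
        imp = f1.named_steps["forest"].feature_importances_
        assert int(np.argmax(imp)) == 4


class TestLeakFreedom:
    def test_train_only_fit_differs_from_all_data_fit(self, rng):
        X = rng.lognormal(size=(60, 3))
        train, test = X[:40], X[40:]
        z_leaky = YeoJohnsonScaler().fit(X).transform(test)
        z_clean = YeoJohnsonScaler().fit(train).transform(test)
        assert not np.allclose(z_leaky, z_clean)


class TestRanking:
    def test_label_feature_always_selected_by_logistic(self, rng):
        y = np.array([0, 1] * 15)
        X = np.column_stack([rng.normal(size=(30, 3)), y + rng.normal(0, 0.01, 30)])
        ds = CohortDataset(X, y, ("n1", "n2", "n3", "truth"))
        ranking = rank_features(ds, "logistic", n_subsets=10, seed=0)
        assert ranking.scores.index[0] == "truth"
        assert ranking.scores.iloc[0] == pytest.approx(1.0)

    def test_forest_scores_normalized(self, rng):
        y = rng.integers(0, 2, size=30)
        X = rng.normal(size=(30, 5))
        X[:, 2] += y
        ds = CohortDataset(X, y, tuple("abcde"))
        ranking = rank_features(ds, "forest", n_subsets=5, seed=1)
        assert ranking.scores.sum() == pytest.approx(1.0)
        assert (ranking.scores >= 0).all()

    def test_unknown_model_kind_rejected(self, rng):
        ds = CohortDataset(rng.normal(size=(10, 2)),
                           np.array([0, 1] * 5), ("a", "b"))
        with pytest.raises(ValueError):
            rank_features(ds, "svm")
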