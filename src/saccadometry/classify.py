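"""Disease-status classifiers and feature-importance ranking.

Two models distinguish PD from control participants from the 61-element
feature vector:

* **L2 logistic regression** preceded by median imputation, a Yeo-Johnson
  power transform with unit-variance scaling, and forward feature
  selection by residual mutual information (RMI): the first feature
  maximizes mutual information with the class label; each later step
  maximizes mutual information between a candidate and the residual of
  the current model (label minus predicted class-1 probability), so
  features that only matter jointly with already-selected ones become
  visible.  Selection stops when stratified k-fold CV ROC-AUC first
  decreases, returning the prefix with the best AUC.
* **Random forest** with 400 trees (no transform needed).

All preprocessing lives inside sklearn Pipelines, so any cross-validation
that clones the pipeline is leak-free by construction.

Feature importance is ranked over 75 random subsets of 2/3 of
participants: the logistic score is the proportion of subset fits in
which a feature was selected; the forest score is mean decrease in
impurity averaged over subset fits and normalized to sum 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline

__all__ = [
    "CohortDataset",
    "FeatureRanking",
    "mutual_information",
    "YeoJohnsonScaler",
    "ResidualMIForwardSelector",
    "make_logistic_pipeline",
    "make_forest",
    "train_logistic",
    "train_forest",
    "rank_features",
]


@dataclass
class CohortDataset:
    """Feature matrix with binary labels (PD = 1, control = 0)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame):
        from .features import FEATURE_NAMES

        names = tuple(c for c in FEATURE_NAMES if c in table.columns)
        X = table.loc[:, list(names)].to_numpy(dtype=float)
        y = (table["group"] == "PD").to_numpy(dtype=int)
        return cls(X=X, y=y, feature_names=names)


def _discretize(v, n_bins):
    """Equal-frequency binning; already-discrete vectors pass through."""
    v = np.asarray(v, dtype=float)
    uniq = np.unique(v)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, v)
    edges = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, v, side="right")


def mutual_information(x, target, n_bins=None):
    """Mutual information (nats) between a feature and a target.

    Continuous variables are discretized into equal-frequency bins
    (sqrt(n) bins, at least 4); a variable with few distinct values is
    used as-is.  Robust for the small cohorts this package targets.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n_bins is None:
        n_bins = max(4, int(np.sqrt(n)))
    return float(
        mutual_info_score(_discretize(x, n_bins), _discretize(target, n_bins))
    )


def _yeo_johnson(X, lmbda):
    """Vectorized Yeo-Johnson transform; ``lmbda`` broadcasts over columns."""
    X = np.asarray(X, dtype=float)
    lm = np.broadcast_to(np.asarray(lmbda, dtype=float), X.shape)
    out = np.empty_like(X)
    pos = X >= 0
    lp = lm[pos]
    xp = X[pos]
    with np.errstate(over="ignore"):
        out[pos] = np.where(
            np.abs(lp) > 1e-10,
            (np.power(xp + 1.0, lp) - 1.0) / np.where(np.abs(lp) > 1e-10, lp, 1.0),
            np.log1p(xp),
        )
        ln = lm[~pos]
        xn = X[~pos]
        two = 2.0 - ln
        out[~pos] = np.where(
            np.abs(two) > 1e-10,
            -(np.power(1.0 - xn, two) - 1.0) / np.where(np.abs(two) > 1e-10, two, 1.0),
            -np.log1p(-xn),
        )
    return out


def _yj_loglik(X, lmbda):
    """Per-column profile log-likelihood of Yeo-Johnson lambda (Gaussian)."""
    n = X.shape[0]
    Z = _yeo_johnson(X, lmbda)
    var = Z.var(axis=0)
    var = np.where(var > 0, var, np.finfo(float).tiny)
    jac = np.sum(np.sign(X) * np.log1p(np.abs(X)), axis=0)
    return -0.5 * n * np.log(var) + (np.asarray(lmbda) - 1.0) * jac


class YeoJohnsonScaler(BaseEstimator, TransformerMixin):
    """Yeo-Johnson power transform + standardization with a constant-column
    guard.

    Per-feature lambda by profile maximum likelihood (coarse-to-fine grid
    search on [-5, 5], vectorized across features — this transform is
    refitted thousands of times inside leave-pair-out loops); transformed
    training columns have mean 0 and variance 1.  Columns constant in
    training carry no information: they map to 0 and are recorded in
    ``dropped_features_``.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.variable_ = X.std(axis=0) > 0
        self.dropped_features_ = np.flatnonzero(~self.variable_)
        lambdas = np.ones(X.shape[1])
        if self.variable_.any():
            Xv = X[:, self.variable_]
            coarse = np.arange(-5.0, 5.01, 0.25)
            ll = np.stack([_yj_loglik(Xv, l) for l in coarse])  # (L, d)
            best = coarse[np.argmax(ll, axis=0)]
            fine_off = np.arange(-0.25, 0.2501, 0.01)
            llf = np.stack([_yj_loglik(Xv, best + o) for o in fine_off])
            lambdas_v = best + fine_off[np.argmax(llf, axis=0)]
            Z = _yeo_johnson(Xv, lambdas_v)
            self.mean_ = Z.mean(axis=0)
            sd = Z.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
            lambdas[self.variable_] = lambdas_v
        self.lambdas_ = lambdas
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = np.zeros_like(X)
        if self.variable_.any():
            Z = _yeo_johnson(X[:, self.variable_], self.lambdas_[self.variable_])
            out[:, self.variable_] = (Z - self.mean_) / self.scale_
        return out


class ResidualMIForwardSelector(BaseEstimator, TransformerMixin):
    """Forward feature selection by residual mutual information.

    Parameters
    ----------
    estimator : classifier with predict_proba, default L2 logistic
        Model used both for residuals and for the CV-AUC stopping rule.
    cv : int
        Stratified folds for the stopping criterion.
    max_features : int or None
        Optional hard cap on the path length.
    random_state : int or None
        Seeds the CV fold assignment (recorded in ``cv_random_state_``).

    Attributes
    ----------
    path_ : list of int — features in order of entry.
    cv_aucs_ : list of float — mean CV ROC-AUC after each entry.
    selected_ : list of int — the prefix of ``path_`` with maximal AUC.
    """

    def __init__(self, estimator=None, cv=5, max_features=None, random_state=None):
        self.estimator = estimator
        self.cv = cv
        self.max_features = max_features
        self.random_state = random_state

    def _model(self):
        if self.estimator is not None:
            return clone(self.estimator)
        return LogisticRegression(C=1.0, max_iter=1000)

    def _cv_auc(self, X, y, cols):
        skf = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.cv_random_state_
        )
        aucs = []
        for tr, te in skf.split(X, y):
            m = self._model().fit(X[np.ix_(tr, cols)], y[tr])
            p = m.predict_proba(X[np.ix_(te, cols)])[:, 1]
            if np.unique(y[te]).size < 2:
                continue
            aucs.append(roc_auc_score(y[te], p))
        return float(np.mean(aucs)) if aucs else np.nan

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, d = X.shape
        self.n_features_in_ = d
        self.cv_random_state_ = (
            self.random_state if self.random_state is not None else 0
        )
        path, aucs = [], []
        remaining = list(range(d))
        cap = self.max_features or d
        residual = y.astype(float)
        while remaining and len(path) < cap:
            scores = np.array(
                [mutual_information(X[:, j], residual) for j in remaining]
            )
            if np.all(scores <= 0):
                break
            j = remaining[int(np.argmax(scores))]  # argmax -> lowest index on ties
            path.append(j)
            remaining.remove(j)
            auc = self._cv_auc(X, y, path)
            stop = len(aucs) > 0 and auc < aucs[-1]
            aucs.append(auc)
            if stop:
                break
            model = self._model().fit(X[:, path], y)
            residual = y - model.predict_proba(X[:, path])[:, 1]
        self.path_ = path
        self.cv_aucs_ = aucs
        best = int(np.argmax(aucs)) if aucs else -1
        self.selected_ = path[: best + 1] if path else []
        self.support_ = np.zeros(d, dtype=bool)
        self.support_[self.selected_] = True
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if not self.selected_:
            # degenerate: nothing informative; pass everything through
            return X
        return X[:, self.selected_]

    def get_support(self):
        return self.support_


def make_logistic_pipeline(l2_strength=1.0, with_selection=True, cv=5,
                           random_state=None):
    """Imputation -> Yeo-Johnson scaling -> (RMI selection) -> L2 logistic.

    ``l2_strength`` is the penalty weight lambda (sklearn C = 1/lambda).
    """
    steps = [
        ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
        ("yeo_johnson", YeoJohnsonScaler()),
    ]
    if with_selection:
        steps.append(
            ("select", ResidualMIForwardSelector(cv=cv, random_state=random_state))
        )
    steps.append(
        ("logistic", LogisticRegression(C=1.0 / l2_strength, max_iter=1000))
    )
    return Pipeline(steps)


def make_forest(n_trees=400, random_state=None):
    """Imputation -> random forest with ``n_trees`` estimators."""
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
            (
                "forest",
                RandomForestClassifier(n_estimators=n_trees, random_state=random_state),
            ),
        ]
    )


def train_logistic(dataset: CohortDataset, l2_strength=1.0, with_selection=True,
                   random_state=None):
    if np.unique(dataset.y).size < 2:
        raise ValueError("need both classes to train")
    return make_logistic_pipeline(
        l2_strength, with_selection=with_selection, random_state=random_state
    ).fit(dataset.X, dataset.y)


def train_forest(dataset: CohortDataset, n_trees=400, random_state=None):
    if np.unique(dataset.y).size < 2:
        raise ValueError("need both classes to train")
    return make_forest(n_trees, random_state=random_state).fit(dataset.X, dataset.y)


@dataclass
class FeatureRanking:
    scores: pd.Series  # per-feature score, highest first
    model_kind: str
    n_subsets: int

    @property
    def top(self):
        return self.scores.index.tolist()


def rank_features(dataset: CohortDataset, model_kind="logistic", n_subsets=75,
                  subset_fraction=2.0 / 3.0, seed=0):
    """Subset-resampling feature importance.

    Draws ``n_subsets`` random subsets of ``subset_fraction`` of
    participants (without replacement, both classes required) and fits the
    chosen model on each.  Logistic score: selection proportion across
    fits.  Forest score: mean decrease in impurity averaged over fits,
    normalized to sum 1.
    """
    if model_kind not in ("logistic", "forest"):
        raise ValueError("model_kind must be 'logistic' or 'forest'")
    rng = np.random.default_rng(seed)
    n = dataset.X.shape[0]
    size = int(n * subset_fraction)
    d = dataset.X.shape[1]
    totals = np.zeros(d)
    for k in range(n_subsets):
        for _ in range(100):
            idx = rng.choice(n, size=size, replace=False)
            if np.unique(dataset.y[idx]).size == 2:
                break
        Xs, ys = dataset.X[idx], dataset.y[idx]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if model_kind == "logistic":
            pipe = make_logistic_pipeline(random_state=sub_seed).fit(Xs, ys)
            totals[pipe.named_steps["select"].get_support()] += 1.0
        else:
            pipe = make_forest(random_state=sub_seed).fit(Xs, ys)
            totals += pipe.named_steps["forest"].feature_importances_
    scores = totals / n_subsets
    if model_kind == "forest" and scores.sum() > 0:
        scores = scores / scores.sum()
    ser = pd.Series(scores, index=list(dataset.feature_names)).sort_values(
        ascending=False, kind="stable"
    )
    return FeatureRanking(scores=ser, model_kind=model_kind, n_subsets=n_subsets)
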