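"""Classifier evaluation: tournament leave-pair-out CV and the 5x2cv
combined F-test.

**Tournament leave-pair-out cross-validation (TLPO-CV).**  For every
unordered pair of participants the model is refitted on the remaining
n - 2 and scores both held-out participants; the higher-scored one wins
the pairing (ties: half a win each).  Total wins rank the participants,
and the ROC/AUC of that ranking against the true labels is a
near-unbiased estimate of the classifier's ROC-AUC.  For n participants
this is n(n-1)/2 fits of n-2 participants each — 1,275 fits of 49 at
n = 51.  With half-wins for ties, the AUC equals the Mann-Whitney
identity U/(n+ * n-) computed from the win ranking.

**5x2cv combined F-test.**  Five stratified 50/50 splits; within each
replication both fold-as-test arrangements give a performance difference
p_ij = AUC_A - AUC_B.  F = (sum_ij p_ij^2) / (2 sum_i s_i^2) with s_i^2
the within-replication variance, referred to an F(10, 5) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "TLPOResult",
    "FiveByTwoResult",
    "CoinFlipClassifier",
    "OracleClassifier",
    "tlpo_cv",
    "roc_from_ranking",
    "five_by_two_f_test",
]


class CoinFlipClassifier(BaseEstimator, ClassifierMixin):
    """Emits uniform-random class-1 probabilities; a null trainer for
    calibration studies."""

    def __init__(self, random_state=None):
        self.random_state = random_state

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.rng_ = np.random.default_rng(self.random_state)
        return self

    def predict_proba(self, X):
        p = self.rng_.uniform(size=len(X))
        return np.column_stack([1 - p, p])


class OracleClassifier(BaseEstimator, ClassifierMixin):
    """Scores each sample by a designated 'truth' column — an upper-bound
    reference trainer for evaluation machinery tests."""

    def __init__(self, column=0):
        self.column = column

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        p = np.asarray(X)[:, self.column].astype(float)
        return np.column_stack([1 - p, p])


def _seed_estimator(estimator, seed):
    """Set every random_state hyperparameter (nested included)."""
    params = {
        name: seed
        for name in estimator.get_params(deep=True)
        if name == "random_state" or name.endswith("__random_state")
    }
    if params:
        estimator.set_params(**params)
    return estimator


@dataclass
class TLPOResult:
    wins: np.ndarray  # per-participant tournament wins
    ranks: np.ndarray  # midranks of the win counts (1 = fewest wins)
    labels: np.ndarray
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    n_fits: int
    train_size_per_fit: int
    failed_pairs: list = field(default_factory=list)


def tlpo_cv(X, y, trainer, seed=0) -> TLPOResult:
    """Tournament leave-pair-out cross-validation.

    ``trainer`` is an (unfitted) sklearn classifier or pipeline with
    ``predict_proba``; it is cloned for every pair and reseeded
    deterministically from ``seed`` and the pair index, so results are
    independent of execution order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 4:
        raise ValueError("TLPO-CV needs at least 4 participants")
    wins = np.zeros(n)
    failed = []
    pairs = list(combinations(range(n), 2))
    for k, (i, j) in enumerate(pairs):
        mask = np.ones(n, dtype=bool)
        mask[[i, j]] = False
        est = _seed_estimator(
            clone(trainer),
            int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31)),
        )
        try:
            est.fit(X[mask], y[mask])
            si, sj = est.predict_proba(X[[i, j]])[:, 1]
        except Exception:
            failed.append((i, j))
            continue
        if si > sj:
            wins[i] += 1.0
        elif sj > si:
            wins[j] += 1.0
        else:
            wins[i] += 0.5
            wins[j] += 0.5
    ranks = sps.rankdata(wins)
    curve = roc_from_ranking(ranks, y)
    return TLPOResult(
        wins=wins,
        ranks=ranks,
        labels=y,
        auc=curve.auc,
        roc_fpr=curve.fpr,
        roc_tpr=curve.tpr,
        n_fits=len(pairs),
        train_size_per_fit=n - 2,
        failed_pairs=failed,
    )


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_from_ranking(ranks, labels) -> ROCResult:
    """ROC curve and AUC from a ranking (higher rank = more case-like).

    The AUC is the Mann-Whitney identity U/(n+ * n-) on midranks, which
    counts concordant case-control pairs with ties at half weight.
    """
    ranks = np.asarray(ranks, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    r = sps.rankdata(ranks)
    u = r[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    fpr, tpr, thr = roc_curve(labels, ranks)
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


@dataclass
class FiveByTwoResult:
    differences: np.ndarray  # shape (5, 2): p_ij = AUC_A - AUC_B
    variances: np.ndarray  # shape (5,): per-replication s_i^2
    F: float
    pvalue: float
    degenerate: bool = False


def five_by_two_f_test(X, y, trainer_a, trainer_b, seed=0) -> FiveByTwoResult:
    """Head-to-head ROC-AUC comparison via the 5x2cv combined F-test.

    Splits are stratified by class so every half contains both classes.
    When every difference is exactly zero (e.g. identical trainers) the
    degenerate flag is set and p = 1 is reported instead of an F ratio.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) < 8:
        raise ValueError("5x2cv needs at least 8 participants")
    p = np.zeros((5, 2))
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(15).astype(np.int64)
    for i in range(5):
        skf = StratifiedKFold(n_splits=2, shuffle=True,
                              random_state=int(rep_seeds[i] % (2**31)))
        folds = [te for _, te in skf.split(X, y)]
        for j, (test_idx, train_idx) in enumerate(
            [(folds[0], folds[1]), (folds[1], folds[0])]
        ):
            aucs = []
            for which, trainer in enumerate((trainer_a, trainer_b)):
                est = _seed_estimator(
                    clone(trainer),
                    int(rep_seeds[5 + i] % (2**31)) + 2 * j + which,
                )
                est.fit(X[train_idx], y[train_idx])
                scores = est.predict_proba(X[test_idx])[:, 1]
                aucs.append(roc_auc_score(y[test_idx], scores))
            p[i, j] = aucs[0] - aucs[1]
    s2 = ((p - p.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    if np.allclose(p, 0.0):
        return FiveByTwoResult(differences=p, variances=s2, F=0.0, pvalue=1.0,
                               degenerate=True)
    denom = 2.0 * s2.sum()
    if denom == 0:
        return FiveByTwoResult(differences=p, variances=s2, F=np.inf, pvalue=0.0,
                               degenerate=True)
    F = float((p**2).sum() / denom)
    return FiveByTwoResult(
        differences=p,
        variances=s2,
        F=F,
        pvalue=float(sps.f.sf(F, 10, 5)),
        degenerate=False,
    )
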