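"""Neuroimaging-style statistics at the level where they are testable:
contrast effect sizes, group differences, and MVPA decoding with
permutation significance.

The MVPA classifier is a linear max-margin (linear-kernel SVM) decoder
evaluated by leave-one-group-out cross-validation; chance and significance
come from an empirical null built by permuting labels across the pooled
patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC

from ._utils import rng_from
from .errors import DimensionError, ParameterError, UndefinedStatisticError


@dataclass
class EffectSizeInput:
    """A contrast parameter estimate with its variance and dof."""

    beta: float
    var_beta: float
    dof: int

    def __post_init__(self):
        if self.var_beta <= 0:
            raise ParameterError("var_beta must be positive")
        if self.dof < 1:
            raise ParameterError("dof must be >= 1")


@dataclass
class MVPAResult:
    """Decoding accuracy with (optionally) its permutation null."""

    accuracy: float
    n_folds: int
    null_accuracies: np.ndarray = field(default_factory=lambda: np.empty(0))
    p: float = float("nan")
    threshold_at_alpha: float = float("nan")


def cohens_d(inp: EffectSizeInput) -> float:
    """Effect size d = beta / sqrt(dof * var(beta)) — equivalently t / sqrt(dof)."""
    return float(inp.beta / np.sqrt(inp.dof * inp.var_beta))


def _make_classifier():
    # linear max-margin with fixed unit regularization
    return LinearSVC(C=1.0, dual=True, max_iter=10000, tol=1e-6, random_state=0)


def mvpa_loocv(patterns, labels, groups) -> MVPAResult:
    """Leave-one-group-out decoding accuracy with a linear SVM.

    One fold per distinct group: the classifier is trained on all other
    groups' patterns and tested on the held-out group; the reported accuracy
    is the mean over folds.  Raises on folds whose training set lacks a
    class.
    """
    X = np.asarray(patterns, dtype=float)
    y = np.asarray(labels)
    g = np.asarray(groups)
    if X.ndim != 2 or len(y) != len(X) or len(g) != len(X):
        raise DimensionError("patterns, labels, groups must be aligned")
    uniq = np.unique(g)
    if len(uniq) < 2:
        raise ParameterError("need at least 2 groups for leave-one-out")
    accs = []
    for hold in uniq:
        tr = g != hold
        if len(np.unique(y[tr])) < 2:
            raise ParameterError(f"training fold without group {hold!r} has a single label")
        clf = _make_classifier()
        clf.fit(X[tr], y[tr])
        accs.append(float(np.mean(clf.predict(X[~tr]) == y[~tr])))
    return MVPAResult(accuracy=float(np.mean(accs)), n_folds=len(uniq))


def permutation_null(patterns, labels, groups, n_perm: int = 1000,
                     alpha: float = 0.05, seed: int = 0) -> MVPAResult:
    """Permutation significance for leave-one-group-out decoding.

    Null accuracies are obtained by relabeling the pooled patterns (labels
    permuted across all groups) and repeating the full cross-validation;
    p = (#{null >= observed} + 1) / (n_perm + 1), and ``threshold_at_alpha``
    is the empirical (1 - alpha) null quantile.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    observed = mvpa_loocv(patterns, labels, groups)
    y = np.asarray(labels)
    rng = rng_from(seed, "mvpa-perm")
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = mvpa_loocv(patterns, rng.permutation(y), groups).accuracy
    p = float((np.sum(null >= observed.accuracy) + 1.0) / (n_perm + 1.0))
    return MVPAResult(accuracy=observed.accuracy, n_folds=observed.n_folds,
                      null_accuracies=null, p=p,
                      threshold_at_alpha=float(np.quantile(null, 1.0 - alpha)))


def mvpa_over_subsets(patterns, labels, groups, subsets) -> list[MVPAResult]:
    """Apply leave-one-group-out decoding over feature subsets (a generic
    hook from which a searchlight over any geometry can be composed)."""
    X = np.asarray(patterns, dtype=float)
    return [mvpa_loocv(X[:, np.asarray(idx)], labels, groups) for idx in subsets]


def group_difference(values_a, values_b, n_perm: int = 1000, seed: int = 0) -> dict:
    """Welch two-sample t with a two-sided permutation p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        raise UndefinedStatisticError("zero variance and equal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    t_obs = float(res.statistic)
    pooled = np.concatenate([a, b])
    rng = rng_from(seed, "group-perm")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        t0 = stats.ttest_ind(perm[: len(a)], perm[len(a):], equal_var=False).statistic
        if abs(t0) >= abs(t_obs):
            count += 1
    return dict(t=t_obs, dof=float(res.df), p=float((count + 1.0) / (n_perm + 1.0)))
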