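"""Linear discriminant validation of candidate morphogroups.

A candidate partition is "supported" when a Gaussian linear discriminant
classifier (pooled within-group covariance, equal priors) predicts group
membership of held-out specimens with accuracy at or above the 90% cutoff.
Two validation designs are provided:

* stratified half-split — per-group 50/50 train/test split preserving the
  proportional makeup of the groups (odd counts give the extra specimen to
  training),
* jackknife (leave-one-out) cross-validation — for datasets whose groups
  are too small to split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import MorphogroupPartition
from .containers import MeasurementMatrix

__all__ = [
    "SUPPORT_CUTOFF",
    "DiscriminantModel",
    "lda_fit",
    "lda_predict",
    "lda_accuracy",
    "stratified_half_split",
    "jackknife_cv_accuracy",
    "meets_support_cutoff",
]

#: Classification-accuracy cutoff for morphometric distinction between groups.
SUPPORT_CUTOFF = 0.90


def meets_support_cutoff(accuracy: float) -> bool:
    """Pure predicate: is a partition morphometrically supported?"""
    return accuracy >= SUPPORT_CUTOFF


@dataclass
class DiscriminantModel:
    group_means: np.ndarray       # k x p
    pooled_covariance: np.ndarray  # p x p
    priors: np.ndarray            # k, sums to 1
    coefficients: np.ndarray      # min(k-1, p) x p discriminant loadings
    variable_names: list
    group_ids: list               # group index order of the rows above

    def __post_init__(self):
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")


def _check_complete(m: MeasurementMatrix):
    if m.mask.any():
        raise ValueError("matrix has missing cells; impute first")


def lda_fit(m: MeasurementMatrix, p: MorphogroupPartition,
            priors: str = "equal") -> DiscriminantModel:
    """Fit Gaussian LDA with pooled within-group covariance.

    ``priors='equal'`` (the default, accounting for unequal sample sizes)
    or ``'frequency'`` for observed-frequency priors.  A singular pooled
    covariance (e.g. more variables than cases) is an error advising
    variable reduction.
    """
    _check_complete(m)
    ids = [s for s in m.specimen_ids if s in p.assignment]
    if len(ids) != m.n_specimens:
        m = m.subset(specimens=ids)
    X = m.values
    y = p.labels_for(m.specimen_ids)
    groups = sorted(set(y))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a discriminant analysis")
    n, nv = X.shape
    k = len(groups)

    means = np.vstack([X[y == g].mean(axis=0) for g in groups])
    Sw = np.zeros((nv, nv))
    for gi, g in enumerate(groups):
        Xg = X[y == g]
        d = Xg - means[gi]
        Sw += d.T @ d
    dof = n - k
    if dof < 1:
        raise ValueError("more groups than spare cases; pooled covariance undefined")
    Sw /= dof
    if np.linalg.matrix_rank(Sw) < nv or np.linalg.cond(Sw) > 1e12:
        raise ValueError(
            "singular pooled variance/covariance matrix (variables >= cases?); "
            "reduce the number of variables")

    if priors == "equal":
        pri = np.full(k, 1.0 / k)
    elif priors == "frequency":
        pri = np.array([(y == g).mean() for g in groups])
    else:
        raise ValueError("priors must be 'equal' or 'frequency'")

    # Fisher discriminant axes: eigenvectors of Sw^-1 Sb (reporting only)
    grand = X.mean(axis=0)
    Sb = np.zeros((nv, nv))
    for gi, g in enumerate(groups):
        ng = (y == g).sum()
        d = (means[gi] - grand)[:, None]
        Sb += ng * (d @ d.T)
    evals, evecs = np.linalg.eig(np.linalg.solve(Sw, Sb))
    order = np.argsort(evals.real)[::-1][: min(k - 1, nv)]
    coeffs = evecs.real[:, order].T

    return DiscriminantModel(means, Sw, pri, coeffs, m.variable_names, groups)


def _log_posteriors(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    Sinv = np.linalg.inv(model.pooled_covariance)
    scores = np.empty((X.shape[0], len(model.group_ids)))
    for gi, mu in enumerate(model.group_means):
        # linear discriminant score: x' S^-1 mu - mu' S^-1 mu / 2 + log prior
        a = Sinv @ mu
        scores[:, gi] = X @ a - 0.5 * mu @ a + np.log(model.priors[gi])
    return scores


def lda_predict(model: DiscriminantModel, m: MeasurementMatrix):
    """Maximum-posterior group for each specimen, plus posteriors."""
    _check_complete(m)
    if m.variable_names != model.variable_names:
        raise ValueError("variables do not match the fitted model")
    scores = _log_posteriors(model, m.values)
    post = np.exp(scores - scores.max(axis=1, keepdims=True))
    post /= post.sum(axis=1, keepdims=True)
    pred = np.array([model.group_ids[i] for i in scores.argmax(axis=1)])
    return pred, post


def lda_accuracy(model: DiscriminantModel, m: MeasurementMatrix,
                 truth: MorphogroupPartition) -> float:
    """Fraction of specimens whose maximum-posterior class equals truth."""
    pred, _ = lda_predict(model, m)
    y = truth.labels_for(m.specimen_ids)
    return float((pred == y).mean())


def stratified_half_split(p: MorphogroupPartition, seed: int):
    """Per-group 50/50 split, extra member of odd groups to training.

    Deterministic per seed.  Any group of size 1 is an error directing to
    jackknife validation.
    """
    rng = np.random.default_rng(seed)
    singles = [g for g in p.groups() if len(g) < 2]
    if singles:
        raise ValueError(
            "group(s) with a single member cannot be split; "
            "use jackknife_cv_accuracy instead")
    train, test = [], []
    for members in p.groups():
        members = sorted(members, key=str)
        order = rng.permutation(len(members))
        n_train = (len(members) + 1) // 2
        train += [members[i] for i in order[:n_train]]
        test += [members[i] for i in order[n_train:]]
    return train, test


def split_validated_accuracy(m: MeasurementMatrix, p: MorphogroupPartition,
                             seed: int) -> float:
    """Train on a stratified half, report accuracy on the held-out half."""
    train, test = stratified_half_split(p, seed)
    model = lda_fit(m.subset(specimens=train), p)
    return lda_accuracy(model, m.subset(specimens=test), p)


def jackknife_cv_accuracy(m: MeasurementMatrix, p: MorphogroupPartition) -> float:
    """Leave-one-out accuracy: refit on n-1, classify the held-out specimen.

    When holding a specimen out reduces its group to one member, that fold
    still uses the remaining member's mean with the pooled covariance (a
    logged degenerate fold).
    """
    _check_complete(m)
    ids = m.specimen_ids
    if any(len(g) < 2 for g in p.groups()):
        raise ValueError("each group needs at least 2 members for jackknife CV")
    hits = 0
    for held in ids:
        rest = [s for s in ids if s != held]
        model = lda_fit(m.subset(specimens=rest), p)
        pred, _ = lda_predict(model, m.subset(specimens=[held]))
        hits += int(pred[0] == p.assignment[held])
    return hits / len(ids)
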