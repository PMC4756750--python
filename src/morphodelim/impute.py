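"""Multivariate-normal completion of measurement tables.

Linear morphometric tables of fossil specimens are rarely complete; the
multivariate methods downstream (UPGMA, discriminant analysis) require
complete data.  This module fills the gaps under a joint multivariate
normal model:

* :func:`em_mvn` — maximum-likelihood mean/covariance from incomplete data
  by EM (grouped by missingness pattern), used to start the chain,
* :func:`da_impute` — data augmentation: a Gibbs alternation of drawing the
  missing block of each specimen from its conditional normal (I-step) and
  drawing (mean, covariance) from the complete-data posterior under a
  noninformative Jeffreys prior (P-step); the default chain length is 100
  steps and the completed matrix is taken after the final I-step,
* :func:`kurtosis_normality_test` — Mardia's multivariate kurtosis test of
  the normality assumption,
* bookkeeping helpers (:func:`missing_fraction`, :func:`prune_missing`).

Observed cells are never altered by any operation here.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MeasurementMatrix

__all__ = [
    "MvnParams",
    "ImputationResult",
    "missing_fraction",
    "prune_missing",
    "em_mvn",
    "da_impute",
    "kurtosis_normality_test",
]


@dataclass
class MvnParams:
    """Mean vector (mm) and symmetric PSD covariance (mm^2)."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        p = self.mean.shape[0]
        if self.covariance.shape != (p, p):
            raise ValueError("covariance shape does not match mean length")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance not symmetric")
        ev = np.linalg.eigvalsh(self.covariance)
        if ev.min() < -1e-8 * max(1.0, ev.max()):
            raise ValueError("covariance not positive semi-definite")


@dataclass
class ImputationResult:
    completed: MeasurementMatrix
    chain_length: int
    seed: int
    params_final: MvnParams
    log: list


def missing_fraction(m: MeasurementMatrix) -> float:
    """Exact proportion of missing cells (rational arithmetic, then float)."""
    if m.n_specimens == 0 or m.n_variables == 0:
        raise ValueError("empty matrix")
    return float(Fraction(int(m.mask.sum()), m.mask.size))


def prune_missing(m: MeasurementMatrix, min_var_obs: float = 0.5,
                  min_spec_obs: float = 0.5):
    """Drop variables then specimens with superfluous missingness.

    Variables observed in fewer than ``min_var_obs`` of specimens are
    removed first, then specimens observed in fewer than ``min_spec_obs``
    of the remaining variables.  Returns ``(pruned, log)``.
    """
    log = []
    obs = ~m.mask
    keep_vars = [v for j, v in enumerate(m.variable_names)
                 if obs[:, j].mean() >= min_var_obs]
    for v in m.variable_names:
        if v not in keep_vars:
            log.append(("variable", v, "observed in < %d%% of specimens" % round(100 * min_var_obs)))
    if not keep_vars:
        raise ValueError("all variables pruned; lower min_var_obs")
    sub = m.subset(variables=keep_vars)
    obs = ~sub.mask
    keep_spec = [s for i, s in enumerate(sub.specimen_ids)
                 if obs[i, :].mean() >= min_spec_obs]
    for s in sub.specimen_ids:
        if s not in keep_spec:
            log.append(("specimen", s, "observed in < %d%% of variables" % round(100 * min_spec_obs)))
    if not keep_spec:
        raise ValueError("all specimens pruned; lower min_spec_obs")
    return sub.subset(specimens=keep_spec), log


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _check_columns(m: MeasurementMatrix):
    obs_counts = (~m.mask).sum(axis=0)
    thin = [m.variable_names[j] for j in np.where(obs_counts < 2)[0]]
    if thin:
        raise ValueError(
            f"variables observed in fewer than 2 specimens: {thin}; "
            "remove them (see prune_missing) before fitting")


def _observed_loglik(X, mask, mu, sigma):
    ll = 0.0
    for i in range(X.shape[0]):
        o = ~mask[i]
        if not o.any():
            continue
        ll += stats.multivariate_normal.logpdf(
            X[i, o], mean=mu[o], cov=sigma[np.ix_(o, o)], allow_singular=True)
    return ll


def em_mvn(m: MeasurementMatrix, tol: float = 1e-6, max_iter: int = 500) -> MvnParams:
    """ML mean/covariance of an incomplete matrix by EM.

    The observed-data log-likelihood is non-decreasing across iterations
    (asserted); iteration stops when its increase falls below ``tol``.
    """
    _check_columns(m)
    X = m.values.copy()
    mask = m.mask
    n, p = X.shape

    mu = np.nanmean(X, axis=0)
    # start covariance: diagonal of column variances (ML, observed cells)
    var = np.nanvar(X, axis=0)
    var[var <= 0] = max(1e-6, np.nanmax(var) * 1e-6 if np.nanmax(var) > 0 else 1e-6)
    sigma = np.diag(var)

    patterns = {}
    for i in range(n):
        patterns.setdefault(tuple(mask[i]), []).append(i)

    ll_old = -np.inf
    for _ in range(max_iter):
        # E-step: expected sufficient statistics
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for pat, rows in patterns.items():
            miss = np.array(pat)
            o = ~miss
            idx = np.array(rows)
            Xo = X[np.ix_(idx, np.where(o)[0])]
            if miss.any():
                Soo = sigma[np.ix_(o, o)]
                Smo = sigma[np.ix_(miss, o)]
                Smm = sigma[np.ix_(miss, miss)]
                B = np.linalg.solve(Soo, Smo.T).T          # regression coeffs
                cond_cov = Smm - B @ Smo.T
                Em = mu[miss] + (Xo - mu[o]) @ B.T          # conditional means
                full = np.empty((len(idx), p))
                full[:, o] = Xo
                full[:, miss] = Em
                s1 += full.sum(axis=0)
                s2 += full.T @ full
                # add conditional covariance for the missing block
                add = np.zeros((p, p))
                add[np.ix_(miss, miss)] = cond_cov * len(idx)
                s2 += add
            else:
                s1 += Xo.sum(axis=0)
                s2 += Xo.T @ Xo
        mu = s1 / n
        sigma = s2 / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2.0

        ll = _observed_loglik(X, mask, mu, sigma)
        if ll < ll_old - 1e-6 * max(1.0, abs(ll_old)):
            raise AssertionError("EM log-likelihood decreased")
        if ll - ll_old < tol:
            break
        ll_old = ll
    return MvnParams(mu, sigma)


# ---------------------------------------------------------------------------
# data augmentation
# ---------------------------------------------------------------------------

def _draw_posterior(X, rng, log, max_retries=10):
    """P-step: (mu, sigma) from the complete-data Jeffreys posterior."""
    n, p = X.shape
    xbar = X.mean(axis=0)
    S = (X - xbar).T @ (X - xbar)
    df = n - 1
    if df <= p:
        df = p + 1  # guard for tiny samples
    ridge = 0.0
    for attempt in range(max_retries):
        try:
            scale = S + ridge * np.eye(p)
            sigma = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
            sigma = np.atleast_2d(sigma)
            np.linalg.cholesky(sigma)
            mu = rng.multivariate_normal(xbar, sigma / n, method="cholesky")
            return mu, sigma
        except np.linalg.LinAlgError:
            ridge = max(np.trace(S) / S.shape[0] * 1e-6, 1e-8) * 10 ** attempt
            log.append(("ridge_retry", attempt, ridge))
    raise np.linalg.LinAlgError("posterior covariance draw failed repeatedly")


def da_impute(m: MeasurementMatrix, steps: int = 100, seed: int = 0,
              params0: MvnParams | None = None) -> ImputationResult:
    """Complete a matrix by data augmentation (one completed draw).

    Alternates the I-step (draw each specimen's missing block from its
    conditional normal given the observed entries and current parameters)
    and the P-step (draw parameters from the complete-data posterior).
    Identical seed implies bit-identical output.  With no missing cells
    the chain is degenerate: the input is returned with its ML parameters.
    """
    log = []
    X = m.values.copy()
    mask = m.mask
    n, p = X.shape
    rng = np.random.default_rng(seed)

    if not mask.any():
        mu = X.mean(axis=0)
        sigma = np.cov(X, rowvar=False, bias=True)
        return ImputationResult(m.copy(), 0, seed, MvnParams(mu, np.atleast_2d(sigma)), log)

    if params0 is None:
        params0 = em_mvn(m)
    mu, sigma = params0.mean.copy(), params0.covariance.copy()
    # keep the start covariance safely PD for conditional draws
    sigma += np.eye(p) * max(1e-10, 1e-10 * np.trace(sigma))

    for _ in range(steps):
        # I-step
        for i in range(n):
            miss = mask[i]
            if not miss.any():
                continue
            o = ~miss
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(miss, o)]
            Smm = sigma[np.ix_(miss, miss)]
            B = np.linalg.solve(Soo, Smo.T).T
            cond_mean = mu[miss] + B @ (X[i, o] - mu[o])
            cond_cov = Smm - B @ Smo.T
            cond_cov = (cond_cov + cond_cov.T) / 2.0
            cond_cov += np.eye(cond_cov.shape[0]) * max(1e-12, 1e-10 * np.trace(cond_cov))
            X[i, miss] = rng.multivariate_normal(cond_mean, cond_cov, method="cholesky")
        # P-step
        mu, sigma = _draw_posterior(X, rng, log)

    # final I-step so the completed data condition on the last parameter draw
    for i in range(n):
        miss = mask[i]
        if not miss.any():
            continue
        o = ~miss
        Soo = sigma[np.ix_(o, o)]
        Smo = sigma[np.ix_(miss, o)]
        Smm = sigma[np.ix_(miss, miss)]
        B = np.linalg.solve(Soo, Smo.T).T
        cond_mean = mu[miss] + B @ (X[i, o] - mu[o])
        cond_cov = Smm - B @ Smo.T
        cond_cov = (cond_cov + cond_cov.T) / 2.0
        cond_cov += np.eye(cond_cov.shape[0]) * max(1e-12, 1e-10 * np.trace(cond_cov))
        X[i, miss] = rng.multivariate_normal(cond_mean, cond_cov, method="cholesky")

    assert np.array_equal(X[~mask], m.values[~mask]), "observed cells altered"
    if (X[mask] <= 0).any():
        # an MVN conditional draw can leave the positive orthant; record it
        log.append(("nonpositive_imputations", int((X[mask] <= 0).sum())))
    df = pd.DataFrame(X, index=m.specimen_ids, columns=m.variable_names)
    completed = MeasurementMatrix(df, list(m.taxon_labels), m.angle_variables,
                                  strict_positive=False)
    return ImputationResult(completed, steps, seed, MvnParams(mu, sigma), log)


# ---------------------------------------------------------------------------
# Mardia's kurtosis test
# ---------------------------------------------------------------------------

def kurtosis_normality_test(m: MeasurementMatrix):
    """Mardia's multivariate kurtosis test on a complete matrix.

    b2p is the mean of squared Mahalanobis distances to the centroid
    (ML covariance); under multivariate normality E[b2p] = p(p + 2) and
    z = (b2p - p(p+2)) / sqrt(8 p (p+2) / n) is asymptotically standard
    normal.  Returns ``(b2p, z, two_sided_p)``.
    """
    if not m.is_complete():
        raise ValueError("kurtosis test requires a complete matrix; impute first")
    X = m.values
    n, p = X.shape
    if n <= p:
        raise ValueError("need more specimens than variables")
    mu = X.mean(axis=0)
    S = np.cov(X, rowvar=False, bias=True)
    S = np.atleast_2d(S)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        raise ValueError("singular covariance; reduce variables") from None
    d = X - mu
    md2 = np.einsum("ij,jk,ik->i", d, Sinv, d)
    b2p = float(np.mean(md2 ** 2))
    z = (b2p - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    pval = 2.0 * stats.norm.sf(abs(z))
    return b2p, float(z), float(pval)
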