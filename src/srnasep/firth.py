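"""Firth bias-reduced logistic regression for a single predictor.

With five samples per class, complete separation is routine and plain
maximum-likelihood logistic regression diverges.  Firth's correction adds the
Jeffreys-prior penalty 0.5*log det I(beta) to the log-likelihood, which keeps
the slope and its confidence bounds finite even under complete separation.
Inference follows the standard bias-reduced-logistic practice: p-values from
the penalized likelihood-ratio test (the profile penalized likelihood with
the slope fixed at zero), and confidence intervals by inverting that test
(profile penalized-likelihood intervals), not Wald intervals, which are
unreliable in separated small samples.

The model here is intercept + one covariate; the screening stage fits one
such model per candidate small RNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import chi2

_CHI2_95 = chi2.ppf(0.95, 1)  # 3.8415; PLR cutoff inverted for the 95% CI


@dataclass(frozen=True)
class FirthFit:
    """Penalized-likelihood fit of logit P(y=1) = intercept + slope * x."""

    intercept: float
    slope: float
    p_value: float
    odds_ratio: float  # exp(slope), per unit of x
    ci_low: float
    ci_high: float
    penalized_loglik: float
    converged: bool


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    p = expit(eta)
    # guard against log(0) in perfectly fitted points
    eps = np.finfo(float).tiny
    ll = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    W = p * (1 - p)
    info = (X * W[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_newton(
    X: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray,
    free: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, bool]:
    """Maximize the penalized log-likelihood over the ``free`` coordinates.

    Newton steps on the Firth-modified score with step-halving; coordinates
    with free=False stay at their beta0 value (used for profile likelihoods).
    """
    beta = beta0.astype(float).copy()
    pll = _penalized_loglik(X, y, beta)
    converged = False
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p)
        info = (X * W[:, None]).T @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = W * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        idx = np.flatnonzero(free)
        step = np.zeros_like(beta)
        sub_info = info[np.ix_(idx, idx)]
        try:
            step[idx] = np.linalg.solve(sub_info, score[idx])
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(score[idx])) < tol:
            converged = True
            break
        # step-halving on the penalized log-likelihood
        new_pll = -np.inf
        for _half in range(25):
            cand = beta + step
            new_pll = _penalized_loglik(X, y, cand)
            if new_pll >= pll - 1e-12:
                break
            step *= 0.5
        if new_pll < pll - 1e-8:
            break
        beta, pll = beta + step, new_pll
    return beta, pll, converged


def _profile_pll(X: np.ndarray, y: np.ndarray, slope: float) -> float:
    """Penalized log-likelihood maximized over the intercept at fixed slope.

    The intercept search starts at logit(ybar) - slope * xbar: for covariates
    far from zero (log2-CPM values routinely sit around 10-15) a careless
    start such as the full-model intercept puts every fitted probability at
    0/1, where the information matrix is numerically singular and Newton
    cannot move.
    """
    ybar = float(np.mean(y))
    b0_start = float(np.log(ybar / (1 - ybar)) - slope * np.mean(X[:, 1]))
    beta0 = np.array([b0_start, slope])
    free = np.array([True, False])
    _, pll, _ = _firth_newton(X, y, beta0, free)
    return pll


def fit_firth_logistic(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> FirthFit:
    """Fit the one-covariate Firth logistic model.

    Parameters
    ----------
    x : covariate values (e.g. log2 CPM), one per sample.
    y : binary labels (0 = reference class, 1 = target class).
    alpha : CI level is 1 - alpha (profile penalized-likelihood interval).

    Raises for constant labels or fewer than 2 samples per class.  A constant
    covariate carries no information: the fit degenerates to slope 0 with
    p = 1 and a unit odds ratio.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 samples")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    n1 = int(y.sum())
    if min(n1, len(y) - n1) < 2:
        raise ValueError("need at least 2 samples per class")
    if np.ptp(x) == 0.0:
        return FirthFit(0.0, 0.0, 1.0, 1.0, 1.0, 1.0, np.nan, True)

    X = np.column_stack([np.ones_like(x), x])
    ybar = float(np.mean(y))
    start = np.array([np.log(ybar / (1 - ybar)), 0.0])
    beta, pll_full, converged = _firth_newton(X, y, start, np.array([True, True]))
    pll_null = _profile_pll(X, y, 0.0)
    lr = max(0.0, 2.0 * (pll_full - pll_null))
    p_value = float(chi2.sf(lr, 1))

    cutoff = chi2.ppf(1 - alpha, 1)
    target = pll_full - 0.5 * cutoff

    def g(b1: float) -> float:
        return _profile_pll(X, y, b1) - target

    def bound(direction: float) -> float:
        step = 0.5 * max(1.0, abs(beta[1]))
        b = beta[1]
        for _ in range(60):
            b_next = b + direction * step
            if g(b_next) < 0:
                return brentq(g, min(b, b_next), max(b, b_next), xtol=1e-8)
            b = b_next
            step *= 1.6
        return direction * np.inf  # profile never drops below the cutoff

    lo = bound(-1.0)
    hi = bound(+1.0)
    return FirthFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        p_value=p_value,
        odds_ratio=float(np.exp(beta[1])),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        penalized_loglik=float(pll_full),
        converged=converged,
    )
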