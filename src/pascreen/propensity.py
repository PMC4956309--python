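"""Propensity model and odds-of-propensity (ATT) weights.

The confounder-adjustment route models the exposure with a main-effects
logistic regression on the dummy-coded confounder design,

    logit Pr(A=1 | X=x) = alpha0 + alpha' x,

and weights each *unexposed* respondent by the odds of their fitted
propensity, w = e(x) / (1 - e(x)); exposed respondents get weight 1 exactly.
Weighted this way, the unexposed group reproduces the confounder distribution
of the exposed group, so a weighted outcome-on-exposure regression targets the
risk difference *in the exposed*.

Fitting is Newton–Raphson (iteratively reweighted least squares) with
step-halving. Separation — fitted probabilities collapsing onto 0/1 with
diverging coefficients — is a hard error: in a screen over many beliefs an
item whose exposure is perfectly predicted by the confounders is reported as
inestimable rather than silently regularized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .exceptions import EstimationError
from .survey import DesignMatrix

MAX_ITER = 100
SCORE_TOL = 1e-8
LOGLIK_RTOL = 1e-10
_PROB_EPS = 1e-8
_DIVERGENCE_NORM = 30.0


@dataclass(frozen=True)
class PropensityModel:
    """Fitted exposure model. ``alpha`` aligns with the design's non-intercept columns."""

    alpha0: float
    alpha: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    fitted: np.ndarray
    columns: tuple[str, ...]

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.alpha0], self.alpha])


def _loglik(a: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: sum a*eta - log(1+exp(eta))
    return float(np.sum(a * eta - np.logaddexp(0.0, eta)))


def _check_separation(beta: np.ndarray, p: np.ndarray, design: DesignMatrix) -> None:
    if np.linalg.norm(beta, ord=np.inf) <= _DIVERGENCE_NORM:
        return
    extreme = (p < _PROB_EPS) | (p > 1 - _PROB_EPS)
    if not np.any(extreme):
        return
    i = int(np.argmax(extreme))
    pattern = {
        name: design.matrix[i, j]
        for j, name in enumerate(design.columns)
        if name != "intercept" and design.matrix[i, j] != 0
    }
    raise EstimationError(
        "complete or quasi-separation detected: fitted propensity within "
        f"{_PROB_EPS:g} of 0/1 with diverging coefficients; offending "
        f"covariate pattern: {pattern or '{intercept only}'}"
    )


def fit_propensity(design: DesignMatrix, a: np.ndarray) -> PropensityModel:
    """Maximum-likelihood logistic fit of exposure on the confounder design.

    Convergence is declared when the score's max absolute entry falls below
    1e-8 or the relative log-likelihood change falls below 1e-10, within 100
    Newton iterations.

    Raises
    ------
    EstimationError
        For constant exposure, rank-deficient designs, separation, or
        non-convergence.
    """
    a = np.asarray(a, dtype=float)
    X = design.matrix
    if X.shape[0] != a.shape[0]:
        raise ValueError("design and exposure lengths differ")
    if a.min() == a.max():
        raise EstimationError("exposure is constant; propensity model is undefined")
    if not np.all(np.isin(a, (0.0, 1.0))):
        raise ValueError("exposure vector must be binary")

    k = X.shape[1]
    beta = np.zeros(k)
    eta = X @ beta
    ll = _loglik(a, eta)
    converged = False
    it = 0
    trace: list[float] = [ll]
    for it in range(1, MAX_ITER + 1):
        p = expit(eta)
        score = X.T @ (a - p)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        w = p * (1 - p)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError as e:
            _check_separation(beta, p, design)
            raise EstimationError(
                "singular information matrix: design is rank deficient on the "
                "observed data"
            ) from e
        # step-halving keeps Newton monotone on flat likelihoods
        new_ll = -np.inf
        for _ in range(30):
            cand = beta + step
            cand_eta = X @ cand
            new_ll = _loglik(a, cand_eta)
            if new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        beta, eta = cand, cand_eta
        _check_separation(beta, expit(eta), design)
        trace.append(new_ll)
        if abs(new_ll - ll) < LOGLIK_RTOL * (abs(ll) + LOGLIK_RTOL):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    else:
        raise EstimationError(
            f"propensity fit did not converge in {MAX_ITER} iterations; "
            f"log-likelihood trace tail: {[round(v, 6) for v in trace[-5:]]}"
        )

    # polish: quadratic convergence drives the score to numerical zero, so
    # fitted probabilities in saturated designs match stratum fractions to
    # machine precision (the standardization identity relies on this)
    for _ in range(3):
        p = expit(eta)
        score = X.T @ (a - p)
        if np.max(np.abs(score)) < 1e-12:
            break
        w = p * (1 - p)
        try:
            beta = beta + np.linalg.solve(X.T @ (X * w[:, None]), score)
        except np.linalg.LinAlgError:
            break
        eta = X @ beta

    p = expit(eta)
    _check_separation(beta, p, design)
    return PropensityModel(
        alpha0=float(beta[0]),
        alpha=beta[1:].copy(),
        converged=converged,
        n_iter=it,
        loglik=_loglik(a, eta),
        fitted=p,
        columns=design.columns,
    )


def att_weights(model: PropensityModel, a: np.ndarray) -> np.ndarray:
    """Marginal-structural-model weights: odds e/(1-e) for A=0 rows, 1 for A=1.

    Raises
    ------
    EstimationError
        If an unexposed respondent has fitted propensity within 1e-12 of 1
        (infinite weight).
    """
    if not model.converged:
        raise EstimationError("propensity model did not converge; refusing weights")
    a = np.asarray(a)
    e = model.fitted
    w = np.ones_like(e)
    unexposed = a == 0
    if np.any(e[unexposed] >= 1 - 1e-12):
        raise EstimationError(
            "infinite weight: an unexposed respondent has fitted propensity ~ 1"
        )
    w[unexposed] = e[unexposed] / (1 - e[unexposed])
    return w
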