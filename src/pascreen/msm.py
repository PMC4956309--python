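"""Weighted linear-probability MSM fit and the G-formula standardization oracle.

The marginal structural model Pr(Y_a = 1 | A = 1) = beta0 + beta1 * a is
estimated by fitting the saturated association model
Pr(Y = 1 | A = a) = beta0 + beta1 * a by weighted least squares with the ATT
odds weights. Because the model is saturated, beta1 is exactly the weighted
outcome-mean difference between the exposed and the (reweighted) unexposed.

The variance of beta1 is the weight-fixed HC0 sandwich

    (X'WX)^{-1} [ sum_i w_i^2 r_i^2 x_i x_i' ] (X'WX)^{-1},

which treats the estimated weights as known constants — the same robust
standard error a GEE routine with identity link and independence working
correlation reports. Uncertainty from the propensity fit is deliberately not
propagated.

:func:`standardize_att` computes the same exposed-population risk difference
by direct stratum enumeration (the G-formula); on saturated fits the two
routes agree to numerical precision, which the test-suite uses as the primary
correctness oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EstimationError, PositivityError

_SATURATION_TOL = 1e-12


@dataclass(frozen=True)
class MSMFit:
    """Weighted linear-probability model estimates for one belief.

    ``beta0`` is the weighted baseline outcome probability (the counterfactual
    unexposed risk in the exposed group); ``beta1`` the adjusted risk
    difference in the exposed.
    """

    beta0: float
    beta1: float
    robust_se_beta1: float
    robust_se_beta0: float
    n_effective: float


def fit_weighted_lpm(y: np.ndarray, a: np.ndarray, w: np.ndarray) -> MSMFit:
    """Weighted least squares of y on (1, a) with HC0 sandwich variance.

    Raises
    ------
    EstimationError
        If either exposure group carries zero total weight.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    s1 = float(w[a == 1].sum())
    s0 = float(w[a == 0].sum())
    if s1 <= 0 or s0 <= 0:
        raise EstimationError("an exposure group has zero total weight")

    # saturated model: the WLS solution is the pair of weighted group means
    m1 = float(np.sum(w[a == 1] * y[a == 1]) / s1)
    m0 = float(np.sum(w[a == 0] * y[a == 0]) / s0)
    beta0, beta1 = m0, m1 - m0

    # verify against the normal equations (guards weight/array misalignment)
    X = np.column_stack([np.ones_like(a), a])
    xtwx = X.T @ (X * w[:, None])
    xtwy = X.T @ (w * y)
    beta_ls = np.linalg.solve(xtwx, xtwy)
    if abs(beta_ls[1] - beta1) > _SATURATION_TOL * max(1.0, abs(beta1)):
        raise AssertionError(
            "saturated WLS identity violated: "
            f"solver {beta_ls[1]!r} vs weighted-mean difference {beta1!r}"
        )

    r = y - (beta0 + beta1 * a)
    bread = np.linalg.inv(xtwx)
    meat = X.T @ (X * (w**2 * r**2)[:, None])
    cov = bread @ meat @ bread
    se0 = math.sqrt(max(cov[0, 0], 0.0))
    se1 = math.sqrt(max(cov[1, 1], 0.0))

    if not (-1.0 - 1e-12 <= beta1 <= 1.0 + 1e-12):
        raise AssertionError("beta1 outside [-1, 1] on binary data")
    return MSMFit(
        beta0=beta0,
        beta1=beta1,
        robust_se_beta1=se1,
        robust_se_beta0=se0,
        n_effective=s1 + s0,
    )


def standardize_att(y, a, strata) -> float:
    """G-formula risk difference in the exposed by direct stratum enumeration.

    Computes sum_x [Pr(Y=1|A=1,x) - Pr(Y=1|A=0,x)] * Pr(x|A=1) over observed
    joint confounder strata. Serves as the independent oracle for the weighted
    MSM route.

    Raises
    ------
    PositivityError
        If some stratum contains exposed but no unexposed respondents.
    EstimationError
        If there are no exposed respondents at all.
    """
    df = pd.DataFrame(
        {"y": np.asarray(y, dtype=float), "a": np.asarray(a, dtype=int), "s": list(strata)}
    )
    n1_total = int((df["a"] == 1).sum())
    if n1_total == 0:
        raise EstimationError("no exposed respondents; ATT contrast undefined")
    out = 0.0
    for stratum, g in df.groupby("s", sort=True):
        n1 = int((g["a"] == 1).sum())
        if n1 == 0:
            continue
        n0 = int((g["a"] == 0).sum())
        if n0 == 0:
            raise PositivityError(
                f"positivity violated: stratum {stratum!r} has exposed but no "
                "unexposed respondents"
            )
        p1 = float(g.loc[g["a"] == 1, "y"].mean())
        p0 = float(g.loc[g["a"] == 0, "y"].mean())
        out += (p1 - p0) * (n1 / n1_total)
    return out
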