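"""Crude (cross-tabulation) estimation of the risk difference and prevalence.

For a single binary belief the crude screen needs only the 2x2 table of
exposure A against outcome Y:

* ``delta_y`` — the unadjusted risk difference
  Pr(Y=1 | A=1) - Pr(Y=1 | A=0), with a Wald standard error from two
  independent binomial proportions;
* ``p`` — the exposure prevalence Pr(A=1) with its binomial standard error.

No continuity correction is applied; a belief with an empty margin is
reported as inestimable rather than patched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import BeliefItem
from .exceptions import EstimationError


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-outcome counts for one belief.

    ``n11``: A=1,Y=1; ``n10``: A=1,Y=0; ``n01``: A=0,Y=1; ``n00``: A=0,Y=0.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("2x2 counts must be nonnegative")

    @property
    def n_exposed(self) -> int:
        return self.n11 + self.n10

    @property
    def n_unexposed(self) -> int:
        return self.n01 + self.n00

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class CrudeEstimate:
    """Crude risk difference and prevalence with Wald standard errors."""

    delta_y: float
    se_delta_y: float
    p: float
    se_p: float
    n: int


def tabulate(ds, belief: BeliefItem | str) -> TwoByTwo:
    """Cross-tabulate one belief's exposure against the outcome."""
    belief_id = belief.id if isinstance(belief, BeliefItem) else belief
    a = ds.belief_exposure(belief_id)
    y = np.asarray(ds.outcome)
    n11 = int(np.sum((a == 1) & (y == 1)))
    n10 = int(np.sum((a == 1) & (y == 0)))
    n01 = int(np.sum((a == 0) & (y == 1)))
    n00 = int(np.sum((a == 0) & (y == 0)))
    return TwoByTwo(n11=n11, n10=n10, n01=n01, n00=n00)


def crude_delta_y(t: TwoByTwo) -> tuple[float, float]:
    """Unadjusted risk difference and its Wald standard error.

    SE is the unpooled difference-of-proportions form
    sqrt(p1(1-p1)/n1 + p0(1-p0)/n0).
    """
    if t.n_exposed == 0 or t.n_unexposed == 0:
        raise EstimationError("belief is constant: one exposure margin is empty")
    p1 = t.n11 / t.n_exposed
    p0 = t.n01 / t.n_unexposed
    se = math.sqrt(p1 * (1 - p1) / t.n_exposed + p0 * (1 - p0) / t.n_unexposed)
    return p1 - p0, se


def prevalence(t: TwoByTwo) -> tuple[float, float]:
    """Exposure prevalence Pr(A=1) and its binomial standard error."""
    if t.total == 0:
        raise EstimationError("empty 2x2 table")
    p = t.n_exposed / t.total
    se = math.sqrt(p * (1 - p) / t.total)
    return p, se


def crude_estimate(t: TwoByTwo) -> CrudeEstimate:
    """Bundle :func:`crude_delta_y` and :func:`prevalence` for one table."""
    dy, se_dy = crude_delta_y(t)
    p, se_p = prevalence(t)
    return CrudeEstimate(delta_y=dy, se_delta_y=se_dy, p=p, se_p=se_p, n=t.total)
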