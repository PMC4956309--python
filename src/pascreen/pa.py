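"""Population-attributability: the product estimator and its delta-method inference.

The population-attributability (PA) of a belief is

    PA = delta_y * p,

the risk difference (crude or MSM-adjusted) times the exposure prevalence —
the expected absolute change in the outcome rate if the belief state were
removed from the whole population. Assuming (approximate) independence of the
two estimators, the delta method gives

    SE(PA) = sqrt(delta_y^2 SE(p)^2 + p^2 SE(delta_y)^2),

with a Wald 95% CI PA +/- 1.96 SE(PA) and a two-sided normal p-value.
Dividing PA by the observed outcome rate gives the population attributable
fraction (PAF); no standard error is attached to the PAF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

from scipy.stats import norm

from .exceptions import EstimationError

Z_95 = 1.96  # conventional two-sided critical value, as printed in reports
ALPHA = 0.05


@dataclass(frozen=True)
class PAEstimate:
    """PA for one belief under one method, with delta-method inference."""

    method: str
    delta_y: float
    se_delta_y: float
    p: float
    se_p: float
    pa: float
    se_pa: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def combine_pa(
    delta_y: float,
    se_delta_y: float,
    p: float,
    se_p: float,
    method: str = "crude",
) -> PAEstimate:
    """Combine a risk difference and a prevalence into a PA estimate.

    ``se_pa == 0`` is handled as a point mass: p-value 0 if PA is nonzero,
    1 otherwise.
    """
    if se_delta_y < 0 or se_p < 0:
        raise ValueError("standard errors must be nonnegative")
    pa = delta_y * p
    se_pa = math.sqrt(delta_y**2 * se_p**2 + p**2 * se_delta_y**2)
    ci_low = pa - Z_95 * se_pa
    ci_high = pa + Z_95 * se_pa
    if se_pa == 0.0:
        p_value = 0.0 if pa != 0.0 else 1.0
    else:
        p_value = 2.0 * float(norm.sf(abs(pa) / se_pa))
    return PAEstimate(
        method=method,
        delta_y=float(delta_y),
        se_delta_y=float(se_delta_y),
        p=float(p),
        se_p=float(se_p),
        pa=float(pa),
        se_pa=float(se_pa),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p_value),
    )


def paf(pa: PAEstimate | float, outcome_rate: float) -> float:
    """Population attributable fraction: PA / Pr(Y=1). Point estimate only."""
    value = pa.pa if isinstance(pa, PAEstimate) else float(pa)
    if outcome_rate <= 0:
        raise EstimationError("outcome rate is zero; PAF undefined")
    return value / outcome_rate


def display_2dp(x: float) -> str:
    """Two-decimal display value using round-half-even (banker's rounding)."""
    return str(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))
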