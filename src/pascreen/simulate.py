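"""Synthetic survey cohorts with known counterfactual truth.

The generator draws, per respondent, a joint confounder stratum x from a
declared distribution pi(x), an exposure A ~ Bernoulli(expit(alpha0 +
alpha' d(x))) on the dummy design d(x), and *both* potential outcomes
Y_0 ~ Bernoulli(m0(x)), Y_1 ~ Bernoulli(m1(x)); the observed outcome is
Y = Y_A. Consistency and conditional exchangeability therefore hold by
construction, and every population quantity the estimators target is
available in closed form by enumerating strata:

    Pr(A=1)        = sum_x pi(x) e(x)
    dY_att         = sum_x [m1(x) - m0(x)] pi(x) e(x) / Pr(A=1)
    PA             = dY_att * Pr(A=1)
    Pr(Y=1)        = sum_x pi(x) [e(x) m1(x) + (1-e(x)) m0(x)]

The outcome model is parameterized directly by per-stratum counterfactual
probabilities so that truth is exact arithmetic, never an integral.

:func:`study_spec` builds the default cohort shape: the five socioeconomic
confounders of the smoking-cessation survey (age group, education, employment,
household income including a "did not respond" level, marital status) with
their published marginal frequencies, one belief with prevalence ~0.84, and
an outcome rate ~0.134. Intercepts are solved numerically so those margins
hold exactly in the population; slopes on the confounders make the exposure
and the baseline outcome risk co-vary across strata, i.e. a genuinely
confounded screen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .config import BeliefItem, ConfounderSpec, StudyConfig
from .crude import crude_estimate
from .exceptions import PAScreenError
from .msm import fit_weighted_lpm
from .pa import combine_pa
from .propensity import att_weights, fit_propensity
from .survey import DesignMatrix, SurveyDataset, encode_confounders

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class SimulationSpec:
    """Generative model for a study-shaped cohort.

    ``strata`` holds one row per joint confounder stratum as level indices
    into ``confounders[j].levels``; ``pi``, ``m0`` and ``m1`` align with its
    rows. The exposure model is logistic with coefficients on the dummy
    design implied by the confounder specs (reference levels dropped).
    """

    confounders: tuple[ConfounderSpec, ...]
    strata: np.ndarray
    pi: np.ndarray
    alpha0: float
    alpha: np.ndarray
    m0: np.ndarray
    m1: np.ndarray
    n: int
    seed: int
    belief: BeliefItem = field(
        default=BeliefItem(
            id="belief",
            column="belief",
            category="attitude",
            exposed_level="1",
            text="synthetic belief item",
        )
    )
    outcome_column: str = "intention"

    def __post_init__(self) -> None:
        k = self.strata.shape[0]
        for name, arr in (("pi", self.pi), ("m0", self.m0), ("m1", self.m1)):
            if np.asarray(arr).shape != (k,):
                raise ValueError(f"{name} must have one entry per stratum")
        if abs(float(np.sum(self.pi)) - 1.0) > _PROB_TOL:
            raise ValueError("stratum probabilities must sum to 1")
        if np.any(self.pi < 0):
            raise ValueError("stratum probabilities must be nonnegative")
        for name, arr in (("m0", self.m0), ("m1", self.m1)):
            if np.any((np.asarray(arr) < 0) | (np.asarray(arr) > 1)):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("cohort size must be positive")

    @property
    def n_strata(self) -> int:
        return int(self.strata.shape[0])

    def stratum_labels(self) -> list[tuple[str, ...]]:
        return [
            tuple(c.levels[i] for c, i in zip(self.confounders, row))
            for row in self.strata
        ]

    def stratum_design(self) -> DesignMatrix:
        """Dummy design with one row per stratum (intercept first)."""
        frame = pd.DataFrame(
            self.stratum_labels(), columns=[c.column for c in self.confounders]
        )
        return encode_confounders(frame, self.confounders)

    @property
    def e(self) -> np.ndarray:
        """True propensity e(x) per stratum."""
        d = self.stratum_design().matrix
        return expit(self.alpha0 + d[:, 1:] @ self.alpha)

    def study_config(self) -> StudyConfig:
        return StudyConfig(
            outcome_column=self.outcome_column,
            beliefs=(self.belief,),
            confounders=self.confounders,
        )


@dataclass(frozen=True)
class SimTruth:
    """Exact population values implied by a :class:`SimulationSpec`."""

    true_prevalence: float
    true_delta_att: float
    true_pa: float
    true_outcome_rate: float
    true_paf: float


def true_values(spec: SimulationSpec) -> SimTruth:
    """Exact enumeration of the estimands over the declared strata."""
    pi, e, m0, m1 = spec.pi, spec.e, spec.m0, spec.m1
    prev = float(np.sum(pi * e))
    if prev > 0:
        p_x_given_a1 = pi * e / prev
        delta_att = float(np.sum((m1 - m0) * p_x_given_a1))
    else:
        delta_att = 0.0
    pa = delta_att * prev
    rate = float(np.sum(pi * (e * m1 + (1 - e) * m0)))
    return SimTruth(
        true_prevalence=prev,
        true_delta_att=delta_att,
        true_pa=pa,
        true_outcome_rate=rate,
        true_paf=pa / rate if rate > 0 else float("nan"),
    )


def _draw(spec: SimulationSpec, n: int, rng: np.random.Generator):
    """Raw arrays (stratum index, A, Y0, Y1, Y) for one replicate."""
    s = rng.choice(spec.n_strata, size=n, p=spec.pi)
    e = spec.e[s]
    a = (rng.random(n) < e).astype(np.int8)
    y0 = (rng.random(n) < spec.m0[s]).astype(np.int8)
    y1 = (rng.random(n) < spec.m1[s]).astype(np.int8)
    y = np.where(a == 1, y1, y0).astype(np.int8)
    return s, a, y0, y1, y


def simulate(
    spec: SimulationSpec,
    n: int | None = None,
    seed: int | None = None,
    keep_counterfactuals: bool = False,
) -> SurveyDataset:
    """Draw a cohort and return it as a validated :class:`SurveyDataset`.

    ``n`` and ``seed`` default to the spec's own fields. With
    ``keep_counterfactuals`` the returned dataset carries a ``counterfactuals``
    attribute (DataFrame with stratum, y0, y1) for debugging and property
    checks; it is never written to file.
    """
    n = spec.n if n is None else int(n)
    seed = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    s, a, y0, y1, y = _draw(spec, n, rng)

    labels = spec.stratum_labels()
    conf = pd.DataFrame(
        [labels[i] for i in s], columns=[c.column for c in spec.confounders]
    )
    beliefs = pd.DataFrame({spec.belief.id: a})
    ds = SurveyDataset(
        outcome=y, beliefs=beliefs, confounders=conf, config=spec.study_config()
    )
    if keep_counterfactuals:
        object.__setattr__(
            ds,
            "counterfactuals",
            pd.DataFrame({"stratum": s, "y0": y0, "y1": y1}),
        )
    return ds


# --- default study-shaped cohort ------------------------------------------

_STUDY_CONFOUNDERS = (
    ConfounderSpec("age_group", ("20-29", "30-39"), "20-29"),
    ConfounderSpec(
        "education", ("highschool_or_less", "some_college", "college_graduate"),
        "highschool_or_less",
    ),
    ConfounderSpec(
        "employment", ("unemployed", "irregular", "regular"), "unemployed"
    ),
    ConfounderSpec(
        "income",
        ("did_not_respond", "lt_4m_jpy", "4_to_8m_jpy", "ge_8m_jpy"),
        "did_not_respond",
    ),
    ConfounderSpec("marital", ("unmarried", "married"), "unmarried"),
)

# published marginal frequencies of the five confounders (n = 500 survey)
_STUDY_MARGINALS = (
    (0.292, 0.708),
    (0.412, 0.324, 0.264),
    (0.332, 0.362, 0.306),
    (0.146, 0.392, 0.356, 0.106),
    (0.530, 0.470),
)

# slopes of exposure (alpha) and baseline risk (kappa) on the 9 dummies:
# age[30-39]; education[some, college]; employment[irregular, regular];
# income[lt4, 4-8, ge8]; marital[married]
_STUDY_ALPHA = np.array([0.5, -0.3, -0.6, 0.3, 0.6, -0.2, 0.2, 0.4, -0.5])
_STUDY_KAPPA = np.array([0.6, -0.3, -0.5, 0.3, 0.5, -0.4, 0.2, 0.4, -0.7])


def study_spec(
    n: int = 500,
    seed: int = 20100313,
    effect: float = 0.08,
    prevalence: float = 0.84,
    outcome_rate: float = 0.134,
    confounding: float = 1.0,
) -> SimulationSpec:
    """Default study-shaped cohort: five socioeconomic confounders, one belief.

    Parameters
    ----------
    effect : float
        Constant counterfactual risk difference m1(x) - m0(x); the ATT risk
        difference is then ``effect`` exactly.
    prevalence, outcome_rate : float
        Population Pr(A=1) and Pr(Y=1); intercepts are solved so these hold
        exactly under the stratum distribution.
    confounding : float
        Scales the exposure-model slopes. 0 gives a constant propensity
        (no confounding); 1 the default confounded design.
    """
    specs = _STUDY_CONFOUNDERS
    level_indices = [range(len(c.levels)) for c in specs]
    strata = np.array(list(itertools.product(*level_indices)), dtype=int)
    pi = np.array(
        [
            np.prod([_STUDY_MARGINALS[j][i] for j, i in enumerate(row)])
            for row in strata
        ]
    )
    pi = pi / pi.sum()  # guard accumulated float error; sums to 1 by design

    frame = pd.DataFrame(
        [
            tuple(c.levels[i] for c, i in zip(specs, row))
            for row in strata
        ],
        columns=[c.column for c in specs],
    )
    d = encode_confounders(frame, specs).matrix[:, 1:]

    alpha = confounding * _STUDY_ALPHA
    eta_a = d @ alpha
    alpha0 = brentq(
        lambda b: float(np.sum(pi * expit(b + eta_a))) - prevalence, -20.0, 20.0
    )
    e = expit(alpha0 + eta_a)

    eta_y = d @ _STUDY_KAPPA

    def rate_gap(k0: float) -> float:
        m0 = expit(k0 + eta_y)
        m1 = np.clip(m0 + effect, 0.0, 1.0)
        return float(np.sum(pi * (e * m1 + (1 - e) * m0))) - outcome_rate

    k0 = brentq(rate_gap, -20.0, 20.0)
    m0 = expit(k0 + eta_y)
    m1 = np.clip(m0 + effect, 0.0, 1.0)
    if np.any(m0 + effect > 1.0) or np.any(m0 + effect < 0.0):
        raise ValueError("effect pushes a counterfactual risk outside [0, 1]")

    return SimulationSpec(
        confounders=specs,
        strata=strata,
        pi=pi,
        alpha0=float(alpha0),
        alpha=alpha,
        m0=m0,
        m1=m1,
        n=n,
        seed=seed,
        belief=BeliefItem(
            id="workplace_smokefree",
            column="workplace_smokefree",
            category="perceived_control",
            exposed_level="1",
            text="I could quit smoking if my workplace became entirely smoke-free.",
        ),
    )


# --- estimator evaluation ---------------------------------------------------


def _estimate_once(spec: SimulationSpec, n: int, rng: np.random.Generator):
    """One replicate: crude and MSM PA estimates on freshly drawn arrays."""
    s, a, _, _, y = _draw(spec, n, rng)
    d_strata = spec.stratum_design()
    X = DesignMatrix(
        matrix=d_strata.matrix[s], columns=d_strata.columns
    )

    n1 = int(a.sum())
    t_counts = {
        "n11": int(np.sum((a == 1) & (y == 1))),
        "n10": int(np.sum((a == 1) & (y == 0))),
        "n01": int(np.sum((a == 0) & (y == 1))),
        "n00": int(np.sum((a == 0) & (y == 0))),
    }
    from .crude import TwoByTwo  # local import avoids cycle at module load

    t = TwoByTwo(**t_counts)
    ce = crude_estimate(t)
    crude = combine_pa(ce.delta_y, ce.se_delta_y, ce.p, ce.se_p, method="crude")

    pm = fit_propensity(X, a)
    w = att_weights(pm, a)
    mf = fit_weighted_lpm(y, a, w)
    msm = combine_pa(mf.beta1, mf.robust_se_beta1, ce.p, ce.se_p, method="msm")
    return crude, msm, n1


def evaluate_estimators(
    spec: SimulationSpec, n_reps: int, n: int, seed: int
) -> pd.DataFrame:
    """Monte-Carlo bias / RMSE / SE-calibration / CI-coverage table.

    Replicate r uses seed ``seed + r``. Replicate-level estimation failures
    (separation, empty margins) are counted, not fatal. The returned frame is
    indexed by method with columns ``mean_pa, bias, rmse, empirical_se,
    mean_se, coverage, n_ok, n_fail`` and carries the analytic truth in
    ``attrs["truth"]``.
    """
    truth = true_values(spec)
    records: dict[str, dict[str, list[float]]] = {
        m: {"pa": [], "se": [], "cover": []} for m in ("crude", "msm")
    }
    n_fail = {"crude": 0, "msm": 0}
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        try:
            crude, msm, _ = _estimate_once(spec, n, rng)
        except PAScreenError:
            n_fail["crude"] += 1
            n_fail["msm"] += 1
            continue
        for m, est in (("crude", crude), ("msm", msm)):
            records[m]["pa"].append(est.pa)
            records[m]["se"].append(est.se_pa)
            records[m]["cover"].append(
                float(est.ci_low <= truth.true_pa <= est.ci_high)
            )

    rows = []
    for m in ("crude", "msm"):
        pa = np.array(records[m]["pa"])
        se = np.array(records[m]["se"])
        cover = np.array(records[m]["cover"])
        rows.append(
            {
                "method": m,
                "mean_pa": pa.mean() if pa.size else np.nan,
                "bias": pa.mean() - truth.true_pa if pa.size else np.nan,
                "rmse": float(np.sqrt(np.mean((pa - truth.true_pa) ** 2)))
                if pa.size
                else np.nan,
                "empirical_se": pa.std(ddof=1) if pa.size > 1 else np.nan,
                "mean_se": se.mean() if se.size else np.nan,
                "coverage": cover.mean() if cover.size else np.nan,
                "n_ok": int(pa.size),
                "n_fail": n_fail[m],
            }
        )
    out = pd.DataFrame(rows).set_index("method")
    out.attrs["truth"] = truth
    return out


# --- spec file I/O -----------------------------------------------------------


def save_spec(spec: SimulationSpec, path) -> None:
    """Write a simulation spec as YAML (strata with pi, e, m0, m1 listed)."""
    e = spec.e
    doc = {
        "n": spec.n,
        "seed": spec.seed,
        "alpha0": float(spec.alpha0),
        "alpha": [float(v) for v in spec.alpha],
        "outcome_column": spec.outcome_column,
        "belief": {
            "id": spec.belief.id,
            "column": spec.belief.column,
            "category": spec.belief.category,
            "exposed_level": spec.belief.exposed_level,
            "text": spec.belief.text,
        },
        "confounders": [
            {"column": c.column, "levels": list(c.levels), "reference": c.reference}
            for c in spec.confounders
        ],
        "strata": [
            {
                "levels": list(labels),
                "pi": float(spec.pi[i]),
                "e": float(e[i]),
                "m0": float(spec.m0[i]),
                "m1": float(spec.m1[i]),
            }
            for i, labels in enumerate(spec.stratum_labels())
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_spec(path) -> SimulationSpec:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    confounders = tuple(
        ConfounderSpec(c["column"], tuple(c["levels"]), c["reference"])
        for c in doc["confounders"]
    )
    level_index = [
        {lvl: i for i, lvl in enumerate(c.levels)} for c in confounders
    ]
    strata = np.array(
        [
            [level_index[j][lvl] for j, lvl in enumerate(row["levels"])]
            for row in doc["strata"]
        ],
        dtype=int,
    )
    b = doc["belief"]
    return SimulationSpec(
        confounders=confounders,
        strata=strata,
        pi=np.array([row["pi"] for row in doc["strata"]], dtype=float),
        alpha0=float(doc["alpha0"]),
        alpha=np.array(doc["alpha"], dtype=float),
        m0=np.array([row["m0"] for row in doc["strata"]], dtype=float),
        m1=np.array([row["m1"] for row in doc["strata"]], dtype=float),
        n=int(doc["n"]),
        seed=int(doc["seed"]),
        belief=BeliefItem(
            id=b["id"],
            column=b["column"],
            category=b["category"],
            exposed_level=str(b["exposed_level"]),
            text=b.get("text", ""),
        ),
        outcome_column=doc.get("outcome_column", "intention"),
    )
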