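"""Belief screening: run the crude and MSM pipelines over every configured belief.

The public surface follows the model/results idiom: build a
:class:`BeliefScreenModel` from a validated dataset (or straight from the CSV
and configuration files), call :meth:`~BeliefScreenModel.fit`, and get a
:class:`BeliefScreenResults` holding one ranked row per belief-method pair —
risk difference, prevalence, PA, delta-method CI, p-value and PAF — plus the
list of beliefs that turned out inestimable and why.

Per-belief estimation failures (constant items, separation, positivity) never
abort the screen; they are recorded with their reason so a 46-item report
stays complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import StudyConfig, load_config
from .crude import crude_estimate, prevalence, tabulate
from .exceptions import PAScreenError
from .msm import fit_weighted_lpm
from .pa import PAEstimate, combine_pa, display_2dp, paf
from .propensity import att_weights, fit_propensity
from .survey import SurveyDataset, encode_confounders, read_survey

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "belief_id",
    "category",
    "text",
    "method",
    "delta_y",
    "p",
    "pa",
    "ci_low",
    "ci_high",
    "p_value",
    "significant",
    "note",
]


@dataclass(frozen=True)
class ScreenRow:
    """One belief-method line of the screening report."""

    belief_id: str
    category: str
    text: str
    estimate: PAEstimate
    paf: float | None
    note: str = ""


@dataclass(frozen=True)
class ScreenError:
    belief_id: str
    method: str
    reason: str


@dataclass
class BeliefScreenResults:
    """Ranked screening report; rows are ordered by descending PA, ties by id."""

    rows: list[ScreenRow]
    errors: list[ScreenError]
    outcome_rate: float
    n: int
    method: str
    p_adjusted: dict[tuple[str, str], float] | None = None
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.rows = sorted(self.rows, key=lambda r: (-r.estimate.pa, r.belief_id))

    def to_frame(self) -> pd.DataFrame:
        """Full-precision report as a DataFrame, one row per belief-method."""
        records = []
        for r in self.rows:
            e = r.estimate
            rec = {
                "belief_id": r.belief_id,
                "category": r.category,
                "text": r.text,
                "method": e.method,
                "delta_y": e.delta_y,
                "p": e.p,
                "pa": e.pa,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_value": e.p_value,
                "significant": e.significant,
                "note": r.note,
                "se_delta_y": e.se_delta_y,
                "se_p": e.se_p,
                "se_pa": e.se_pa,
                "paf": r.paf,
                "pa_display": display_2dp(e.pa),
            }
            if self.p_adjusted is not None:
                rec["p_value_bh"] = self.p_adjusted.get((r.belief_id, e.method))
            records.append(rec)
        cols = REPORT_COLUMNS + ["se_delta_y", "se_p", "se_pa", "paf", "pa_display"]
        if self.p_adjusted is not None:
            cols.append("p_value_bh")
        return pd.DataFrame.from_records(records, columns=cols)

    def to_tsv(self, path) -> None:
        """Write the report as TSV (full precision plus a 2-decimal display column)."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    def run_summary(self) -> str:
        """Machine-readable key-value run summary."""
        lines = [
            f"n\t{self.n}",
            f"outcome_rate\t{self.outcome_rate!r}",
            f"method\t{self.method}",
            f"n_rows\t{len(self.rows)}",
            f"n_inestimable\t{len(self.errors)}",
        ]
        for err in self.errors:
            lines.append(f"error\t{err.belief_id}\t{err.method}\t{err.reason}")
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        """Human-readable ranked table."""
        head = (
            f"Belief screen: n = {self.n}, outcome rate = {self.outcome_rate:.3f}, "
            f"method = {self.method}\n"
        )
        id_w = max([12] + [len(r.belief_id) for r in self.rows]) + 2
        widths = (id_w, 19, 8, 7, 7, 7, 17, 9)
        header = (
            f"{'belief_id':<{widths[0]}}{'category':<{widths[1]}}"
            f"{'method':<{widths[2]}}{'dY':>{widths[3]}}{'p':>{widths[4]}}"
            f"{'PA':>{widths[5]}}{'95% CI':>{widths[6]}}{'p-val':>{widths[7]}}"
        )
        rule = "-" * len(header)
        body = []
        for r in self.rows:
            e = r.estimate
            ci = f"({e.ci_low:+.2f},{e.ci_high:+.2f})"
            star = "*" if e.significant else " "
            body.append(
                f"{r.belief_id:<{widths[0]}}{r.category:<{widths[1]}}"
                f"{e.method:<{widths[2]}}{e.delta_y:>{widths[3]}.2f}"
                f"{e.p:>{widths[4]}.2f}{e.pa:>{widths[5]}.2f}"
                f"{ci:>{widths[6]}}{e.p_value:>{widths[7] - 1}.3f}{star}"
            )
        tail = []
        if self.errors:
            tail.append(rule)
            for err in self.errors:
                tail.append(f"inestimable: {err.belief_id} [{err.method}] — {err.reason}")
        return "\n".join([head + rule, header, rule, *body, *tail]) + "\n"


class BeliefScreenModel:
    """Screening model over all configured beliefs of a survey dataset.

    Parameters
    ----------
    dataset : SurveyDataset
        Validated survey data (see :func:`pascreen.survey.read_survey`).
    """

    def __init__(self, dataset: SurveyDataset):
        self.dataset = dataset
        self.config: StudyConfig = dataset.config

    @classmethod
    def from_csv(cls, data_path, config_path) -> "BeliefScreenModel":
        config = load_config(config_path)
        return cls(read_survey(data_path, config))

    def fit(
        self,
        method: str = "both",
        bh: bool = False,
        weight_cap: float | None = None,
    ) -> BeliefScreenResults:
        """Run the screen.

        Parameters
        ----------
        method : {"crude", "msm", "both"}
            Which estimation route(s) to run per belief.
        bh : bool
            Add Benjamini–Hochberg adjusted p-values (per method). Off by
            default; the primary report flags raw p < 0.05.
        weight_cap : float, optional
            Optional upper truncation for the MSM weights; no truncation by
            default.
        """
        if method not in ("crude", "msm", "both"):
            raise ValueError("method must be 'crude', 'msm' or 'both'")
        methods = ["crude", "msm"] if method == "both" else [method]
        ds = self.dataset
        y = np.asarray(ds.outcome, dtype=float)
        design = encode_confounders(ds.confounders, self.config.confounders)

        rows: list[ScreenRow] = []
        errors: list[ScreenError] = []
        for belief in self.config.beliefs:
            t = tabulate(ds, belief)
            for m in methods:
                try:
                    if m == "crude":
                        ce = crude_estimate(t)
                        est = combine_pa(
                            ce.delta_y, ce.se_delta_y, ce.p, ce.se_p, method="crude"
                        )
                    else:
                        a = ds.belief_exposure(belief.id)
                        pm = fit_propensity(design, a)
                        w = att_weights(pm, a)
                        if weight_cap is not None:
                            w = np.minimum(w, float(weight_cap))
                        mf = fit_weighted_lpm(y, a, w)
                        p, se_p = prevalence(t)
                        est = combine_pa(
                            mf.beta1, mf.robust_se_beta1, p, se_p, method="msm"
                        )
                except PAScreenError as exc:
                    logger.warning("belief %s inestimable (%s): %s", belief.id, m, exc)
                    errors.append(ScreenError(belief.id, m, str(exc)))
                    continue
                rate = ds.outcome_rate
                rows.append(
                    ScreenRow(
                        belief_id=belief.id,
                        category=belief.category,
                        text=belief.text,
                        estimate=est,
                        paf=paf(est, rate) if rate > 0 else None,
                    )
                )

        p_adjusted = None
        if bh and rows:
            p_adjusted = {}
            for m in methods:
                sub = [r for r in rows if r.estimate.method == m]
                if not sub:
                    continue
                _, adj, _, _ = multipletests(
                    [r.estimate.p_value for r in sub], method="fdr_bh"
                )
                for r, q in zip(sub, adj):
                    p_adjusted[(r.belief_id, m)] = float(q)

        return BeliefScreenResults(
            rows=rows,
            errors=errors,
            outcome_rate=ds.outcome_rate,
            n=ds.n,
            method=method,
            p_adjusted=p_adjusted,
        )


def screen_beliefs(
    ds: SurveyDataset,
    method: str = "both",
    bh: bool = False,
    weight_cap: float | None = None,
) -> BeliefScreenResults:
    """Functional wrapper around :class:`BeliefScreenModel`."""
    return BeliefScreenModel(ds).fit(method=method, bh=bh, weight_cap=weight_cap)


def write_report(results: BeliefScreenResults, path) -> None:
    """Write a screening report to a TSV file."""
    results.to_tsv(path)
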