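"""Reading, validating and encoding respondent-level survey tables.

The survey file is a delimited table (CSV, header row) with one row per
respondent. :func:`read_survey` validates it against a :class:`~pascreen.config.StudyConfig`
and returns a :class:`SurveyDataset` whose outcome and belief columns are
recoded to {0, 1} — A = 1 is whatever raw value the configuration declares as
``exposed_level`` for that item. Rows with missing values in any declared
column are dropped (with a logged count); a confounder may instead declare a
"did not respond"-style level, which is then kept as an ordinary category.

:func:`encode_confounders` produces the dummy-coded design matrix used by the
propensity model: an intercept column of ones followed by one indicator per
non-reference level, in declared confounder order then declared level order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import BeliefItem, ConfounderSpec, StudyConfig
from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)


def _norm(value) -> str:
    """Canonical token for a raw cell value: '1'/'1.0'/' Yes ' -> '1'/'1'/'yes'."""
    if isinstance(value, float) and float(value).is_integer():
        value = int(value)
    s = str(value).strip().lower()
    # integer-valued strings such as "1.0" from float-typed CSV columns
    if s.endswith(".0") and s[:-2].lstrip("-").isdigit():
        s = s[:-2]
    return s


def _recode_binary(raw: pd.Series, positive_level: str, what: str) -> np.ndarray:
    """Map a two-valued column to {0,1} with ``positive_level`` coded 1."""
    tokens = raw.map(_norm)
    observed = sorted(tokens.unique())
    if len(observed) > 2:
        raise DataError(
            f"{what}: expected a binary column but observed "
            f"{len(observed)} distinct values {observed}"
        )
    pos = _norm(positive_level)
    if len(observed) == 2 and pos not in observed:
        raise DataError(
            f"{what}: declared positive/exposed level {positive_level!r} "
            f"not among observed values {observed}"
        )
    return (tokens == pos).to_numpy(dtype=np.int8)


@dataclass(frozen=True)
class SurveyDataset:
    """Validated respondent-level data, recoded for analysis.

    Attributes
    ----------
    outcome : ndarray of {0,1}
        Behavioral-intention indicator Y (1 = intends the behavior).
    beliefs : DataFrame of {0,1}
        One column per belief item, named by belief id; A = 1 means the
        declared exposed state is held.
    confounders : DataFrame
        Categorical columns with values restricted to the declared levels.
    config : StudyConfig
        The configuration the dataset was validated against.
    """

    outcome: np.ndarray
    beliefs: pd.DataFrame
    confounders: pd.DataFrame
    config: StudyConfig

    @property
    def n(self) -> int:
        return int(self.outcome.shape[0])

    @property
    def outcome_rate(self) -> float:
        return float(np.mean(self.outcome))

    def belief_exposure(self, belief_id: str) -> np.ndarray:
        """The recoded exposure vector A for one belief."""
        return self.beliefs[belief_id].to_numpy(dtype=np.int8)

    def to_frame(self) -> pd.DataFrame:
        """Flat table: outcome, recoded beliefs (0/1), confounder labels."""
        out = pd.DataFrame({self.config.outcome_column: self.outcome})
        for bid in self.beliefs.columns:
            out[self.config.belief(bid).column] = self.beliefs[bid].to_numpy()
        for col in self.confounders.columns:
            out[col] = self.confounders[col].to_numpy()
        return out

    def canonical_config(self) -> StudyConfig:
        """Configuration matching :meth:`write` output (0/1 coding throughout)."""
        return replace(
            self.config,
            outcome_positive_level="1",
            beliefs=tuple(replace(b, exposed_level="1") for b in self.config.beliefs),
        )

    def write(self, path) -> None:
        """Write the dataset back to CSV in canonical 0/1 coding.

        Re-reading with :meth:`canonical_config` reproduces the dataset.
        """
        self.to_frame().to_csv(path, index=False)


def read_survey(path, config: StudyConfig) -> SurveyDataset:
    """Read and validate a survey CSV against the study configuration.

    Raises
    ------
    ConfigurationError
        If a declared column is absent from the file.
    DataError
        If the file is empty, a declared binary column has more than two
        observed values, or a confounder value is not a declared level.
    """
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError as e:
        raise DataError(f"survey file {path} is empty") from e
    if raw.shape[0] == 0:
        raise DataError(f"survey file {path} has a header but no rows")

    declared = [config.outcome_column]
    declared += [b.column for b in config.beliefs]
    declared += [c.column for c in config.confounders]
    missing = [c for c in declared if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"declared columns missing from {path}: {missing}")

    before = raw.shape[0]
    data = raw.dropna(subset=declared)
    dropped = before - data.shape[0]
    if dropped:
        logger.info("dropped %d of %d rows with missing declared values", dropped, before)
    if data.shape[0] == 0:
        raise DataError("all rows have missing values in declared columns")

    outcome = _recode_binary(
        data[config.outcome_column],
        config.outcome_positive_level,
        f"outcome column {config.outcome_column!r}",
    )

    beliefs = pd.DataFrame(index=range(data.shape[0]))
    for b in config.beliefs:
        beliefs[b.id] = _recode_binary(
            data[b.column], b.exposed_level, f"belief {b.id!r} (column {b.column!r})"
        )

    confounders = pd.DataFrame(index=range(data.shape[0]))
    for c in config.confounders:
        tokens = data[c.column].map(_norm)
        level_by_token = {_norm(l): l for l in c.levels}
        unknown = sorted(set(tokens.unique()) - set(level_by_token))
        if unknown:
            raise DataError(
                f"confounder {c.column!r}: observed values {unknown} "
                f"not among declared levels {list(c.levels)}"
            )
        confounders[c.column] = tokens.map(level_by_token).to_numpy()

    ds = SurveyDataset(
        outcome=outcome, beliefs=beliefs, confounders=confounders, config=config
    )
    logger.info(
        "read %d respondents, %d beliefs, %d confounders; outcome rate %.3f",
        ds.n, len(config.beliefs), len(config.confounders), ds.outcome_rate,
    )
    return ds


@dataclass(frozen=True)
class DesignMatrix:
    """Intercept + dummy indicators for every non-reference confounder level."""

    matrix: np.ndarray
    columns: tuple[str, ...]

    @property
    def n(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def k(self) -> int:
        return int(self.matrix.shape[1])


def encode_confounders(
    confounders: pd.DataFrame, specs: tuple[ConfounderSpec, ...] | list[ConfounderSpec]
) -> DesignMatrix:
    """Dummy-code categorical confounders with declared reference levels.

    Column order is deterministic: intercept first, then for each spec (in
    order) one column per non-reference level (in declared order). Columns are
    named ``column[level]``.
    """
    n = confounders.shape[0]
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for spec in specs:
        values = confounders[spec.column].to_numpy()
        unknown = sorted(set(values) - set(spec.levels))
        if unknown:
            raise DataError(
                f"confounder {spec.column!r}: unseen levels at encode time: {unknown}"
            )
        for level in spec.nonreference_levels:
            cols.append((values == level).astype(float))
            names.append(f"{spec.column}[{level}]")
    return DesignMatrix(matrix=np.column_stack(cols), columns=tuple(names))
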