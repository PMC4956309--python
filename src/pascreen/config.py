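"""Study configuration: which columns hold the outcome, the belief items and the confounders.

A configuration maps the rectangular survey file onto the analysis roles:

* one binary *outcome* column (behavioral intention, ``Y``),
* any number of binary *belief* columns (theory-of-planned-behavior items,
  each treated in turn as the exposure indicator ``A``),
* categorical *confounder* columns (socioeconomic status and similar).

Configurations are usually loaded from a YAML file with blocks ``outcome:``,
``beliefs:`` and ``confounders:``; see :func:`load_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .exceptions import ConfigurationError

BELIEF_CATEGORIES = ("attitude", "norm", "perceived_control")


@dataclass(frozen=True)
class BeliefItem:
    """One candidate belief: a binary survey item screened as an exposure.

    Parameters
    ----------
    id : str
        Short identifier used in reports and as the column name of the recoded
        exposure indicator.
    column : str
        Source column in the survey file.
    category : str
        One of ``attitude``, ``norm`` or ``perceived_control``.
    exposed_level : str
        The raw value coded as A = 1 (the belief state held). Matching is
        case-insensitive after stripping whitespace.
    text : str
        Item wording, carried through to reports.
    """

    id: str
    column: str
    category: str
    exposed_level: str
    text: str = ""

    def __post_init__(self) -> None:
        if self.category not in BELIEF_CATEGORIES:
            raise ConfigurationError(
                f"belief {self.id!r}: category {self.category!r} is not one of "
                f"{BELIEF_CATEGORIES}"
            )
        if not self.id:
            raise ConfigurationError("belief id must be non-empty")


@dataclass(frozen=True)
class ConfounderSpec:
    """A categorical confounder with an explicit dummy-coding reference level."""

    column: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ConfigurationError(
                f"confounder {self.column!r} needs at least 2 levels, got {self.levels}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError(f"confounder {self.column!r} has duplicate levels")
        if self.reference not in self.levels:
            raise ConfigurationError(
                f"confounder {self.column!r}: reference {self.reference!r} "
                f"not among levels {self.levels}"
            )

    @property
    def nonreference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)


@dataclass(frozen=True)
class StudyConfig:
    """Full column-role declaration for one survey analysis."""

    outcome_column: str
    beliefs: tuple[BeliefItem, ...]
    confounders: tuple[ConfounderSpec, ...] = ()
    outcome_positive_level: str = "1"

    def __post_init__(self) -> None:
        ids = [b.id for b in self.beliefs]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate belief ids in configuration")
        cols = [c.column for c in self.confounders]
        if len(set(cols)) != len(cols):
            raise ConfigurationError("duplicate confounder columns in configuration")

    def belief(self, belief_id: str) -> BeliefItem:
        for b in self.beliefs:
            if b.id == belief_id:
                return b
        raise KeyError(belief_id)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        try:
            outcome = d["outcome"]
            if isinstance(outcome, str):
                outcome_column, positive = outcome, "1"
            else:
                outcome_column = outcome["column"]
                positive = str(outcome.get("positive_level", "1"))
            beliefs = tuple(
                BeliefItem(
                    id=str(b["id"]),
                    column=str(b["column"]),
                    category=str(b["category"]),
                    exposed_level=str(b["exposed_level"]),
                    text=str(b.get("text", "")),
                )
                for b in d.get("beliefs", [])
            )
            confounders = tuple(
                ConfounderSpec(
                    column=str(c["column"]),
                    levels=tuple(str(l) for l in c["levels"]),
                    reference=str(c["reference"]),
                )
                for c in d.get("confounders", [])
            )
        except KeyError as e:  # missing required key
            raise ConfigurationError(f"missing configuration key: {e}") from e
        return cls(
            outcome_column=str(outcome_column),
            beliefs=beliefs,
            confounders=confounders,
            outcome_positive_level=positive,
        )

    def to_dict(self) -> dict:
        return {
            "outcome": {
                "column": self.outcome_column,
                "positive_level": self.outcome_positive_level,
            },
            "beliefs": [
                {
                    "id": b.id,
                    "column": b.column,
                    "category": b.category,
                    "exposed_level": b.exposed_level,
                    "text": b.text,
                }
                for b in self.beliefs
            ],
            "confounders": [
                {"column": c.column, "levels": list(c.levels), "reference": c.reference}
                for c in self.confounders
            ],
        }


def load_config(path) -> StudyConfig:
    """Read a YAML study configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigurationError(f"configuration file {path} is not a mapping")
    return StudyConfig.from_dict(d)


def save_config(config: StudyConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False, allow_unicode=True)
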