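import numpy as np
import pandas as pd
import pytest

from pascreen.config import BeliefItem, ConfounderSpec, StudyConfig
from pascreen.survey import SurveyDataset


def make_dataset(y, beliefs, confounders=None, specs=None) -> SurveyDataset:
    """Build a validated SurveyDataset directly from arrays.

    ``beliefs`` maps belief id -> 0/1 array; ``confounders`` maps column ->
    label array. Confounder specs default to sorted observed levels with the
    first as reference.
    """
    y = np.asarray(y, dtype=np.int8)
    bdf = pd.DataFrame({k: np.asarray(v, dtype=np.int8) for k, v in beliefs.items()})
    confounders = confounders or {}
    cdf = pd.DataFrame({k: np.asarray(v, dtype=object) for k, v in confounders.items()})
    if specs is None:
        specs = tuple(
            ConfounderSpec(col, tuple(sorted(map(str, set(cdf[col])))),
                           sorted(map(str, set(cdf[col])))[0])
            for col in cdf.columns
        )
    items = tuple(
        BeliefItem(id=k, column=k, category="attitude", exposed_level="1")
        for k in beliefs
    )
    config = StudyConfig(
        outcome_column="intention", beliefs=items, confounders=tuple(specs)
    )
    if cdf.empty:
        cdf = pd.DataFrame(index=range(len(y)))
    return SurveyDataset(outcome=y, beliefs=bdf, confounders=cdf, config=config)


@pytest.fixture
def six_row_csv(tmp_path):
    """Handwritten 6-respondent survey file with one belief and one confounder."""
    path = tmp_path / "survey.csv"
    path.write_text(
        "intention,b1,region\n"
        "Yes,yes,north\n"
        "yes,YES,south\n"
        "No,Yes,north\n"
        "yes,no,south\n"
        "no,No,north\n"
        "no,no,south\n"
    )
    config = StudyConfig(
        outcome_column="intention",
        outcome_positive_level="yes",
        beliefs=(
            BeliefItem(
                id="b1", column="b1", category="attitude", exposed_level="yes",
                text="a handwritten belief",
            ),
        ),
        confounders=(ConfounderSpec("region", ("north", "south"), "north"),),
    )
    return path, config


def saturated_fixture(rng, n_range=(30, 80), k_range=(2, 4)):
    """Random single-confounder fixture where positivity holds in every stratum."""
    while True:
        n = int(rng.integers(*n_range))
        k = int(rng.integers(*k_range))
        s = rng.integers(0, k, n)
        e = rng.uniform(0.2, 0.8, k)
        a = (rng.random(n) < e[s]).astype(int)
        if all(a[s == j].min() == 0 and a[s == j].max() == 1 for j in np.unique(s)):
            break
    y = (rng.random(n) < rng.uniform(0.1, 0.6, k)[s]).astype(int)
    return s, a, y
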