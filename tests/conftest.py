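import numpy as np
import pandas as pd
import pytest

from dietval import composition, scoring, synthetic


@pytest.fixture(scope="session")
def schema() -> scoring.DhqSchema:
    return scoring.DhqSchema.default()


@pytest.fixture(scope="session")
def small_cohort() -> synthetic.SyntheticCohort:
    return synthetic.fixture_small()


@pytest.fixture(scope="session")
def small_table(small_cohort) -> composition.CompositionTable:
    return composition.CompositionTable.from_frames(
        small_cohort.foods, small_cohort.components
    )


@pytest.fixture(scope="session")
def cohort96_generator() -> synthetic.CohortGenerator:
    """Paper-shaped generator (n=96, ~30 repeat recalls); calibration is
    computed once for the whole session."""
    gen = synthetic.CohortGenerator(
        synthetic.CohortSpec(n_participants=96, p_repeat_recall=0.3125, seed=0)
    )
    gen.item_loadings
    return gen


def cohort_to_day_frame(cohort: synthetic.SyntheticCohort) -> pd.DataFrame:
    table = composition.CompositionTable.from_frames(cohort.foods, cohort.components)
    return composition.day_intake_frame(cohort.recalls, table)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20220)
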