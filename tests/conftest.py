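import importlib.resources

import pandas as pd
import pytest

from eyelab import psychometrics as psy
from eyelab import synthetic_data as synth


@pytest.fixture(scope="session")
def reference_loadings() -> pd.DataFrame:
    """Printed two-factor loading table (both study cohorts)."""
    source = importlib.resources.files("eyelab.data") / "reference_loadings.csv"
    with importlib.resources.as_file(source) as path:
        return pd.read_csv(path, comment="#")


@pytest.fixture(scope="session")
def study2_design() -> synth.StudyDesign:
    return synth.generate_design(76, seed=11)


@pytest.fixture(scope="session")
def study2_ratings(study2_design) -> pd.DataFrame:
    return synth.generate_ratings(study2_design, synth.RatingModelSpec(seed=12))


@pytest.fixture(scope="session")
def factor_solution(study2_ratings):
    items = study2_ratings[list(psy.PERSONALITY_ITEMS)]
    return psy.ml_factor_analysis(items, 2)


@pytest.fixture(scope="session")
def scale_table(study2_ratings) -> pd.DataFrame:
    return psy.scale_scores(study2_ratings, synth.DEFAULT_MAPPING)
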