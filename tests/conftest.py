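import numpy as np
import pandas as pd
import pytest

from kanopa.catalog import load_reference_tallies
from kanopa.kano import FeatureTally, KanoCategory


def tally_from_row(row) -> FeatureTally:
    return FeatureTally(
        feature_code=row["feature_code"],
        counts={KanoCategory(c): int(row[c]) for c in "AMOIRQ"},
        n=int(row["n"]),
    )


@pytest.fixture(scope="session")
def reference_tallies() -> pd.DataFrame:
    """Published per-stratum vote tallies with their printed verdicts."""
    return load_reference_tallies()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_survey():
    """A complete (no missingness) synthetic survey of 60 respondents."""
    from kanopa.synthetic import Scenario, generate_survey

    return generate_survey(Scenario(n_respondents=60, missing_rate=0.0, seed=11))
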