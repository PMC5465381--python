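"""Static metadata: the 52-feature design catalog and reference tallies.

The design-feature catalog enumerates 52 candidate functions of
exercise-promotion mobile apps, each derived from a behaviour-change
technique (goal setting, self-monitoring, contingent rewards, social
support, prompts/cues, ...). Codes run A1..A52 and are the join key of
every table the pipeline emits.

The reference tallies are published per-feature Kano vote counts from the
motivating survey of middle-aged adults (one stratum per subsample), kept
as package data so the categorization rules can be validated against known
outputs without the raw respondent data.
"""

from __future__ import annotations

from importlib import resources
from functools import lru_cache

import pandas as pd

__all__ = [
    "FEATURE_CODES",
    "load_catalog",
    "load_reference_tallies",
    "load_example_prevalence",
]

#: All 52 feature codes in catalog order.
FEATURE_CODES: tuple[str, ...] = tuple(f"A{i}" for i in range(1, 53))


def _data_path(name: str):
    return resources.files("kanopa.data").joinpath(name)


@lru_cache(maxsize=None)
def load_catalog() -> pd.DataFrame:
    """Feature catalog: columns ``feature_code``, ``description``."""
    with resources.as_file(_data_path("feature_catalog.csv")) as p:
        df = pd.read_csv(p)
    assert tuple(df["feature_code"]) == FEATURE_CODES
    return df


@lru_cache(maxsize=None)
def load_reference_tallies() -> pd.DataFrame:
    """Published per-feature vote tallies by stratum.

    Columns: stratum (total, pa_medium, pa_low, mpse_high, mpse_medium,
    mpse_low), n, feature_code, A, M, O, I, R, Q, and the published rounded
    category_strength, total_strength and classification string.
    """
    with resources.as_file(_data_path("reference_tallies.csv")) as p:
        return pd.read_csv(p)


@lru_cache(maxsize=None)
def load_example_prevalence() -> pd.DataFrame:
    """Example market-prevalence map (share of surveyed apps offering each
    feature, in percent; blank where the feature was not audited)."""
    with resources.as_file(_data_path("prevalence_example.csv")) as p:
        return pd.read_csv(p)
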