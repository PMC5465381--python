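"""Synthetic survey generator.

Emulates the statistical structure the pipeline assumes — ~105 respondents
aged 40-69, IPAQ activity patterns spanning the three PA levels, ten
correlated MPSE Likert items with level-dependent location, per-feature
Kano answer propensities that vary by PA level and MPSE level, and sparse
MCAR missingness in the Kano answers — so every stage is testable without
any respondent data. The generating ground truth (true category per
feature, true levels) is returned alongside the survey table.

Kano answers are produced by inverting the evaluation matrix: a category is
drawn from the respondent's propensity vector and realized as a uniformly
random answer pair among the matrix cells carrying that category, so every
generated pair classifies back to its recorded true category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import FEATURE_CODES
from .instruments import (
    ActivityRecord,
    Domain,
    Intensity,
    Level,
    score_ipaq,
)
from .kano import (
    EVALUATION_MATRIX,
    AnswerLevel,
    FeatureTally,
    KanoCategory,
    KanoPair,
)
from .io import ipaq_column_pairs, kano_answer_columns, survey_columns

__all__ = [
    "Scenario",
    "SyntheticSurvey",
    "CATEGORY_ORDER",
    "answer_pair_for_category",
    "default_kano_propensities",
    "generate_survey",
    "fixture_from_tally",
]

#: Propensity vectors are ordered (A, M, O, I, R, Q).
CATEGORY_ORDER: tuple[KanoCategory, ...] = (
    KanoCategory.A,
    KanoCategory.M,
    KanoCategory.O,
    KanoCategory.I,
    KanoCategory.R,
    KanoCategory.Q,
)

# Inverse lookup of the evaluation matrix: category -> its answer-pair cells.
_CELLS_BY_CATEGORY: dict[KanoCategory, list[tuple[AnswerLevel, AnswerLevel]]] = {
    c: sorted(
        (pair for pair, cat in EVALUATION_MATRIX.items() if cat is c),
        key=lambda p: (p[0].value, p[1].value),
    )
    for c in KanoCategory
}


def answer_pair_for_category(
    category: KanoCategory, rng: np.random.Generator
) -> tuple[AnswerLevel, AnswerLevel]:
    """A uniformly random answer pair classifying to the given category."""
    cells = _CELLS_BY_CATEGORY[KanoCategory(category)]
    return cells[rng.integers(len(cells))]


def default_kano_propensities() -> dict[tuple[str, Level, Level], np.ndarray]:
    """Study-shaped per-feature propensities over the six categories.

    Baseline perception is indifferent-dominated (as observed on the total
    sample, where nearly every feature was indifferent). Low-PA respondents
    shift mass toward must-be and one-dimensional (features read as
    necessities), high-MPSE respondents toward one-dimensional (performance
    is valued), medium-MPSE mildly toward must-be; reverse/questionable
    answers stay rare throughout.
    """
    base = np.array([0.12, 0.11, 0.11, 0.58, 0.05, 0.03])  # A M O I R Q
    out: dict[tuple[str, Level, Level], np.ndarray] = {}
    for code in FEATURE_CODES:
        for pa in Level:
            for mpse in Level:
                p = base.copy()
                if pa is Level.LOW:
                    p += np.array([0.02, 0.14, 0.10, -0.26, 0.0, 0.0])
                if mpse is Level.HIGH:
                    p += np.array([0.02, 0.0, 0.14, -0.16, 0.0, 0.0])
                elif mpse is Level.MEDIUM:
                    p += np.array([0.0, 0.08, 0.0, -0.08, 0.0, 0.0])
                p = np.clip(p, 0.005, None)
                out[(code, pa, mpse)] = p / p.sum()
    return out


@dataclass
class Scenario:
    """Generator settings; defaults mirror the motivating study's structure."""

    n_respondents: int = 105
    age_range: tuple[int, int] = (40, 69)
    #: P(low, medium, high) PA — the observed subsample mix 22/18/62 of 102.
    pa_level_probs: tuple[float, float, float] = (22 / 102, 18 / 102, 62 / 102)
    #: Latent MPSE location (mean, sd) of the ten 1-5 items per level.
    mpse_level_profiles: Mapping[Level, tuple[float, float]] = field(
        default_factory=lambda: {
            Level.LOW: (2.0, 0.5),
            Level.MEDIUM: (3.2, 0.5),
            Level.HIGH: (4.3, 0.5),
        }
    )
    kano_propensities: Mapping[tuple[str, Level, Level], np.ndarray] | None = None
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if abs(sum(self.pa_level_probs) - 1.0) > 1e-9:
            raise ValueError("pa_level_probs must sum to 1")
        if self.kano_propensities is None:
            self.kano_propensities = default_kano_propensities()
        for key, p in self.kano_propensities.items():
            if abs(float(np.sum(p)) - 1.0) > 1e-9:
                raise ValueError(f"propensity for {key} does not sum to 1")


@dataclass
class SyntheticSurvey:
    """Survey table in the interchange schema plus the generating truth."""

    table: pd.DataFrame
    truth: pd.DataFrame  # respondent_id, pa_level, mpse_level, <code>_category


def _ipaq_records_for_level(level: Level, rng: np.random.Generator) -> list[ActivityRecord]:
    """Activity records that score to the requested PA level.

    Constructed from level-typical templates with jitter, then verified
    against the scoring rules (rejection sampling, since the categorical
    rules are disjunctive and not invertible).
    """
    for _ in range(100):
        records: list[ActivityRecord] = []
        if level is Level.LOW:
            if rng.random() < 0.5:
                records.append(
                    ActivityRecord(
                        Domain.LEISURE, Intensity.WALKING,
                        int(rng.integers(1, 3)), float(rng.integers(10, 20)),
                    )
                )
        elif level is Level.MEDIUM:
            records.append(
                ActivityRecord(
                    Domain.LEISURE, Intensity.MODERATE,
                    int(rng.integers(5, 7)), float(rng.integers(30, 60)),
                )
            )
            if rng.random() < 0.5:
                records.append(
                    ActivityRecord(
                        Domain.TRANSPORT, Intensity.WALKING,
                        int(rng.integers(1, 3)), float(rng.integers(10, 25)),
                    )
                )
        else:
            records.append(
                ActivityRecord(
                    Domain.LEISURE, Intensity.VIGOROUS,
                    int(rng.integers(4, 7)), float(rng.integers(50, 90)),
                )
            )
            if rng.random() < 0.5:
                records.append(
                    ActivityRecord(
                        Domain.LEISURE, Intensity.WALKING,
                        int(rng.integers(2, 5)), float(rng.integers(20, 40)),
                    )
                )
        if score_ipaq(records).pa_level is level:
            return records
    raise RuntimeError(f"could not realize PA level {level} by rejection sampling")


def _mpse_items(
    profile: tuple[float, float], rng: np.random.Generator
) -> list[int]:
    """Ten correlated Likert items: shared respondent factor + item noise."""
    mean, sd = profile
    factor = rng.normal(0.0, sd)
    items = mean + factor + rng.normal(0.0, 0.45, size=10)
    return [int(v) for v in np.clip(np.rint(items), 1, 5)]


def generate_survey(scenario: Scenario | None = None) -> SyntheticSurvey:
    """Generate a complete synthetic survey; bit-reproducible under the seed."""
    sc = scenario if scenario is not None else Scenario()
    rng = np.random.default_rng(sc.seed)
    levels = (Level.LOW, Level.MEDIUM, Level.HIGH)

    rows = []
    truth_rows = []
    for i in range(sc.n_respondents):
        rid = f"R{i + 1:03d}"
        age = int(rng.integers(sc.age_range[0], sc.age_range[1] + 1))
        sex = "M" if rng.random() < 0.5 else "F"
        pa_level = levels[rng.choice(3, p=np.asarray(sc.pa_level_probs))]
        mpse_level = levels[rng.integers(3)]

        row: dict = {"respondent_id": rid, "age": age, "sex": sex}
        for k, item in enumerate(_mpse_items(sc.mpse_level_profiles[mpse_level], rng), 1):
            row[f"mpse_{k:02d}"] = item

        records = _ipaq_records_for_level(pa_level, rng)
        by_class = {(r.domain, r.intensity): r for r in records}
        for days_col, min_col, d, inten in ipaq_column_pairs():
            r = by_class.get((d, inten))
            row[days_col] = r.days_per_week if r else 0
            row[min_col] = r.minutes_per_day if r else 0.0

        truth: dict = {
            "respondent_id": rid,
            "pa_level": pa_level.value,
            "mpse_level": mpse_level.value,
        }
        for code in FEATURE_CODES:
            p = np.asarray(sc.kano_propensities[(code, pa_level, mpse_level)])
            category = CATEGORY_ORDER[rng.choice(6, p=p)]
            f, d = answer_pair_for_category(category, rng)
            row[f"{code}_f"] = int(f)
            row[f"{code}_d"] = int(d)
            truth[f"{code}_category"] = category.value
        rows.append(row)
        truth_rows.append(truth)

    table = pd.DataFrame(rows, columns=survey_columns())

    if sc.missing_rate > 0:
        kano_cols = kano_answer_columns()
        mask = rng.random((len(table), len(kano_cols))) < sc.missing_rate
        block = table[kano_cols].astype("Int64").to_numpy(dtype=object)
        block[mask] = pd.NA
        table[kano_cols] = pd.DataFrame(block, columns=kano_cols, index=table.index).astype("Int64")

    return SyntheticSurvey(table=table, truth=pd.DataFrame(truth_rows))


def fixture_from_tally(
    tally: FeatureTally, rng: np.random.Generator
) -> list[KanoPair]:
    """Answer pairs whose tally reproduces the given counts exactly.

    Counts are deterministic; the realization of each vote as a matrix cell
    is randomized within its category.
    """
    pairs: list[KanoPair] = []
    for category in CATEGORY_ORDER:
        for _ in range(tally.counts[category]):
            f, d = answer_pair_for_category(category, rng)
            pairs.append(
                KanoPair(feature_code=tally.feature_code, functional=f, dysfunctional=d)
            )
    return pairs
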