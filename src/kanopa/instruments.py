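"""Respondent-level instruments: IPAQ-long-form scoring, the mobile-phone
self-efficacy (MPSE) scale, and the age inclusion filter.

IPAQ long form records, for each of four life domains (work, transport,
domestic/garden, leisure), how many days in the past week and how many
minutes per day the respondent performed activity of a given intensity.
Scoring follows the IPAQ group's protocol: each activity class carries a
MET weight (metabolic equivalent of task), weekly minutes per intensity
class are truncated at 1260 (the 3 h/day equivalent), and MET-minutes/week
accumulate as MET x days x minutes. The continuous score is then collapsed
into a categorical physical-activity level (low / medium / high) by the
protocol's disjunctive day-count and MET-minute rules.

MPSE is a 10-item, 5-point Likert adaptation of the Computer Self-Efficacy
Scale; it is scored as the item sum (range 10-50) and split into tertiles
for stratification.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Domain",
    "Intensity",
    "IntensityClass",
    "ActivityRecord",
    "IpaqProfile",
    "RespondentProfile",
    "Level",
    "DEFAULT_MET_TABLE",
    "VALID_DOMAIN_INTENSITY",
    "INTENSITY_CLASS",
    "met_minutes",
    "truncate_intensity",
    "score_ipaq",
    "pa_category",
    "mpse_score",
    "tertile_split",
    "cronbach_alpha",
    "apply_inclusion_filter",
]

logger = logging.getLogger(__name__)


class Domain(str, enum.Enum):
    WORK = "work"
    TRANSPORT = "transport"
    DOMESTIC_GARDEN = "domestic_garden"
    LEISURE = "leisure"


class Intensity(str, enum.Enum):
    WALKING = "walking"
    MODERATE = "moderate"
    VIGOROUS = "vigorous"
    CYCLING = "cycling"
    VIGOROUS_YARD = "vigorous_yard"
    MODERATE_YARD = "moderate_yard"
    INDOOR_CHORES = "indoor_chores"


class IntensityClass(str, enum.Enum):
    """Protocol intensity classes for truncation and the categorical rules."""

    WALKING = "walking"
    MODERATE = "moderate"
    VIGOROUS = "vigorous"


class Level(str, enum.Enum):
    """Three-level stratification labels shared by PA and MPSE."""

    LOW = "LOW"
    MEDIUM = "MEDIUM"
    HIGH = "HIGH"


#: The ten (domain, intensity) activity classes of the IPAQ long form.
VALID_DOMAIN_INTENSITY: frozenset[tuple[Domain, Intensity]] = frozenset(
    {
        (Domain.WORK, Intensity.WALKING),
        (Domain.WORK, Intensity.MODERATE),
        (Domain.WORK, Intensity.VIGOROUS),
        (Domain.TRANSPORT, Intensity.WALKING),
        (Domain.TRANSPORT, Intensity.CYCLING),
        (Domain.DOMESTIC_GARDEN, Intensity.VIGOROUS_YARD),
        (Domain.DOMESTIC_GARDEN, Intensity.MODERATE_YARD),
        (Domain.DOMESTIC_GARDEN, Intensity.INDOOR_CHORES),
        (Domain.LEISURE, Intensity.WALKING),
        (Domain.LEISURE, Intensity.MODERATE),
        (Domain.LEISURE, Intensity.VIGOROUS),
    }
)

#: Protocol MET weights per activity class.
DEFAULT_MET_TABLE: dict[tuple[Domain, Intensity], float] = {
    (Domain.WORK, Intensity.WALKING): 3.3,
    (Domain.WORK, Intensity.MODERATE): 4.0,
    (Domain.WORK, Intensity.VIGOROUS): 8.0,
    (Domain.TRANSPORT, Intensity.WALKING): 3.3,
    (Domain.TRANSPORT, Intensity.CYCLING): 6.0,
    (Domain.DOMESTIC_GARDEN, Intensity.VIGOROUS_YARD): 5.5,
    (Domain.DOMESTIC_GARDEN, Intensity.MODERATE_YARD): 4.0,
    (Domain.DOMESTIC_GARDEN, Intensity.INDOOR_CHORES): 3.0,
    (Domain.LEISURE, Intensity.WALKING): 3.3,
    (Domain.LEISURE, Intensity.MODERATE): 4.0,
    (Domain.LEISURE, Intensity.VIGOROUS): 8.0,
}

# Walking stays walking; only work/leisure vigorous activity is "vigorous"
# for the categorical rules; cycling, yard work and chores count as moderate.
INTENSITY_CLASS: dict[Intensity, IntensityClass] = {
    Intensity.WALKING: IntensityClass.WALKING,
    Intensity.MODERATE: IntensityClass.MODERATE,
    Intensity.VIGOROUS: IntensityClass.VIGOROUS,
    Intensity.CYCLING: IntensityClass.MODERATE,
    Intensity.VIGOROUS_YARD: IntensityClass.MODERATE,
    Intensity.MODERATE_YARD: IntensityClass.MODERATE,
    Intensity.INDOOR_CHORES: IntensityClass.MODERATE,
}

#: Weekly per-intensity-class truncation cap in minutes (3 h/day x 7 days).
DEFAULT_TRUNCATION_CAP = 1260.0


@dataclass(frozen=True)
class ActivityRecord:
    """One IPAQ item: days/week and minutes/day of one activity class."""

    domain: Domain
    intensity: Intensity
    days_per_week: int
    minutes_per_day: float

    def __post_init__(self) -> None:
        if (self.domain, self.intensity) not in VALID_DOMAIN_INTENSITY:
            raise ValueError(
                f"invalid activity class ({self.domain.value}, {self.intensity.value})"
            )
        if not 0 <= self.days_per_week <= 7:
            raise ValueError("days_per_week must be in 0..7")
        if self.minutes_per_day < 0:
            raise ValueError("minutes_per_day must be >= 0")

    @property
    def weekly_minutes(self) -> float:
        return self.days_per_week * self.minutes_per_day

    @property
    def intensity_class(self) -> IntensityClass:
        return INTENSITY_CLASS[self.intensity]


@dataclass(frozen=True)
class IpaqProfile:
    """Scored IPAQ: MET-minutes/week by intensity class and the PA level."""

    met_minutes_by_intensity: Mapping[IntensityClass, float]
    total_met_minutes: float
    pa_level: Level


def met_minutes(
    record: ActivityRecord,
    met_table: Mapping[tuple[Domain, Intensity], float] | None = None,
) -> float:
    """MET-minutes/week of a single record: MET weight x days x minutes."""
    table = DEFAULT_MET_TABLE if met_table is None else met_table
    key = (record.domain, record.intensity)
    if key not in table:
        raise KeyError(f"no MET value for activity class {key}")
    return table[key] * record.days_per_week * record.minutes_per_day


def truncate_intensity(weekly_minutes: float, cap: float = DEFAULT_TRUNCATION_CAP) -> float:
    """Cap weekly minutes of one intensity class at the protocol maximum."""
    if weekly_minutes < 0:
        raise ValueError("weekly minutes must be >= 0")
    return min(weekly_minutes, cap)


def score_ipaq(
    records: Sequence[ActivityRecord],
    met_table: Mapping[tuple[Domain, Intensity], float] | None = None,
    cap: float = DEFAULT_TRUNCATION_CAP,
) -> IpaqProfile:
    """Score a respondent's IPAQ records into MET-minutes and a PA level.

    Truncation is applied to the pooled weekly minutes of each intensity
    class before MET weighting: when a class exceeds the cap, every record
    in the class is scaled down proportionally, preserving the domain mix of
    the capped remainder.
    """
    table = DEFAULT_MET_TABLE if met_table is None else met_table

    weekly_by_class: dict[IntensityClass, float] = {c: 0.0 for c in IntensityClass}
    for r in records:
        weekly_by_class[r.intensity_class] += r.weekly_minutes
    scale = {
        c: (truncate_intensity(m, cap) / m if m > 0 else 1.0)
        for c, m in weekly_by_class.items()
    }

    met_by_class: dict[IntensityClass, float] = {c: 0.0 for c in IntensityClass}
    for r in records:
        met_by_class[r.intensity_class] += met_minutes(r, table) * scale[r.intensity_class]
    total = sum(met_by_class.values())

    level = pa_category(records, total_met_minutes=total)
    return IpaqProfile(
        met_minutes_by_intensity=met_by_class,
        total_met_minutes=total,
        pa_level=level,
    )


def pa_category(
    records: Sequence[ActivityRecord], total_met_minutes: float
) -> Level:
    """Categorical PA level from the protocol's disjunctive rules.

    HIGH: vigorous activity on >=3 days with a weekly total of >=1500
    MET-min, or any-intensity activity on >=7 days with >=3000 MET-min.
    MEDIUM: >=3 days of vigorous activity of >=20 min/day, or >=5 days of
    moderate activity or walking of >=30 min/day, or >=5 days of any
    combination reaching >=600 MET-min. Otherwise LOW.
    """
    active = [r for r in records if r.days_per_week > 0 and r.minutes_per_day > 0]
    vig_days = sum(r.days_per_week for r in active if r.intensity_class is IntensityClass.VIGOROUS)
    total_days = sum(r.days_per_week for r in active)
    vig20_days = sum(
        r.days_per_week
        for r in active
        if r.intensity_class is IntensityClass.VIGOROUS and r.minutes_per_day >= 20
    )
    modwalk30_days = sum(
        r.days_per_week
        for r in active
        if r.intensity_class in (IntensityClass.MODERATE, IntensityClass.WALKING)
        and r.minutes_per_day >= 30
    )

    if (vig_days >= 3 and total_met_minutes >= 1500) or (
        total_days >= 7 and total_met_minutes >= 3000
    ):
        return Level.HIGH
    if (
        vig20_days >= 3
        or modwalk30_days >= 5
        or (total_days >= 5 and total_met_minutes >= 600)
    ):
        return Level.MEDIUM
    return Level.LOW


class IncompleteScaleError(ValueError):
    """An instrument cannot be scored because items are missing."""


def mpse_score(items: Sequence[float]) -> float:
    """Sum the 10 MPSE Likert items (each 1-5; total range 10-50)."""
    items = list(items)
    if len(items) != 10:
        raise IncompleteScaleError(f"expected 10 items, got {len(items)}")
    vals = []
    for x in items:
        if x is None or (isinstance(x, float) and math.isnan(x)):
            raise IncompleteScaleError("missing MPSE item")
        if not 1 <= x <= 5:
            raise ValueError(f"MPSE item {x} outside 1..5")
        vals.append(float(x))
    return float(sum(vals))


def tertile_split(scores: pd.Series | Sequence[float]) -> pd.Series:
    """Partition scores into LOW / MEDIUM / HIGH tertiles by rank.

    Group sizes are made as equal as the ranks allow; every score tied with
    a boundary score is assigned to the lower group, so the mapping from
    score to level is deterministic and weakly monotone.
    """
    s = pd.Series(scores, dtype=float)
    n = len(s)
    if n < 3:
        raise ValueError("tertile split needs at least 3 scores")
    ordered = np.sort(s.to_numpy())
    b1 = int(math.floor(n / 3 + 0.5))
    b2 = int(math.floor(2 * n / 3 + 0.5))
    cut1 = ordered[b1 - 1]
    cut2 = ordered[b2 - 1]
    levels = pd.Series(Level.HIGH, index=s.index, dtype=object)
    levels[s <= cut2] = Level.MEDIUM
    levels[s <= cut1] = Level.LOW
    sizes = levels.value_counts()
    logger.info(
        "tertile split: LOW=%d MEDIUM=%d HIGH=%d (cuts <=%g, <=%g)",
        sizes.get(Level.LOW, 0), sizes.get(Level.MEDIUM, 0), sizes.get(Level.HIGH, 0),
        cut1, cut2,
    )
    return levels


def cronbach_alpha(item_matrix: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with unbiased (n-1 denominator) sample variances throughout.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 respondents and 2 items")
    if np.isnan(x).any():
        raise ValueError("item matrix contains missing values")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass(frozen=True)
class RespondentProfile:
    """Derived strata for one respondent; levels are None where unscorable."""

    respondent_id: str
    age: int
    pa_level: Level | None = None
    mpse_score: float | None = None
    mpse_level: Level | None = None


def apply_inclusion_filter(
    respondents: pd.DataFrame,
    age_column: str = "age",
    min_age: int = 40,
    max_age: int = 69,
) -> pd.DataFrame:
    """Keep respondents aged 40-69 inclusive; log exclusion counts.

    Rows with a missing age are excluded and logged under a distinct reason.
    """
    age = pd.to_numeric(respondents[age_column], errors="coerce")
    missing = age.isna()
    out_of_range = ~missing & ((age < min_age) | (age > max_age))
    kept = respondents.loc[~missing & ~out_of_range]
    if missing.any():
        logger.warning("excluded %d respondent(s) with missing age", int(missing.sum()))
    if out_of_range.any():
        logger.info(
            "excluded %d respondent(s) outside age range %d-%d",
            int(out_of_range.sum()), min_age, max_age,
        )
    return kept
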