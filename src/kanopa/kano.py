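"""Kano-model categorization of survey answer pairs and per-feature voting.

The Kano method elicits quality perception of a product feature with a pair
of questions: a *functional* question (how would you feel if the feature
were present?) and a *dysfunctional* question (how would you feel if it
were absent?), each answered on the same five-point scale. The pair of
answers is looked up in the Kano evaluation matrix, which assigns one of
six quality categories:

* ``A`` attractive — presence delights, absence does not dissatisfy;
* ``O`` one-dimensional — satisfaction tracks performance in both directions;
* ``M`` must-be — taken for granted, absence dissatisfies;
* ``I`` indifferent — presence or absence does not matter;
* ``R`` reverse — presence dissatisfies;
* ``Q`` questionable — a contradictory answer pair.

A sample's verdict on a feature is the plurality winner of the per-respondent
categories, refined by two strength statistics and the Lee–Newcomb rule:
when the *category strength* (percentage-point gap between the two most
frequent categories) is below 6% while the *total strength* (share of
positive A/O/M votes) is at least 60%, the feature is "statistically
impossible to classify" and is reported as a mixed (X) set of categories.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AnswerLevel",
    "KanoCategory",
    "KanoPair",
    "FeatureTally",
    "Classification",
    "KanoThresholds",
    "EVALUATION_MATRIX",
    "COLUMN_ORDER",
    "TIEBREAK_ORDER",
    "classify_pair",
    "tally_feature",
    "category_strength",
    "total_strength",
    "classify_feature",
    "round_half_away",
]

logger = logging.getLogger(__name__)


class AnswerLevel(enum.IntEnum):
    """Five-point answer scale of the functional/dysfunctional questions.

    File encoding is the integer value: 1 = "Satisfied" ... 5 = "Dissatisfied".
    """

    SATISFIED = 1
    SHOULD_BE = 2
    INDIFFERENT = 3
    LIVE_WITH = 4
    DISSATISFIED = 5


class KanoCategory(str, enum.Enum):
    """The six Kano quality categories."""

    A = "A"  # attractive
    O = "O"  # one-dimensional  # noqa: E741
    M = "M"  # must-be
    I = "I"  # indifferent  # noqa: E741
    R = "R"  # reverse
    Q = "Q"  # questionable

    @property
    def is_positive(self) -> bool:
        return self in _POSITIVE


_POSITIVE = frozenset({KanoCategory.A, KanoCategory.O, KanoCategory.M})

#: Fixed column order of the tally tables (A, M, O, I, R, Q); used to break
#: ordering ties among equally frequent categories in a mixed set.
COLUMN_ORDER: tuple[KanoCategory, ...] = (
    KanoCategory.A,
    KanoCategory.M,
    KanoCategory.O,
    KanoCategory.I,
    KanoCategory.R,
    KanoCategory.Q,
)

#: Positive-priority order used to break a tied plurality winner when the
#: feature is NOT sent to the mixed category ("aggressive position" on
#: positive categories): must-be > one-dimensional > attractive >
#: indifferent > reverse > questionable.
TIEBREAK_ORDER: tuple[KanoCategory, ...] = (
    KanoCategory.M,
    KanoCategory.O,
    KanoCategory.A,
    KanoCategory.I,
    KanoCategory.R,
    KanoCategory.Q,
)

# Kano evaluation matrix: rows = functional answer, columns = dysfunctional
# answer, both in scale order Satisfied, Should-be, Indifferent, Live-with,
# Dissatisfied.
_MATRIX_ROWS: dict[AnswerLevel, tuple[str, str, str, str, str]] = {
    AnswerLevel.SATISFIED: ("Q", "A", "A", "A", "O"),
    AnswerLevel.SHOULD_BE: ("R", "I", "I", "I", "M"),
    AnswerLevel.INDIFFERENT: ("R", "I", "I", "I", "M"),
    AnswerLevel.LIVE_WITH: ("R", "I", "I", "I", "M"),
    AnswerLevel.DISSATISFIED: ("R", "R", "R", "R", "Q"),
}

EVALUATION_MATRIX: dict[tuple[AnswerLevel, AnswerLevel], KanoCategory] = {
    (f, d): KanoCategory(_MATRIX_ROWS[f][d - 1])
    for f in AnswerLevel
    for d in AnswerLevel
}


class NotClassifiableError(ValueError):
    """Raised when an answer pair with a missing answer is classified.

    Missing answers must be resolved upstream (multiple imputation) before
    categorization; missingness is never a seventh category.
    """


def classify_pair(
    functional: AnswerLevel | int | None, dysfunctional: AnswerLevel | int | None
) -> KanoCategory:
    """Look up the Kano category for one (functional, dysfunctional) pair."""
    if functional is None or dysfunctional is None:
        raise NotClassifiableError(
            "missing functional or dysfunctional answer; impute before classifying"
        )
    return EVALUATION_MATRIX[(AnswerLevel(functional), AnswerLevel(dysfunctional))]


@dataclass(frozen=True)
class KanoPair:
    """One respondent's answer pair for one design feature."""

    feature_code: str
    functional: AnswerLevel | None
    dysfunctional: AnswerLevel | None

    @property
    def is_complete(self) -> bool:
        return self.functional is not None and self.dysfunctional is not None

    def category(self) -> KanoCategory:
        return classify_pair(self.functional, self.dysfunctional)


@dataclass(frozen=True)
class FeatureTally:
    """Vote counts over the six Kano categories for one feature in a subsample."""

    feature_code: str
    counts: Mapping[KanoCategory, int]
    n: int

    def __post_init__(self) -> None:
        counts = {c: int(self.counts.get(c, 0)) for c in KanoCategory}
        if any(v < 0 for v in counts.values()):
            raise ValueError("negative category count")
        if sum(counts.values()) != self.n:
            raise ValueError(
                f"counts sum to {sum(counts.values())} but n={self.n} "
                f"for feature {self.feature_code}"
            )
        object.__setattr__(self, "counts", counts)

    def count(self, category: KanoCategory) -> int:
        return self.counts[category]


@dataclass(frozen=True)
class KanoThresholds:
    """Lee–Newcomb decision thresholds: mixed if strength < 6% and total ≥ 60%."""

    strength_threshold_pct: float = 6.0
    total_threshold_pct: float = 60.0

    def __post_init__(self) -> None:
        for v in (self.strength_threshold_pct, self.total_threshold_pct):
            if not 0.0 < v < 100.0:
                raise ValueError("thresholds must lie strictly in (0, 100)")


@dataclass(frozen=True)
class Classification:
    """Categorization verdict for one feature: a single category or a mixed set."""

    feature_code: str
    kind: str  # "SINGLE" or "MIXED"
    categories: tuple[KanoCategory, ...]
    category_strength_pct: float
    total_strength_pct: float

    def __post_init__(self) -> None:
        if self.kind not in ("SINGLE", "MIXED"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "SINGLE" and len(self.categories) != 1:
            raise ValueError("SINGLE classification must hold exactly one category")
        if self.kind == "MIXED" and len(self.categories) < 2:
            raise ValueError("MIXED classification needs at least two categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("duplicate categories in classification")

    @property
    def has_positive(self) -> bool:
        return any(c.is_positive for c in self.categories)

    @property
    def positive_categories(self) -> tuple[KanoCategory, ...]:
        return tuple(c for c in self.categories if c.is_positive)

    @property
    def includes_indifferent(self) -> bool:
        return KanoCategory.I in self.categories

    def render(self) -> str:
        """Render as printed in the tally tables, e.g. ``M`` or ``X(I, A)``."""
        if self.kind == "SINGLE":
            return self.categories[0].value
        return "X(" + ", ".join(c.value for c in self.categories) + ")"


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (68.75 -> 69).

    Display convention of the strength columns; never used in threshold
    comparisons, which operate on the unrounded percentages.
    """
    import math

    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def tally_feature(pairs: Sequence[KanoPair]) -> FeatureTally:
    """Count per-category votes for one feature from complete answer pairs."""
    if not pairs:
        raise ValueError("cannot tally an empty list of pairs")
    codes = {p.feature_code for p in pairs}
    if len(codes) != 1:
        raise ValueError(f"mixed feature codes in tally input: {sorted(codes)}")
    counts: dict[KanoCategory, int] = {c: 0 for c in KanoCategory}
    for p in pairs:
        counts[p.category()] += 1
    return FeatureTally(feature_code=codes.pop(), counts=counts, n=len(pairs))


def _top_two_counts(tally: FeatureTally) -> tuple[int, int]:
    """Largest and second-largest *distinct* count values (0 if absent)."""
    distinct = sorted(set(tally.counts.values()), reverse=True)
    top = distinct[0]
    second = distinct[1] if len(distinct) > 1 else 0
    return top, second


def category_strength(tally: FeatureTally) -> float:
    """Percentage-point gap between the two most frequent categories.

    When two or more categories share the top count the gap is zero by
    definition. Returned unrounded; rounding is a presentation concern.
    """
    if tally.n <= 0:
        raise ValueError("empty tally")
    top, second = _top_two_counts(tally)
    leaders = [c for c in KanoCategory if tally.counts[c] == top]
    if len(leaders) >= 2:
        return 0.0
    return 100.0 * (top - second) / tally.n


def total_strength(tally: FeatureTally) -> float:
    """Percentage of respondents voting a positive category (A, O or M).

    The denominator is the full subsample, including R and Q votes.
    """
    if tally.n <= 0:
        raise ValueError("empty tally")
    pos = sum(tally.counts[c] for c in _POSITIVE)
    return 100.0 * pos / tally.n


def classify_feature(
    tally: FeatureTally, thresholds: KanoThresholds | None = None
) -> Classification:
    """Categorize a feature from its vote tally.

    Plurality vote with the Lee–Newcomb refinement: if the category strength
    is strictly below the 6% threshold while the total strength reaches the
    60% threshold (both compared unrounded), the feature is mixed (X). The
    mixed set contains every category sharing the top count; when the top
    count is held by a single category the runners-up at the second-largest
    distinct count are included as well. Mixed-set ordering is by descending
    count, ties by the fixed column order A, M, O, I, R, Q.

    Otherwise the verdict is the single plurality winner; a tied top count is
    broken by positive priority M > O > A > I > R > Q.
    """
    if thresholds is None:
        thresholds = KanoThresholds()
    if tally.n <= 0:
        raise ValueError("empty tally")
    s = category_strength(tally)
    t = total_strength(tally)
    top, second = _top_two_counts(tally)
    leaders = [c for c in COLUMN_ORDER if tally.counts[c] == top]

    if s < thresholds.strength_threshold_pct and t >= thresholds.total_threshold_pct:
        members = list(leaders)
        if len(leaders) == 1 and second > 0:
            members += [c for c in COLUMN_ORDER if tally.counts[c] == second]
        if len(members) >= 2:
            return Classification(
                feature_code=tally.feature_code,
                kind="MIXED",
                categories=tuple(members),
                category_strength_pct=s,
                total_strength_pct=t,
            )
        # unanimous vote: mixed condition can hold (s==100 impossible; only
        # via thresholds), fall through to a single verdict

    winner = min(leaders, key=TIEBREAK_ORDER.index)
    if winner in (KanoCategory.R, KanoCategory.Q):
        warnings.warn(
            f"feature {tally.feature_code}: plurality winner is "
            f"{winner.value} (reverse/questionable)",
            stacklevel=2,
        )
    return Classification(
        feature_code=tally.feature_code,
        kind="SINGLE",
        categories=(winner,),
        category_strength_pct=s,
        total_strength_pct=t,
    )
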