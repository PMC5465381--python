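"""Stratified Kano categorization and the demand-vs-supply comparison.

The categorization runs on the total sample and on six subsamples: the
three physical-activity levels (from IPAQ) and the three mobile-phone
self-efficacy tertiles. Respondents missing the score for one dimension
drop out of that dimension's strata only. The demand-supply report lines
up every feature that won at least one positive category anywhere against
a user-supplied market-prevalence map (share of surveyed apps offering
the feature), the "aggressive position": a feature is worth recommending
as soon as any winning category is positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import FEATURE_CODES
from .instruments import Level, RespondentProfile
from .kano import (
    COLUMN_ORDER,
    Classification,
    FeatureTally,
    KanoCategory,
    KanoPair,
    KanoThresholds,
    classify_feature,
    round_half_away,
    tally_feature,
)

__all__ = [
    "STRATUM_NAMES",
    "Stratum",
    "build_strata",
    "categorize_stratum",
    "classification_table",
    "positive_feature_count",
    "load_prevalence_map",
    "DemandSupplyRow",
    "demand_supply_report",
    "demand_supply_table",
]

logger = logging.getLogger(__name__)

STRATUM_NAMES: tuple[str, ...] = (
    "TOTAL",
    "PA_LOW",
    "PA_MEDIUM",
    "PA_HIGH",
    "MPSE_LOW",
    "MPSE_MEDIUM",
    "MPSE_HIGH",
)


@dataclass(frozen=True)
class Stratum:
    name: str
    respondent_ids: frozenset[str]

    @property
    def n(self) -> int:
        return len(self.respondent_ids)


def build_strata(profiles: Sequence[RespondentProfile]) -> list[Stratum]:
    """Seven strata: the total sample plus PA and MPSE level subsamples.

    A respondent lacking a PA level is excluded from the PA strata only,
    and likewise for MPSE; empty strata are reported, not errors.
    """
    if not profiles:
        raise ValueError("no respondents to stratify")
    total = frozenset(p.respondent_id for p in profiles)
    by_pa = {
        lvl: frozenset(p.respondent_id for p in profiles if p.pa_level is lvl)
        for lvl in Level
    }
    by_mpse = {
        lvl: frozenset(p.respondent_id for p in profiles if p.mpse_level is lvl)
        for lvl in Level
    }
    strata = [
        Stratum("TOTAL", total),
        Stratum("PA_LOW", by_pa[Level.LOW]),
        Stratum("PA_MEDIUM", by_pa[Level.MEDIUM]),
        Stratum("PA_HIGH", by_pa[Level.HIGH]),
        Stratum("MPSE_LOW", by_mpse[Level.LOW]),
        Stratum("MPSE_MEDIUM", by_mpse[Level.MEDIUM]),
        Stratum("MPSE_HIGH", by_mpse[Level.HIGH]),
    ]
    logger.info("strata sizes: %s", {s.name: s.n for s in strata})
    return strata


def categorize_stratum(
    stratum: Stratum,
    kano_pairs: Mapping[str, Sequence[KanoPair]],
    thresholds: KanoThresholds | None = None,
) -> list[Classification]:
    """Classify every feature from the stratum members' answer pairs.

    ``kano_pairs`` maps respondent_id to that respondent's (complete,
    post-imputation) answer pairs. Output is one Classification per feature
    in catalog order; an empty stratum yields an empty list with a warning.
    """
    if stratum.n == 0:
        logger.warning("stratum %s is empty; no classifications", stratum.name)
        return []
    by_feature: dict[str, list[KanoPair]] = {code: [] for code in FEATURE_CODES}
    for rid in sorted(stratum.respondent_ids):
        for pair in kano_pairs[rid]:
            by_feature[pair.feature_code].append(pair)
    out = []
    for code in FEATURE_CODES:
        pairs = by_feature[code]
        if not pairs:
            continue
        out.append(classify_feature(tally_feature(pairs), thresholds))
    return out


def classification_table(
    classifications: Sequence[Classification],
    tallies: Mapping[str, FeatureTally] | None = None,
) -> pd.DataFrame:
    """Render classifications in the published tally-table layout.

    Columns: feature_code, A, M, O, I, R, Q, category_strength,
    total_strength (both display-rounded), classification.
    """
    rows = []
    for c in classifications:
        row: dict = {"feature_code": c.feature_code}
        if tallies is not None:
            t = tallies[c.feature_code]
            for cat in COLUMN_ORDER:
                row[cat.value] = t.counts[cat]
        row["category_strength"] = round_half_away(c.category_strength_pct)
        row["total_strength"] = round_half_away(c.total_strength_pct)
        row["classification"] = c.render()
        rows.append(row)
    return pd.DataFrame(rows)


def positive_feature_count(classifications: Iterable[Classification]) -> int:
    """Number of features whose winning set includes a positive category."""
    return sum(1 for c in classifications if c.has_positive)


NOT_AVAILABLE = "NOT_AVAILABLE"


def load_prevalence_map(path_or_df) -> dict[str, float | str]:
    """Read a prevalence CSV (feature_code, prevalence_pct; blank = unknown)."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    out: dict[str, float | str] = {}
    for _, row in df.iterrows():
        code = str(row["feature_code"])
        if code not in FEATURE_CODES:
            logger.warning("prevalence map: unknown feature code %r ignored", code)
            continue
        val = row["prevalence_pct"]
        if pd.isna(val):
            out[code] = NOT_AVAILABLE
        else:
            val = float(val)
            if not 0 <= val <= 100:
                raise ValueError(f"prevalence {val} for {code} outside [0, 100]")
            out[code] = val
    return out


@dataclass(frozen=True)
class DemandSupplyRow:
    """Positive winning categories of one feature across all strata."""

    feature_code: str
    positive_by_stratum: Mapping[str, tuple[KanoCategory, ...]]
    tied_with_indifferent: Mapping[str, bool]
    prevalence: float | str


def demand_supply_report(
    classifications_by_stratum: Mapping[str, Sequence[Classification]],
    prevalence: Mapping[str, float | str] | None = None,
) -> tuple[list[DemandSupplyRow], dict]:
    """Demanded features (>=1 positive winning category anywhere) vs supply.

    Returns the per-feature rows plus a summary with the mean prevalence
    over rows whose prevalence is available and the denominators used.
    """
    prevalence = dict(prevalence or {})
    by_stratum = {
        name: {c.feature_code: c for c in cls}
        for name, cls in classifications_by_stratum.items()
    }
    rows: list[DemandSupplyRow] = []
    for code in FEATURE_CODES:
        positive: dict[str, tuple[KanoCategory, ...]] = {}
        tied: dict[str, bool] = {}
        for name, cls in by_stratum.items():
            c = cls.get(code)
            if c is not None and c.has_positive:
                positive[name] = c.positive_categories
                tied[name] = c.includes_indifferent
        if positive:
            rows.append(
                DemandSupplyRow(
                    feature_code=code,
                    positive_by_stratum=positive,
                    tied_with_indifferent=tied,
                    prevalence=prevalence.get(code, NOT_AVAILABLE),
                )
            )
    available = [r.prevalence for r in rows if r.prevalence != NOT_AVAILABLE]
    summary = {
        "n_demanded_features": len(rows),
        "n_with_prevalence": len(available),
        "mean_prevalence_pct": (float(np.mean(available)) if available else math.nan),
        "positive_feature_count_by_stratum": {
            name: positive_feature_count(cls)
            for name, cls in classifications_by_stratum.items()
        },
    }
    return rows, summary


def demand_supply_table(
    rows: Sequence[DemandSupplyRow],
    stratum_names: Sequence[str] = STRATUM_NAMES,
) -> pd.DataFrame:
    """Flatten the demand-supply rows to a CSV-ready table.

    Per stratum, the positive categories are rendered like ``(O, M)`` with a
    companion boolean column marking a tie with the indifferent category.
    """
    recs = []
    for r in rows:
        rec: dict = {"feature_code": r.feature_code}
        for name in stratum_names:
            cats = r.positive_by_stratum.get(name, ())
            rec[name] = ", ".join(c.value for c in cats)
            rec[f"{name}_tied_with_indifferent"] = bool(
                r.tied_with_indifferent.get(name, False)
            )
        rec["prevalence_pct"] = (
            "" if r.prevalence == NOT_AVAILABLE else r.prevalence
        )
        recs.append(rec)
    return pd.DataFrame(recs)
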