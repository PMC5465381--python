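"""Survey file format, validation and run configuration.

The survey interchange format is a single wide CSV (RFC-4180, UTF-8, header
required), one row per respondent:

* ``respondent_id``, ``age``, ``sex``;
* ``mpse_01`` .. ``mpse_10`` — Likert 1-5 ("strongly disagree" .. "strongly
  agree");
* two columns per IPAQ activity class, ``<domain>_<intensity>_days`` (0-7)
  and ``<domain>_<intensity>_min`` (minutes/day);
* two columns per design feature, ``<code>_f`` and ``<code>_d`` — the
  functional and dysfunctional Kano answers coded 1 = "Satisfied" ..
  5 = "Dissatisfied".

A blank cell is a missing value everywhere.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .catalog import FEATURE_CODES
from .instruments import (
    DEFAULT_MET_TABLE,
    DEFAULT_TRUNCATION_CAP,
    VALID_DOMAIN_INTENSITY,
    ActivityRecord,
    Domain,
    Intensity,
)
from .kano import AnswerLevel, KanoPair, KanoThresholds

__all__ = [
    "SurveyValidationError",
    "ipaq_column_pairs",
    "survey_columns",
    "kano_answer_columns",
    "read_survey",
    "write_survey",
    "ipaq_records_from_row",
    "kano_pairs_from_row",
    "RunConfig",
]

logger = logging.getLogger(__name__)

# Deterministic column order for the 11 IPAQ activity classes.
_IPAQ_PAIRS: tuple[tuple[Domain, Intensity], ...] = tuple(
    sorted(VALID_DOMAIN_INTENSITY, key=lambda di: (di[0].value, di[1].value))
)


def ipaq_column_pairs() -> list[tuple[str, str, Domain, Intensity]]:
    """(days_column, minutes_column, domain, intensity) for every activity class."""
    out = []
    for d, i in _IPAQ_PAIRS:
        stem = f"{d.value}_{i.value}"
        out.append((f"{stem}_days", f"{stem}_min", d, i))
    return out


def kano_answer_columns() -> list[str]:
    """The 104 Kano answer columns in catalog order (A1_f, A1_d, ...)."""
    cols = []
    for code in FEATURE_CODES:
        cols += [f"{code}_f", f"{code}_d"]
    return cols


def survey_columns() -> list[str]:
    """The exact survey CSV header."""
    cols = ["respondent_id", "age", "sex"]
    cols += [f"mpse_{i:02d}" for i in range(1, 11)]
    for days_col, min_col, _, _ in ipaq_column_pairs():
        cols += [days_col, min_col]
    cols += kano_answer_columns()
    return cols


class SurveyValidationError(ValueError):
    """Itemized schema violations found while reading a survey file."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid survey file:\n" + "\n".join(f"  - {p}" for p in problems))


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read and validate a survey CSV; return a typed DataFrame.

    Likert and Kano answers come back as nullable integers (pd.NA = missing).
    Raises :class:`SurveyValidationError` listing every violation found.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"respondent_id": str})
    problems: list[str] = []

    expected = survey_columns()
    missing_cols = [c for c in expected if c not in df.columns]
    unknown_cols = [c for c in df.columns if c not in expected]
    if missing_cols:
        problems.append(f"missing columns: {missing_cols[:5]}{'...' if len(missing_cols) > 5 else ''}")
    if unknown_cols:
        problems.append(f"unknown columns: {unknown_cols}")
    if df.empty:
        problems.append("no respondent rows")
    if problems:
        raise SurveyValidationError(problems)
    df = df[expected]

    dupes = df["respondent_id"][df["respondent_id"].duplicated()].unique().tolist()
    if dupes:
        problems.append(f"duplicate respondent_id: {dupes}")

    likert_cols = [f"mpse_{i:02d}" for i in range(1, 11)] + kano_answer_columns()
    for col in likert_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.notna() & ~vals.isin([1, 2, 3, 4, 5])]
        for idx in bad:
            problems.append(f"row {idx}: column {col} value {df.at[idx, col]!r} outside 1..5")
        df[col] = vals.astype("Int64")

    for days_col, min_col, _, _ in ipaq_column_pairs():
        days = pd.to_numeric(df[days_col], errors="coerce")
        bad = df.index[days.notna() & ~days.between(0, 7)]
        for idx in bad:
            problems.append(f"row {idx}: column {days_col} value {df.at[idx, days_col]!r} outside 0..7")
        df[days_col] = days.astype("Int64")
        mins = pd.to_numeric(df[min_col], errors="coerce")
        bad = df.index[mins.notna() & (mins < 0)]
        for idx in bad:
            problems.append(f"row {idx}: column {min_col} negative")
        df[min_col] = mins.astype(float)

    if problems:
        raise SurveyValidationError(problems)

    n_missing = df.isna().sum()
    with_missing = n_missing[n_missing > 0]
    if len(with_missing):
        logger.info(
            "survey %s: %d rows, missing cells in %d column(s): %s",
            path.name, len(df), len(with_missing),
            ", ".join(f"{c}={int(v)}" for c, v in with_missing.items()),
        )
    return df


def write_survey(df: pd.DataFrame, path: str | Path) -> None:
    """Write a survey table in the interchange CSV format."""
    df.to_csv(path, index=False, lineterminator="\n")


def ipaq_records_from_row(row: Mapping[str, Any]) -> list[ActivityRecord] | None:
    """Build the activity records for one respondent; None if any field missing."""
    records = []
    for days_col, min_col, domain, intensity in ipaq_column_pairs():
        days, mins = row[days_col], row[min_col]
        if pd.isna(days) or pd.isna(mins):
            return None
        records.append(
            ActivityRecord(
                domain=domain,
                intensity=intensity,
                days_per_week=int(days),
                minutes_per_day=float(mins),
            )
        )
    return records


def kano_pairs_from_row(row: Mapping[str, Any]) -> list[KanoPair]:
    """The 52 answer pairs of one respondent; missing answers become None."""
    pairs = []
    for code in FEATURE_CODES:
        f, d = row[f"{code}_f"], row[f"{code}_d"]
        pairs.append(
            KanoPair(
                feature_code=code,
                functional=None if pd.isna(f) else AnswerLevel(int(f)),
                dysfunctional=None if pd.isna(d) else AnswerLevel(int(d)),
            )
        )
    return pairs


@dataclass
class RunConfig:
    """All tunable pipeline parameters; defaults are the study settings."""

    strength_threshold_pct: float = 6.0
    total_threshold_pct: float = 60.0
    imputation_m: int = 3
    predictor_alpha: float = 0.05
    regression_alpha: float = 0.05
    separation_bound: float = 15.0
    truncation_cap: float = DEFAULT_TRUNCATION_CAP
    min_age: int = 40
    max_age: int = 69
    seed: int = 0
    met_table: dict[tuple[Domain, Intensity], float] = field(
        default_factory=lambda: dict(DEFAULT_MET_TABLE)
    )

    @property
    def thresholds(self) -> KanoThresholds:
        return KanoThresholds(self.strength_threshold_pct, self.total_threshold_pct)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        flat = {
            "kano.strength_threshold_pct": "strength_threshold_pct",
            "kano.total_threshold_pct": "total_threshold_pct",
            "imputation.m": "imputation_m",
            "imputation.predictor_alpha": "predictor_alpha",
            "imputation.seed": "seed",
            "regression.alpha": "regression_alpha",
            "regression.separation_bound": "separation_bound",
            "ipaq.truncation_cap": "truncation_cap",
            "inclusion.min_age": "min_age",
            "inclusion.max_age": "max_age",
            "seed": "seed",
        }
        for dotted, attr in flat.items():
            section, _, key = dotted.partition(".")
            if key:
                if isinstance(raw.get(section), Mapping) and key in raw[section]:
                    kwargs[attr] = raw[section][key]
            elif section in raw:
                kwargs[attr] = raw[section]
        cfg = cls(**kwargs)
        met = (raw.get("ipaq") or {}).get("met_table") if isinstance(raw.get("ipaq"), Mapping) else None
        if met:
            for name, value in met.items():
                domain_str, _, intensity_str = name.rpartition("_")
                # names use the survey column stems, e.g. leisure_walking
                for (d, i) in DEFAULT_MET_TABLE:
                    if f"{d.value}_{i.value}" == name:
                        cfg.met_table[(d, i)] = float(value)
                        break
                else:
                    raise ValueError(f"unknown MET table entry {name!r}")
        return cfg

    def log_parameters(self) -> dict[str, Any]:
        """Flat dict of every parameter actually used, for the run log."""
        d = dataclasses.asdict(self)
        d["met_table"] = {f"{k[0].value}_{k[1].value}": v for k, v in self.met_table.items()}
        return d
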