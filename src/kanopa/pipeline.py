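"""End-to-end analysis pipeline.

Order of stages: age inclusion filter -> instrument scoring (IPAQ level,
MPSE score and tertile) -> strata -> multiple imputation of missing Kano
answers (m datasets) -> per-imputation, per-stratum Kano categorization ->
union-of-winners reconciliation -> demand-supply report -> per-feature
multinomial regression. Every stage's parameters and seeds go to the run
log; two runs with identical inputs and configuration produce byte-identical
output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .catalog import FEATURE_CODES
from .instruments import (
    IncompleteScaleError,
    Level,
    RespondentProfile,
    apply_inclusion_filter,
    mpse_score,
    score_ipaq,
    tertile_split,
)
from .io import (
    RunConfig,
    ipaq_records_from_row,
    kano_answer_columns,
    kano_pairs_from_row,
    read_survey,
)
from .kano import Classification, FeatureTally, KanoPair, classify_feature, tally_feature
from .missing import ImputationConfig, ImputedDatasets, UnionResult, impute, union_of_winners
from .regression import (
    ContrastSpec,
    MnlReport,
    coefficient_table,
    fit_mnl,
    gof_screen,
    lr_tests_by_predictor,
    recode_outcome,
)
from .strata import (
    STRATUM_NAMES,
    Stratum,
    build_strata,
    categorize_stratum,
    classification_table,
    demand_supply_report,
    demand_supply_table,
    load_prevalence_map,
)

__all__ = ["PipelineResult", "score_respondents", "run_pipeline"]

logger = logging.getLogger(__name__)

#: A respondent enters the Kano analysis only if they answered at least
#: this share of the 104 Kano cells; sparser rows are treated as not having
#: filled the questionnaire and are excluded rather than imputed wholesale.
MIN_KANO_ANSWER_SHARE = 0.5


@dataclass
class PipelineResult:
    profiles: list[RespondentProfile]
    strata: list[Stratum]
    imputed: ImputedDatasets
    classifications_by_stratum: dict[str, list[Classification]]
    tallies_by_stratum: dict[str, dict[str, FeatureTally]]
    union_by_stratum: dict[str, dict[str, UnionResult]]
    demand_rows: list
    demand_summary: dict
    regression_reports: dict[str, list[MnlReport]]
    run_log: dict


def score_respondents(survey: pd.DataFrame, config: RunConfig) -> list[RespondentProfile]:
    """Derive PA level, MPSE score and MPSE tertile for every respondent."""
    mpse_cols = [f"mpse_{i:02d}" for i in range(1, 11)]
    scores: dict[str, float] = {}
    pa_levels: dict[str, Level | None] = {}
    for _, row in survey.iterrows():
        rid = row["respondent_id"]
        try:
            scores[rid] = mpse_score([None if pd.isna(v) else v for v in row[mpse_cols]])
        except IncompleteScaleError:
            pass
        records = ipaq_records_from_row(row)
        if records is None:
            pa_levels[rid] = None
        else:
            pa_levels[rid] = score_ipaq(
                records, met_table=config.met_table, cap=config.truncation_cap
            ).pa_level

    mpse_levels = (
        tertile_split(pd.Series(scores)) if len(scores) >= 3 else pd.Series(dtype=object)
    )
    profiles = []
    for _, row in survey.iterrows():
        rid = row["respondent_id"]
        profiles.append(
            RespondentProfile(
                respondent_id=rid,
                age=int(row["age"]),
                pa_level=pa_levels.get(rid),
                mpse_score=scores.get(rid),
                mpse_level=mpse_levels.get(rid),
            )
        )
    return profiles


def _classify_all_strata(
    strata: Sequence[Stratum],
    pairs_by_respondent: Mapping[str, list[KanoPair]],
    config: RunConfig,
) -> tuple[dict[str, list[Classification]], dict[str, dict[str, FeatureTally]]]:
    classifications: dict[str, list[Classification]] = {}
    tallies: dict[str, dict[str, FeatureTally]] = {}
    for stratum in strata:
        cls = categorize_stratum(stratum, pairs_by_respondent, config.thresholds)
        classifications[stratum.name] = cls
        per_feature: dict[str, FeatureTally] = {}
        for code in FEATURE_CODES:
            feature_pairs = [
                p
                for rid in sorted(stratum.respondent_ids)
                for p in pairs_by_respondent[rid]
                if p.feature_code == code
            ]
            if feature_pairs:
                per_feature[code] = tally_feature(feature_pairs)
        tallies[stratum.name] = per_feature
    return classifications, tallies


def _apply_union(
    run1: Sequence[Classification], union: Mapping[str, UnionResult]
) -> list[Classification]:
    """Replace each run-1 winner set by the cross-imputation union."""
    out = []
    for c in run1:
        u = union[c.feature_code]
        if set(u.categories) == set(c.categories):
            out.append(c)  # keep run-1's count-based ordering
        else:
            out.append(
                Classification(
                    feature_code=c.feature_code,
                    kind="MIXED" if len(u.categories) > 1 else "SINGLE",
                    categories=tuple(u.categories),
                    category_strength_pct=c.category_strength_pct,
                    total_strength_pct=c.total_strength_pct,
                )
            )
    return out


def run_pipeline(
    survey: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    prevalence=None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the complete analysis; optionally write the output bundle."""
    config = config or RunConfig()
    if not isinstance(survey, pd.DataFrame):
        survey = read_survey(survey)

    # inclusion filter
    survey = apply_inclusion_filter(
        survey, min_age=config.min_age, max_age=config.max_age
    ).reset_index(drop=True)
    if survey.empty:
        raise ValueError("no respondents remain after the inclusion filter")

    # instrument scoring and Kano completeness
    profiles_all = score_respondents(survey, config)
    kano_cols = kano_answer_columns()
    answered_share = survey[kano_cols].notna().mean(axis=1)
    kano_valid = survey.loc[answered_share >= MIN_KANO_ANSWER_SHARE].copy()
    n_dropped = len(survey) - len(kano_valid)
    if n_dropped:
        logger.info("%d respondent(s) dropped: insufficient Kano answers", n_dropped)
    valid_ids = set(kano_valid["respondent_id"])
    profiles = [p for p in profiles_all if p.respondent_id in valid_ids]

    # multiple imputation of the Kano answers
    imp_cfg = ImputationConfig(
        m=config.imputation_m, predictor_alpha=config.predictor_alpha, seed=config.seed
    )
    imputed = impute(kano_valid, imp_cfg, variables=[
        c for c in kano_cols if kano_valid[c].isna().any()
    ])

    # strata and per-imputation categorization
    strata = build_strata(profiles)
    runs: list[dict[str, list[Classification]]] = []
    first_tallies: dict[str, dict[str, FeatureTally]] = {}
    first_classifications: dict[str, list[Classification]] = {}
    for k, dataset in enumerate(imputed.datasets):
        pairs_by_respondent = {
            row["respondent_id"]: kano_pairs_from_row(row)
            for _, row in dataset.iterrows()
        }
        cls, tal = _classify_all_strata(strata, pairs_by_respondent, config)
        runs.append(cls)
        if k == 0:
            first_classifications, first_tallies = cls, tal

    union_by_stratum = {
        name: union_of_winners([run[name] for run in runs])
        for name in STRATUM_NAMES
        if first_classifications.get(name)
    }
    final_classifications = {
        name: _apply_union(first_classifications[name], union_by_stratum[name])
        for name in union_by_stratum
    }
    for name in first_classifications:
        final_classifications.setdefault(name, first_classifications[name])

    # demand vs supply
    prevalence_map = None
    if prevalence is not None:
        prevalence_map = (
            prevalence if isinstance(prevalence, dict) else load_prevalence_map(prevalence)
        )
    demand_rows, demand_summary = demand_supply_report(final_classifications, prevalence_map)

    # per-feature two-factor regression on the first imputed dataset
    regression_reports = _run_regressions(
        imputed.datasets[0], profiles, config
    )

    run_log = {
        "parameters": config.log_parameters(),
        "n_input": int(len(survey)),
        "n_kano_valid": int(len(kano_valid)),
        "n_imputed_cells": len(imputed.provenance),
        "strata_sizes": {s.name: s.n for s in strata},
        "winner_disagreements": {
            name: sorted(f for f, u in res.items() if u.disagreement)
            for name, res in union_by_stratum.items()
        },
        "demand_summary": {
            k: v for k, v in demand_summary.items() if k != "positive_feature_count_by_stratum"
        },
        "positive_feature_count_by_stratum": demand_summary[
            "positive_feature_count_by_stratum"
        ],
    }

    result = PipelineResult(
        profiles=profiles,
        strata=strata,
        imputed=imputed,
        classifications_by_stratum=final_classifications,
        tallies_by_stratum=first_tallies,
        union_by_stratum=union_by_stratum,
        demand_rows=demand_rows,
        demand_summary=demand_summary,
        regression_reports=regression_reports,
        run_log=run_log,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _run_regressions(
    dataset: pd.DataFrame, profiles: Sequence[RespondentProfile], config: RunConfig
) -> dict[str, list[MnlReport]]:
    """Fit each feature's model under two reference codings.

    The medium/medium reference yields the low-vs-medium and high-vs-medium
    contrasts; the low/low reference adds high-vs-low. Respondents lacking
    either factor level are excluded from the regression sample.
    """
    by_id = {p.respondent_id: p for p in profiles}
    usable = [
        rid
        for rid in dataset["respondent_id"]
        if by_id[rid].pa_level is not None and by_id[rid].mpse_level is not None
    ]
    if len(usable) < 10:
        logger.warning("regression skipped: only %d respondents with both factors", len(usable))
        return {}
    sub = dataset.set_index("respondent_id").loc[usable]
    predictors = pd.DataFrame(
        {
            "pa": [by_id[r].pa_level for r in usable],
            "mpse": [by_id[r].mpse_level for r in usable],
        },
        index=usable,
    )
    pairs_by_id = {rid: kano_pairs_from_row(sub.loc[rid]) for rid in usable}

    contrasts = {
        "ref_medium": ContrastSpec({"pa": Level.MEDIUM, "mpse": Level.MEDIUM}),
        "ref_low": ContrastSpec({"pa": Level.LOW, "mpse": Level.LOW}),
    }
    reports: dict[str, list[MnlReport]] = {name: [] for name in contrasts}
    for code in FEATURE_CODES:
        outcome = [
            recode_outcome(next(p for p in pairs_by_id[rid] if p.feature_code == code).category())
            for rid in usable
        ]
        if len(set(outcome)) < 2:
            logger.info("feature %s: single outcome class, regression skipped", code)
            continue
        for name, contrast in contrasts.items():
            try:
                rep = fit_mnl(
                    outcome,
                    predictors,
                    contrast,
                    feature_code=code,
                    separation_bound=config.separation_bound,
                )
            except Exception as exc:  # pragma: no cover - degenerate data
                logger.warning("feature %s (%s): fit failed: %s", code, name, exc)
                continue
            rep = gof_screen(rep, alpha=config.regression_alpha)
            rep = lr_tests_by_predictor(rep)
            reports[name].append(rep)
    return reports


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write the CSV bundle and the run log (deterministic bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, cls in result.classifications_by_stratum.items():
        table = classification_table(cls, result.tallies_by_stratum.get(name))
        table.to_csv(outdir / f"strata_{name.lower()}.csv", index=False, lineterminator="\n")
    demand_supply_table(result.demand_rows).to_csv(
        outdir / "demand_supply.csv", index=False, lineterminator="\n"
    )
    for name, reports in result.regression_reports.items():
        coefficient_table(reports).to_csv(
            outdir / f"regression_{name}.csv", index=False, lineterminator="\n"
        )
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(result.run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
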