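"""Model-based multiple imputation of categorical survey answers.

Missing answers (in practice the Kano functional/dysfunctional items) are
filled m times by proper imputation: for each incomplete variable a
multinomial model of the variable on its significantly predictive
complete covariates is fitted on the complete cases, and each missing cell
receives m independent draws from the fitted predictive distribution.
Functional and dysfunctional answers are imputed as separate variables;
the Kano category is always recomputed from answers, never imputed
directly.

Predictor screening uses the likelihood-ratio (G) statistic of the
target x candidate contingency table — identically the likelihood-ratio
test of a saturated multinomial logit of the target on one categorical
candidate against the intercept-only model. With all-categorical
covariates the fitted predictive distribution of the saturated model is
the conditional category frequency within the covariate cell, which is
what the draws use (falling back to the observed marginal for unseen
cells or when no predictor survives screening).

After the m single-feature categorizations, the per-feature verdicts are
reconciled by the union-of-winners rule: the final winning set is the
union of the winning category sets across imputations, with a flag on
features whose winners disagreed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kano import COLUMN_ORDER, Classification, KanoCategory

__all__ = [
    "ImputationConfig",
    "ImputedDatasets",
    "UnionResult",
    "screen_predictors",
    "impute",
    "union_of_winners",
]

logger = logging.getLogger(__name__)

#: At most this many screened predictors condition the draws; beyond that
#: the joint cells of ~100-respondent surveys are mostly empty.
MAX_CONDITIONING_PREDICTORS = 2


@dataclass(frozen=True)
class ImputationConfig:
    """m imputations per missing value; predictors kept at p < alpha."""

    m: int = 3
    predictor_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.predictor_alpha < 1:
            raise ValueError("predictor_alpha must be in (0, 1)")


@dataclass
class ImputedDatasets:
    """m complete copies of the survey plus per-cell imputation provenance."""

    datasets: list[pd.DataFrame]
    provenance: dict[tuple[Hashable, str], list] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)


def _lr_pvalue(target: pd.Series, candidate: pd.Series) -> float:
    """p-value of the contingency-table likelihood-ratio (G) test."""
    table = pd.crosstab(target, candidate)
    table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    res = stats.chi2_contingency(table.to_numpy(), lambda_="log-likelihood")
    return float(res.pvalue)


def screen_predictors(
    target_variable: str,
    candidate_predictors: Sequence[str],
    data: pd.DataFrame,
    predictor_alpha: float = 0.05,
) -> list[str]:
    """Retain candidates that significantly predict the target.

    Each candidate is tested one at a time by the likelihood-ratio test of
    the multinomial model of the target on that candidate, over the
    target's complete cases; candidates with p < alpha survive, ordered by
    increasing p.
    """
    complete = data.loc[data[target_variable].notna()]
    if complete.empty:
        raise ValueError(f"no complete cases for target {target_variable!r}")
    pvals: list[tuple[float, str]] = []
    for cand in candidate_predictors:
        p = _lr_pvalue(complete[target_variable], complete[cand])
        if p < predictor_alpha:
            pvals.append((p, cand))
    retained = [c for _, c in sorted(pvals, key=lambda t: (t[0], t[1]))]
    logger.info(
        "screening %s: retained %d/%d predictors at alpha=%g",
        target_variable, len(retained), len(candidate_predictors), predictor_alpha,
    )
    return retained


def _predictive_draw(
    rng: np.random.Generator,
    target: pd.Series,
    predictors: pd.DataFrame | None,
    row_key,
) -> object:
    """One draw from the conditional (or marginal) category distribution."""
    observed = target.dropna()
    dist = observed
    if predictors is not None and len(predictors.columns):
        cell = tuple(predictors.loc[row_key])
        mask = (predictors.loc[observed.index] == pd.Series(cell, index=predictors.columns)).all(axis=1)
        if mask.any():
            dist = observed[mask]
    values, counts = np.unique(dist.to_numpy(), return_counts=True)
    return values[rng.choice(len(values), p=counts / counts.sum())]


def impute(
    data: pd.DataFrame,
    config: ImputationConfig | None = None,
    variables: Sequence[str] | None = None,
    candidate_predictors: Sequence[str] | None = None,
) -> ImputedDatasets:
    """Multiply impute missing categorical cells; seeded and reproducible.

    ``variables`` defaults to every column with at least one missing value;
    ``candidate_predictors`` defaults to every fully observed column except
    ``respondent_id``. Non-missing cells are never altered.
    """
    if config is None:
        config = ImputationConfig()
    if variables is None:
        variables = [c for c in data.columns if data[c].isna().any()]
    for v in variables:
        if data[v].isna().all():
            raise ValueError(f"variable {v!r} is missing for every respondent")
    if candidate_predictors is None:
        candidate_predictors = [
            c for c in data.columns
            if c != "respondent_id" and c not in variables and not data[c].isna().any()
        ]

    rng = np.random.default_rng(config.seed)
    datasets = [data.copy() for _ in range(config.m)]
    provenance: dict[tuple[Hashable, str], list] = {}

    for var in variables:
        if not data[var].isna().any():
            continue
        retained = screen_predictors(var, candidate_predictors, data, config.predictor_alpha)
        conditioning = retained[:MAX_CONDITIONING_PREDICTORS]
        predictors = data[conditioning] if conditioning else None
        missing_rows = data.index[data[var].isna()]
        for row in missing_rows:
            draws = [
                _predictive_draw(rng, data[var], predictors, row)
                for _ in range(config.m)
            ]
            provenance[(row, var)] = draws
            for k, d in enumerate(datasets):
                d.at[row, var] = draws[k]

    return ImputedDatasets(datasets=datasets, provenance=provenance)


@dataclass(frozen=True)
class UnionResult:
    """Final winning-category set for one feature across imputations."""

    feature_code: str
    categories: tuple[KanoCategory, ...]
    disagreement: bool  # True when the m winner sets were not identical

    @property
    def has_positive(self) -> bool:
        return any(c.is_positive for c in self.categories)

    def render(self) -> str:
        if len(self.categories) == 1:
            return self.categories[0].value
        return "X(" + ", ".join(c.value for c in self.categories) + ")"


def union_of_winners(
    classifications_per_imputation: Sequence[Sequence[Classification]],
) -> dict[str, UnionResult]:
    """Union the winning categories of m categorization runs per feature.

    The union is ordered by the fixed tally column order (A, M, O, I, R, Q);
    features whose winners differ across imputations are flagged.
    """
    runs = [
        {c.feature_code: c for c in run} for run in classifications_per_imputation
    ]
    if not runs:
        raise ValueError("no classification runs given")
    features = set(runs[0])
    for k, run in enumerate(runs[1:], start=2):
        if set(run) != features:
            raise ValueError(f"imputation run {k} covers a different feature set")

    out: dict[str, UnionResult] = {}
    for feat in sorted(features, key=lambda f: (len(f), f)):
        winner_sets = [frozenset(run[feat].categories) for run in runs]
        union = frozenset().union(*winner_sets)
        disagreement = len(set(winner_sets)) > 1
        if disagreement:
            logger.warning("feature %s: winners disagree across imputations", feat)
        out[feat] = UnionResult(
            feature_code=feat,
            categories=tuple(c for c in COLUMN_ORDER if c in union),
            disagreement=disagreement,
        )
    return out
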