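"""Per-feature multinomial logistic two-factor analysis.

For each design feature the per-respondent Kano category is recoded into
three outcome classes — *valued* (attractive or one-dimensional),
*must-be*, and *indifferent* (everything else) — and regressed on the two
categorical factors, physical-activity level and mobile-phone
self-efficacy tertile, with a maximum-likelihood multinomial logit
(baseline outcome: indifferent; dummy-coded predictors at configurable
reference levels).

Model fit is screened with grouped Pearson and deviance statistics; models
whose deviance is significant at alpha are excluded from the
likelihood-ratio tests of the predictors. Coefficient reports carry b,
Wald chi-square (1 df), two-sided p, the odds ratio exp(b) and the 95%
Wald confidence interval. Complete or quasi-complete separation (an
escaped coefficient or an unusable Hessian) is flagged and the Wald
inference for the affected terms suppressed rather than reported as
meaningless numbers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .instruments import Level
from .kano import KanoCategory

__all__ = [
    "INDIFFERENT",
    "MUST_BE",
    "VALUED",
    "OUTCOME_ORDER",
    "ContrastSpec",
    "MnlReport",
    "recode_outcome",
    "fit_mnl",
    "gof_screen",
    "lr_test",
    "refit_with_reference",
    "coefficient_table",
]

logger = logging.getLogger(__name__)

INDIFFERENT = "INDIFFERENT"
MUST_BE = "MUST_BE"
VALUED = "VALUED"
#: Baseline outcome first; contrast equations are reported for the rest.
OUTCOME_ORDER = (INDIFFERENT, MUST_BE, VALUED)

_LEVEL_ORDER = (Level.LOW, Level.MEDIUM, Level.HIGH)

_Z975 = float(stats.norm.ppf(0.975))


def recode_outcome(category: KanoCategory) -> str:
    """Collapse the six Kano categories to the three regression outcomes."""
    if category in (KanoCategory.A, KanoCategory.O):
        return VALUED
    if category is KanoCategory.M:
        return MUST_BE
    return INDIFFERENT


@dataclass(frozen=True)
class ContrastSpec:
    """Reference levels of the dummy coding (outcome baseline: indifferent)."""

    predictor_references: Mapping[str, Level] = field(
        default_factory=lambda: {"pa": Level.MEDIUM, "mpse": Level.MEDIUM}
    )


@dataclass
class MnlReport:
    """Fit of one feature's multinomial model."""

    feature_code: str
    loglik: float
    n: int
    gof: dict  # pearson_stat/_p, deviance_stat/_p, df
    coefficients: pd.DataFrame  # outcome, term, b, se, wald_chi2, p, odds_ratio, ci_low, ci_high
    separation_flag: bool
    converged: bool
    excluded: bool = False
    lr_tests: dict | None = None  # per predictor: chi2, df, p
    _context: dict | None = None  # inputs kept for nested refits


def _design_matrix(
    predictors: pd.DataFrame, contrast: ContrastSpec
) -> pd.DataFrame:
    """Intercept + one dummy per non-reference observed predictor level."""
    cols: dict[str, np.ndarray] = {"const": np.ones(len(predictors))}
    for name in predictors.columns:
        ref = contrast.predictor_references.get(name)
        values = predictors[name].map(lambda v: Level(v))
        observed = [lvl for lvl in _LEVEL_ORDER if (values == lvl).any()]
        if ref is None or ref not in observed:
            raise ValueError(f"reference level for {name!r} not observed in data")
        for lvl in observed:
            if lvl is ref:
                continue
            cols[f"{name}[{lvl.value}]"] = (values == lvl).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=predictors.index)


def fit_mnl(
    outcome: Sequence[str],
    predictors: pd.DataFrame,
    contrast: ContrastSpec | None = None,
    feature_code: str = "",
    separation_bound: float = 15.0,
) -> MnlReport:
    """Fit the three-outcome multinomial logit for one feature."""
    if contrast is None:
        contrast = ContrastSpec()
    y = pd.Series(list(outcome), index=predictors.index)
    observed_outcomes = [o for o in OUTCOME_ORDER if (y == o).any()]
    if len(observed_outcomes) < 2:
        raise ValueError("need at least two observed outcome classes")
    codes = y.map({o: i for i, o in enumerate(observed_outcomes)}).to_numpy()
    exog = _design_matrix(predictors, contrast)

    model = sm.MNLogit(codes, exog)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=200, disp=0)
        except Exception:
            res = model.fit(method="bfgs", maxiter=500, disp=0)
        converged = bool(res.mle_retvals.get("converged", True))
        params = np.asarray(res.params)  # (k_exog, J-1)
        bse = np.asarray(res.bse)  # NaN where the Hessian is unusable
    rows = []
    separation = not converged
    for j, out_name in enumerate(observed_outcomes[1:]):
        for i, term in enumerate(exog.columns):
            b = params[i, j]
            se = bse[i, j]
            bad = (not np.isfinite(se)) or abs(b) > separation_bound
            if bad:
                separation = True
            wald = (b / se) ** 2 if not bad else np.nan
            rows.append(
                {
                    "outcome": out_name,
                    "term": term,
                    "b": b,
                    "se": se if not bad else np.nan,
                    "wald_chi2": wald,
                    "p": stats.chi2.sf(wald, 1) if not bad else np.nan,
                    "odds_ratio": np.exp(b),
                    "ci_low": np.exp(b - _Z975 * se) if not bad else np.nan,
                    "ci_high": np.exp(b + _Z975 * se) if not bad else np.nan,
                }
            )
    coef = pd.DataFrame(rows)

    gof = _grouped_gof(codes, exog, res, len(observed_outcomes))

    return MnlReport(
        feature_code=feature_code,
        loglik=float(res.llf),
        n=len(y),
        gof=gof,
        coefficients=coef,
        separation_flag=separation,
        converged=converged,
        _context={
            "outcome": y,
            "predictors": predictors,
            "contrast": contrast,
            "exog": exog,
            "result": res,
            "observed_outcomes": observed_outcomes,
            "separation_bound": separation_bound,
        },
    )


def _grouped_gof(codes, exog: pd.DataFrame, res, n_outcomes: int) -> dict:
    """Pearson and deviance statistics over covariate patterns."""
    probs = np.asarray(res.predict(exog.to_numpy()))
    pattern_key = [tuple(row) for row in exog.to_numpy()]
    df_cells = pd.DataFrame({"pattern": pattern_key, "code": codes})
    df_cells["idx"] = np.arange(len(codes))

    pearson = 0.0
    deviance = 0.0
    n_patterns = 0
    for _, grp in df_cells.groupby("pattern", sort=False):
        n_patterns += 1
        n_g = len(grp)
        p_g = probs[grp["idx"].iloc[0]]
        observed = np.bincount(grp["code"].to_numpy(), minlength=n_outcomes)
        expected = n_g * p_g
        ok = expected > 0
        pearson += float(((observed[ok] - expected[ok]) ** 2 / expected[ok]).sum())
        nz = ok & (observed > 0)
        deviance += float(2.0 * (observed[nz] * np.log(observed[nz] / expected[nz])).sum())

    n_params = exog.shape[1] * (n_outcomes - 1)
    df = n_patterns * (n_outcomes - 1) - n_params
    if df <= 0:
        return {
            "pearson_stat": pearson, "pearson_p": np.nan,
            "deviance_stat": deviance, "deviance_p": np.nan, "df": df,
        }
    return {
        "pearson_stat": pearson,
        "pearson_p": float(stats.chi2.sf(pearson, df)),
        "deviance_stat": deviance,
        "deviance_p": float(stats.chi2.sf(deviance, df)),
        "df": df,
    }


def gof_screen(report: MnlReport, alpha: float = 0.05) -> MnlReport:
    """Exclude the model from LR testing when the deviance is significant."""
    p = report.gof.get("deviance_p")
    report.excluded = bool(p is not None and np.isfinite(p) and p < alpha)
    if report.excluded:
        report.lr_tests = None
        logger.info(
            "feature %s: deviance p=%.4f < %g, excluded from LR tests",
            report.feature_code, p, alpha,
        )
    return report


def lr_test(full_result, reduced_result) -> dict:
    """Likelihood-ratio test of nested multinomial fits.

    chi2 = 2 (llf_full - llf_reduced); df = difference in free parameters.
    """
    full_names = set(full_result.model.exog_names)
    reduced_names = set(reduced_result.model.exog_names)
    if not reduced_names <= full_names:
        raise ValueError("models are not nested")
    j_full = np.asarray(full_result.params).shape[1]
    j_red = np.asarray(reduced_result.params).shape[1]
    if j_full != j_red:
        raise ValueError("models fit different outcome sets; not nested")
    df = (len(full_names) - len(reduced_names)) * j_full
    chi2 = 2.0 * (full_result.llf - reduced_result.llf)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {"chi2": float(chi2), "df": int(df), "p": p}


def lr_tests_by_predictor(report: MnlReport) -> MnlReport:
    """LR test of each predictor by refitting the model without its dummies."""
    if report.excluded:
        return report
    ctx = report._context
    res_full = ctx["result"]
    exog = ctx["exog"]
    codes = pd.Series(list(ctx["outcome"])).map(
        {o: i for i, o in enumerate(ctx["observed_outcomes"])}
    ).to_numpy()
    tests: dict[str, dict] = {}
    for name in ctx["predictors"].columns:
        keep = [c for c in exog.columns if not c.startswith(f"{name}[")]
        reduced = sm.MNLogit(codes, exog[keep])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res_red = reduced.fit(method="newton", maxiter=200, disp=0)
            except Exception:
                res_red = reduced.fit(method="bfgs", maxiter=500, disp=0)
        tests[name] = lr_test(res_full, res_red)
    report.lr_tests = tests
    return report


def refit_with_reference(
    report: MnlReport, new_references: Mapping[str, Level]
) -> MnlReport:
    """Refit under a different dummy coding; the log-likelihood is invariant."""
    ctx = report._context
    contrast = ContrastSpec(predictor_references=dict(new_references))
    return fit_mnl(
        ctx["outcome"],
        ctx["predictors"],
        contrast,
        feature_code=report.feature_code,
        separation_bound=ctx["separation_bound"],
    )


def coefficient_table(reports: Sequence[MnlReport]) -> pd.DataFrame:
    """Stack per-feature coefficient reports with fit diagnostics."""
    frames = []
    for r in reports:
        df = r.coefficients.copy()
        df.insert(0, "feature_code", r.feature_code)
        df["pearson_stat"] = r.gof["pearson_stat"]
        df["pearson_p"] = r.gof["pearson_p"]
        df["deviance_stat"] = r.gof["deviance_stat"]
        df["deviance_p"] = r.gof["deviance_p"]
        df["excluded"] = r.excluded
        df["separation_flag"] = r.separation_flag
        if r.lr_tests:
            for pred, t in r.lr_tests.items():
                df[f"lr_{pred}_chi2"] = t["chi2"]
                df[f"lr_{pred}_p"] = t["p"]
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
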