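"""Multinomial two-factor analysis: recoding, fitting, LR tests, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from kanopa.instruments import Level
from kanopa.kano import KanoCategory
from kanopa.regression import (
    INDIFFERENT,
    MUST_BE,
    VALUED,
    ContrastSpec,
    fit_mnl,
    gof_screen,
    lr_test,
    lr_tests_by_predictor,
    recode_outcome,
    refit_with_reference,
)

LEVELS = (Level.LOW, Level.MEDIUM, Level.HIGH)


def _simulate(rng, n, b_must, b_valued):
    """Draw outcomes from a known two-factor multinomial logit.

    b_* = (intercept, pa_low, pa_high, mpse_low, mpse_high), medium reference.
    """
    level_arr = np.array(LEVELS, dtype=object)
    pa = level_arr[rng.integers(0, 3, size=n)]
    mpse = level_arr[rng.integers(0, 3, size=n)]
    x = np.column_stack(
        [
            np.ones(n),
            [v is Level.LOW for v in pa],
            [v is Level.HIGH for v in pa],
            [v is Level.LOW for v in mpse],
            [v is Level.HIGH for v in mpse],
        ]
    ).astype(float)
    eta = np.column_stack([np.zeros(n), x @ np.asarray(b_must), x @ np.asarray(b_valued)])
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    outcome = [
        (INDIFFERENT, MUST_BE, VALUED)[rng.choice(3, p=row)] for row in p
    ]
    predictors = pd.DataFrame({"pa": pa, "mpse": mpse})
    return outcome, predictors, x


class TestRecode:
    @pytest.mark.parametrize(
        "category,expected",
        [
            (KanoCategory.A, VALUED),
            (KanoCategory.O, VALUED),
            (KanoCategory.M, MUST_BE),
            (KanoCategory.I, INDIFFERENT),
            (KanoCategory.R, INDIFFERENT),
            (KanoCategory.Q, INDIFFERENT),
        ],
    )
    def test_mapping(self, category, expected):
        assert recode_outcome(category) == expected


class TestFit:
    def test_parameter_recovery(self, rng):
        b_must = (-0.5, 0.8, -0.4, 0.3, -0.6)
        b_valued = (-0.2, -0.5, 0.7, -0.3, 0.9)
        outcome, predictors, _ = _simulate(rng, 2000, b_must, b_valued)
        rep = fit_mnl(outcome, predictors)
        truth = {MUST_BE: b_must, VALUED: b_valued}
        terms = ["const", "pa[LOW]", "pa[HIGH]", "mpse[LOW]", "mpse[HIGH]"]
        for out_name, b_true in truth.items():
            sub = rep.coefficients.query("outcome == @out_name").set_index("term")
            for term, bt in zip(terms, b_true):
                b, se = sub.at[term, "b"], sub.at[term, "se"]
                assert abs(b - bt) < 3 * se, (out_name, term)

    def test_or_ci_consistency(self, rng):
        outcome, predictors, _ = _simulate(rng, 500, (0.2,) * 5, (-0.1,) * 5)
        rep = fit_mnl(outcome, predictors)
        z = stats.norm.ppf(0.975)
        for _, row in rep.coefficients.iterrows():
            assert row["odds_ratio"] == pytest.approx(np.exp(row["b"]), abs=1e-8)
            assert row["ci_low"] == pytest.approx(np.exp(row["b"] - z * row["se"]), abs=1e-8)
            assert row["ci_high"] == pytest.approx(np.exp(row["b"] + z * row["se"]), abs=1e-8)
            assert row["ci_low"] <= row["odds_ratio"] <= row["ci_high"]

    def test_separation_flagged(self, rng):
        # no VALUED outcome ever observed at low MPSE: quasi-separation
        outcome, predictors, _ = _simulate(rng, 400, (0.0,) * 5, (0.5, 0, 0, 0, 0.5))
        outcome = [
            INDIFFERENT if (o == VALUED and m is Level.LOW) else o
            for o, m in zip(outcome, predictors["mpse"])
        ]
        rep = fit_mnl(outcome, predictors)
        assert rep.separation_flag
        bad = rep.coefficients.query("outcome == @VALUED and term == 'mpse[LOW]'")
        assert np.isnan(bad["wald_chi2"]).all() and np.isnan(bad["p"]).all()

    def test_single_outcome_class_rejected(self):
        predictors = pd.DataFrame({"pa": [Level.LOW] * 4 + [Level.MEDIUM] * 4,
                                   "mpse": [Level.MEDIUM] * 8})
        with pytest.raises(ValueError):
            fit_mnl([INDIFFERENT] * 8, predictors)

    def test_brute_force_likelihood_oracle(self, rng):
        """Fitted probabilities match an independent optimizer of the
        multinomial log-likelihood."""
        outcome, predictors, x = _simulate(rng, 300, (0.3, 0.5, -0.2, 0.1, -0.4),
                                           (-0.2, 0.2, 0.4, -0.1, 0.3))
        rep = fit_mnl(outcome, predictors)
        y = np.array([(INDIFFERENT, MUST_BE, VALUED).index(o) for o in outcome])

        def negll(theta):
            b = theta.reshape(2, 5).T  # (k, 2)
            eta = np.column_stack([np.zeros(len(y)), x @ b])
            lse = np.log(np.exp(eta - eta.max(axis=1, keepdims=True)).sum(axis=1)) + eta.max(axis=1)
            return -(eta[np.arange(len(y)), y] - lse).sum()

        res = optimize.minimize(negll, np.zeros(10), method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
        assert -res.fun == pytest.approx(rep.loglik, abs=1e-5)

    def test_well_specified_model_rarely_excluded(self, rng):
        excluded = 0
        runs = 60
        for _ in range(runs):
            outcome, predictors, _ = _simulate(rng, 250, (0.3, 0.4, -0.3, 0.2, -0.2),
                                               (-0.1, 0.3, 0.3, -0.2, 0.4))
            rep = gof_screen(fit_mnl(outcome, predictors))
            excluded += rep.excluded
        # exclusion rate should be near the nominal alpha=.05
        assert excluded <= int(0.15 * runs)


class TestLrTest:
    def test_identical_models(self, rng):
        outcome, predictors, _ = _simulate(rng, 300, (0.2,) * 5, (0.1,) * 5)
        rep = fit_mnl(outcome, predictors)
        res = rep._context["result"]
        out = lr_test(res, res)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-8)
        assert out["p"] == 1.0

    def test_strong_effect_detected(self, rng):
        b_valued = (0.0, 0.0, 2.0, 0.0, 0.0)  # strong PA effect
        outcome, predictors, _ = _simulate(rng, 2000, (0.0,) * 5, b_valued)
        rep = lr_tests_by_predictor(fit_mnl(outcome, predictors))
        assert rep.lr_tests["pa"]["p"] < 1e-3
        assert rep.lr_tests["pa"]["df"] == 4

    def test_non_nested_errors(self, rng):
        outcome, predictors, _ = _simulate(rng, 200, (0.1,) * 5, (0.1,) * 5)
        full = fit_mnl(outcome, predictors)._context["result"]
        other = fit_mnl(outcome, predictors[["pa"]].assign(mpse=predictors["mpse"]),
                        ContrastSpec({"pa": Level.LOW, "mpse": Level.LOW}))
        with pytest.raises(ValueError):
            lr_test(other._context["result"], full)


class TestGofScreen:
    @pytest.mark.parametrize("p,expected", [(0.30, False), (0.01, True)])
    def test_threshold(self, p, expected, rng):
        outcome, predictors, _ = _simulate(rng, 200, (0.1,) * 5, (0.1,) * 5)
        rep = fit_mnl(outcome, predictors)
        rep.gof["deviance_p"] = p
        assert gof_screen(rep).excluded is expected


class TestReferenceChanges:
    def test_loglik_invariant(self, rng):
        outcome, predictors, _ = _simulate(rng, 600, (0.3, 0.4, -0.2, 0.2, -0.3),
                                           (0.1, -0.2, 0.3, 0.2, 0.1))
        rep = fit_mnl(outcome, predictors)
        rep2 = refit_with_reference(rep, {"pa": Level.LOW, "mpse": Level.HIGH})
        assert rep2.loglik == pytest.approx(rep.loglik, abs=1e-8)

    def test_swapped_pair_negates(self, rng):
        outcome, predictors, _ = _simulate(rng, 600, (0.3, 0.4, -0.2, 0.2, -0.3),
                                           (0.1, -0.2, 0.3, 0.2, 0.1))
        rep_m = fit_mnl(outcome, predictors)  # mpse ref MEDIUM
        rep_h = refit_with_reference(rep_m, {"pa": Level.MEDIUM, "mpse": Level.HIGH})
        b_h_vs_m = rep_m.coefficients.query("outcome == @VALUED and term == 'mpse[HIGH]'")["b"].iloc[0]
        b_m_vs_h = rep_h.coefficients.query("outcome == @VALUED and term == 'mpse[MEDIUM]'")["b"].iloc[0]
        assert b_m_vs_h == pytest.approx(-b_h_vs_m, abs=1e-5)

    def test_composite_contrast_identity(self, rng):
        # (H vs L) equals (H vs M) + (M vs L)
        outcome, predictors, _ = _simulate(rng, 800, (0.3, 0.4, -0.2, 0.2, -0.3),
                                           (0.1, -0.2, 0.3, 0.2, 0.1))
        ref_m = fit_mnl(outcome, predictors)
        ref_l = refit_with_reference(ref_m, {"pa": Level.MEDIUM, "mpse": Level.LOW})
        q = "outcome == @MUST_BE and term == @t"
        t = "mpse[HIGH]"
        h_vs_m = ref_m.coefficients.query(q)["b"].iloc[0]
        h_vs_l = ref_l.coefficients.query(q)["b"].iloc[0]
        t = "mpse[LOW]"
        l_vs_m = ref_m.coefficients.query(q)["b"].iloc[0]
        assert h_vs_l == pytest.approx(h_vs_m - l_vs_m, abs=1e-5)
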