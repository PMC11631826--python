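"""Selection-on-observables and linear-IV comparators."""

import numpy as np
import pandas as pd
import pytest

from conftest import ORACLE_TERMS, complete_cases
from petliv.comparators import (
    _covariate_design,
    iptw_ra,
    naive_ols,
    two_stage_least_squares,
    wald_late,
)
from petliv.liv_core import TermSet
from petliv.synthetic_data import generate_cohort, oracle_dgp

REDUCED_TERMS = TermSet(main_terms=("age", "female"), quadratic_terms=(),
                        covariate_interactions=(), iv_interactions=())


def _mc_estimates(estimator, reps=8, n=20_000, seed0=600, **dgp_overrides):
    """Replicated (estimate - truth) differences for Monte-Carlo checks."""
    diffs = []
    for r in range(reps):
        cfg = oracle_dgp(n, seed=seed0 + r, **dgp_overrides)
        sc = generate_cohort(cfg)
        cohort, truth = complete_cases(sc)
        diffs.append(estimator(cohort) - truth["individual_effect"].mean())
    return np.asarray(diffs)


class TestIPTWRA:
    def test_randomized_treatment_matches_difference_in_means(self):
        """With a near-flat selection index, treatment is as-good-as-random
        and IPTW-RA must agree with the raw difference in means."""
        cfg = oracle_dgp(20_000, seed=50, rho_conf=0.0, rho_ess=0.0,
                         selection_coefs={"intercept": -0.2, "z": 0.05},
                         cluster_pref_spread=0.1)
        cohort, _ = complete_cases(generate_cohort(cfg))
        est = iptw_ra(cohort, ORACLE_TERMS)
        dim = cohort.loc[cohort["D"] == 1, "Y"].mean() - cohort.loc[cohort["D"] == 0, "Y"].mean()
        n1 = (cohort["D"] == 1).sum()
        mc_se = cohort["Y"].std() * np.sqrt(1 / n1 + 1 / (len(cohort) - n1))
        assert abs(est.ate - dim) <= 3 * mc_se

    @pytest.mark.parametrize(
        "treat_terms,outcome_terms",
        [(REDUCED_TERMS, ORACLE_TERMS), (ORACLE_TERMS, REDUCED_TERMS)],
        ids=["treatment-model-misspecified", "outcome-model-misspecified"],
    )
    def test_double_robustness(self, treat_terms, outcome_terms):
        diffs = _mc_estimates(
            lambda c: iptw_ra(c, treat_terms, outcome_terms=outcome_terms).ate,
            rho_conf=0.0, rho_ess=0.0,
        )
        mc_se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 3 * mc_se + 0.02

    def test_both_models_misspecified_is_biased(self):
        """The double-robustness check has power: with BOTH models reduced
        the estimate is clearly biased."""
        diffs = _mc_estimates(
            lambda c: iptw_ra(c, REDUCED_TERMS, outcome_terms=REDUCED_TERMS).ate,
            rho_conf=0.0, rho_ess=0.0,
        )
        mc_se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) > 10 * mc_se

    def test_recycled_predictions_equal_weighted_g_computation(self, oracle_cohort):
        """Independent route: two arm-specific weighted regressions and
        predict-and-difference must reproduce the recycled-prediction ATE."""
        cohort, _ = oracle_cohort
        preds = iptw_ra(cohort, ORACLE_TERMS)
        Xc, _ = _covariate_design(cohort, ORACLE_TERMS)
        d = cohort["D"].to_numpy()
        y = cohort["Y"].to_numpy()
        sw = np.sqrt(preds.weights)
        b1, *_ = np.linalg.lstsq(Xc[d == 1] * sw[d == 1, None], y[d == 1] * sw[d == 1], rcond=None)
        b0, *_ = np.linalg.lstsq(Xc[d == 0] * sw[d == 0, None], y[d == 0] * sw[d == 0], rcond=None)
        gcomp = (Xc @ b1 - Xc @ b0).mean()
        assert abs(preds.ate - gcomp) <= 1e-8

    def test_unit_weights_reduce_to_plain_regression_adjustment(self, oracle_cohort):
        cohort, _ = oracle_cohort
        ra = iptw_ra(cohort, ORACLE_TERMS, weighting=False)
        Xc, _ = _covariate_design(cohort, ORACLE_TERMS)
        d = cohort["D"].to_numpy()
        y = cohort["Y"].to_numpy()
        b1, *_ = np.linalg.lstsq(Xc[d == 1], y[d == 1], rcond=None)
        b0, *_ = np.linalg.lstsq(Xc[d == 0], y[d == 0], rcond=None)
        assert ra.ate == pytest.approx(float((Xc @ b1 - Xc @ b0).mean()), abs=1e-10)
        assert np.all(ra.weights == 1.0)

    def test_weight_cap_truncates_and_counts(self, oracle_cohort):
        cohort, _ = oracle_cohort
        capped = iptw_ra(cohort, ORACLE_TERMS, weight_cap=1.01)
        assert capped.n_truncated > 0
        assert capped.weights.max() <= 1.01


class TestTwoStageLeastSquares:
    def test_homogeneous_dgp_unbiased_while_ols_is_not(self):
        tsls = _mc_estimates(lambda c: two_stage_least_squares(c, ORACLE_TERMS).point,
                             rho_ess=0.0, rho_conf=0.5)
        ols = _mc_estimates(lambda c: naive_ols(c, ORACLE_TERMS).point,
                            rho_ess=0.0, rho_conf=0.5)
        assert abs(tsls.mean()) <= 3 * tsls.std(ddof=1) / np.sqrt(len(tsls)) + 0.02
        assert abs(ols.mean()) > 10 * ols.std(ddof=1) / np.sqrt(len(ols))

    def test_binary_perfect_instrument_equals_wald_ratio(self):
        rng = np.random.default_rng(4)
        n = 2000
        z = rng.integers(0, 2, n).astype(float)
        df = pd.DataFrame(
            {
                "Z": z, "D": z.astype(int),
                "Y": 2.0 - 3.0 * z + rng.normal(0, 1, n),
                "region_id": rng.integers(0, 6, n),
                "age": rng.normal(60, 10, n), "female": rng.integers(0, 2, n),
                "ethnicity": "white",
                "hba1c": rng.normal(70, 15, n), "bmi": rng.normal(32, 6, n),
                "egfr": rng.normal(85, 15, n), "sbp": rng.normal(130, 15, n),
                "dbp": rng.normal(80, 10, n), "duration": rng.normal(5, 3, n),
            }
        )
        no_cov = TermSet(main_terms=(), quadratic_terms=(),
                         covariate_interactions=(), iv_interactions=())
        tsls = two_stage_least_squares(df, no_cov)
        wald = wald_late(df, z == 0, z == 1)
        assert tsls.point == pytest.approx(wald.point, abs=1e-10)

    def test_agrees_with_statsmodels_sandbox_iv(self, oracle_cohort):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        cohort, _ = oracle_cohort
        sub = cohort.iloc[:5000]
        Xc, _ = _covariate_design(sub, ORACLE_TERMS)
        X = np.column_stack([Xc, sub["D"].to_numpy(float)])
        W = np.column_stack([Xc, sub["Z"].to_numpy(float)])
        ref = IV2SLS(sub["Y"].to_numpy(float), X, instrument=W).fit()
        ours = two_stage_least_squares(sub, ORACLE_TERMS)
        assert ours.point == pytest.approx(ref.params[-1], abs=1e-8)

    def test_constant_instrument_rejected(self, oracle_cohort):
        cohort, _ = oracle_cohort
        with pytest.raises(ValueError, match="no instrument variation"):
            two_stage_least_squares(cohort.assign(Z=0.3), ORACLE_TERMS)

    def test_weak_instrument_flagged(self, oracle_cohort):
        cohort, _ = oracle_cohort
        sub = cohort.iloc[:2000].copy()
        rng = np.random.default_rng(0)
        sub["Z"] = rng.uniform(0, 1, len(sub))  # noise instrument
        with pytest.warns(UserWarning, match="weak first stage"):
            est = two_stage_least_squares(sub, ORACLE_TERMS)
        assert est.weak_instrument


class TestWaldLATE:
    def test_printed_style_fixture_ratio(self):
        """Outcome rises 5 -> 7 and uptake 0.2 -> 0.6 across the two
        instrument levels: the Wald ratio is exactly 5.0."""
        n = 500
        low = pd.DataFrame({"Y": 5.0, "D": (np.arange(n) % 5 == 0).astype(int)})
        high = pd.DataFrame({"Y": 7.0, "D": (np.arange(n) % 5 < 3).astype(int)},
                            index=range(n))
        df = pd.concat([low, high], ignore_index=True)
        mask_low = np.arange(len(df)) < n
        res = wald_late(df, mask_low, ~mask_low)
        assert res.point == pytest.approx((7.0 - 5.0) / (0.6 - 0.2))

    def test_homogeneous_dgp_recovers_truth(self):
        def est(c):
            med = c["Z"].median()
            return wald_late(c, (c["Z"] < med).to_numpy(), (c["Z"] >= med).to_numpy()).point

        diffs = _mc_estimates(est, rho_ess=0.0, rho_conf=0.5)
        assert abs(diffs.mean()) <= 3 * diffs.std(ddof=1) / np.sqrt(len(diffs))

    def test_matches_integrated_closed_form_mte(self, oracle_cohort):
        """Between two instrument levels the Wald estimand approximates the
        closed-form MTE averaged over the resistance interval the
        instrument shift moves patients across."""
        from scipy.stats import norm

        cohort, _ = oracle_cohort
        cfg = oracle_dgp(20_000, seed=7)
        z = cohort["Z"]
        lo_grp = (z < z.quantile(0.3)).to_numpy()
        hi_grp = (z > z.quantile(0.7)).to_numpy()
        res = wald_late(cohort, lo_grp, hi_grp)
        p_lo = cohort.loc[lo_grp, "D"].mean()
        p_hi = cohort.loc[hi_grp, "D"].mean()
        grid = np.linspace(p_lo, p_hi, 400)
        mte_avg = np.mean(cfg.tau0 + cfg.rho_ess * cfg.sigma_gain * norm.ppf(grid))
        assert res.point == pytest.approx(mte_avg, abs=3 * res.se)

    def test_empty_group_and_zero_denominator_rejected(self, oracle_cohort):
        cohort, _ = oracle_cohort
        sub = cohort.iloc[:100]
        with pytest.raises(ValueError, match="empty instrument group"):
            wald_late(sub, np.zeros(100, bool), np.ones(100, bool))
        same = np.arange(100) < 50
        flat = sub.copy()
        flat["D"] = 1
        with pytest.raises(ValueError, match="compliers"):
            wald_late(flat, same, ~same)
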