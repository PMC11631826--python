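"""The LIV estimator: probit stage, outcome stage, analytic MTE, PeT
integration, and plugin-LASSO term selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

from conftest import ORACLE_TERMS, complete_cases, fit_liv
from petliv.liv_core import (
    ModelSpec,
    PropensityFit,
    SeparationError,
    TermSet,
    _probit_mle,
    dstar_assignment,
    fit_outcome,
    fit_propensity,
    mte,
    pet_effects,
    select_terms_lasso,
)
from petliv.synthetic_data import generate_cohort, oracle_dgp


class TestPropensityStage:
    def test_probit_agrees_with_statsmodels(self, oracle_cohort):
        import statsmodels.api as sm

        cohort, _ = oracle_cohort
        sub = cohort.iloc[:3000]
        spec = ModelSpec(ORACLE_TERMS, sub)
        X, names = spec.stage1_design(sub)
        ours = _probit_mle(X, sub["D"].to_numpy(float))
        ref = sm.Probit(sub["D"].to_numpy(float), X).fit(disp=0)
        assert np.allclose(ours, ref.params, atol=1e-6)

    def test_index_coefficient_recovery(self):
        """At large n the probit MLE recovers the generating index within
        3 standard errors (statsmodels provides the SEs independently)."""
        import statsmodels.api as sm

        cfg = oracle_dgp(40_000, seed=3)
        cohort, _ = complete_cases(generate_cohort(cfg))
        spec = ModelSpec(ORACLE_TERMS, cohort)
        X, names = spec.stage1_design(cohort)
        ref = sm.Probit(cohort["D"].to_numpy(float), X).fit(disp=0)
        true = {
            "const": cfg.selection_coefs["intercept"],
            "Z": cfg.selection_coefs["z"],
            "hba1c": cfg.selection_coefs["hba1c"],
            "bmi": cfg.selection_coefs["bmi"],
        }
        for term, coef in true.items():
            j = names.index(term)
            assert abs(ref.params[j] - coef) < 3 * ref.bse[j], term

    def test_propensity_clipped_and_support_recorded(self, oracle_cohort):
        cohort, _ = oracle_cohort
        prop = fit_propensity(cohort, ORACLE_TERMS)
        assert prop.p_hat.min() >= 1e-3 and prop.p_hat.max() <= 1 - 1e-3
        assert prop.support == (prop.p_hat.min(), prop.p_hat.max())

    def test_degenerate_treatment_rejected(self, oracle_cohort):
        cohort, _ = oracle_cohort
        bad = cohort.assign(D=1)
        with pytest.raises(ValueError, match="all D identical"):
            fit_propensity(bad, ORACLE_TERMS)

    def test_separation_detected(self):
        rng = np.random.default_rng(0)
        n = 500
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        d = (x > 0).astype(float)  # perfectly separated
        with pytest.raises(SeparationError):
            _probit_mle(X, d)


class TestOutcomeStage:
    def test_noiseless_polynomial_recovered_exactly(self, oracle_cohort):
        cohort, _ = oracle_cohort
        sub = cohort.iloc[:20_000].copy()
        prop = fit_propensity(sub, ORACLE_TERMS)
        p = prop.p_hat
        sub["Y"] = 3.0 - 2.0 * p + 1.5 * p**2 - 0.5 * p**3
        fit = fit_outcome(sub, p, ORACLE_TERMS, support=prop.support)
        grid = np.linspace(p.min() + 0.01, p.max() - 0.01, 7)
        expected = -2.0 + 3.0 * grid - 1.5 * grid**2
        got = fit.mte_curve(grid)
        assert np.allclose(got, expected, atol=1e-6)

    def test_nonfinite_outcome_rejected(self, oracle_cohort):
        cohort, _ = oracle_cohort
        bad = cohort.iloc[:500].copy()
        bad.loc[bad.index[3], "Y"] = np.nan
        prop = fit_propensity(bad, ORACLE_TERMS)
        with pytest.raises(ValueError, match="non-finite"):
            fit_outcome(bad, prop.p_hat, ORACLE_TERMS)

    def test_rank_deficiency_names_aliased_columns(self, oracle_cohort):
        cohort, _ = oracle_cohort
        sub = cohort.iloc[:2000].copy()
        prop = fit_propensity(sub, ORACLE_TERMS)
        sub["dbp"] = sub["sbp"]  # alias two covariates in the outcome stage
        with pytest.raises(ValueError, match="rank deficient"):
            fit_outcome(sub, prop.p_hat, ORACLE_TERMS)


class TestMTE:
    def test_linear_fit_gives_constant_mte(self, oracle_cohort):
        cohort, _ = oracle_cohort
        sub = cohort.iloc[:10_000].copy()
        terms = TermSet(quadratic_terms=(), covariate_interactions=(),
                        iv_interactions=(), pscore_poly_degree=1)
        prop = fit_propensity(sub, terms)
        sub["Y"] = 4.2 * prop.p_hat + 1.0
        fit = fit_outcome(sub, prop.p_hat, terms, support=prop.support)
        for p in (0.2, 0.5, 0.8):
            assert mte(fit, {}, p) == pytest.approx(4.2, abs=1e-8)

    def test_matches_central_finite_difference_of_fitted_surface(self, oracle_cohort):
        cohort, _ = oracle_cohort
        prop, fit, _ = fit_liv(cohort)

        def surface(p):  # propensity-dependent part of the fitted outcome
            return (fit.poly.basis(np.array([p])) @ fit.beta_poly).item()

        h = 1e-5
        for p in (0.3, 0.5, 0.7):
            num = (surface(p + h) - surface(p - h)) / (2 * h)
            ana = fit.mte_curve(np.array([p])).item()
            assert ana == pytest.approx(num, rel=1e-6)

    def test_out_of_support_requires_extrapolate_flag(self, oracle_cohort):
        cohort, _ = oracle_cohort
        _, fit, _ = fit_liv(cohort)
        with pytest.raises(ValueError, match="support"):
            mte(fit, {}, 0.9999)
        assert np.isfinite(mte(fit, {}, 0.9999, extrapolate=True))

    def test_interaction_shift_enters_mte(self, oracle_cohort):
        """With a propensity-covariate interaction, the MTE at a profile one
        SD above the HbA1c mean differs from the mean profile by the
        interaction coefficient."""
        cohort, _ = oracle_cohort
        terms = TermSet(quadratic_terms=(), covariate_interactions=(),
                        iv_interactions=("hba1c",))
        spec = ModelSpec(terms, cohort)
        prop = fit_propensity(cohort, spec=spec)
        fit = fit_outcome(cohort, prop.p_hat, spec=spec, support=prop.support)
        mean_prof = {c: float(cohort[c].mean()) for c in
                     ("age", "hba1c", "bmi", "egfr", "sbp", "dbp", "duration")}
        mean_prof.update({"female": 0, "ethnicity": "white"})
        hi = dict(mean_prof)
        hi["hba1c"] = mean_prof["hba1c"] + float(cohort["hba1c"].std(ddof=0))
        delta = mte(fit, hi, 0.5) - mte(fit, mean_prof, 0.5)
        coef = fit.params["iv_x_hba1c"]
        assert delta == pytest.approx(coef, rel=1e-6)


class TestPeTEffects:
    def test_constant_mte_gives_constant_pet(self, oracle_cohort):
        cohort, _ = oracle_cohort
        sub = cohort.iloc[:5000].copy()
        terms = TermSet(quadratic_terms=(), covariate_interactions=(),
                        iv_interactions=(), pscore_poly_degree=1)
        prop = fit_propensity(sub, terms)
        sub["Y"] = -2.5 * prop.p_hat
        fit = fit_outcome(sub, prop.p_hat, terms, support=prop.support)
        pet = pet_effects(prop, fit, sub, seed=0)
        assert np.allclose(pet.pet_effect, -2.5, atol=1e-8)

    def test_uniform_half_interval_means(self, oracle_cohort):
        """MTE(u) = u, propensity 0.5, support (0.1, 0.9): the treated branch
        integrates u over (0.1, 0.5) -> 0.3, the untreated over (0.5, 0.9)
        -> 0.7."""
        cohort, _ = oracle_cohort
        sub = cohort.iloc[:2000].copy()
        terms = TermSet(quadratic_terms=(), covariate_interactions=(),
                        iv_interactions=(), pscore_poly_degree=2)
        prop = fit_propensity(sub, terms)
        sub["Y"] = 0.5 * prop.p_hat**2  # d/dp = p
        fit = fit_outcome(sub, prop.p_hat, terms, support=prop.support)
        fake_prop = PropensityFit(
            params=prop.params,
            p_hat=np.full(len(sub), 0.5),
            support=(0.1, 0.9),
            spec=prop.spec,
        )
        n_draws = 1000
        pet = pet_effects(fake_prop, fit, sub, n_draws=n_draws, seed=11)
        se = (0.4 / np.sqrt(12)) / np.sqrt(n_draws / 2)  # SE of a uniform mean
        treated = pet.pet_effect[sub["D"] == 1]
        untreated = pet.pet_effect[sub["D"] == 0]
        assert treated.mean() == pytest.approx(0.3, abs=2 * se)
        assert untreated.mean() == pytest.approx(0.7, abs=2 * se)

    def test_branch_combination_identity_exact(self, oracle_cohort):
        cohort, _ = oracle_cohort
        prop, fit, pet = fit_liv(cohort, seed=5)
        u_sorted = np.sort(pet.u_draws)
        all_draw_mean = fit.mte_curve(u_sorted).mean() + fit.mte_shift(cohort)
        combined = (pet.draw_weight * pet.branch_treated
                    + (1 - pet.draw_weight) * pet.branch_untreated)
        assert np.allclose(combined, all_draw_mean, rtol=0, atol=1e-12)

    def test_dstar_rule_equivalent_to_threshold_rule(self, oracle_cohort):
        cohort, _ = oracle_cohort
        prop = fit_propensity(cohort.iloc[:300], ORACLE_TERMS)
        rng = np.random.default_rng(2)
        u = np.sort(rng.uniform(*prop.support, 500))
        assert np.array_equal(
            dstar_assignment(prop.p_hat, u), u[None, :] < prop.p_hat[:, None]
        )

    def test_no_essential_heterogeneity_balances_branches(self, homogeneous_cohort):
        cohort, _ = homogeneous_cohort
        _, _, pet = fit_liv(cohort, seed=1)
        treated = pet.pet_effect[cohort["D"] == 1]
        untreated = pet.pet_effect[cohort["D"] == 0]
        mc_se = np.sqrt(treated.var() / len(treated) + untreated.var() / len(untreated))
        assert abs(treated.mean() - untreated.mean()) <= 3 * max(mc_se, 0.05)

    def test_support_edge_fallback_counted(self, oracle_cohort):
        cohort, _ = oracle_cohort
        sub = cohort.iloc[:1000]
        prop = fit_propensity(sub, ORACLE_TERMS)
        fit = fit_outcome(sub, prop.p_hat, ORACLE_TERMS, support=prop.support)
        # force a treated patient to the lower support edge
        forced = PropensityFit(
            params=prop.params,
            p_hat=np.where(np.arange(len(sub)) == 0, prop.support[0], prop.p_hat),
            support=prop.support,
            spec=prop.spec,
        )
        d = sub["D"].to_numpy().copy()
        d[0] = 1
        pet = pet_effects(forced, fit, sub.assign(D=d), n_draws=50, seed=3)
        assert pet.n_fallback >= 1
        assert pet.n_draws_used[0] == 1


class TestRigorousLasso:
    def test_forced_only_candidate_returned_unchanged(self, oracle_cohort):
        cohort, _ = oracle_cohort
        sel = select_terms_lasso(cohort.iloc[:3000], ORACLE_TERMS, stage=1)
        assert sel == set()

    def test_planted_signal_selected_and_noise_dropped(self):
        """A strong HbA1c effect-modifier plants a propensity-HbA1c
        interaction in the outcome stage; the plugin LASSO should keep it in
        nearly every replicate while keeping null interactions rarely."""
        reps = 25
        hits = {"iv_x_hba1c": 0}
        null_hits = []
        for r in range(reps):
            cfg = oracle_dgp(10_000, seed=800 + r, tau_x={"hba1c": -0.25})
            cohort, _ = complete_cases(generate_cohort(cfg))
            prop = fit_propensity(cohort, ORACLE_TERMS)
            sel = select_terms_lasso(cohort, TermSet(), stage=2, p_hat=prop.p_hat)
            hits["iv_x_hba1c"] += "iv_x_hba1c" in sel
            null_hits.append(len(sel & {"iv_x_egfr", "iv_x_sbp", "age_sq",
                                        "hba1c_x_age", "hba1c_x_female"}))
        assert hits["iv_x_hba1c"] >= 0.9 * reps
        # each null term kept in at most ~10% of replicates on average
        assert np.mean(null_hits) <= 0.5

    def test_degenerate_candidate_rejected(self, oracle_cohort):
        cohort, _ = oracle_cohort
        sub = cohort.iloc[:2000].copy()
        sub["egfr"] = 100.0  # constant covariate -> degenerate interaction column
        with pytest.raises(ValueError, match="collinear"):
            select_terms_lasso(sub, TermSet(), stage=1)
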