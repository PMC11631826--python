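"""Fit the local-IV estimator and recover the marginal-treatment-effect
curve on a cohort whose true curve is known in closed form.

Under the oracle configuration the unobserved gain is linked to the
latent resistance V so that MTE(v) = tau0 + rho * sigma * Phi^{-1}(v):
patients least resistant to DPP4i (small v) benefit most.
"""

import numpy as np
import pandas as pd

from petliv import ModelSpec, TermSet, fit_outcome, fit_propensity, mte, pet_effects
from petliv.synthetic_data import closed_form_mte, generate_cohort, oracle_dgp
from petliv.target_trial import complete_case_filter

cfg = oracle_dgp(30_000, seed=4)
cohort, _ = complete_case_filter(generate_cohort(cfg).cohort)

terms = TermSet(quadratic_terms=(), covariate_interactions=(), iv_interactions=())
spec = ModelSpec(terms, cohort)
prop = fit_propensity(cohort, spec=spec)
outcome = fit_outcome(cohort, prop.p_hat, spec=spec, support=prop.support)
print(f"propensity support: ({prop.support[0]:.3f}, {prop.support[1]:.3f})")

profile = {c: float(cohort[c].mean()) for c in
           ("age", "hba1c", "bmi", "egfr", "sbp", "dbp", "duration")}
profile.update({"female": 0, "ethnicity": "white"})
prof = pd.DataFrame([profile])
print("\nMTE at the mean covariate profile (mmol/mol):")
for p in (0.2, 0.35, 0.5, 0.65, 0.8):
    est = float(mte(outcome, prof, p))
    true = closed_form_mte(cfg, profile, p)
    print(f"  v={p:.2f}: fitted {est:+.2f}   closed form {true:+.2f}")

pet = pet_effects(prop, outcome, cohort, seed=4)
q = np.percentile(pet.pet_effect, [5, 25, 50, 75, 95])
print("\npersonalised (PeT) effects, percentiles 5/25/50/75/95:")
print("  " + "  ".join(f"{v:+.2f}" for v in q))
print(f"mean PeT (= LIV ATE): {pet.pet_effect.mean():+.2f}; true ATE {cfg.tau0:+.2f}")
print("the spread across patients reflects essential heterogeneity, not noise")
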