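import numpy as np
import pandas as pd
import pytest

from petliv.liv_core import (
    ModelSpec,
    TermSet,
    fit_outcome,
    fit_propensity,
    pet_effects,
)
from petliv.synthetic_data import DGPConfig, generate_cohort, oracle_dgp
from petliv.target_trial import complete_case_filter

#: term set used for oracle-recovery fits: mains plus the forced blocks,
#: no candidate interactions (the oracle generator has none)
ORACLE_TERMS = TermSet(
    quadratic_terms=(), covariate_interactions=(), iv_interactions=()
)


def fit_liv(cohort: pd.DataFrame, seed: int = 0, terms: TermSet = ORACLE_TERMS,
            n_draws: int = 1000):
    """Run the two LIV stages plus PeT integration; returns (prop, outcome, pet)."""
    spec = ModelSpec(terms, cohort)
    prop = fit_propensity(cohort, spec=spec)
    out = fit_outcome(cohort, prop.p_hat, spec=spec, support=prop.support)
    pet = pet_effects(prop, out, cohort, n_draws=n_draws, seed=seed)
    return prop, out, pet


def complete_cases(sc):
    """Complete-case cohort with the truth table aligned row-for-row."""
    cohort, _ = complete_case_filter(sc.cohort)
    truth = sc.truth.set_index("patient_id").loc[cohort["patient_id"]].reset_index()
    return cohort.reset_index(drop=True), truth


@pytest.fixture(scope="session")
def liv():
    return fit_liv


@pytest.fixture(scope="session")
def oracle_cohort():
    """n=20k cohort under the oracle configuration (rho_ess=0.5, sigma_gain=4)."""
    return complete_cases(generate_cohort(oracle_dgp(20_000, seed=7)))


@pytest.fixture(scope="session")
def homogeneous_cohort():
    """n=20k cohort with no essential heterogeneity (rho_ess=0)."""
    return complete_cases(generate_cohort(oracle_dgp(20_000, seed=17, rho_ess=0.0)))


@pytest.fixture(scope="session")
def big_default_cohort():
    """n=1e5 cohort under the default (study-emulating) configuration."""
    cfg = DGPConfig(n_patients=100_000, n_clusters=160, n_regions=10,
                    missing_outcome_prob=0.0, seed=5)
    return generate_cohort(cfg)
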