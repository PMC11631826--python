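"""Synthetic EHR-style cohorts with a preference-based instrument and
essential heterogeneity.

The generator emulates the structure of a primary-care cohort of people
with type-2 diabetes starting a second-line glucose-lowering drug
(DPP4i-analogue, ``D=1``, versus SU-analogue, ``D=0``): ~160 prescribing
clusters with heterogeneous tendency-to-prescribe (TTP), covariates with
marginals close to the published target population, latent-index treatment
selection ``D = 1{P(x, z) > V}`` with ``V ~ Uniform[0, 1]``, treatment-effect
heterogeneity in observed covariates (overt) and in the latent resistance
``V`` (essential), unobserved confounding of the baseline outcome, and
missing follow-up measurements.

Because treatment selection follows the latent-index model exactly, the
marginal treatment effect has a closed form (:func:`closed_form_mte`)
that downstream estimators can be checked against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DGPConfig",
    "SyntheticCohort",
    "generate_cohort",
    "closed_form_mte",
    "true_estimands",
    "DegenerateCohortError",
]

STUDY_START = date(2011, 1, 1)
STUDY_DAYS = 1826  # five calendar years, 2011-2015

#: continuous covariates: name -> (mean, sd, lower clip, upper clip)
DEFAULT_COVARIATE_PARAMS: dict = {
    "age": (61.0, 12.0, 18.0, 95.0),
    "hba1c": (73.0, 17.0, 30.0, 140.0),
    "bmi": (32.5, 6.3, 16.0, 60.0),
    "egfr": (85.0, 18.0, 15.0, 130.0),
    "sbp": (134.0, 15.0, 90.0, 200.0),
    "dbp": (80.0, 10.0, 50.0, 120.0),
    "duration": (5.5, 4.8, 0.1, 30.0),
    "female_prob": 0.40,
    "ethnicity_probs": {"white": 0.875, "south_asian": 0.090, "black_mixed_other": 0.035},
}

CONTINUOUS_COVARIATES = ("age", "hba1c", "bmi", "egfr", "sbp", "dbp", "duration")

#: probit-index coefficients; continuous covariates enter standardised,
#: the instrument enters on its natural [0, 1] scale.
DEFAULT_SELECTION_COEFS: dict = {
    "intercept": -1.07,
    "z": 2.0,
    "hba1c": -0.25,
    "bmi": 0.18,
    "duration": 0.05,
    "age": -0.02,
}

#: untreated mean change in HbA1c (mmol/mol): intercept plus per-unit
#: coefficients on mean-centred raw covariates.
DEFAULT_OUTCOME_COEFS: dict = {
    "intercept": -12.0,
    "hba1c": -0.35,
    "duration": 0.2,
}


def oracle_dgp(n_patients: int = 50_000, seed: int = 0, **overrides) -> "DGPConfig":
    """Estimator-validation configuration with a closed-form effect surface.

    Selection is preference-dominated (instrument coefficient 4 on the
    probit index, wide cluster spread) so the propensity traverses most
    of (0, 1); there is no overt effect modification (``tau_x`` empty),
    essential heterogeneity is at half strength with a 4 mmol/mol gain
    SD, outcome noise is kept low, and follow-up is fully observed.
    Under this configuration the true marginal treatment effect is
    ``tau0 + rho_ess * sigma_gain * Phi^{-1}(v)`` exactly.
    """
    coefs = dict(DEFAULT_SELECTION_COEFS)
    coefs["z"] = 4.0
    coefs["intercept"] = float(stats.norm.ppf(0.374) - 4.0 * 0.374)
    base = dict(
        n_patients=n_patients,
        n_clusters=100,
        n_regions=10,
        cluster_pref_spread=1.0,
        selection_coefs=coefs,
        tau0=-1.0,
        tau_x={},
        rho_ess=0.5,
        sigma_gain=4.0,
        rho_conf=0.3,
        sigma_y=3.0,
        missing_outcome_prob=0.0,
        measurement_jitter_days=0.0,
        seed=seed,
    )
    base.update(overrides)
    return DGPConfig(**base)


class DegenerateCohortError(ValueError):
    """Raised when the generated cohort violates a support condition."""


@dataclass
class DGPConfig:
    """Parameters of the data-generating process.

    ``tau_x`` holds per-unit effect-modifier coefficients on mean-centred
    raw covariates (e.g. ``{"hba1c": -0.08}`` means the treatment effect
    falls by 0.08 mmol/mol per mmol/mol of baseline HbA1c above its mean).
    ``rho_ess`` controls essential heterogeneity: the unobserved gain
    component has conditional mean ``rho_ess * sigma_gain * Phi^{-1}(V)``.
    ``rho_conf`` is the correlation between the baseline-outcome noise and
    the (pro-treatment) latent selection shock, i.e. unobserved confounding.
    """

    n_patients: int = 13_240
    n_clusters: int = 160
    n_regions: int = 10
    cluster_pref_spread: float = 0.6
    covariate_params: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS))
    selection_coefs: dict = field(default_factory=lambda: dict(DEFAULT_SELECTION_COEFS))
    outcome_coefs: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_COEFS))
    tau0: float = -1.3
    tau_x: dict = field(default_factory=lambda: {"hba1c": -0.08})
    rho_ess: float = 0.3
    sigma_gain: float = 4.0
    rho_conf: float = 0.3
    sigma_y: float = 10.0
    missing_outcome_prob: float = 0.318
    measurement_jitter_days: float = 45.0
    burn_in_events: int | None = None
    ttp_window_days: int = 365
    ttp_min_events: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_clusters <= 0 or self.n_clusters > self.n_patients:
            raise ValueError("n_clusters must be in [1, n_patients]")
        if self.n_regions <= 0 or self.n_regions > self.n_clusters:
            raise ValueError("n_regions must be in [1, n_clusters]")
        if not (0.0 <= self.missing_outcome_prob <= 1.0):
            raise ValueError("missing_outcome_prob must be a probability in [0, 1]")
        for name in ("rho_ess", "rho_conf"):
            if not (-1.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [-1, 1]")
        for name in ("cluster_pref_spread", "sigma_gain", "sigma_y",
                     "measurement_jitter_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative scale")
        if self.selection_coefs.get("z", 0.0) <= 0:
            raise ValueError(
                "selection_coefs['z'] must be strictly positive "
                "(monotone treatment uptake in the instrument)"
            )

    def covariate_center(self, name: str) -> float:
        return float(self.covariate_params[name][0])

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "DGPConfig":
        return cls(**d)


@dataclass
class SyntheticCohort:
    """A generated cohort plus its simulation-only ground truth.

    ``cohort`` follows the patient-level analysis schema (see
    :mod:`petliv.target_trial`); ``truth`` is a parallel table keyed by
    ``patient_id`` with potential outcomes, the latent resistance ``V``
    and the noise components.
    """

    cohort: pd.DataFrame
    truth: pd.DataFrame
    dgp: DGPConfig


def _tau_profile(config: DGPConfig, cov: dict[str, np.ndarray | float]) -> np.ndarray | float:
    """Observed-modifier part of the treatment effect: tau0 + tau_x.(x - centre)."""
    out = config.tau0
    for name, coef in config.tau_x.items():
        out = out + coef * (np.asarray(cov[name]) - config.covariate_center(name))
    return out


def closed_form_mte(config: DGPConfig, x: dict[str, float], v: float) -> float:
    """True marginal treatment effect at covariate profile ``x`` and resistance ``v``.

    Under the generator's normal-gain model,
    ``MTE(x, v) = tau0 + tau_x.(x - centre) + rho_ess * sigma_gain * Phi^{-1}(v)``.
    """
    if not 0.0 < v < 1.0:
        raise ValueError("v must lie strictly inside (0, 1)")
    base = _tau_profile(config, x)
    return float(base + config.rho_ess * config.sigma_gain * stats.norm.ppf(v))


def _draw_covariates(config: DGPConfig, n: int, rng: np.random.Generator) -> dict:
    p = config.covariate_params
    cov: dict[str, np.ndarray] = {}
    for name in CONTINUOUS_COVARIATES:
        mean, sd, lo, hi = p[name]
        cov[name] = np.clip(rng.normal(mean, sd, n), lo, hi)
    cov["female"] = (rng.random(n) < p["female_prob"]).astype(np.int64)
    eth = p["ethnicity_probs"]
    cov["ethnicity"] = rng.choice(list(eth.keys()), size=n, p=list(eth.values()))
    return cov


def _selection_index(config: DGPConfig, cov: dict, z: np.ndarray) -> np.ndarray:
    """Probit index mu_D(x, z); continuous covariates standardised by their
    generator mean/SD so coefficients are on a comparable scale."""
    coefs = config.selection_coefs
    idx = np.full_like(z, coefs.get("intercept", 0.0), dtype=float)
    idx += coefs["z"] * z
    for name, b in coefs.items():
        if name in ("intercept", "z"):
            continue
        if name == "female":
            idx += b * cov["female"]
        else:
            mean, sd = config.covariate_params[name][:2]
            idx += b * (cov[name] - mean) / sd
    return idx


def _baseline_mean(config: DGPConfig, cov: dict) -> np.ndarray:
    coefs = config.outcome_coefs
    mu0 = np.full(len(cov["age"]), coefs.get("intercept", 0.0), dtype=float)
    for name, b in coefs.items():
        if name == "intercept":
            continue
        mu0 += b * (cov[name] - config.covariate_center(name))
    return mu0


def _rolling_ttp(
    cluster_of: np.ndarray,
    day: np.ndarray,
    mu_no_z: np.ndarray,
    z_coef: float,
    v: np.ndarray,
    config: DGPConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sequentially compute each patient's TTP instrument and treatment.

    Each cluster starts from a burn-in prescription history drawn from its
    own preference, and every patient's day-zero prescription is appended
    to the history so later patients in the same cluster see it.  The
    patient's own prescription is never in their window (strictly earlier
    dates only).  Returns (z, low_support flag, d).
    """
    n = len(day)
    n_clusters = config.n_clusters
    window = config.ttp_window_days
    rate = max(10, round(config.n_patients / config.n_clusters * 365.0 / STUDY_DAYS))
    m0 = config.burn_in_events if config.burn_in_events is not None else rate

    alpha = rng.normal(0.0, config.cluster_pref_spread, n_clusters)
    base = stats.norm.ppf(0.374)  # marginal DPP4i share in the target population

    z = np.empty(n)
    low = np.zeros(n, dtype=bool)
    d = np.zeros(n, dtype=np.int64)

    # D = 1{Phi(mu) > V}  <=>  mu > Phi^{-1}(V); precompute the threshold so
    # the sequential loop needs no distribution calls
    thresh = stats.norm.ppf(v)
    order = np.lexsort((day, cluster_of))
    boundaries = np.searchsorted(cluster_of[order], np.arange(n_clusters + 1))
    for c in range(n_clusters):
        burn_days = np.sort(rng.integers(-365, 0, m0))
        burn_cls = (rng.random(m0) < stats.norm.cdf(base + alpha[c])).astype(np.int64)
        dates = list(burn_days)
        csum = np.cumsum(burn_cls).tolist()  # prefix sums of DPP4i indicators
        lo_ptr = 0
        members = order[boundaries[c]:boundaries[c + 1]]
        for i in members:
            t = day[i]
            while lo_ptr < len(dates) and dates[lo_ptr] <= t - window:
                lo_ptr += 1
            n_tot = len(dates) - lo_ptr
            if n_tot > 0:
                n_dpp = csum[-1] - (csum[lo_ptr - 1] if lo_ptr > 0 else 0)
                z[i] = n_dpp / n_tot
                low[i] = n_tot < config.ttp_min_events
            else:
                # no events left in the window: fall back to the cluster's
                # cumulative share to date, flagged as low support
                z[i] = csum[-1] / len(dates)
                low[i] = True
            d_i = 1 if mu_no_z[i] + z_coef * z[i] > thresh[i] else 0
            d[i] = d_i
            dates.append(t)
            csum.append(csum[-1] + d_i)
    return z, low, d


def generate_cohort(config: DGPConfig) -> SyntheticCohort:
    """Generate a cohort under the latent-index selection model.

    All randomness is driven by ``config.seed`` through named child
    streams (cluster assignment, covariates, selection, outcomes,
    missingness), so the output is byte-identical across runs and stable
    under changes confined to one stage.
    """
    config.validate()
    n = config.n_patients
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("assign", "covariates", "selection", "prescribing", "outcome", "missing"),
            root.spawn(6),
        )
    }

    cluster_of = streams["assign"].integers(0, config.n_clusters, n)
    region_of = cluster_of % config.n_regions
    day = streams["assign"].integers(0, STUDY_DAYS, n)

    cov = _draw_covariates(config, n, streams["covariates"])

    v = streams["selection"].uniform(0.0, 1.0, n)
    w = stats.norm.ppf(v)  # normal transform of the resistance

    mu_no_z = _selection_index(config, cov, np.zeros(n))
    z, z_low, d = _rolling_ttp(
        cluster_of, day, mu_no_z, config.selection_coefs["z"], v, config,
        streams["prescribing"],
    )
    if d.min() == d.max():
        raise DegenerateCohortError(
            "degenerate treatment support: every patient received the same "
            "treatment (D identical); strengthen covariate/instrument variation"
        )

    rng_y = streams["outcome"]
    xi = rng_y.normal(0.0, 1.0, n)
    theta = rng_y.normal(0.0, 1.0, n)
    eta = config.sigma_gain * (
        config.rho_ess * w + np.sqrt(1.0 - config.rho_ess**2) * xi
    )
    # selection shock -w is pro-treatment; correlating eps0 with it induces
    # unobserved confounding of the baseline outcome
    eps0 = config.sigma_y * (
        config.rho_conf * (-w) + np.sqrt(1.0 - config.rho_conf**2) * theta
    )
    y0 = _baseline_mean(config, cov) + eps0
    effect = _tau_profile(config, cov) + eta
    y1 = y0 + effect
    y = np.where(d == 1, y1, y0)

    rng_m = streams["missing"]
    jitter = np.round(rng_m.normal(0.0, config.measurement_jitter_days, n)).astype(int)
    followup_day = day + 364 + jitter
    observed = rng_m.random(n) >= config.missing_outcome_prob
    hba1c_offset = np.minimum(rng_m.exponential(45.0, n), 400.0).astype(int)
    vitals_offset = np.minimum(rng_m.exponential(150.0, n), 700.0).astype(int)

    start = pd.Timestamp(STUDY_START)
    index_date = start + pd.to_timedelta(day, unit="D")
    fu_date = pd.Series(start + pd.to_timedelta(followup_day, unit="D"))
    fu_date[~observed] = pd.NaT
    cohort = pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=np.int64),
            "cluster_id": cluster_of,
            "region_id": region_of,
            "index_date": index_date,
            "D": d,
            "Z": z,
            "z_low_support": z_low.astype(np.int64),
            "age": cov["age"],
            "female": cov["female"],
            "ethnicity": cov["ethnicity"],
            "hba1c": cov["hba1c"],
            "bmi": cov["bmi"],
            "egfr": cov["egfr"],
            "sbp": cov["sbp"],
            "dbp": cov["dbp"],
            "duration": cov["duration"],
            "baseline_hba1c_date": index_date - pd.to_timedelta(hba1c_offset, unit="D"),
            "vitals_date": index_date - pd.to_timedelta(vitals_offset, unit="D"),
            "followup_hba1c": np.where(observed, cov["hba1c"] + y, np.nan),
            "followup_date": fu_date,
            "Y": np.where(observed, y, np.nan),
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=np.int64),
            "V": v,
            "Y0": y0,
            "Y1": y1,
            "individual_effect": effect,
            "eta": eta,
            "eps0": eps0,
        }
    )
    return SyntheticCohort(cohort=cohort, truth=truth, dgp=config)


def true_estimands(sc: SyntheticCohort, scheme=None) -> pd.DataFrame:
    """True ATE and CATEs from the simulation ground truth.

    Returns one row per (scheme, stratum) plus an ``overall`` row; empty
    strata are retained with ``n=0`` and an ``empty`` flag rather than
    silently dropped.
    """
    from .target_trial import SubgroupScheme, assign_subgroups

    if scheme is None:
        scheme = SubgroupScheme()
    merged = sc.cohort.merge(sc.truth[["patient_id", "individual_effect"]], on="patient_id")
    labelled = assign_subgroups(merged, scheme)
    rows = [
        {
            "scheme": "overall",
            "subgroup": "overall",
            "n": len(labelled),
            "true_effect": float(labelled["individual_effect"].mean()),
            "empty": False,
        }
    ]
    for name in scheme.label_columns():
        levels = scheme.levels(name)
        for level in levels:
            mask = labelled[name] == level
            n_s = int(mask.sum())
            rows.append(
                {
                    "scheme": name,
                    "subgroup": level,
                    "n": n_s,
                    "true_effect": float(labelled.loc[mask, "individual_effect"].mean())
                    if n_s
                    else float("nan"),
                    "empty": n_s == 0,
                }
            )
    return pd.DataFrame(rows)


def write_cohort(sc: SyntheticCohort, cohort_path, truth_path=None) -> None:
    """Write the cohort (and optionally the truth table) as CSV with ISO dates
    and empty strings for missing values."""
    df = sc.cohort.copy()
    for col in ("index_date", "baseline_hba1c_date", "vitals_date", "followup_date"):
        df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
    df.to_csv(cohort_path, index=False, na_rep="")
    if truth_path is not None:
        sc.truth.to_csv(truth_path, index=False, na_rep="")


def read_cohort(cohort_path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(cohort_path, keep_default_na=True)
    for col in ("index_date", "baseline_hba1c_date", "vitals_date", "followup_date"):
        df[col] = pd.to_datetime(df[col])
    return df
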