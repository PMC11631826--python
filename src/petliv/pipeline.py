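"""End-to-end pipeline: simulate/load -> construct -> diagnose -> estimate
-> infer -> report.

A run is fully described by a :class:`RunConfig`; every run writes its
resolved configuration, a manifest with content hashes of all outputs,
and delimited tables for the cohort, eligibility flow, instrument
diagnostics, per-patient personalised effects and the effect estimates
(LIV plus comparators, for the target / trial-eligible / trial-ineligible
populations).  A single master seed is expanded into named per-stage
streams so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparators import iptw_ra, two_stage_least_squares
from .effects_inference import aggregate_effects, bootstrap_ci, estimate_agreement
from .instrument import weak_iv_test
from .liv_core import ModelSpec, TermSet, fit_outcome, fit_propensity, pet_effects, select_specification
from .synthetic_data import DGPConfig, generate_cohort, write_cohort
from .target_trial import (
    EligibilityCriteria,
    SubgroupScheme,
    apply_eligibility,
    assign_subgroups,
    complete_case_filter,
    population_masks,
    split_rct_eligibility,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "liv_closure"]


@dataclass
class RunConfig:
    """Resolved settings of one analysis run; round-trips through YAML."""

    dgp: DGPConfig = field(default_factory=DGPConfig)
    cohort_path: str | None = None  # load instead of simulate when set
    n_draws: int = 1000
    pscore_poly_degree: int = 3
    run_lasso: bool = True
    bootstrap_reps: int = 500
    alpha: float = 0.05
    benchmark_point: float | None = None
    benchmark_ci: tuple | None = None
    seed: int = 0
    out_dir: str = "petliv_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dgp"] = self.dgp.to_dict()
        if d.get("benchmark_ci") is not None:
            d["benchmark_ci"] = list(d["benchmark_ci"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("dgp"), dict):
            d["dgp"] = DGPConfig.from_dict(d["dgp"])
        if d.get("benchmark_ci") is not None:
            d["benchmark_ci"] = tuple(d["benchmark_ci"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    flow: dict
    diagnostics: dict
    files: dict
    version: str
    manifest_hash: str = ""

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload.pop("manifest_hash")
        body = json.dumps(payload, indent=2, sort_keys=True, default=str)
        self.manifest_hash = hashlib.sha256(body.encode()).hexdigest()
        payload["manifest_hash"] = self.manifest_hash
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def _config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("out_dir")  # where a run lands must not change what it computes
    return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()


def liv_closure(terms: TermSet, n_draws: int, scheme: SubgroupScheme):
    """Closure re-running propensity + outcome + PeT + aggregation with a
    frozen term specification; suitable for :func:`bootstrap_ci`."""

    def run(cohort: pd.DataFrame, seed: int) -> pd.Series:
        spec = ModelSpec(terms, cohort)
        prop = fit_propensity(cohort, spec=spec)
        out = fit_outcome(cohort, prop.p_hat, spec=spec, support=prop.support)
        pet = pet_effects(prop, out, cohort, n_draws=n_draws, seed=seed)
        masks = population_masks(cohort)
        table = aggregate_effects(pet.pet_effect, cohort, scheme, masks, method="LIV")
        idx = table["method"] + "|" + table["population"] + "|" + table["scheme"] + "|" + table["subgroup"]
        return pd.Series(table["point"].to_numpy(), index=idx)

    return run


def _comparator_closure(terms: TermSet, scheme: SubgroupScheme):
    def run(cohort: pd.DataFrame, seed: int) -> pd.Series:
        preds = iptw_ra(cohort, terms)
        masks = population_masks(cohort)
        table = aggregate_effects(preds.effect, cohort, scheme, masks, method="IPTW-RA")
        idx = table["method"] + "|" + table["population"] + "|" + table["scheme"] + "|" + table["subgroup"]
        ser = pd.Series(table["point"].to_numpy(), index=idx)
        tsls = two_stage_least_squares(cohort, terms)
        ser["2SLS|target|overall|overall"] = tsls.point
        return ser

    return run


def run_pipeline(config: RunConfig) -> RunManifest:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _run_pipeline(config, out_dir)
    except Exception:
        (out_dir / "failed").touch()
        raise


def _run_pipeline(config: RunConfig, out_dir: Path) -> RunManifest:
    root = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(("dgp", "udraws", "bootstrap"), root.spawn(3))
    }

    # --- simulate or load ---------------------------------------------------
    if config.cohort_path is not None:
        from .synthetic_data import read_cohort

        raw = read_cohort(config.cohort_path)
        truth = None
    else:
        dgp = dataclasses.replace(config.dgp, seed=stage_seeds["dgp"])
        sc = generate_cohort(dgp)
        raw, truth = sc.cohort, sc.truth
        write_cohort(sc, out_dir / "cohort.csv", out_dir / "truth.csv")

    flow: dict = {"raw": len(raw)}

    # --- target-trial construction -----------------------------------------
    criteria = EligibilityCriteria()
    eligible, flow_report = apply_eligibility(raw, criteria)
    flow["eligible"] = len(eligible)
    analysis, miss_report = complete_case_filter(eligible)
    flow["complete_case"] = len(analysis)
    scheme = SubgroupScheme()
    analysis = assign_subgroups(split_rct_eligibility(analysis, criteria), scheme)
    analysis = analysis.reset_index(drop=True)

    flow_report.to_csv(out_dir / "eligibility_flow.csv", index=False)
    miss_report.to_csv(out_dir / "missingness.csv", index=False)

    # --- instrument diagnostics --------------------------------------------
    diag = weak_iv_test(analysis)
    diag.balance.to_csv(out_dir / "iv_balance.csv", index=False)
    diagnostics = {
        "f_statistic": diag.f_statistic,
        "f_benchmark": diag.f_benchmark,
        "n_clusters": diag.n_clusters,
        "cluster_var": diag.cluster_var,
        "n_unbalanced_covariates": int((~diag.balance["balanced"]).sum()),
    }

    # --- term selection and LIV fit ----------------------------------------
    candidate = TermSet(pscore_poly_degree=config.pscore_poly_degree)
    terms = select_specification(analysis, candidate) if config.run_lasso else candidate
    spec = ModelSpec(terms, analysis)
    prop = fit_propensity(analysis, spec=spec)
    outcome = fit_outcome(analysis, prop.p_hat, spec=spec, support=prop.support)
    pet = pet_effects(prop, outcome, analysis, n_draws=config.n_draws,
                      seed=stage_seeds["udraws"])

    pet_table = pd.DataFrame(
        {
            "patient_id": analysis["patient_id"],
            "p_hat": prop.p_hat,
            "pet_effect": pet.pet_effect,
            "side": pet.side,
            "n_draws_used": pet.n_draws_used,
        }
    )
    pet_table.to_csv(out_dir / "pet_effects.csv", index=False)

    # --- aggregation and comparators ---------------------------------------
    masks = population_masks(analysis)
    liv_table = aggregate_effects(pet.pet_effect, analysis, scheme, masks, method="LIV")
    preds = iptw_ra(analysis, terms)
    iptw_table = aggregate_effects(preds.effect, analysis, scheme, masks, method="IPTW-RA")
    tsls = two_stage_least_squares(analysis, terms)
    tsls_table = pd.DataFrame(
        [{
            "method": "2SLS", "estimand": "ATE", "population": "target",
            "scheme": "overall", "subgroup": "overall", "n": len(analysis),
            "point": tsls.point, "small_sample": False,
        }]
    )
    effects = pd.concat([liv_table, iptw_table, tsls_table], ignore_index=True)

    # --- bootstrap inference -------------------------------------------------
    if config.bootstrap_reps > 0:
        key = effects["method"] + "|" + effects["population"] + "|" + effects["scheme"] + "|" + effects["subgroup"]
        liv_ci = bootstrap_ci(
            liv_closure(terms, config.n_draws, scheme), analysis,
            B=config.bootstrap_reps, alpha=config.alpha,
            seed=stage_seeds["bootstrap"],
        )
        cmp_ci = bootstrap_ci(
            _comparator_closure(terms, scheme), analysis,
            B=config.bootstrap_reps, alpha=config.alpha,
            seed=stage_seeds["bootstrap"] + 1,
        )
        ci = pd.concat([liv_ci, cmp_ci])
        effects["ci_low"] = ci["ci_low"].reindex(key).to_numpy()
        effects["ci_high"] = ci["ci_high"].reindex(key).to_numpy()
        effects["B"] = config.bootstrap_reps
    else:
        effects["ci_low"] = np.nan
        effects["ci_high"] = np.nan
        effects["B"] = 0
    effects.to_csv(out_dir / "effects.csv", index=False)

    # --- benchmark agreement -------------------------------------------------
    if config.benchmark_ci is not None:
        row = effects.query(
            "method == 'LIV' and population == 'rct_eligible' and scheme == 'overall'"
        )
        agreement = estimate_agreement(float(row["point"].iloc[0]), config.benchmark_ci)
        diagnostics["estimate_agreement"] = agreement.agree
        (out_dir / "agreement.json").write_text(
            json.dumps(dataclasses.asdict(agreement), indent=2)
        )

    resolved = out_dir / "config.yaml"
    config.to_yaml(resolved)

    files = {}
    for f in sorted(out_dir.glob("*")):
        if f.is_file() and f.name not in ("manifest.json",):
            files[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = RunManifest(
        config_hash=_config_hash(config),
        seeds=stage_seeds,
        flow=flow,
        diagnostics=diagnostics,
        files=files,
        version=__version__,
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest
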