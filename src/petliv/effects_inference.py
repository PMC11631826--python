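"""Aggregation of individual effects to ATE/CATEs with bootstrap inference.

Individual-level effect estimates (PeT effects from the local-IV fit, or
recycled-prediction differences from comparators) are averaged over the
population and over pre-specified subgroup strata.  Confidence intervals
come from a nonparametric bootstrap stratified by region and treatment
group, with t-distribution intervals centred at the full-sample point
estimate (percentile intervals available behind a flag).  A benchmark
agreement check records whether a target-trial point estimate falls
inside a reference trial's confidence interval (closed at the
endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementResult",
    "aggregate_effects",
    "bootstrap_ci",
    "stratified_resample",
    "estimate_agreement",
]

MIN_STRATUM = 10


@dataclass
class AgreementResult:
    agree: bool
    target_point: float
    benchmark_ci: tuple


def aggregate_effects(
    effects: np.ndarray,
    cohort: pd.DataFrame,
    scheme=None,
    population_masks: Mapping[str, pd.Series] | None = None,
    method: str = "LIV",
    min_stratum: int = MIN_STRATUM,
) -> pd.DataFrame:
    """Unweighted means of individual effects overall and per stratum.

    ``effects`` is aligned positionally with ``cohort``.  Returns one row
    per (population, scheme, subgroup): the overall rows carry estimand
    ``ATE``, subgroup rows ``CATE``.  Strata smaller than ``min_stratum``
    are kept but flagged.
    """
    from .target_trial import SubgroupScheme, assign_subgroups

    if len(effects) != len(cohort):
        raise ValueError("effects and cohort are not aligned")
    if scheme is None:
        scheme = SubgroupScheme()
    if population_masks is None:
        population_masks = {"target": pd.Series(True, index=cohort.index)}
    labelled = cohort
    if not set(scheme.label_columns()) <= set(cohort.columns):
        labelled = assign_subgroups(cohort, scheme)
    eff = np.asarray(effects, float)

    rows = []
    for pop, mask in population_masks.items():
        m = np.asarray(mask, bool)
        if m.sum() == 0:
            continue
        rows.append(
            {
                "method": method, "estimand": "ATE", "population": pop,
                "scheme": "overall", "subgroup": "overall",
                "n": int(m.sum()), "point": float(eff[m].mean()),
                "small_sample": bool(m.sum() < min_stratum),
            }
        )
        for col in scheme.label_columns():
            for level in scheme.levels(col):
                sm = m & (labelled[col].to_numpy() == level)
                n_s = int(sm.sum())
                if n_s == 0:
                    continue
                rows.append(
                    {
                        "method": method, "estimand": "CATE", "population": pop,
                        "scheme": col, "subgroup": level,
                        "n": n_s, "point": float(eff[sm].mean()),
                        "small_sample": bool(n_s < min_stratum),
                    }
                )
    return pd.DataFrame(rows)


def stratified_resample(
    cohort: pd.DataFrame,
    rng: np.random.Generator,
    strata_cols: tuple = ("region_id", "D"),
) -> pd.DataFrame:
    """Resample patients with replacement within each stratum, preserving
    stratum sizes.  With a single stratum this is the ordinary
    nonparametric bootstrap."""
    if not strata_cols:
        idx = rng.integers(0, len(cohort), len(cohort))
        return cohort.iloc[idx].reset_index(drop=True)
    codes = pd.MultiIndex.from_frame(cohort[list(strata_cols)]).factorize()[0]
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    bounds = np.searchsorted(sorted_codes, np.arange(sorted_codes[-1] + 2))
    take = np.empty(len(cohort), dtype=np.int64)
    pos = 0
    for s in range(len(bounds) - 1):
        lo, hi = bounds[s], bounds[s + 1]
        size = hi - lo
        if size == 0:
            continue
        take[pos:pos + size] = order[lo + rng.integers(0, size, size)]
        pos += size
    return cohort.iloc[take].reset_index(drop=True)


def bootstrap_ci(
    pipeline_closure: Callable[[pd.DataFrame, int], pd.Series],
    cohort: pd.DataFrame,
    B: int = 500,
    alpha: float = 0.05,
    strata_cols: tuple = ("region_id", "D"),
    seed: int | None = None,
    percentile: bool = False,
    max_failure_rate: float = 0.05,
) -> pd.DataFrame:
    """Bootstrap confidence intervals for every estimate a closure returns.

    ``pipeline_closure(cohort, seed)`` must re-run the full estimation
    (both stages and aggregation, with the frozen term specification) and
    return a Series of point estimates.  Patients are resampled with
    replacement within region x treatment strata.  The default interval
    is ``point +/- t_{1-alpha/2, B-1} * SD(bootstrap estimates)`` centred
    at the full-sample estimate.  Replicates that fail (e.g. separation)
    are skipped; more than ``max_failure_rate`` failures aborts.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(B + 1)]
    point = pipeline_closure(cohort, seeds[0])

    reps = []
    failures: list[str] = []
    rng_master = np.random.default_rng(root.spawn(1)[0])
    for b in range(B):
        sample = stratified_resample(cohort, rng_master, strata_cols)
        try:
            reps.append(pipeline_closure(sample, seeds[b + 1]))
        except Exception as exc:  # noqa: BLE001 - replicate failures are data-driven
            failures.append(f"replicate {b}: {exc}")
    if len(failures) > max_failure_rate * B:
        raise RuntimeError(
            f"{len(failures)}/{B} bootstrap replicates failed; first failure: "
            f"{failures[0]}"
        )
    rep_df = pd.DataFrame(reps)
    B_eff = len(rep_df)
    out = pd.DataFrame({"point": point})
    if percentile:
        out["ci_low"] = rep_df.quantile(alpha / 2)
        out["ci_high"] = rep_df.quantile(1 - alpha / 2)
    else:
        half = stats.t.ppf(1 - alpha / 2, B_eff - 1) * rep_df.std(ddof=1)
        out["ci_low"] = point - half
        out["ci_high"] = point + half
    out["B"] = B_eff
    out["n_failed"] = len(failures)
    return out


def estimate_agreement(target_point: float, benchmark_ci: tuple) -> AgreementResult:
    """Benchmark agreement: is the target-trial point estimate inside the
    reference trial's confidence interval (closed at the endpoints)?"""
    lo, hi = benchmark_ci
    if lo is None or hi is None or np.isnan(lo) or np.isnan(hi):
        raise ValueError("benchmark confidence interval is missing")
    if lo > hi:
        raise ValueError("benchmark CI has low > high")
    return AgreementResult(
        agree=bool(lo <= target_point <= hi),
        target_point=float(target_point),
        benchmark_ci=(float(lo), float(hi)),
    )
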