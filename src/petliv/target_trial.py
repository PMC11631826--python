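"""Target-trial cohort construction.

Turns a raw patient-level table into the analysis cohort of an emulated
trial: eligibility filtering with a flow report, day-zero alignment of
the outcome window, complete-case filtering, clinically defined subgroup
labels, and the split into trial-eligible and trial-ineligible
subpopulations (the benchmark trial enrolled ages 18-78 with baseline
HbA1c 44-87 mmol/mol).

The outcome is the change in HbA1c (mmol/mol) from day zero to week 52,
with the follow-up measure accepted within +/-90 days of day 364; the
contrast is change under DPP4i minus change under SU, so negative values
favour DPP4i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "CohortSchemaError",
    "EligibilityCriteria",
    "SubgroupScheme",
    "apply_eligibility",
    "split_rct_eligibility",
    "assign_subgroups",
    "complete_case_filter",
    "MODEL_COVARIATES",
]

#: covariates entering the estimation models (complete cases required)
MODEL_COVARIATES = ["age", "female", "ethnicity", "hba1c", "bmi", "egfr", "sbp", "dbp", "duration"]

OUT_OF_RANGE = "out-of-range"


class CohortSchemaError(KeyError):
    """An eligibility predicate referenced a column the cohort lacks."""


@dataclass
class EligibilityCriteria:
    """Named row-wise predicates defining the target population.

    Each predicate maps the cohort frame to a boolean keep-mask and must
    be a pure function of single-row fields.  Defaults follow the study
    protocol: baseline HbA1c measured within 180 days before day zero,
    blood pressure / renal measures within 540 days, and adults only.
    """

    baseline_hba1c_window_days: int = 180
    covariate_recency_window_days: int = 540
    rct_age_range: tuple = (18.0, 78.0)
    rct_hba1c_range: tuple = (44.0, 87.0)
    extra_rules: list = field(default_factory=list)  # (name, frame -> keep mask)

    def rules(self) -> list[tuple[str, Callable[[pd.DataFrame], pd.Series]]]:
        hb_win = self.baseline_hba1c_window_days
        cov_win = self.covariate_recency_window_days
        base: list[tuple[str, Callable]] = [
            ("adult", lambda df: df["age"] >= 18),
            (
                f"baseline_hba1c_within_{hb_win}d",
                lambda df: (df["index_date"] - df["baseline_hba1c_date"]).dt.days <= hb_win,
            ),
            (
                f"vitals_within_{cov_win}d",
                lambda df: (df["index_date"] - df["vitals_date"]).dt.days <= cov_win,
            ),
        ]
        return base + list(self.extra_rules)


def _check_columns(cohort: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise CohortSchemaError(f"cohort is missing required columns: {missing}")


def apply_eligibility(
    cohort: pd.DataFrame, criteria: EligibilityCriteria | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter to the target population; returns (cohort, flow report).

    Rules are applied in order and the report attributes removals to the
    first rule a row fails, mirroring a study flow diagram.  The
    surviving set does not depend on rule order (conjunction).
    """
    if criteria is None:
        criteria = EligibilityCriteria()
    report_rows = []
    current = cohort
    for name, rule in criteria.rules():
        try:
            keep = rule(current)
        except KeyError as exc:
            raise CohortSchemaError(
                f"eligibility rule {name!r} references a missing column: {exc}"
            ) from exc
        keep = keep.fillna(False).astype(bool)
        report_rows.append({"rule": name, "removed": int((~keep).sum())})
        current = current.loc[keep]
    report = pd.DataFrame(report_rows, columns=["rule", "removed"])
    return current.copy(), report


def split_rct_eligibility(
    cohort: pd.DataFrame, criteria: EligibilityCriteria | None = None
) -> pd.DataFrame:
    """Label rows as benchmark-trial eligible without dropping any.

    Adds ``rct_eligible`` with values 1 (eligible: age and baseline HbA1c
    inside the trial's inclusion ranges, bounds inclusive), 0 (ineligible)
    and -1 (indeterminate: age or HbA1c missing; such rows belong to
    neither stratum).
    """
    if criteria is None:
        criteria = EligibilityCriteria()
    _check_columns(cohort, ["age", "hba1c"])
    out = cohort.copy()
    age, hb = out["age"], out["hba1c"]
    lo_a, hi_a = criteria.rct_age_range
    lo_h, hi_h = criteria.rct_hba1c_range
    eligible = (age >= lo_a) & (age <= hi_a) & (hb >= lo_h) & (hb <= hi_h)
    flag = np.where(eligible, 1, 0)
    indeterminate = age.isna() | hb.isna()
    flag = np.where(indeterminate, -1, flag)
    out["rct_eligible"] = flag.astype(np.int64)
    n_ind = int(indeterminate.sum())
    if n_ind:
        import warnings

        warnings.warn(
            f"{n_ind} rows have missing age or baseline HbA1c and are excluded "
            "from both benchmark-eligibility strata",
            stacklevel=2,
        )
    return out


@dataclass
class SubgroupScheme:
    """Pre-specified subgroup bands for conditional effects.

    Continuous bands are half-open (lower bound inclusive, upper bound
    exclusive) except the terminal bands, matching the protocol's
    "44 to <64" style definitions and WHO BMI classes.
    """

    age_edges: tuple = (50.0, 60.0, 70.0, 79.0)
    age_labels: tuple = ("Younger than 50", "50-59", "60-69", "70-78", "79 or older")
    hba1c_edges: tuple = (44.0, 64.0, 75.0, 88.0)
    hba1c_labels: tuple = ("<44", "44-<64", "64-<75", "75-<88", ">=88")
    bmi_min: float = 15.0
    bmi_edges: tuple = (25.0, 30.0, 35.0)
    bmi_labels: tuple = (
        "Under/normal weight (15-24.9)",
        "Overweight (25-29.9)",
        "Obese class 1 (30-34.9)",
        "Obese class 2 & 3 (35+)",
    )
    ethnicity_levels: tuple = ("white", "south_asian", "black_mixed_other")
    sex_labels: tuple = ("male", "female")

    def label_columns(self) -> list[str]:
        return ["age_band", "hba1c_band", "bmi_band", "ethnicity_band", "sex_band"]

    def levels(self, column: str) -> tuple:
        return {
            "age_band": self.age_labels,
            "hba1c_band": self.hba1c_labels,
            "bmi_band": self.bmi_labels + (OUT_OF_RANGE,),
            "ethnicity_band": self.ethnicity_levels + (OUT_OF_RANGE,),
            "sex_band": self.sex_labels,
        }[column]


def _band(values: pd.Series, edges, labels, lower_bound=None) -> np.ndarray:
    """Half-open banding with open-ended terminal bands; values below an
    explicit lower bound get the out-of-range label."""
    idx = np.searchsorted(np.asarray(edges), values.to_numpy(), side="right")
    out = np.asarray(labels, dtype=object)[idx]
    if lower_bound is not None:
        out = np.where(values.to_numpy() < lower_bound, OUT_OF_RANGE, out)
    out = np.where(values.isna().to_numpy(), OUT_OF_RANGE, out)
    return out


def assign_subgroups(cohort: pd.DataFrame, scheme: SubgroupScheme | None = None) -> pd.DataFrame:
    """Attach one label column per subgroup scheme.

    Every non-missing value maps to exactly one band; values outside all
    bands (e.g. BMI below 15) receive an explicit out-of-range label.
    """
    if scheme is None:
        scheme = SubgroupScheme()
    _check_columns(cohort, ["age", "hba1c", "bmi", "ethnicity", "female"])
    out = cohort.copy()
    out["age_band"] = _band(out["age"], scheme.age_edges, scheme.age_labels)
    out["hba1c_band"] = _band(out["hba1c"], scheme.hba1c_edges, scheme.hba1c_labels)
    out["bmi_band"] = _band(out["bmi"], scheme.bmi_edges, scheme.bmi_labels, scheme.bmi_min)
    eth = out["ethnicity"].to_numpy(dtype=object)
    known = np.isin(eth, scheme.ethnicity_levels)
    out["ethnicity_band"] = np.where(known, eth, OUT_OF_RANGE)
    out["sex_band"] = np.where(out["female"].to_numpy() == 1, "female", "male")
    return out


def complete_case_filter(
    cohort: pd.DataFrame,
    followup_anchor_days: int = 364,
    followup_tolerance_days: int = 90,
    covariates: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcome windowing plus complete-case restriction.

    The follow-up HbA1c is valid only if measured within the tolerance of
    day ``followup_anchor_days`` after day zero; otherwise the outcome is
    set missing.  Rows missing the outcome or any model covariate are
    dropped.  Returns (analysis cohort, per-column missingness report).
    """
    if covariates is None:
        covariates = MODEL_COVARIATES
    _check_columns(cohort, ["index_date", "followup_date", "followup_hba1c", "hba1c", "Y"])
    out = cohort.copy()
    target = out["index_date"] + pd.to_timedelta(followup_anchor_days, unit="D")
    off_window = (out["followup_date"] - target).dt.days.abs() > followup_tolerance_days
    off_window = off_window.fillna(True)
    out.loc[off_window, ["followup_hba1c", "followup_date", "Y"]] = [np.nan, pd.NaT, np.nan]
    out["Y"] = out["followup_hba1c"] - out["hba1c"]

    checked = ["Y"] + list(covariates)
    miss = out[checked].isna()
    report = pd.DataFrame(
        {"column": checked, "n_missing": miss.sum().to_numpy(), "n_total": len(out)}
    )
    keep = ~miss.any(axis=1)
    if not keep.any():
        import warnings

        warnings.warn("complete-case filter removed every row", stacklevel=2)
    return out.loc[keep].copy(), report


def population_masks(cohort: pd.DataFrame) -> dict[str, pd.Series]:
    """Standard analysis populations: the whole target population and the
    benchmark-trial eligible / ineligible subpopulations."""
    if "rct_eligible" not in cohort.columns:
        cohort = split_rct_eligibility(cohort)
    return {
        "target": pd.Series(True, index=cohort.index),
        "rct_eligible": cohort["rct_eligible"] == 1,
        "rct_ineligible": cohort["rct_eligible"] == 0,
    }
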