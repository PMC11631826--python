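"""Construct the emulated-trial analysis cohort: eligibility, outcome
window, complete cases, subgroups and the benchmark-trial split."""

from petliv import (
    DGPConfig,
    apply_eligibility,
    assign_subgroups,
    complete_case_filter,
    generate_cohort,
    split_rct_eligibility,
)

raw = generate_cohort(DGPConfig(n_patients=8000, n_clusters=80, n_regions=8, seed=2)).cohort

eligible, flow = apply_eligibility(raw)
print("eligibility flow (rows removed per rule, in order):")
print(flow.to_string(index=False))

analysis, miss = complete_case_filter(eligible)
print(f"\ncomplete cases: {len(analysis)} of {len(eligible)} eligible "
      "(outcome must fall within +/-90 days of week 52)")

analysis = assign_subgroups(split_rct_eligibility(analysis))
n_el = (analysis.rct_eligible == 1).sum()
print(f"benchmark-trial eligible (age 18-78, HbA1c 44-87): {n_el} "
      f"({n_el / len(analysis):.0%}); the rest form the trial-ineligible stratum")

print("\npatients per baseline-HbA1c band:")
print(analysis.hba1c_band.value_counts().to_string())
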