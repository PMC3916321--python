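"""Demographic comparison table for a simulated case-control cohort.

Generates the metadata table of a 20+20 cohort (15:5 male:female per group,
a few smokers, dialysis duration for inpatient cases only) and runs the
standard univariate group tests: two-sample t for continuous variables,
Pearson chi-square for sex composition.
"""

from rehokit import SimConfig, demographics_table, generate_cohort, pearson_corr

config = SimConfig(grid_shape=(8, 8, 8), n_volumes=20, n_per_group=20,
                   roi_specs=[], seed=12)
meta = generate_cohort(config).metadata

table = demographics_table(meta)
print(table.to_string(index=False))

patients = meta[meta.group == "patient"].dropna(subset=["dialysis_months"])
r, p = pearson_corr(patients["dialysis_months"].to_numpy(),
                    patients["mmse"].to_numpy())
print(f"\ndialysis duration vs MMSE (patients, n={len(patients)}): r = {r:.3f}, p = {p:.3f}")
print(
    "\nWith the 15:5 sex ratio fixed in both groups the chi-square is exactly 0;"
    "\nthe continuous tests should all be non-significant because both groups"
    "\nare drawn from nearly identical distributions."
)
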