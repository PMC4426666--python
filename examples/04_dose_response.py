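"""Dose-response analysis of glucagon-family peptides.

Simulates the packaged slice cohort design (doses 0.5-450 nM, n = 5 per
dose, treatments on the descending phase at 180-200 deg) for an active
peptide (GCG) and an inactive one (GLP-1), then builds the dose-response
table: mean shift +/- SEM per dose, one-way ANOVA across groups, and
Bonferroni-adjusted comparisons against the PBS vehicle.
"""

from circaluc import dose_response, estimate_cohort_shifts
from circaluc.synthetic import generate_cohort, packaged_cohort_spec

spec = packaged_cohort_spec(("GCG", "GLP-1"), seed=3)
estimates = estimate_cohort_shifts(generate_cohort(spec))
table = dose_response(estimates, vehicle_label="PBS")

cols = ["peptide", "dose_nM", "mean_shift_h", "sem_h", "n", "stars"]
print(table.table[cols].round(2).to_string(index=False))
for pep, a in table.anova.items():
    print(f"{pep}: one-way ANOVA F{a['df']} = {a['F']:.2f}, p = {a['p']:.2g}")
# GCG delays the clock by ~3 h, but only at the highest doses (its EC50 is
# ~60 nM); GLP-1 has a null phase-response, so no dose separates from PBS.
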