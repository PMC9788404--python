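"""Kaplan-Meier stratification of a simulated cohort by immunophenotype.

Simulates 300 patients (per-subtype exponential hazards, uniform censoring),
groups them by the two-marker call on the primary lesion, and compares
progression-free survival with the log-rank test.
"""

from ihcsubtype import (
    SyntheticCohortConfig,
    assemble_survival,
    classify_cohort,
    km_by_group,
    logrank_test,
    simulate_cohort,
)

sim = simulate_cohort(SyntheticCohortConfig(n_patients=300, seed=4))
calls, _ = classify_cohort(sim.ihc_records)
dataset = assemble_survival(
    sim.clinical_records, calls=calls, endpoint="pfs", grouping="two_marker"
)

for curve in km_by_group(dataset):
    median = next(
        (t for t, s in zip(curve.times, curve.survival) if s <= 0.5), float("nan")
    )
    print(
        f"{curve.group:12s} n={curve.n_subjects:3d} events={curve.n_events:3d} "
        f"median PFS ~ {median:5.1f} months"
    )

result = logrank_test(dataset)
print(f"\nlog-rank: chi2 = {result.statistic:.2f}, df = {result.df}, "
      f"p = {result.p_value:.2e}")
print("Basal tumors progress latest under the generator's hazard ordering "
      "(basal < mixed < luminal), and the log-rank test detects the split.")
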