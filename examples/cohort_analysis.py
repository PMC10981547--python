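"""Full cohort analysis on the bundled 18-patient example tables.

Computes every patient's sitting-vs-supine CIEDE2000 difference, classifies
it against the 4.1 acceptability threshold, summarizes the cohort, relates
the differences to biometric covariates, and cross-tabulates above-reference
laboratory flags by acceptability group.
"""

from tonguecolor import (
    association_table,
    compare_patient,
    count_flags_by_group,
    flag_above_reference,
    load_example_biometrics,
    load_example_lab_pairs,
    summarize_cohort,
)

pairs = load_example_lab_pairs()
records = load_example_biometrics()

comparisons = [compare_patient(sit, sup) for sit, sup in pairs]
summary = summarize_cohort(comparisons)
print(f"n = {summary.n} patients")
print(f"mean dE00   = {summary.mean_dE00:.2f}")
print(f"median dE00 = {summary.median_dE00:.2f}")
print(f"acceptable (< {summary.threshold_used}) = "
      f"{100 * summary.proportion_acceptable:.1f}%")
print("-> for ~4 in 5 patients, posture does not visibly change tongue color")

print("\nassociations with dE00 (r for numeric, eta^2 for categorical):")
de00 = {c.patient_id: c.result.dE00 for c in comparisons}
for a in association_table(de00, records):
    star = " *" if a.p_value < 0.05 else ""
    print(f"  {a.covariate:<8} {a.kind:<11} {a.value:+.2f}  p={a.p_value:.3f}{star}")

flags = {r.patient_id: len(flag_above_reference(r)) for r in records}
groups = count_flags_by_group(comparisons, flags)
acc, nacc = groups["acceptable"], groups["not_acceptable"]
print(f"\nlab values above reference criteria, by acceptability group:")
print(f"  dE00 < 4.1 : {acc['at_most_one_item']}/{acc['n']} patients "
      f"({acc['pct_at_most_one']:.1f}%) with <= 1 flagged item")
print(f"  dE00 >= 4.1: {nacc['at_least_two_items']}/{nacc['n']} patients "
      f"with >= 2 flagged items")
print("-> large positional color shifts cluster in patients with poorly")
print("   controlled blood pressure / glucose / lipids")
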