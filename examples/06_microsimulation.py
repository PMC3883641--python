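"""Paired baseline/taxed cohort microsimulation (reduced size).

Runs the 24-cohort design at 500 individuals per cohort with common random
numbers and prints the headline contrasts: relative reductions in
overweight/obesity prevalence and diabetes incidence in the final year,
overall and by population margin.
"""

from ssbtax.microsim import (build_cohorts, margin_reductions,
                             overall_outcomes, relative_reduction, run_paired)

cohorts = build_cohorts(500)
base, taxed = run_paired(cohorts, tax_rate=0.20, seed=1)

print("overall yearly outcomes (baseline):")
print(overall_outcomes(base).round(3).to_string())

ow = relative_reduction(base, taxed, "overweight_prevalence")
dm = relative_reduction(base, taxed, "diabetes_incidence")
print(f"\n20% tax, final-year relative reductions: "
      f"overweight {ow:.2f}%, diabetes incidence {dm:.2f}%")
print("\nby population margin (overweight %):")
print(margin_reductions(base, taxed).round(2).to_string())
# Younger, male and rural groups see the largest overweight reductions
# (their BMI distributions sit closer below the 25 kg/m^2 threshold);
# diabetes reductions track glycemic-load changes and baseline incidence.
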