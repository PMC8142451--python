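"""Apply the eligibility screen and classify outcomes.

Runs the exclusion flow chart on a generated cohort, classifies each
included spell as case or control at the 48-hour boundary, and prints
the attrition log, the HAI prevalence and the leading organisms.
"""

import numpy as np

from nosoflow import GeneratorConfig, generate_cohort, organism_table
from nosoflow.pipeline import build_cohort

patients, spells = generate_cohort(
    GeneratorConfig(n_spells=10_000, seed=42, beta_transfer=np.log(1.09))
)
cohort = build_cohort(patients, spells)

print(cohort.exclusion_log.to_frame().to_string(index=False))
records = cohort.records
prevalence = records["case"].mean()
print(f"\nincluded spells: {len(records)}  HAI prevalence: {prevalence:.1%}")
print(f"time-at-risk trim threshold: {cohort.trim_threshold:.1f} days (top 1%)")

cases = records.loc[records["case"] == 1, "organism"]
print("\nmost frequently isolated organisms among cases:")
print(organism_table(cases).head(5).round(2).to_string(index=False))
# Each spell is removed by the FIRST rule it fails, so the log rows sum
# to the total attrition; prevalence sits near the ~12% the generator
# is calibrated to.
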