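"""Re-run the analysis under the three alternative specifications.

Shifts the case index 12 and 24 hours earlier, swaps the surgical
exclusion to operative OPCS-4 codes, and restricts cases to sterile
isolation sites — printing the adjusted per-transfer OR of each.
"""

import numpy as np

from nosoflow import GeneratorConfig, SensitivitySpec, generate_cohort, run_sensitivity
from nosoflow.pipeline import run_analysis

patients, spells = generate_cohort(
    GeneratorConfig(n_spells=15_000, seed=3, beta_transfer=np.log(1.09))
)

primary = run_analysis(patients, spells)
row = primary.multivariable.term("n_transfers")
print(f"{'primary':>20}: OR {row.odds_ratio:.2f} ({row.ci_low:.2f}-{row.ci_high:.2f})")

for name in ("index_shift_12h", "index_shift_24h", "surgical_by_opcs", "sterile_sites_only"):
    result = run_sensitivity(SensitivitySpec(name), patients, spells)
    row = result.multivariable.term("n_transfers")
    print(f"{name:>20}: OR {row.odds_ratio:.2f} ({row.ci_low:.2f}-{row.ci_high:.2f}), "
          f"n={result.multivariable.n}")
# The generator has no reverse-causality mechanism (no isolation moves
# before sampling), so all specifications agree with the generating
# effect within Monte-Carlo error — shifting the index or narrowing the
# case definition changes n but not the estimand.
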