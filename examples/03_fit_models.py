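"""Fit the univariable and adjusted transfer-infection models.

Derives the index-censored covariates, screens candidate covariates
univariably, fits both logistic specifications and runs the
hospital-site clustering check.
"""

import numpy as np

from nosoflow import GeneratorConfig, generate_cohort, icc_site, screen_covariates
from nosoflow.pipeline import build_cohort, fit_multivariable, fit_univariable

patients, spells = generate_cohort(
    GeneratorConfig(n_spells=15_000, seed=3, beta_transfer=np.log(1.09))
)
records = build_cohort(patients, spells).records

kept = screen_covariates(
    records,
    ["n_transfers", "elix_band", "icu_before_index", "ethnicity", "weekend_admission", "gender"],
)
print(f"univariable screen retains: {kept}")

for label, result in (("univariable", fit_univariable(records)),
                      ("adjusted", fit_multivariable(records))):
    row = result.term("n_transfers")
    print(f"{label:>11} per-transfer OR {row.odds_ratio:.2f} "
          f"(95% CI {row.ci_low:.2f} to {row.ci_high:.2f}), n={result.n}")

icc = icc_site(records)
print(f"hospital-site ICC: {icc.icc:.4f} (between-site variance {icc.between_variance:.4f})")
# The adjusted OR estimates the generating effect (1.09); the ICC is
# near zero because the generator gives sites no infection effect, so
# treating spells as independent across sites is justified.
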