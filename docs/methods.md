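# Methods

This note records the modelling assumptions, the design of the
synthetic EHR generator, the numerical conventions, and the known
limitations of `nosoflow`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself
compute.

## The case–control design

The unit of analysis is the *hospital spell* — one continuous
admission, from (non-elective) admission to discharge or death.
Spells from the same patient are treated as independent observations;
the clustering check (`icc_site`) is provided to verify that
second-level heterogeneity is negligible, as is typical for
hospital-site clustering of infection outcomes.

All timestamps are fractional days on a single global clock. A spell
is a **case** when it carries at least one positive culture collected
at least 48 h (exactly 2.0 days; the boundary itself counts as
hospital-acquired) after admission; the **index time** is the first
positive collection for cases and the discharge/death time for
controls. Positive cultures inside the first 48 h mark
community-acquired infection and exclude the spell entirely.

Exposure must precede outcome, so every covariate is computed on the
history *strictly before* the index: a ward change, ICU entry or
episode start falling exactly on the index does not count.

### Covariates

* **Intrahospital transfers** (the exposure): changes of ward ID
  between consecutive ward stays before the index. Same-ward
  consecutive stays (bed moves, untimestamped in the source systems)
  contribute nothing; returns to a previously occupied ward count.
  The transfer from the emergency department to the first inpatient
  ward is not represented: the event stream begins at inpatient
  admission.
* **Elixhauser comorbidity count**: the number of distinct indicator
  groups (0–31) among the ICD-10 codes of consultant episodes that
  *began* before the index. The shipped map keys each group to its
  standard ICD-10 prefixes; codes are matched by longest prefix.
* **Procedures**: OPCS-4 codes are aggregated per consultant episode
  without their own timestamps. Episodes that ended on or before the
  index contribute their full count; the episode containing the index
  contributes `count × (index − start)/(end − start)`, i.e. procedures
  are assumed evenly spread over the episode. At the control limit
  (index = discharge) this reduces to the plain sum.
* **Dominant TFC**: the treatment function code (specialty) under
  which the patient spent the longest pre-index duration, episodes
  truncated at the index; exact ties go to the earlier specialty.
* **Banding**: age {65–70, 71–75, 76–80, 81–85, 86+} (inclusive
  integer bands); time at risk [2,5), [5,7), [7,10), [10,15), [15,20),
  [20,30), [30,40), [40,∞) days; Elixhauser {0, 1–3, 4–6, 7–9, 10+};
  procedures, floored when fractional, {0, 1, 2–8, 9–13, 14+}. Band
  labels that overlap at their edges are resolved as left-closed,
  right-open intervals.

### Eligibility screen

Rules run in a fixed order (non-elective → age ≥ 65 → duration ≥ 48 h
→ non-surgical TFC → no infection in the first 48 h → internally
consistent timestamps → complete model fields); each spell is
attributed to the first rule it fails, which produces the familiar
flow-chart attrition log. "At least 48 hours" is inclusive
(duration ≥ 2.0 days); "infection in the first 48 hours" is strict
(collection < 2.0 days after admission). The surgical-specialty list
is configurable; the default is the generator's four surgical TFCs.
Records with time at risk strictly above the empirical 99th percentile
(linear-interpolation order statistic) are trimmed; a fixed absolute
threshold may be supplied instead. Missing microbiology means
control; records missing a model field are dropped and logged.

### Inference

`fit_logistic` is a thin, validated layer over maximum-likelihood
logistic regression (statsmodels): categoricals are dummy-coded
against their first level, Wald 95% CIs use z = 1.959964, and perfect
or quasi-perfect separation raises an error naming the offending
term(s) rather than returning a non-identified fit. The univariable
screen retains candidates whose likelihood-ratio p-value falls below
α = 0.05, with gender kept a priori. Case/control comparisons of
banded covariates use the Pearson chi-square without continuity
correction.

The clustering check fits a random-intercept logistic model by
Gauss–Hermite quadrature maximum likelihood (21 nodes; the variance
parameter is optimised on the log-sd scale, bounded in
[e⁻¹⁶, e⁶]) and reports the latent-threshold intraclass correlation
ICC = σ²/(σ² + π²/3).

### Sensitivity analyses

1. **Index shift (12/24 h)**: case index times move earlier by the
   shift; cases whose new time at risk falls under 48 h leave the
   analysis; controls are untouched. By default all covariates are
   re-censored at the shifted index (a flag restricts the shift to the
   time-at-risk value only).
2. **Surgical exclusion by OPCS-4**: spells carrying a listed
   operative code before the index are removed instead of excluding by
   specialty. Codes inherit implied timestamps evenly spread over
   their episode, consistent with the interpolation assumption. The
   default code list matches the generator's surgical codes and is a
   placeholder — supply the locally appropriate list for real data.
3. **Sterile sites only**: cases whose isolate is not from blood or
   urine are removed (default) or, optionally, demoted to controls
   with covariates re-censored at discharge.

## The synthetic EHR generator

The generator emulates the *marginal* structure of an elderly,
non-elective, medical inpatient population in a three-site urban
network, with a known causal transfer effect:

| quantity | default | calibration target |
| --- | --- | --- |
| transfer count mixture (0/1/2/3+) | 0.278/0.442/0.171/0.110 (renormalised) | printed transfer marginals |
| length of stay | 2 + LogNormal(ln 4.3, 1.2) d | median 6.3 d, IQR ≈ 3.6–11.7 d |
| baseline hazard | 0.0145 /day | ≈ 12% HAI prevalence among included spells |
| Elixhauser count | Binomial(31, 3.54/31) | mean 3.54, SD ≈ 1.9 |
| ICU attendance | 2.5% | printed ICU share |
| hospital site mixture | 0.318/0.509/0.173 | printed site case-mix |
| TFC mixture | 6 majors at printed shares, 10 minors uniform | printed specialty case-mix |
| organism mixture | nine named pathogens at printed shares + pooled remainder | printed pathogen table |
| sterile-site fraction | 0.55 | — (unreported; chosen once) |
| decoy fraction | 20% | exercisable exclusions |

Infection is drawn day by day over the at-risk window (48 h after
admission to discharge): for each risk day a candidate collection
time is drawn uniformly within the day and infection fires with
probability

```
expit( logit(h₀) + β_t · transfers_before(s)
       + 0.13 · (elixhauser − 3.54) + 1.2 · icu_before(s)
       + 0.008 · (age − 79) )
```

The first success places the positive sample at `s`; the covariates
entering each day's hazard are evaluated on the history strictly
before that day's candidate time, so the chronology the analysis
assumes holds by construction. Covariate effects are present in the
hazard but the covariates themselves are drawn independently of the
transfer process, so the generator contains no confounding of the
exposure by default — adjusted and unadjusted estimates coincide up
to non-collapsibility.

**Transfer timing.** Ward-move offsets are exponential with mean
0.75 days, truncated at discharge: non-elective admissions move from
assessment units to their destination ward within the first day or
two, so most transfers precede the 48-hour at-risk boundary. This is
also what makes the spell-level logistic analysis an (almost) correctly
specified model for the day-level generating hazard: the pre-index
transfer count recorded for a case equals the covariate that fired its
hazard, and a control's full-spell count almost always equals its
count on every at-risk day. Were transfers spread uniformly over the
spell with a total count independent of stay length, cases (censored
at infection) would mechanically record a fraction of their transfers
while controls record all of them, and the fitted effect would be
severely biased — a design artefact, not an estimator defect. The
residual mismatch (the ~7% of transfer mass beyond 48 h) attenuates
the fitted log-odds multiplicatively by roughly 10–15%; at the
calibrated effect size (OR 1.09 per transfer) this is within ±0.02 on
the log scale, which the 50-replicate recovery test measures directly.

**Decoys.** A configurable 20% of spells deliberately fail exactly one
eligibility rule (elective, under-65, under-48-h, surgical specialty,
infected within 48 h) so the exclusion logic is testable on generated
data. Comorbidity codes are the canonical representative code of each
sampled indicator group, placed in the first episode, making the
Elixhauser count exactly invertible in tests.

What the generator does **not** emulate: ward-network topology, staff
movement and staffing levels, antibiotic or device exposure,
coinfections (one organism per sample), seasonal admission pressure,
reverse causality (isolation moves triggered by suspected infection),
stay-prolonging effects of infection, and confounding between
transfers and the other covariates. Passing recovery tests therefore
show that the *pipeline* estimates a known effect without bias under
the design's own assumptions — not that those assumptions hold in any
real hospital.

## Numerical conventions and degenerate inputs

* Interval logic is half-open `[start, end)`; tiling is checked to
  1e-9 days.
* Ties: equal earliest positive collections keep file order (with a
  warning); equal dominant-TFC durations keep the earlier specialty.
* The timing validator never raises; it returns inconsistency codes.
* Zero-length episodes, single-level model terms, single-class
  outcomes, unknown specimen sites, empty case sets and single-cluster
  ICC requests raise explicit errors.
* CSV round trips write floats as `%.17g` and parse with
  `float_precision="round_trip"`, so the object graph survives
  serialisation bit-exactly; identical (config, seed) pairs produce
  identical bytes.

## Problem sizes used in the checks

Recovery and null-safety checks run the full pipeline at 25 000 spells
per replicate — 50 replicates for bias/coverage of the recovery
estimator, 100 for null safety — chosen so that every covariate band
retains both cases and controls in every replicate and the Monte-Carlo
error of the mean log-odds is well below the ±0.02 bias criterion.
The library-level fixture cohort uses 12 000 spells with a stronger
generating effect (OR 1.2) for the same reason at smaller scale.

## Known limitations

* The spell-level logistic model is an approximation to the day-level
  hazard; the measured attenuation grows with the generating effect
  size (noticeable above OR ≈ 1.3 per transfer) and with the share of
  transfer mass falling inside the at-risk window.
* The Elixhauser prefix map is a compact rendition of the standard
  ICD-10 coding, not an exhaustive one; for production use against
  real coded data, review the prefix lists.
* The surgical TFC and surgical OPCS-4 default lists are placeholders
  aligned with the generator; faithful replication on real data
  requires the locally governed lists.
* `icc_site` with very few clusters (e.g. three hospital sites)
  estimates the between-cluster variance with little information;
  treat the ICC as a diagnostic, not an estimate with useful
  uncertainty.
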