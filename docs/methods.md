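# Methods

## Scoring model

AGILE is an unweighted deficit count over ten binary items in four
domains.  All arithmetic is exact integer arithmetic; the only derived
item is grip strength, where the deficit criterion is the mean of three
dynamometer readings at or below 30 kg for men and 20 kg for women.
Both thresholds are inclusive ("≤"), which matters in practice because
integer-kg readings put many subjects exactly on the boundary.

The IFi sums 38 generic deficits in {0, 0.5, 1} and two banded
instrument totals.  Two textual ambiguities in the band definitions are
resolved as follows:

- the MNA band "24 → 0" is read as *MNA ≥ 24 → 0*, since MNA totals
  reach 30 and any other reading leaves (24, 30] unmapped;
- the IFi tertile boundaries overlap at 27.0 in their printed form;
  the bands are implemented half-open below, with 27.0 assigned to the
  moderate band: light [0, 16], moderate (16, 27], severe (27, 40].

AGILE stratification defaults to the tertile scheme (light 0–3,
moderate 4–7, severe 8–10) used for every stratified analysis; the
four-level variant (not-frail = 0) is available by configuration.
Missing AGILE items are rejected, not imputed: no imputation rule is
part of the instrument definition, so completeness is enforced at
validation and scoring time.

`select_items` reconstructs the screener-derivation procedure as a
per-domain ranking: given per-item mortality risk ratios and domain
quotas (3 physical, 3 mental, 2 nutritional, 2 socio-economic), it keeps
the quota-many largest-RR items per domain, breaking ties on the
lexicographically smaller item id so the selection is deterministic.
Whether the original derivation used univariate or adjusted RRs is not
determinable; the operation is agnostic — it consumes whatever effect
estimates it is given.

## Synthetic-cohort generator

The generator emulates the structure an instrument-validation analysis
assumes, not any particular patient population:

- **Demographics.** Age ~ Normal(77, 7²) truncated at 65; sex female
  with probability 0.555.
- **Latent trait.** z = λ·s(age) + ε with s the standardized truncated
  age, ε ~ N(0, 1), and λ = 0.6 by default.  λ was chosen once so that
  the age gradient across strata spans roughly 74 → 80 years, the
  pattern a frailty instrument should show; it is exposed in the config.
- **Items.** Item j is Bernoulli(logistic(αⱼ + βⱼ z)).  The common
  discrimination β = 1.5 is a design default: marginal prevalences
  identify only αⱼ, and β controls how strongly items co-vary through
  the latent trait (and hence Cronbach's alpha and the score's spread).
  αⱼ is calibrated by Brent root-finding on the *population* expectation,
  computed by quadrature (201 equal-mass age nodes × 41 Gauss–Hermite
  noise nodes), so calibration is deterministic and seeds affect only
  sampling noise.  Target prevalences exactly 0 or 1 are honoured as
  deterministic constant items.  Default item targets are the screener's
  overall deficit prevalences (e.g. help up/down stairs 51.8 %).
- **Grip readings.** Three readings per subject are drawn consistent
  with the grip item: the target mean is uniform on the deficit or
  non-deficit side of the sex threshold, and per-reading noise is
  centred so re-deriving the deficit from the readings reproduces the
  item exactly.
- **IFi inputs.** Each generic item is the mean of two latent-linked
  Bernoulli halves (values in {0, 0.5, 1}) with expected score 0.5;
  SSS and MNA totals are linear in z with rounding and range clipping.
  This yields an IFi distribution (mean ≈ 20, SD ≈ 9) comparable to a
  mixed ambulatory cohort and strongly correlated with AGILE through z.
- **Outcomes.** Two modes.  *stratum_conditional* (default): each
  outcome is Bernoulli with a per-stratum probability; the light/severe
  endpoints default to mortality 6.5/41.8 %, disability 16.1/64.2 %,
  hospitalization 17.2/58.7 %, and the unprinted moderate value is the
  log-odds midpoint (configurable).  *per_unit_logistic*:
  logit P = γ₀ + log(OR)·score with OR defaults 1.56/1.44/1.24 per
  AGILE point (an IFi-driven variant exists); γ₀ is calibrated on the
  realized scores to the stratum-implied marginal prevalence.  The true
  slope equals log(OR) exactly and the generating model has zero age and
  sex effects, so an age/sex-adjusted logistic fit estimates the same
  conditional OR — this is what makes the parameter-recovery and CI
  coverage experiments clean.  Outcomes are non-exclusive (a decedent
  may also count as disabled/hospitalized) and are drawn independently
  given the score; no competing-risk structure is modelled.
- **Disability bookkeeping.** Baseline BADL lost is Normal per stratum
  (means 0.5/2.2/3.8), rounded and clipped to [0, 5] so an increase is
  always representable; subjects drawn as incident-disabled gain a
  uniform 1..(6−baseline) activities at follow-up, others keep their
  baseline (no recovery model).
- **Attrition.** Independent Bernoulli dropout at 16.8 % by default; a
  frailty-dependence knob exists but defaults to 0 (no differential
  dropout is assumed).
- **Paired raters.** Rater B flips each of rater A's item codes
  independently with probability f.  The population kappa of this model
  on pooled item codes is closed-form (observed agreement 1−f, chance
  agreement from the pooled marginals), so the f achieving a target
  kappa (e.g. 0.86) is found by bisection, and simulation only verifies
  the Monte-Carlo agreement.

What the generator does *not* emulate: the real joint dependence of
items beyond a single latent trait, informative dropout, competing
risks, measurement drift between raters beyond symmetric flips, and the
full geriatric-assessment battery.  Tests passing on this generator
demonstrate that the arithmetic, calibration and estimation machinery
are correct under the stated model — not that the instrument has any
particular operating characteristics in real populations.

## Validation statistics

- **Cohen's kappa** uses product-marginal chance agreement and the
  Fleiss large-sample null variance for its p-value.  Identical constant
  raters return kappa 1 with a degenerate-marginals warning rather than
  0/0.
- **Cronbach's alpha** uses the sample (ddof = 1) variance convention
  for items and total alike, declared in the result metadata.
- **Lin's CCC** uses biased (1/n) moment estimators, the standard
  plug-in form.  The pipeline compares AGILE with IFi rescaled to the
  0–10 range (and reports the raw-scale value too), since raw-scale CCC
  mostly measures the 4× scale difference.
- **CCC sample size** is the one-sided Fisher-z formula
  n = ((z₁₋α + z_power)/Δ)² + 3 with Δ the Fisher-scale CCC difference.
  For 0.75 → 0.80 at α = 0.05, power 0.90 it returns 546.  The method
  string in the result documents the variant so any differing published
  figure can be traced to its (often unstated) formula.
- **Outcome models** are logistic ML fits, outcome ~ predictor + age +
  female, with Wald 95 % CIs and p-values (the printed
  symmetric-on-log-scale intervals of validation reports imply Wald, not
  profile, intervals).  The exponentiated coefficient is an odds ratio;
  the output field is named `rr` to match the reporting convention of
  clinical validation papers, with the OR interpretation documented.
  Perfect separation raises an explicit error, as does non-convergence
  after 200 iterations.
- **ROC/AUC** enumerates all distinct score thresholds and integrates
  by trapezoid; with heavily tied integer scores this is identically the
  tie-corrected rank formulation (concordant + ½·tied)/(n₁n₀), an
  equivalence the test suite checks exhaustively on small inputs and
  property-checks against an independent pair-counting oracle and
  scikit-learn.
- **Stratified tables** render "percent (count)" to one decimal,
  rounding half away from zero (207/400 = 51.75 → "51.8"); continuous
  rows get one-way ANOVA p (optional Bonferroni-corrected pairwise
  Welch tests), binary rows get the Cochran–Armitage chi-square for
  trend across ordered strata with integer scores.

## Problem sizes and tolerances

Calibration checks run on a 100,000-subject cohort: empirical item
prevalences and stratum-endpoint outcome prevalences are required to sit
within 3 Monte-Carlo standard errors of their configured targets, and
the completion fraction within 0.5 percentage points of 83.2 %.
Parameter recovery uses n = 20,000 (point estimate within 5 % of the
generating OR) and 200 replicates of n = 5,000 for 95 % Wald-CI coverage
(accepted band 93–97 %).  The rater simulation uses 10,000 paired item
ratings (kappa within ±0.02 of target).  Exhaustive oracle equivalences
cover all 1,024 screener response patterns and all small ROC
configurations up to n = 8.  Numerical root-finding uses Brent's method
with xtol 1e-12 on intercepts bracketed in [−60, 60].

## Known limitations

The 38 generic IFi items are anonymous coded deficits — the package
does not claim to reproduce the identities or effect sizes of the
non-screener items, and accepts any labelled 38-item list.  Cohort-
specific estimates from any particular study (per-item RRs, exact AUCs)
are functions of the unavailable original data; the package reproduces
the methodology and the calibrated generator's own endpoints instead.
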