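# Methods

## The protocol as a rule engine

The department protocol is encoded as a declarative rule set
(`rulesets/department.yaml`): a list of named factors, each with a point
weight (1, or 2 for BMI ≥ 30 kg/m²), a predicate over raw patient fields, and
a scoring stage. Scoring is two-staged by design:

* **Pre-operative score** — everything known before the cesarean. It alone
  decides intraoperative mechanical prophylaxis (pneumatic cuff at score
  ≥ 2): a patient whose score reaches 2 only through postpartum blood loss
  was not cuffed in theatre, and the engine never attributes one
  retroactively.
* **Final score** — pre-operative score plus the postpartum markup (+1 for
  PPH ≥ 1000 mL or transfusion). It decides postnatal pharmacologic
  prophylaxis (final score ≥ 3 → at least 10 days of enoxaparin, 40 mg daily
  below 100 kg booking weight, 60 mg at or above).

Patients on antenatal LMWH (prior VTE, high-risk thrombophilia) are excluded
from scoring entirely; they continue LMWH with a cuff during CS and are
reported separately in all cohort summaries.

Cutoff conventions where the source material is ambiguous, both configurable
in the rule set: preterm is **strictly < 34 completed weeks** (consistent
with worked cases delivering at 31 and 33 weeks scoring the preterm point),
and the PPH markup threshold is **inclusive ≥ 1000 mL** (a worked case with
exactly 1000 mL blood loss carries the markup point). "Medical comorbidities"
is a single boolean — its published examples (cancer, heart failure, active
SLE, …) are documentation, and multiple comorbidities still contribute one
point. Missing optional booleans in input CSVs default to false with a logged
warning; missing age/BMI/weight/parity/gestational-age/urgency are hard
errors — clinical-style data should fail loudly.

### Worked-example fixture

`data/published_vte_cases.csv` reconstructs the 16 published postpartum VTE
case profiles (11 preprotocol, 5 protocol period) from their tabulated factor
annotations; unstated covariates (booking weight, term gestational age) are
synthetic fill-ins chosen so the factor list is unchanged. Two published
inconsistencies are recorded rather than reconciled:

* Protocol-period case 5 prints "score = 1" while its own factor annotation
  (age 40, BMI 28) implies 2 — and the narrative says the patient received an
  intraoperative cuff, which the protocol reserves for score ≥ 2. The fixture
  keeps the printed scalar in a `printed_score` column and tests against the
  factor-list-derived score of 2.
* The published whole-cohort screening metrics imply 9 events at score ≥ 3,
  while the case table lists 8; the fixture asserts 8.

## Guideline comparators

The RCOG/ACCP/ACOG comparators share one declarative schema: a mechanical
policy (universal for all three, since each recommends pneumatic compression
for every CS in the comparison) and a disjunctive pharmacologic trigger over
major/minor factor lists (≥ 1 major; ≥ k minors; ≥ k minors plus emergency
CS; emergency CS alone). The published recoding did not enumerate the exact
factor lists applied, so the bundled presets are documented approximations —
RCOG-style cutoffs (age ≥ 35, BMI ≥ 30, preterm < 37 weeks) for the RCOG
list, and an ACCP major/minor split with thrombophilia, immobility,
comorbidity, systemic infection and major hemorrhage/transfusion as majors.
Consequently the hypothetical rates (78.9% RCOG, 27.1% ACCP in the protocol
cohort) are treated as orderings and plausibility bands, never as exact
targets: on any default synthetic cohort the package asserts
RCOG ≥ ACCP ≥ ACOG pharmacologic rates, with the department protocol below
ACCP.

## Synthetic cohorts

The generator emulates the study cohorts' statistical structure, not their
patients:

* Each risk factor is an **independent Bernoulli** at the observed prevalence
  (protocol-period defaults, e.g. age ≥ 40 at 11.2%, BMI bands at 13%/4.97%,
  emergency CS at 58.6%, major PPH/transfusion at 6.05%; a preprotocol set is
  bundled). Independence is an assumption — only marginals are published. Its
  adequacy for testing is checked, not presumed: the independence model's
  mean score (≈ 0.62) and pharmacologic rate (≈ 2.7%, vs 3.25% observed) sit
  close to the observed score distribution.
* Continuous covariates are sampled **uniformly within the band** implied by
  each flag (age 40–45 vs 20–39; BMI 25–30 vs 30–42 vs 18.5–25; gestational
  age 26–34 vs 37–42; PPH 1000–3000 mL vs 100–900 mL). Within-band shape is
  unidentified from the published marginals and the uniforms exist only to
  exercise cutoff logic — no within-band inference should be read into them.
* **VTE events** are Bernoulli with probability set by the final-score
  stratum (1/4064 below 2, 1/583 at 2, 3/156 at ≥ 3), multiplied by
  `treatment_effect_rr` for patients the protocol treats pharmacologically
  (default 1.0 = no modelled effect, so stratum incidences are recovered
  as-is). **Bleeding complications** are Bernoulli at a score-independent
  rate (0.76% protocol / 0.96% preprotocol defaults); no causal LMWH-bleeding
  link is modelled, since none was observed.
* All randomness flows from one named seed through a single
  `numpy.random.Generator`; identical parameters give byte-identical CSVs.

What passing tests on these cohorts therefore show: the engine, comparators
and evaluation pipeline are internally correct under the stated marginal
structure. What they do not show: anything about factor correlations,
within-band covariate distributions, or real-world protocol effectiveness.

The exact score distribution is the weighted Poisson-binomial of the factor
indicators (fourteen weight-1 Bernoullis, a three-valued BMI component, a
weight-1 markup), computed by sequential convolution and renormalized before
the 1e-12 sum-to-one check; it is verified against brute-force enumeration
over all factor combinations and against Monte-Carlo draws at n = 10⁶
(3-standard-error agreement).

## Statistical conventions

* **Incidence CIs and screening-metric CIs** are Clopper–Pearson (exact
  binomial tail inversion, via `statsmodels`' beta method). The choice is
  fixed as the default because it reproduces the published sensitivity
  interval for 5/11 events, 16.7–76.6% (Wilson does not); the bounds are
  tested against their defining tail equations to 1e-10.
* **Two-proportion comparison**: continuity-corrected (Yates) chi-squared by
  default for adequately sized tables; Fisher's exact test when any expected
  cell is below 5 (`method="auto"`), with the selection logged. The Yates
  test reproduces the published p = .043 for 11/3309 vs 5/4803
  (continuity-corrected z ≈ 2.02). Fisher's two-sided p-value sums all
  conditional outcomes whose point probability does not exceed the observed
  table's — the common convention; the doubling alternative is not offered.
  Degenerate margins yield p = 1 with a warning rather than an exception.
* **Screening evaluation** treats final score ≥ 3 ("screen positive") against
  observed postpartum VTE ("disease"). Undefined ratios (e.g. sensitivity
  with zero events) are explicit NaN-with-flag, never silent zeros. The
  published specificity (97.1%) and accuracy (97%) are internally
  inconsistent with the reconstructable 2×2 (which gives 97.0%/96.8%) and
  are not asserted anywhere.
* **NNS/NNT**: NNS = 1/ARR; NNT = NNS × treated fraction. With the observed
  ARR ≈ 0.002 and treated fractions 3–5%, NNS ≈ 500 and NNT 15–25.
* **Rounding** of reported percentages is round-half-up at the printed number
  of decimals (`round_half_up`); machine outputs always carry unrounded
  values.

## Numerical and test-design choices

* The pipeline-closure check (null p-values uniform, KS test on 200
  simulated pre/post pairs at α = 0.01) runs at event risk 0.10 and n = 2000
  per arm. At rare-event risks (~0.2%) no two-proportion test has a uniform
  null — the Yates statistic is discrete and deliberately conservative at ~10
  events — so uniformity is checked in the asymptotic regime where the claim
  holds.
* Monte-Carlo test sizes: 10⁶ draws for the acceptance-level distribution and
  parameter-recovery checks, 1–3 × 10⁵ for the unit-level versions; all
  sampling checks use 3 binomial standard errors around the target.
* Fisher's test is checked against exhaustive hypergeometric enumeration for
  every non-degenerate 2×2 table with N ≤ 30, enumerating by margins (the
  p-value depends only on the margins and one cell).

## Known limitations

* Factor independence in the generator; no correlation hook is wired into the
  default path.
* The comparator factor lists are approximations (see above); comparator
  outputs are for divergence analysis, not clinical use under those
  guidelines.
* No timing-of-first-dose modelling, no contraindication logic beyond the
  antenatal-LMWH exclusion, no extended 6-week postpartum prophylaxis logic,
  and no causal interpretation of the pre/post incidence difference — the
  package evaluates a screening rule, it does not estimate treatment effects.
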