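# Methods note

## The problem and the model

DRESS syndrome is a delayed drug hypersensitivity reaction: maculopapular
rash, fever, eosinophilia and/or atypical lymphocytes, and internal organ
involvement, with onset typically two to eight weeks after the culprit
drug is introduced. Because patients are often on several drugs, causality
must be apportioned per drug. This package implements structured causality
scoring: each algorithm is a declarative table mapping the level of each
evidence item to integer points; the net score is the sum, a strict
threshold gives the binary related/unrelated call, and contiguous bands
give a qualitative category.

Three tables ship with the package:

1. **RegiSCAR** (diagnosis, not causality): fever, lymphadenopathy,
   eosinophilia grade, atypical lymphocytes, skin extent and morphology,
   biopsy, organ count, resolution time, exclusion of alternative causes.
   Range −4…+9; bands ≤+1 excluded, +2–+3 possible, +4 probable, ≥+5
   definite. The band wording follows the "+4 probable / ≥+5 definite"
   convention; both the points and bands are config-overridable. A total
   strictly greater than +2 is the inclusion gate for ALDRESS.
2. **SEFV** (Spanish Pharmacovigilance System, Karch–Lasagna family):
   chronology, literature, withdrawal, rechallenge, alternative causes,
   contributing factors, complementary explorations. Chronology windows:
   1–7 days compatible, 8–21 partially compatible, >21 incompatible, drug
   started on/after onset excluding. Bands ≤0 unlikely, 1–3 conditional,
   4–5 possible, 6–7 probable, ≥8 definite; validation positivity is
   strictly >6.
3. **ALDRESS** (DRESS-specific): chronology with DRESS windows (15–56 days
   compatible, 8–14 and 57–90 partially compatible, 1–7 and >90
   incompatible, onset before start excluding), dechallenge, rechallenge,
   notoriety, microbiological alternative cause, immunology (LTT/patch),
   and a −1 penalty when a concomitant drug has equal or higher
   notoriety. Validation positivity is strictly >7.

### The ALDRESS point allocation is a documented convention

The ALDRESS *items* and its positivity rule (net score > 7) are fixed;
the per-level points shipped in `tables/aldress.yaml` are this package's
own convention, chosen under three constraints: (a) a textbook single-drug
case — compatible chronology +3, dechallenge improved +2, well-known drug
+2, alternatives excluded +1 — must land at 8 > 7 and classify related;
(b) missing information (unknown / not recorded / not done) is always
worth 0 points, so incomplete records are score-neutral rather than
penalized; (c) upgrading any single item level never lowers the net score
(monotonicity, property-tested). Anyone holding the authoritative
allocation can drop it in as a YAML file; the engine revalidates band
coverage and level completeness on load.

Two binary rules are supported. The default is the strict threshold
(>7 / >6), which is the rule used for validation. The classical
category rule (possible/probable/definite ⇒ related) is available via
`classify(..., rule="category")`; for SEFV the two disagree for scores
4–6, and the threshold rule wins by default.

## Diagnostic accuracy

Evaluation is at patient level: truth is the case/control label (a *case*
received exactly one drug, so causality is attributable by design; a
*control* had ≥2 suspects), and an algorithm's call for a patient is
positive when it flags any of that patient's drugs as related. From the
2×2 table we report sensitivity, specificity, PPV, NPV and accuracy, each
with an exact Clopper–Pearson interval (scipy's beta inversion; the test
suite cross-checks it against direct bisection of the binomial tails and
verifies ≥95% coverage at n=30). LR+ is computed from unrounded
proportions and carries no interval. A metric with an empty denominator is
reported as undefined, never as 0. Fisher's exact test uses the
conventional two-sided rule (sum of tables with point probability ≤
observed; no mid-p).

## Agreement

Cohen's κ = (p_o − p_e)/(1 − p_e) with identity, linear
(1 − |i−j|/(k−1)) or quadratic (1 − ((i−j)/(k−1))²) weights; with two
categories the weighted and unweighted statistics coincide. The standard
error is the large-sample Fleiss–Cohen–Everitt variance under the
alternative, and the same ASE drives the z statistic, the two-sided
normal p, and the κ ± z_{α/2}·ASE confidence interval — so each reported
row is internally consistent. (Some packages use the null-hypothesis SE
for z; we deliberately do not, to keep z and the CI on one SE.) The
default weighting for ordinal ratings is quadratic, the common ecosystem
default; it is a flag because raters' category sets vary. Interpretation
uses the Landis–Koch bands with conventional cut points (<0.10 none,
then 0.20/0.40/0.60/0.80 steps). κ is undefined (explicit error) when all
ratings fall in one identical category (p_e = 1).

## Synthetic cohorts

`synthetic_cohort.generate` emulates the marginal structure of a
37-patient DRESS case–control population:

- 7 single-drug cases, 30 controls with 2–4 suspects (uniform);
- culprit drug multinomial: lamotrigine 9/37, amoxicillin–clavulanate and
  carbamazepine 7/37 each, cotrimoxazole 5/37, amoxicillin 4/37,
  sulfasalazine 2/37, benznidazole / eslicarbazepine / phenytoin 1/37;
  innocent co-medications come from a fixed low-notoriety pool;
- age ~ Normal(41.62, 17.09²) truncated to [16, 95] (the source summary's
  "median … ± …" is treated as mean ± sd); 54.1% male;
- per-pathogen microbiology (positive, negative, not recorded) rates,
  e.g. CMV (7, 14, 16)/37; the hepatitis-B screen is never recorded by
  default. Autoimmune antecedent counts (33 none, 2 RA, 2 PsA, 1 AS) sum
  to 38 in the source summary and are normalized to probabilities;
- LTT (positive, negative, not done) = (3, 17, 17)/37 — explicit counts
  sum to 33, the 4 unaccounted subjects default to not done; two thirds of
  LTT-positive patients also have a positive patch test;
- culprit latency: log-normal conditioned on the ALDRESS-compatible
  window [15, 56] days. The configured defaults are a mean time to onset
  of 23 days with sd 7; the underlying log-normal mean is solved
  numerically so that the *window-conditioned* mean equals 23 exactly
  (with sd 10 the 15-day floor makes a conditional mean of 23
  unattainable, which is why the default spread is 7). Innocent drugs
  mostly start during the prodrome (1–7 days before onset), a minority
  8–90 days before;
- RegiSCAR inputs are drawn with a floor (fever, marked eosinophilia,
  suggestive rash, ≥1 organ, slow resolution) that guarantees a total of
  ≥ +4, so every generated patient passes the inclusion gate, mirroring a
  cohort recruited under that gate.

### The separation contract

Culprit and innocent exposures draw from documented conditional evidence
profiles constructed so that the default ALDRESS table classifies every
patient correctly unless an error is planted:

- **case culprits**: compatible chronology, dechallenge improved,
  well-known notoriety; when the patient-level infection/immunology
  findings would otherwise mask the culprit (net non-positive
  contribution), the profile includes a documented positive rechallenge
  (inadvertent re-exposure);
- **control exposures** (including the true culprit): evidence is
  *diluted* — all suspects withdrawn simultaneously (dechallenge
  unassessable), no rechallenge — reflecting why these patients are
  controls in the first place: the available evidence cannot single out
  one drug. Their maximal reachable ALDRESS score is 6 < the threshold;
- two correlations keep the bounds tight: LTT positivity occurs only in
  single-drug cases (where the tested drug is unambiguous; the cohort-wide
  3/37 rate is preserved in expectation), and a patient with a positive
  microbiology screen never carries an LTT negative (downgraded to not
  done — when an intercurrent infection is documented the LTT is typically
  not pursued);
- **planted miss** (`planted_error[0]` cases): latency 8–14 days,
  dechallenge unassessable, occasional notoriety — the culprit tops out
  at 6;
- **planted false alarm** (`planted_error[1]` controls): one innocent
  gains the full culprit-like profile and every other suspect is capped
  below well-known notoriety, so the promoted drug scores ≥ 8.

With `planted_error=(a, b)` the patient-level evaluation therefore yields
the confusion matrix (7−a, a, b, 30−b) *exactly, for every seed* — this
is a test-fixture contract, verified end to end in the suite for 20 seeds
and for a grid of (a, b).

These profiles are deliberately cleaner than reality: real multi-drug
patients do not have a deterministic score ceiling, real rechallenge is
rare, notoriety assessments disagree between raters, and records are
incomplete in ways the generator does not model. Passing the planted
recovery tests shows the scoring/evaluation machinery is correct and the
thresholds are strict; it says nothing about ALDRESS's clinical accuracy
on real cohorts, which only prospective data can establish. SEFV metrics
on these synthetic cohorts likewise reflect the generator's conventions
(notably its 1–7-day chronology window clashing with DRESS latency), not
any field measurement.

## Numerical choices and degenerate inputs

- Dates are ISO-8601 days; latency = index − start, day 0 = same day;
  latency ≤ 0 is excluding for both chronology modules.
- With repeated exposure episodes of the same drug,
  `score_patient_drug` scores the episode with the most compatible
  chronology (ties: shorter |latency|).
- Clopper–Pearson bounds are exact: x = 0 ⇒ low = 0, x = n ⇒ high = 1.
- Fisher's p is clipped to [0, 1]; a zero margin gives p = 1.
- κ ASE = 0 (degenerate perfect agreement) reports z = ±∞ with a point CI
  rather than dividing by zero.
- Score tables validate on load: duplicate items, band gaps/overlaps, and
  bands not covering the analytic score range are configuration errors.
- The latency calibration solves the window-conditioned mean with a
  bracketed root find over the underlying log-normal mean and raises if
  the configured mean is unattainable in the window.

## Problem sizes

The shipped validation suite uses the study-scale cohort (n = 37) for the
planted-recovery checks (20 seeds, plus a planted-error grid), 1000 seeds
for the mean-onset law-of-large-numbers check, a 10 000-patient cohort for
the culprit-drug multinomial check, the full x ≤ n ≤ 30 grid for the
interval oracle, and 1000 randomized tables for threshold strictness.

## Known limitations

- The ALDRESS point allocation is a convention (above), not an
  authoritative reproduction.
- Patient-level immunology: the LTT is stored per patient, not per drug,
  so in multi-drug patients a positive LTT raises every suspect's score
  equally. A per-drug immunology extension would need a schema change.
- No multi-rater (Fleiss) κ, no McNemar, no ROC — the validation design
  uses two raters/algorithms and fixed thresholds.
- The generator matches marginals, not joint structure; it is not an
  imputation of any real cohort.
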