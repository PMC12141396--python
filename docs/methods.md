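# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `racea`.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The decision model

A Markov cohort model compares initial therapy with tofacitinib (TOF) versus
adalimumab (ADA), both with background methotrexate, from a societal
perspective.

**Structure.** Six states: `initial` (first cycle on the assigned drug),
`acr70` / `acr50` / `acr20` (on treatment, stratified by the best ACR
response achieved at month 6), `palliative` (off the index drug, on
conventional management) and absorbing `death`.  The whole cohort starts in
`initial`; at the end of cycle 0 it splits by the exclusive response-category
probabilities (nonresponders move to palliative care), responders then face
a constant per-cycle withdrawal hazard to palliative care.  Death competes
with every transition at an age-indexed per-cycle probability (flat by
default).  Response is assessed exactly once, at month 6, mirroring a
single-endpoint treat-to-target design.

**Time.** Cycle length 0.5 years, horizon 27 years (54 cycles), ages 51–78.
Accrual uses start-of-cycle occupancy; the discount factor for cycle *k* is
(1 + r)^(−k·cycle length) with cycle 0 undiscounted and r = 5%/year for both
costs and QALYs (configurable, including 0).  A half-cycle correction
(averaging start- and end-of-cycle occupancy) exists but is off by default;
it changes totals by well under the model's parametric uncertainty.

**Disability and utility.** Each state carries a HAQ level: baseline HAQ in
`initial`; baseline minus a per-category improvement ΔHAQ while responding
(clamped to [0, 3]); on palliative care HAQ progresses linearly from
baseline at a constant annual rate indexed to model time.  Utility is linear
in HAQ, u = a − b·HAQ clamped to [floor, 1], with defaults a = 0.862,
b = 0.327 — the widely used linear HAQ→utility mapping for RA — and floor
0.30.  A severe-adverse-event QALY channel (per on-treatment cycle) exists
and defaults to zero.

**Costs** per cycle, all in CNY: drug cost while on treatment; a cheaper
conventional-therapy drug cost on palliative care; state (non-drug medical)
cost base + slope·HAQ; direct nonmedical and indirect costs as per-cycle
constants on alive states.  Dominance/ICER logic: ΔC < 0 with ΔQ > 0 is
"dominant" (no ratio), the reverse "dominated", same-signed differences give
ΔC/ΔQ, and ΔQ = 0 with ΔC ≠ 0 reports "cost difference only".

**Base-case inputs.** Response-category probabilities are the observed
month-6 category counts out of 58 per arm (TOF 20/11/11/16 at
ACR70/ACR50-only/ACR20-only/none; ADA 22/12/11/13).  The economic inputs are
the package's calibrated base case, chosen once to sit in the published
cost landscape for China after tofacitinib entered centralized procurement:
TOF ¥1,500 vs ADA ¥19,500 per 6-month cycle, palliative drug ¥400, state
cost ¥1,500 + ¥3,000·HAQ, nonmedical ¥600 and indirect ¥40 per cycle,
baseline HAQ 0.6, ΔHAQ (0.60, 0.55, 0.0) by category, palliative HAQ
progression 0.035/year, withdrawal 4%/cycle (TOF) vs 6.5%/cycle (ADA; TNF
inhibitors lose effect faster in routine care, e.g. through
anti-drug-antibody formation), flat mortality 0.5%/cycle (cohort survival
to age 78 ≈ 76%), willingness to pay ¥257,094/QALY (3× per-capita GDP).
With these inputs TOF dominates (ΔC ≈ −¥167k, ΔQ ≈ +0.26); the per-arm
totals that the published analysis reports cannot be re-derived because its
unit costs, utilities and transition inputs are unpublished, so only the
incremental arithmetic and qualitative structure are meaningful comparators.

## 2. Sensitivity analyses

**Tornado.** Each parameter moves ±10% from base; both arms re-run; the
outcome is incremental net monetary benefit NMB = WTP·ΔQ − ΔC.  NMB rather
than the ICER because the base case is dominant and negative ratios are not
orderable.  Inputs common to both strategies (utility coefficients, state
cost coefficients, ΔHAQ, palliative drug cost, nonmedical/indirect costs)
are varied *jointly* in both arms — varying a shared input per-arm would
manufacture spurious incremental sensitivity.  Cumulative ACR rates are
varied on the cumulative scale: perturbing the ACR50 rate reallocates mass
between the adjacent exclusive categories, keeping the split on the
simplex; values are clamped to the feasible interval with a warning.  With
the packaged base case the three widest bars are the TOF ACR50 rate, the
ADA drug cost and the ADA ACR50 rate.

**PSA.** Parametric Monte Carlo: costs ~ gamma with shape = (mean/se)² and
scale = se²/mean; utilities and other [0, 1] (or scaled) quantities ~ beta
by moment matching; each arm's four response-category probabilities ~
Dirichlet with concentration equal to its observed counts (keeping draws on
the simplex; the sampling sentence that describes the distributions is
interpreted as this parametric Monte Carlo).  One draw per logical
parameter: shared inputs get the same perturbation in both arms.  Default
dispersions: 10% of the mean for costs and ΔHAQ, se 0.03 for utility
coefficients.  5,000 iterations; the CEAC is evaluated on one common draw
set over a 101-point WTP grid from 0 to 5× per-capita GDP; a standard-error
of zero makes a distribution degenerate at its base value.

## 3. The synthetic cohort generator

The generator emulates the study population so the pipeline is testable
without patient data.

**Marginals.** Right-skewed measures (disease duration, SJC, TJC, morning
stiffness, ESR, CRP, RF, HAQ) are log-normal, parameterised by published
median/quartiles (with zero inflation where the lower quartile is 0);
symmetric measures (age, BMI, VAS) are truncated normals; sex is Bernoulli.
Joint counts are integer-rounded with physiologic bounds (0–28); tails are
clamped at clinically plausible maxima (stiffness 240 min, CRP 200 mg/L,
RF 600 IU/mL, duration 40 y) since a single extreme draw otherwise dominates
small-sample means.

**Dependence and arm imbalance.** Disease-activity measures are noisy
readouts of one latent severity factor (Gaussian copula, so marginals are
unaffected).  The ADA arm's higher severity is a mean shift of that factor;
per-variable loadings are derived from the requested marginal shifts (capped
at 0.95, residual applied as a direct shift) so that the arm difference is
one-dimensional — the structure under which propensity-score matching is
actually the right tool.  Zero inflation is tied negatively to the same
factor, and the SJC/TJC zero indicators are drawn jointly conditioned on not
both being zero: a patient escalating to a JAK inhibitor or biologic has at
least one active joint domain, and this guarantees every patient is
ACR-assessable.

**Calibration.** The published baseline table is internally inconsistent:
with the standard DAS28-ESR formula (global health = 10×VAS) its joint-count
quartiles plus ESR/VAS medians imply arm DAS28 means far above its printed
3.25/4.36.  The generator therefore keeps ESR/CRP/HAQ/duration/RF at the
printed medians and compresses the joint-count dispersion (and VAS location
3.45) so that the *derived* DAS28 means land on the printed values; this is
the `table1_cohort_spec()` configuration.  The *default* `CohortSpec` keeps
the same imbalance structure at half the log-scale shift: the full published
imbalance leaves so little propensity overlap at 100 patients/arm that 1:1
matching without replacement cannot produce a balanced matched cohort of
useful size (see §5).

**Month-6 outcomes.** Each patient draws one exclusive response category
(multinomial with the configured probabilities); the month-6 core set is
then constructed so the ACR classifier returns exactly that category:
joint-count improvements are drawn at or beyond the category threshold on
the integer grid, two continuous auxiliaries are placed inside the
category's band, one may lag below threshold when four are assessable, and
ESR (integer-valued, bounded below by 1) is constructed to pass its
threshold exactly via floors.  The round trip
`acr_response(baseline, month6) == category` is exact for every patient and
seed, which makes responder-rate recovery a pure multinomial experiment.
RF is carried forward unchanged (its dynamics are an observational contrast
in the source setting, not a model component).

**What passing tests do and do not show.** Rate recovery, balance behaviour
and round-trip exactness validate the *pipeline arithmetic* under a
generator whose baseline variables are conditionally independent given one
severity factor, whose outcomes follow the ACR rule exactly, and which has
no missing data, dropout or measurement error.  Real cohorts violate all of
these; passing here says nothing about confounding by unmeasured variables
or about the clinical truth of the response probabilities.

## 4. Propensity matching

Logistic regression (statsmodels GLM, binomial family, IRLS, tolerance
1e-10, ≤100 iterations) of TOF assignment on the 13 baseline covariates of
the study's baseline table; right-skewed covariates enter the linear
predictor as log1p so a handful of extreme CRP/RF values cannot dominate
(balance diagnostics stay on the raw scale).  Records are sorted by patient
id before fitting, which makes the whole stage invariant to input order.
Constant covariates are dropped (coefficient 0); exact collinearity is
reported with the offending column; complete separation (likelihood at its
supremum with perfect classification) raises an error advising covariate
removal, while quasi-separation merely warns.

Matching is greedy 1:1 nearest-neighbour without replacement on the logit
of the score, processing TOF candidates in descending score order with ties
broken by id, caliper = 0.2 × SD of the pooled logits.  An over-tight
caliper yields an empty cohort with a warning, not an error.  SMDs use the
(TOF − ADA) mean difference over the *pre-matching* pooled SD in both the
pre- and post-match rows — the usual balance-diagnostic convention, which
avoids re-estimating a dispersion from the small matched sample; binary
covariates use √(p̄(1−p̄)).

## 5. Numerical and design notes

* Occupancy conservation holds to 1e-12 per cycle; the engine equals exact
  path enumeration on small chains to 1e-10.
* Currency figures are rounded only at reporting; CSV output uses `%.17g`
  so files round-trip doubles exactly, and the pipeline manifest records
  SHA-256 hashes to make reproducibility checkable.
* All randomness flows through numpy `default_rng` with explicit seeds; the
  CLI `--seed` overrides the configured cohort seed and PSA seed (seed+1).
* Problem sizes in the packaged checks: 1,000 replicate cohorts of 58/arm
  for rate-recovery coverage, 10,000/arm for point recovery, 20 cohorts of
  100/arm for matching balance, 5,000 PSA iterations, 1,000 random chains
  for the engine oracle.
* **Balance limitation.** The maximum |SMD| over 13 covariates has a pure
  sampling floor: even two *identically distributed* matched arms of ~100
  pairs produce max |SMD| ≈ 0.10–0.26 per replicate.  Post-match balance
  below 0.1 — and uniformly below 0.25 across many replicates — is
  therefore not attainable at this sample size for any generator setting;
  the realistic statement, which the tests assert, is that matching always
  reduces the worst imbalance and typically lands its maximum near the
  randomization floor.

## 6. Limitations

* The economic base case is a calibrated, internally consistent input set,
  not the (unpublished) inputs of the source analysis; absolute per-arm
  totals are not comparable quantities, only the incremental structure.
* Mortality is flat and HAQ-independent by default (a hook exists for an
  age-indexed schedule); no excess mortality with disability.
* Single treatment line: initial therapy → palliative care; no sequencing
  of further biologics, no adverse-event or dropout simulation.
* Palliative-care HAQ follows a cohort-level schedule indexed to model time
  rather than time-since-entry, a standard simplification that slightly
  understates the disability of late switchers.
* Baseline covariates are conditionally independent given a single severity
  factor; real correlation structures are richer.
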