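# Methods

## Study design being modelled

The pipeline reproduces the mechanics of a case–control mortality study in
which both groups are decedents drawn from the same source cohort (legal
handgun purchasers): cases die by firearm suicide (ICD-10 underlying cause
X72–X74, any subdivision), controls die in motor-vehicle crashes as
occupants or drivers (an explicit closed list of ICD-10 transport ranges:
V02–V04; V09.0, V09.2; V12–V14; V19.0–V19.2, V19.4–V19.6; V20–V79;
V80.3–V80.5; V81.0–V81.1; V82.0–V82.1; V83–V86; V87.0–V87.8; V88.0–V88.8;
V89.0, V89.2). Intentional and undetermined-intent transport deaths are
excluded *structurally*: their codes never appear in the control list, so
no separate intent filter exists. Range semantics: a 3-character range such
as V20–V79 matches any code whose 3-character root falls lexicographically
inside it, plus all subdivisions; a 4-character range such as V80.3–V80.5
matches only the listed subcodes and their further subdivisions.

Eligibility removes decedents under the legal handgun-purchase age of 21
(boundary: exactly 21.0 is retained), then records with missing sex, then
missing county urbanicity. The order is a package choice — fixed so the
exclusion report reconciles exactly (each person counted once, at the first
filter that removes them) and reruns are reproducible.

## Exposure phenotyping

Exposures are emergency-department/inpatient visits (pooled; the
distinction is not modelled) carrying ICD-9-CM diagnosis or external-cause
codes in *any* diagnostic field, within a closed lookback window
[death − 3 years, death]. Window arithmetic is calendar-based
(`DateOffset(years=3)`), not 365·3 days; whether the original design used
days or calendar years is ambiguous, and calendar years were chosen and
are documented here. Matching strips the decimal point from both code and
prefix and anchors the prefix at position 0, so dotted and undotted
discharge-data dialects behave identically.

The taxonomy has six categories — mental illness, substance use, pain,
chronic disease, assault, suicidal ideation/attempt — with disaggregated
components (e.g. depression … schizophrenia under mental illness).
Component implies category implies any-visit on every output row; the
coder is idempotent and invariant to visit row order; categories are not
mutually exclusive. The shipped code map
(`data/codemap_synthetic.csv`) is an **illustrative synthetic fixture**:
prefixes are clinically plausible per component but are not a validated
clinical code list. The map is a first-class input (CSV or YAML) precisely
so a validated list can be dropped in. The restriction of drug poisonings
to unintentional intent is encoded in the map itself (poisoning components
list only unintentional external-cause prefixes), not as a runtime flag.

## Regression models

Case status is modelled by logistic regression, fitted by IRLS
(statsmodels GLM, binomial family; convergence when the max absolute
coefficient change is below 1e-8, cap 100 iterations). The covariate set is
fixed: sex, age in years (continuous, untransformed), death year
(continuous), marital status, education, urbanicity. Reference levels —
female, married/partner, high school or less, large metro — are package
choices; "unknown" is retained as its own level rather than dropped.
Variants: *separate* (one model per exposure, full covariates),
*simultaneous* (all terms of a level in one model), *components* (both
variants within each category over its components).

The covariance is the sandwich B⁻¹MB⁻¹ with B = X′WX the expected (=
observed, canonical link) information, M the outer product of
per-observation scores xᵢ(yᵢ − pᵢ), and an HC1-style factor n/(n−k)
(switchable to HC0). On a saturated 2×2 this reduces to the Woolf SE
√(1/a+1/b+1/c+1/d) times the HC1 factor, which the tests verify, along
with agreement to 1e-6 with a finite-difference score oracle and (at HC0)
with the statsmodels Logit sandwich. Confidence intervals are Wald on the
log-odds scale with z = 1.959964. Fits with |coefficient| > 15 or a
singular information matrix are flagged as separated and reported
non-estimable rather than raised; batch runs continue past them.

## Quantitative selection-bias analysis

The bias parameter is OR_select = (S_case,0·S_control,1)/(S_case,1·S_control,0);
with all cases selected (the default assumption) it is
S_control,1/S_control,0, benchmarked where selection proportions are
unknown by the ratio of the control-sample exposure rate to a living
benchmark rate (only the ratio enters, so the rates' unit is irrelevant).
Each iteration draws T from a triangular prior with mode OR_select and
limits 20% below/above the mode **on the OR scale** (a deliberate reading
of "20% lower/higher than the mode"; log-scale limits would be a different
prior), and Z ~ N(0,1), and emits
exp(ln(OR_observed·T) + Z·SE(ln OR_observed)). SE(ln OR_observed) comes
from the model fit when available, or is recovered from a printed 95% CI as
(ln hi − ln lo)/(2·1.959964); both paths are exposed. Summaries are the
median and the 2.5th/97.5th percentiles of the draws (numpy linear
interpolation between order statistics; at 50,000 iterations the percentile
definition matters less than Monte Carlo noise). Fewer than 1,000
iterations are refused because tail percentiles are unstable.

Batch runs derive one independent seed per exposure from the master seed
and a CRC-32 of the exposure label via a `SeedSequence`, making results
deterministic and independent of row order. Whether draws should be shared
across exposures was open; independent draws were chosen.

Properties maintained (and tested): the median is strictly increasing in
OR_select and OR_observed; with a symmetric triangular prior the median
converges to OR_observed·OR_select; scaling OR_observed by c scales the
median and both SI bounds by c; degenerate inputs (zero SE, point-mass
prior) pass the observed OR through unchanged.

## Synthetic data generator

The generator emulates the study conditions: 3,862 cases and 1,553 controls
by default, control-group exposure prevalences and crude odds ratios at the
scale of the study's descriptive table, covariate marginals likewise, death
dates uniform over 2008–2013, ages from truncated normals (56.0 ± 16.7 for
cases, 50.8 ± 15.8 for controls, truncated at 18 so a small under-21 tail
exercises the eligibility filter), and small missing-data rates for sex and
urbanicity. Case exposure prevalence is never specified directly: it is
derived from the control prevalence and the true OR through the logistic
identity p₁ = OR·p/(1−p+OR·p). Exposures are independent across categories
— the joint distribution is unknown, and independence is an explicit
simplification; a confounding toggle shifts exposure odds by sex stratum
for adjusted-model tests but defaults off. Exposed persons receive one
mapped visit uniformly inside the lookback window; everyone receives noise
visits with unmapped codes at rate 0.30 (roughly reproducing the ~46–49%
any-visit rates once mapped visits are added).

Control selection draws a pool (default 3× the target; the pool size is a
package parameter, since only the retained count is specified by the
design) and retains each control with probability proportional to
selection_rr^exposed, scaled to hit the target count in expectation. Under
this rule the selection-proportion ratio S_control,1/S_control,0 equals
selection_rr *exactly*, the retained exposure prevalence is
r·p/(1−p+r·p), and the crude OR converges to true_or/selection_rr — so
feeding selection_rr into the QBA as OR_select recovers the truth, which is
the end-to-end recovery test. The only published selection ratio (1.71, for
suicidal ideation/attempt) is the default for that category; others default
to 1.

What the generator does **not** emulate: purchase-history linkage and
time-since-purchase structure, correlated exposures, visit-frequency
heterogeneity, coding error in the diagnoses themselves. Passing tests
therefore demonstrate that the estimators and the bias correction are
correct under the stated mechanism, not that the illustrative code map or
independence assumptions describe real discharge data.

## Problem sizes and numerical choices

The parameter-recovery check runs 200 replicate cohorts of 20,000 analysed
persons with a rare exposure (0.3% of pool controls, true OR 4.6,
selection_rr 1.71 — the regime of the sparsest exposures in a
deceased-control design, where exposed controls number in the tens) and
5,000-iteration simulations per replicate. The rare-exposure choice is
deliberate: with a fixed, correctly specified bias mode, the simulation
interval is conservative, and at common prevalences its coverage is pushed
toward 100% by the prior's width alone; at this prevalence random error
and prior spread are comparable and the nominal ~95% behaviour of the
interval is actually informative. Null-effect and closed-form selection
checks run at n = 50,000 and n = 10⁶ respectively, where Monte Carlo error
is well below the tested tolerances.

## Known limitations

- The shipped code map is synthetic; substantive exposure prevalence on
  real data requires the authoritative clinical code list.
- The probabilistic purchaser–death record linkage that produced the real
  cohort is out of scope; inputs are assumed already linked.
- The QBA is a selection-bias analysis only; misclassification and
  unmeasured confounding are not modelled.
- Separated component models are flagged and skipped, not penalised
  (no Firth correction).
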