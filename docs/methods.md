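# Methods

This note documents the models and procedures implemented in
`picturesort`, the assumptions behind them, the parameters that matter,
and what the synthetic-data tests do and do not establish about real
cohorts.

## The instrument and its scoring model

A picture-sort frequency instrument asks respondents to sort food cards
into ordinal frequency categories. The package models it with three
configuration objects:

**Food registry** (`registry.json`). Each card is a food item assigned to
one of 10 groupings (breads; vegetables and salad; fruits; beverages;
soups or stews; cereals; dairy and eggs; rice, pasta, etc.; meat,
chicken, or fish; desserts and snacks) and to at most one of 6 AHEI
components. Flags carry the scoring exclusions: `is_potato` (potatoes are
never vegetables, whatever the preparation), `is_fruit_juice` (juice
belongs with sugar-sweetened beverages, not fruit), `is_alcohol`
(excluded from frequency totals), `is_salad` (salad counts as a vegetable
by default; `include_salad=False` drops it from the vegetable component
while keeping it in totals, since usage varies between index variants).
The packaged registry is an explicit synthetic fixture: the real card
list of the instrument that motivated this package is unpublished, so we
provide a 38-item stand-in with Navajo-typical items (blue corn mush,
mutton stew, frybread, …) chosen so every grouping has ≥3 items and every
scoring rule is exercisable. Frybread and other fried breads map to no
AHEI component rather than whole grains, consistent with the whole-grain
component's intent. Users override the registry with their own JSON/CSV.

**Dialects** (`dialects.yaml`). The child instrument has 4 scored
categories (never / sometimes / once a day / more than once per day — the
two-step "every day" probe is collapsed upstream), the adult instrument 5
(adding *weekly* and *sometimes but not weekly*). Label → servings/day
maps are anchored at 0 and 2. The interior values are design choices,
monotone and configurable: child *sometimes* = 0.5 (midpoint of
"everything between never and daily"), adult *weekly* = 0.143 (1/7) and
*sometimes but not weekly* = 0.033 (≈ monthly).

**Component standards** (`standards.yaml`). Each AHEI component is scored
0–10 by clamped linear interpolation between a zero-score and a
full-score intake. Cutoffs follow the AHEI-2010 servings criteria where a
frequency-only instrument permits: vegetables 5/d, fruit 4/d,
nuts/legumes 1/d, SSB + juice reverse-scored to 0 at ≥1/d, red/processed
meat reverse-scored to 0 at ≥1.5/d. The AHEI whole-grain criterion is
grams-based and cannot be computed from frequencies, so a 1.5 servings/d
full-score anchor replaces it. All cutoffs live in configuration, not
code.

Derived indices: modified AHEI total (sum of the 6 component scores,
0–60); healthy foods score (the 4 health-positive components, 0–40);
fruit, vegetable and F&V (= fruit + vegetable) subscores; and the
healthy-to-total daily servings ratio. The F&V score is implemented as
the sum of the two subscores; nothing in the source material indicates a
different weighting. A ratio with zero total frequency is a missing
value, never 0/0 → 0: a subject who reports nothing is distinguishable
from one who eats nothing healthy.

## Psychosocial scales

Scales are item sets on a 4-point Likert response (1–4, deliberately no
neutral midpoint; definitions with fruit/vegetable subscale tags live in
`scales.json`, again a documented stand-in for unpublished instrument
wording). Scores are means of answered items; rescaling to [0, 1] is
(x − 1)/3 for the 1–4 range, which makes coefficients of variation
comparable across instruments with different theoretical ranges (CoV is
not shift-invariant, so rescaling must precede it).

Internal consistency is Cronbach's α with sample (n−1) variances on
complete cases; degenerate inputs (k < 2, zero total variance) raise
rather than return a number. The item-removal rule computes α-if-deleted
for every item and removes the single best item iff the *relative*
improvement (α_after − α)/α exceeds 0.30. The relative reading (rather
than +0.30 absolute points) is the one consistent with the removal
decisions tabulated in the validation study this design follows
(0.31 → 0.67 removes at +116%; 0.60 → 0.65 stays at +8%). Ties between
equal α-if-deleted values break to the first item in scale order,
deterministically. A non-positive baseline α is flagged; the decision is
then computed against |α|, and any improvement from α ≤ 0 to a positive
value qualifies.

## Adult reference measures

The abbreviated FFQ has 7 F&V questions whose per-item *daily servings*
are summed, excluding French fries but including other potatoes. Raw
frequency-category capture varies between FFQ versions, so the package
takes already-converted servings/day per item and leaves the conversion
table (`to_weekly` multipliers for the obesogenic items) in
configuration. The obesogenic dietary index is the arithmetic mean of
three weekly frequencies (fast food, French fries, soda); any missing
item makes the index missing because a 2-item mean would silently change
the construct.

## Convergent validity and retention

Correlations are pairwise-complete Pearson coefficients; p-values are
two-sided, from t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom
(two-sided because no direction is pre-registered for the index–reference
pairs; the direction enters through the sign rule instead). The retention
rule keeps an index iff p ≤ 0.1 *and* the sign of r matches the expected
direction (positive for self-efficacy and FFQ F&V, negative for the
obesogenic index) against at least one of the cohort's references
("either" rather than "both" for adults, which is the reading consistent
with the retained sets the original analysis reports). The boundary is
strict in the stated direction: p = 0.1 retains, anything above does not.
No multiple-testing correction is applied, matching the evaluation design
this package reproduces; at n ≈ 25 the rule is equivalent to
|r| ≳ 0.34.

## Test-retest reliability

Bland-Altman agreement on subjects with both timepoints (pairing by
subject id; exclusions counted and reported; minimum 3 pairs).
Differences are follow-up − baseline by default; the convention is
configurable and documented in every result. Limits of agreement are
d̄ ± 1.96·SD(d) with the n−1 SD; the repeatability coefficient is the
half-width 1.96·SD(d); the percentage of differences within the limits
uses the closed interval and is expected to be ≈95% under normality.

The reliability coefficient is implemented as an explicit
interpretation: within-person variance σ²_w = SD(d)²/2 (a difference of
two occasions carries both occasion errors), total variance from the
pooled 2n values, and R = 1 − σ²_w/σ²_total floored at zero. R is an
intraclass-type quantity — σ²_b/(σ²_b + σ²_w) in expectation — and the
report footer flags the formula as an interpretation since "reliability
coefficient" is not a uniquely defined estimator.

Rounding happens only at the markdown rendering layer (1 decimal for
scores, 2 for correlations and ratios); CSV/JSON outputs are full
precision, and the whole report is a pure function of inputs and
configuration.

## Synthetic cohorts

`generate_cohort` emulates a two-timepoint feasibility cohort with known
ground truth. Defaults are the study conditions the package is designed
around: 25 children and 18 adults at baseline with 72%/67% follow-up
completion, latent diet-quality SD 1, reporting-bias SD 0.3, item loading
0.8, target inter-item correlation 0.3 (giving population α ≈ 0.56–0.77
across the packaged scales, the observed range for such instruments),
within-person SD 0.5, and reference correlation ρ = 0.5 (the mid-range of
reported index–reference correlations). Adult reference scales are
anchored at FFQ F&V mean 3.0/SD 1.8 servings/d and obesogenic index mean
2.5/SD 1.7 per week.

Model: subject latent T ~ N(0, latent_sd); time-specific quality
Q_t = T + δ_t with δ_t ~ N(0, σ_within); item propensity
w_i·Q_t + b + ε_i with per-subject reporting bias b and item noise ε_i
drawn once per subject (so σ_within = 0 reproduces baseline responses
exactly at follow-up). Healthy items load +w, sugary drinks and
red/processed meat −w, neutral items 0. Propensities are cut at fixed
thresholds per dialect, chosen so every category keeps ≥5% marginal mass
at defaults. Likert items follow a one-factor model whose latent
correlation is *calibrated* (bivariate-normal cell probabilities,
bisection) so that the observed inter-item Pearson correlation of the
discretized items equals the target — making the closed form
k·r̄/(1 + (k−1)·r̄) an exact population target for the estimated α. The
self-efficacy factor carries the programmed correlation ρ with the
child's latent diet quality (it is the child reference construct); the
tendency-to-choose factor is independent. Adult references are
linear-Gaussian in standardized Q_t with correlation +ρ (FFQ) and −ρ
(obesogenic), floored at 0; the flooring clips < 7% of mass and
attenuates the realized correlation by ~0.01–0.02.

The continuous `retest` table carries Q_t itself, so SD(diff)/√2 recovers
σ_within and reference-vs-latent correlations recover ρ without ordinal
attenuation. Correlations of the *discretized* picture-sort indices with
anything are attenuated by coarsening — deliberately, because that is the
measurement process being emulated.

**What the generator does not emulate:** demographic covariates beyond
role labels, item-level missingness and refusal patterns, seasonal diet
change between baseline and follow-up (the within-person term is pure
noise, not drift), non-Gaussian reporting styles (e.g. end-category
pile-up), and any dependence between a child and their own family adult.
Passing parameter-recovery tests therefore shows the *arithmetic and
statistical machinery* is correct under the stated model, not that the
instrument is valid in any particular population.

## Problem sizes and numerical choices

Property tests use the smallest sizes at which the analytic targets are
sharp: α recovery at n = 1,000–5,000 (±0.03–0.05), ρ recovery at
n = 10,000 (±0.05), σ_within recovery at n = 5,000 (±5%), limits-of-
agreement coverage at n = 10,000 (95% ± 2 points); the full suite runs in
well under a minute. Comparisons to frozen hand-computed oracles use
exact or 1e-9–1e-12 tolerances. Scores are clamped (never extrapolated)
outside the standard's anchor range; all randomness flows from one seeded
`numpy` generator per cohort, so every table is reproducible bit-for-bit
from (config, seed).

## Known limitations

- The packaged registry, scale wordings and FFQ item set are synthetic
  stand-ins for unpublished instrument appendices; real analyses must
  supply their own registry/scales files.
- Five of the eleven AHEI-2010 components (trans fat, long-chain fats,
  PUFA, sodium, alcohol) cannot be estimated from a frequency-only
  picture sort and are out of scope, as is energy/portion modelling.
- The reliability coefficient formula is one defensible estimator among
  several; compare with a two-way ICC before cross-study comparisons.
- Bland-Altman here is the classical constant-bias variant; proportional
  bias (regression-based limits) and log-transformed limits are not
  implemented.
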