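# Methods

## The grading model

`prognograde` treats the quality of a body of prognostic evidence as an
ordinal level on a four-point scale (1 = very low … 4 = high, rendered
`+` … `++++`), determined by a starting level plus a sum of integer
adjustments:

```
level = clamp(starting_level + Σ level_delta, 1, 4)
```

**Starting level.** Prognosis studies mature through phases: phase 1
explores candidate associations, phase 2 confirms independent
associations, phase 3 tests an explanatory model. A strict majority of
phase-2/3 studies starts the body at 4 (high); otherwise it starts at 3
(moderate). The tie breaks to the lower start. The moderate start for
phase-1 evidence is the only value consistent with the published
narrative worked example under −1/−2/+1 arithmetic, and is asserted by
the oracle test over all six of its rows.

**Deltas.** Serious concern on a downgrade factor subtracts 1, very
serious subtracts 2; each upgrade factor present adds 1. How far each
factor should move the level is genuinely open in this framework, so the
magnitudes are exposed (`deltas=` on `grade()`/`fit()`) with these
conventional defaults. Upgrades are summed with downgrades before
clamping; a phase-1 body can in principle reach high (3 − 0 + 2), which
callers may prevent by overriding deltas. `unclear` and `not_applicable`
ratings never move the level but are recorded in the ledger and
footnotes.

## Factor rules

All "most/majority" tests are strict majorities (> 50% of the weight),
by study count by default; `weighting="participants"` switches to
participant-weighted majorities. All rule thresholds live in
`Thresholds` (11 fields, loadable from JSON/YAML); boundaries are
inclusive ("4.25 or greater", "at least 10", "50% or greater").

**Study limitations.** Each study carries six QUIPS domain ratings
(low/moderate/high/unclear; unclear pools with moderate). A study is
classified high-risk when ≥ 5 of 6 domains are high, moderate-risk when
≥ 4 of 6 domains are moderate or worse, low-risk when ≥ 4 are low. Body
rating: very serious if most studies are high-risk, serious if most are
moderate-or-worse, no concern otherwise.

**Inconsistency.** A single-study body always downgrades (the literature
is not established). If the reviewer explicitly recorded that
between-study differences are *not* clinically meaningful, statistical
heterogeneity is not acted on. Otherwise, with a meta-analysis, serious
inconsistency requires at least two of three signals: (a) point
estimates on both sides of the null with minimal CI overlap (minimum
pairwise overlap fraction < 0.10 — the framework names no number, so
this operationalization is configurable), (b) heterogeneity-test
p < 0.05, (c) I² ≥ 50%. In a narrative synthesis, serious means the
reported directions vary across studies — a study reporting "no
association" without an estimate counts as a differing result class —
while CIs overlap minimally or are unavailable. Significant effects in
opposite directions with disjoint intervals are very serious in either
mode. Requiring two of the three statistical signals keeps the false-flag
rate under homogeneity low (< 10% in the shipped simulation at τ = 0,
k = 10) while detecting genuine heterogeneity (> 80% at τ = 1).

**Indirectness.** Serious when a majority of studies carry any of the
population/factor/outcome flags; very serious when a majority are
flagged on two or more dimensions. The rationale names the dimensions.

**Imprecision.** Per-study sample-size adequacy = an a-priori
justification, or ≥ 10 outcome events per candidate prognostic variable
(dichotomous outcomes), or ≥ 100 endpoint cases (continuous or
indeterminable). A study's interval is excessively wide when it contains
the null and reaches both the appreciable-risk and
appreciable-protection regions (the moderate-effect thresholds). A study
is *imprecise* only when both inadequate and wide; a study reporting no
interval cannot be judged at all. The body downgrades only when most
studies are imprecise AND there are few studies (≤ 3) AND few total
participants (< 400, an engine keyword); if the majority of studies are
precise the body is never downgraded, regardless of size. When no study
reports enough to judge, the rating is `unclear` (recorded, no delta).
When a dichotomous study fails the events-per-variable rule while its
event count would satisfy the 100-case rule, the rationale carries an
explicit rule-of-thumb-conflict note instead of silently picking a side.

**Publication bias.** With no registry for prognosis research, serious
by default. Exempt when the factor has been repetitively investigated —
at least 4 studies, the smallest count consistent with the published
worked rows (the 4-study row exempt, every 2–3-study row downgraded).
When the repetition is purely phase-1, the rationale records that the
body is not downgraded a second time for phase alone.

**Effect size.** Magnitude rules of thumb: OR (and RR/HR) moderate at
2.5, large at 4.25, judged on m = max(point, 1/point) so protective
effects classify by reciprocal; SMD moderate at 0.5, large at 0.8 on
|point|. Meta mode upgrades when the pooled estimate is moderate or
large; narrative mode when a strict majority of studies report
same-direction moderate-or-large effects. Collective judgment calls
(e.g. upgrading on a large-plus-small pair) are supported as recorded
overrides, never as silent rule bends.

**Exposure-response gradient.** Present when every study reporting ≥ 3
exposure levels shows a strictly monotone effect series (tolerance 0 by
default) and the directions agree across studies; `not_applicable` when
no study reports exposure levels.

**Overrides.** Any factor's rating may be overridden by the review team
with a mandatory justification; the assessment is marked `overridden`
and the justification becomes its rationale and footnote.

## Meta-analytic machinery

Ratio measures are analysed on the natural-log scale (null at 0); SMDs
on their own scale (null at 0). Mixing the two families in one body is a
validation error. Standard errors are recovered from reported CIs as
(log-)width / 2z, with z from the standard normal quantile of the
stated confidence level (1.959964 at 95%). Pooling is inverse-variance;
the random-effects model is DerSimonian–Laird,
τ² = max(0, (Q − df)/(Σw − Σw²/Σw)), chosen as the field's conventional
closed-form estimator (alternatives are out of scope). Q, its
chi-square p-value and I² = max(0, (Q − df)/Q) × 100 are always reported
from the fixed-effect weights. 2×2 tables use the Woolf odds-ratio
estimator with a +0.5 continuity correction on every cell when any cell
is zero; a fully zero margin is an error.

## Synthetic bodies

The generator emulates the statistical structure the inconsistency and
imprecision rules assume: per study, a true log odds ratio
θᵢ ~ Normal(true_theta, τ²); the cohort splits into exposed/unexposed
halves; events are binomial with a logistic link (unexposed at the
baseline risk, exposed at baseline odds × exp(θᵢ)); the observed table
yields the study's Woolf OR and CI. Defaults — 2,000 participants per
study, 30% baseline risk — reflect the large school-cohort scale typical
of pediatric pain prognosis. Phase, risk-of-bias domains and
indirectness flags are drawn from explicit profiles; all randomness
flows from the scenario seed, with no global state.

What the generator does *not* emulate: selective reporting and
within-study covariate adjustment (all generated estimates are
univariate), attrition, time-to-event outcomes, correlated cohorts, or
measurement heterogeneity across instruments. Passing the simulation
suite therefore shows the engine behaves correctly under the assumed
sampling model, not that real extraction sheets are free of those
complications.

Shipped presets (fixed seeds) plant known truths: `homogeneous-null`,
`homogeneous-large-effect`, `heterogeneous` (τ = 0.3, k = 30),
`single-small-study`, `gradient-present` (ORs 1.2/1.7/2.1 over doses
1/3/5), `phase2-clean`. The test suite verifies each preset's planted
outcome, DerSimonian–Laird τ recovery (median within 25% of truth over
200 replicates), nominal 93–97% coverage of the fixed-effect CI at
τ = 0 (500 replicates), and 3–8% type-I error of the Q test — problem
sizes chosen so the whole suite runs in seconds on one CPU.

## Numerical and degenerate-input choices

- I² is capped strictly below 100 (it is a limit, not an attainable value).
- Zero-width intervals in the overlap diagnostic count as fully
  overlapping when contained in the partner interval, else disjoint;
  touching intervals are not disjoint but overlap fraction 0.
- A study whose only estimate lacks a CI contributes direction (by point)
  but neither pooling weight nor overlap information.
- Homogeneous inputs (Q ≤ df) floor τ² at exactly 0, making the random-
  and fixed-effect pools coincide.
- `validate_body` reports findings rather than raising, so ill-formed
  extraction sheets can be listed in full; `grade()` refuses to run on a
  body with findings.
- Serialization is canonical JSON with absent fields omitted (never
  zero-filled); round-trips are byte-identical.

## Input schema

JSON/YAML documents mirror the type definitions in
`prognograde.model` (`BodyOfEvidence` → `StudyRecord` → `EffectEstimate`
/ `RiskOfBiasProfile`); unknown keys are rejected with field-level
diagnostics. The per-study CSV alternative uses one row per study with
the body-level columns (`factor_name`, `outcome_name`,
`synthesis_mode`) repeated, one univariate and one multivariate effect
block per row (`uni_point`, `uni_ci_low`, … / `multi_*`), and does not
carry exposure-level series (use JSON/YAML for those). Narrative
vote-count columns and cohort identifiers are extracted inputs,
reproduced verbatim in the summary-of-findings table — blank cells mean
"not reported", never zero.

## Known limitations

- Phase classification, QUIPS item-level scoring and vote counts are
  inputs; the package does not infer them from study text.
- The narrative inconsistency rule counts a "no association" report as a
  differing result; a review team that judges such a pattern consistent
  should record an override, which the table footnotes will surface.
- No funnel-plot or regression-based publication-bias statistics: the
  framework's rule is count-based by design.
- No across-outcome aggregation or strength-of-recommendation grading.
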