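# prognograde

Grading the quality of a body of evidence about a **prognostic factor** —
a measurement associated with the subsequent course of an existing health
condition — is harder than grading intervention evidence: the primary
studies are observational cohorts of varying maturity, effect estimates
are often incompletely reported, and no trial registry exists to rule out
publication bias. `prognograde` implements an adapted GRADE framework for
exactly this setting, as a deterministic, fully auditable grading engine
for systematic reviewers of prognosis research.

One *body of evidence* is everything a review found about one factor for
one outcome. Grading starts from the **phase of investigation** — a
majority of confirmatory/explanatory (phase 2/3) cohorts starts the body
at *high* (level 4, `++++`), a majority of hypothesis-generating phase-1
studies at *moderate* (level 3, `+++`) — and then applies five downgrade
factors and two upgrade factors:

| factor | rule (defaults) |
|---|---|
| study limitations | QUIPS six-domain risk-of-bias aggregation; −1 if most studies are at moderate/unclear risk for most domains, −2 if most are high-risk in almost all domains |
| inconsistency | Cochran's Q test, I² ≥ 50%, direction straddling the null with minimal CI overlap; single-study bodies always downgrade |
| indirectness | population / factor / outcome flags; −1 if a majority of studies carry any, −2 if a majority are indirect on two or more dimensions |
| imprecision | ≥ 10 outcome events per candidate variable (dichotomous) or ≥ 100 endpoint cases; intervals spanning the null plus both appreciable regions; "Unclear" when nothing is reported |
| publication bias | downgrade by default; exempt once ≥ 4 cohorts investigated the factor |
| moderate/large effect | +1 when the pooled (or majority-reported) effect reaches OR 2.5 / SMD 0.5 (moderate) or OR 4.25 / SMD 0.8 (large) |
| exposure-response gradient | +1 for a strictly monotone dose-effect series, consistent across the studies that report one |

The final level is `clamp(start + Σ deltas, 1, 4)`; every judgment is a
ledger entry with a machine-generated rationale, and reviewer overrides
(with mandatory justification) take precedence anywhere. Meta-analytic
diagnostics (inverse-variance pooling, DerSimonian–Laird τ², Q, I²) are
computed internally; results render as the adapted summary-of-findings
table in meta-analysis or narrative layout.

## Worked example

```python
from prognograde import (BodyOfEvidence, EffectEstimate, GradeModel,
                         RiskOfBiasProfile, StudyRecord)

rob = RiskOfBiasProfile(study_participation="moderate", study_attrition="moderate",
                        prognostic_factor_measurement="moderate", outcome_measurement="low",
                        confounding="moderate", analysis="low")
studies = [
    StudyRecord(study_id=sid, phase=1, n_participants=n, n_events=ev,
                n_prognostic_variables=6, rob=rob, vote_univariate=vote,
                effects=[EffectEstimate(measure="OR", point=o, ci_low=lo, ci_high=hi)])
    for sid, n, ev, o, lo, hi, vote in [
        ("stanford-2008", 800, 240, 2.8, 2.0, 3.9, "positive"),
        ("monastero-2006", 900, 270, 2.6, 1.9, 3.6, "positive"),
        ("termine-2004", 700, 210, 3.0, 2.1, 4.3, "positive"),
        ("wang-2007", 800, 240, 1.6, 0.9, 2.3, "null"),
    ]
]
body = BodyOfEvidence(factor_name="Female sex", outcome_name="Headache persistence",
                      studies=studies, synthesis_mode="narrative")
res = GradeModel(body).fit()
print(res.summary())
```

```
                      Adapted GRADE quality of evidence
==============================================================================
Prognostic factor: Female sex
Outcome:           Headache persistence
Studies: 4   Participants: 3200   Synthesis: narrative
------------------------------------------------------------------------------
factor              rating           delta  rationale
------------------------------------------------------------------------------
phase               not_applicable      +0  4/4 studies are phase 1 (hypothesis-gener...
study_limitations   serious             -1  most evidence is from studies at moderate...
inconsistency       no_concern          +0  directions vary but confidence intervals ...
indirectness        no_concern          +0  study populations, factors and outcomes r...
imprecision         no_concern          +0  the majority of studies are precise (or t...
publication_bias    no_concern          +0  factor repetitively investigated (4 studi...
effect_size         present             +1  3/4 studies report same-direction moderat...
dose_response       not_applicable      +0  no study reports effects at multiple expo...
------------------------------------------------------------------------------
Starting level: 3   Final level: 3 (moderate, +++)
Footnotes:
  [1] study_limitations: most evidence is from studies at moderate or unclear risk of bias for most QUIPS domains (4 moderate-risk)
==============================================================================
```

Reading: four phase-1 cohorts start at moderate; pervasive moderate risk
of bias costs one level; four cohorts lift the publication-bias default;
three of four studies report same-direction moderate effects, earning the
effect-size upgrade — net `3 − 1 + 1 = 3`, moderate quality (`+++`).

A command-line interface wraps the same machinery:

```bash
prognograde grade --layout narrative bodies/*.yaml   # summary-of-findings table
prognograde check body.yaml                          # validation findings only
prognograde thresholds                               # effective rule-of-thumb config
prognograde simulate --preset heterogeneous          # synthetic body with known truth
```

Body documents are JSON/YAML (one body per document) or per-study CSV;
see `docs/methods.md` for the schema, rule details and design choices.

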