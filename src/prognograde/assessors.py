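"""Rule-based assessors, one per GRADE factor.

Each assessor inspects the body of evidence (and, for meta-analytic
bodies, the pooled result) and returns a :class:`FactorAssessment` with a
machine-generated rationale. Reviewer overrides recorded on the body take
precedence over every rule and are marked as such.

Numeric rules of thumb live in :class:`Thresholds`; the shipped defaults
are the field's conventional cut-offs: odds ratio 2.5 / 4.25 and SMD
0.5 / 0.8 for moderate / large effects, I-squared 50% for substantial
heterogeneity, 10 outcome events per candidate prognostic variable, and
100 endpoint cases for continuous (or indeterminable) outcomes.
"""

from __future__ import annotations

from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import meta
from .model import (
    DOWNGRADE_FACTORS,
    UPGRADE_FACTORS,
    BodyOfEvidence,
    EffectEstimate,
    FactorAssessment,
    StudyRecord,
)

#: Level deltas by rating; serious/very-serious magnitudes follow the
#: intervention-GRADE convention (-1 / -2) and can be overridden per call.
DEFAULT_DELTAS: dict[str, int] = {"serious": -1, "very_serious": -2, "present": 1}

#: Participant floor below which a small narrative body supports an
#: across-study imprecision downgrade (used with `few_studies`).
DEFAULT_SMALL_BODY_PARTICIPANTS = 400


class Thresholds(BaseModel):
    """Tunable rule-of-thumb cut-offs consumed by the assessors."""

    model_config = ConfigDict(extra="forbid")

    or_moderate: float = Field(default=2.5, gt=0)
    or_large: float = Field(default=4.25, gt=0)
    smd_moderate: float = Field(default=0.5, gt=0)
    smd_large: float = Field(default=0.8, gt=0)
    i2_substantial: float = Field(default=50.0, ge=0, lt=100)
    events_per_variable: float = Field(default=10.0, gt=0)
    continuous_endpoint_cases: int = Field(default=100, gt=0)
    min_studies_no_pub_bias: int = Field(default=4, ge=1)
    few_studies: int = Field(default=3, ge=1)
    overlap_minimal: float = Field(default=0.10, ge=0, le=1)
    rob_majority: float = Field(default=0.5, ge=0, lt=1)

    @model_validator(mode="after")
    def _ordered(self) -> "Thresholds":
        if self.or_large < self.or_moderate:
            raise ValueError("or_large must be >= or_moderate")
        if self.smd_large < self.smd_moderate:
            raise ValueError("smd_large must be >= smd_moderate")
        return self


def rating_delta(rating: str, deltas: Optional[dict[str, int]] = None) -> int:
    table = DEFAULT_DELTAS if deltas is None else {**DEFAULT_DELTAS, **deltas}
    return table.get(rating, 0)


def _assessment(
    factor: str,
    rating: str,
    rationale: str,
    deltas: Optional[dict[str, int]] = None,
    overridden: bool = False,
) -> FactorAssessment:
    return FactorAssessment(
        factor=factor,
        rating=rating,
        level_delta=rating_delta(rating, deltas),
        rationale=rationale,
        overridden=overridden,
    )


def _override(
    body: BodyOfEvidence, factor: str, deltas: Optional[dict[str, int]] = None
) -> Optional[FactorAssessment]:
    ov = body.overrides.get(factor)
    if ov is None:
        return None
    return _assessment(
        factor,
        ov.rating,
        f"reviewer override: {ov.justification}",
        deltas,
        overridden=True,
    )


def _weights(studies: Sequence[StudyRecord], weighting: str) -> list[float]:
    if weighting == "participants":
        return [float(s.n_participants) for s in studies]
    if weighting == "count":
        return [1.0] * len(studies)
    raise ValueError(f"unknown weighting {weighting!r}")


def _majority(part: float, total: float, frac: float) -> bool:
    """Strict majority: more than `frac` of the total weight."""
    return part > frac * total


# ---------------------------------------------------------------------------
# starting level


def starting_level(body: BodyOfEvidence) -> tuple[int, str]:
    """Starting quality level from the phase-of-investigation mix.

    Confirmatory / explanatory evidence (a strict majority of phase-2/3
    studies) starts high (4); hypothesis-generating phase-1 evidence starts
    moderate (3). Ties break conservatively to the lower start.
    """
    k = body.k
    n23 = sum(1 for s in body.studies if s.phase in (2, 3))
    if n23 > k / 2:
        return 4, (
            f"{n23}/{k} studies are phase 2/3 (confirmatory or explanatory); "
            "starting level high"
        )
    return 3, (
        f"{k - n23}/{k} studies are phase 1 (hypothesis-generating, vulnerable "
        "to false positives); starting level moderate"
    )


# ---------------------------------------------------------------------------
# downgrade factors


def _rob_class(study: StudyRecord) -> str:
    ratings = study.rob.ratings()
    n_high = sum(1 for r in ratings if r == "high")
    n_mod_worse = sum(1 for r in ratings if r in ("moderate", "unclear", "high"))
    n_low = sum(1 for r in ratings if r == "low")
    if n_high >= 5:  # "almost all of the domains"
        return "high"
    if n_mod_worse > 3:  # most of the six domains
        return "moderate"
    if n_low > 3:
        return "low"
    return "mixed"


def assess_study_limitations(
    body: BodyOfEvidence,
    thresholds: Optional[Thresholds] = None,
    weighting: str = "count",
    deltas: Optional[dict[str, int]] = None,
) -> FactorAssessment:
    """QUIPS-domain aggregation across studies.

    A study is at high overall risk when >= 5 of its 6 domains are high; at
    moderate overall risk when most domains are moderate/unclear (or worse);
    at low overall risk when most domains are low. The body has very serious
    limitations when most evidence comes from high-risk studies, serious
    limitations when most comes from moderate-or-worse studies, and no
    concern otherwise. 'Most' is a strict majority (by study count, or by
    participants when weighting='participants').
    """
    if ov := _override(body, "study_limitations", deltas):
        return ov
    th = thresholds or Thresholds()
    classes = [_rob_class(s) for s in body.studies]
    w = _weights(body.studies, weighting)
    total = sum(w)
    w_high = sum(wi for wi, c in zip(w, classes) if c == "high")
    w_mod_worse = sum(wi for wi, c in zip(w, classes) if c in ("high", "moderate"))
    counts = ", ".join(
        f"{classes.count(c)} {c}-risk" for c in ("low", "moderate", "high", "mixed")
        if classes.count(c)
    )
    if _majority(w_high, total, th.rob_majority):
        return _assessment(
            "study_limitations",
            "very_serious",
            f"most evidence is from studies at high risk of bias in almost all "
            f"QUIPS domains ({counts})",
            deltas,
        )
    if _majority(w_mod_worse, total, th.rob_majority):
        return _assessment(
            "study_limitations",
            "serious",
            f"most evidence is from studies at moderate or unclear risk of bias "
            f"for most QUIPS domains ({counts})",
            deltas,
        )
    return _assessment(
        "study_limitations",
        "no_concern",
        f"most evidence is from studies at low risk of bias ({counts})",
        deltas,
    )


def _study_direction(study: StudyRecord) -> str:
    """risk / protective / null_or_unknown, using CI significance when available."""
    e = study.preferred_effect()
    if e is None:
        return "null_or_unknown"
    null = e.null_value
    if e.has_ci:
        if e.ci_low > null:
            return "risk"
        if e.ci_high < null:
            return "protective"
        return "null_or_unknown"
    if e.point > null:
        return "risk"
    if e.point < null:
        return "protective"
    return "null_or_unknown"


def _usable_log_effects(body: BodyOfEvidence) -> list[meta.LogEffect]:
    out = []
    for s in body.studies:
        e = s.preferred_effect()
        if e is not None and e.has_ci:
            try:
                out.append(meta.to_log_effect(e, study_id=s.study_id))
            except (meta.PrecisionUnavailable, ValueError):
                continue
    return out


def assess_inconsistency(
    body: BodyOfEvidence,
    pooled: Optional[meta.PooledResult] = None,
    thresholds: Optional[Thresholds] = None,
    deltas: Optional[dict[str, int]] = None,
) -> FactorAssessment:
    """Unexplained heterogeneity or variability of results across studies.

    A single-study body always downgrades: one estimate is an indicator
    that the literature is not well established, not evidence of
    consistency. With a meta-analysis, serious inconsistency needs at least
    two of three statistical signals (direction straddles the null with
    minimal CI overlap; heterogeneity test p < 0.05; I-squared at or above
    the substantial cut-off) — and is vetoed if the reviewer judged the
    between-study differences not clinically meaningful. Without a
    meta-analysis, serious inconsistency means the reported directions vary
    across studies while the CIs overlap minimally or are unavailable.
    Opposite significant directions with disjoint intervals are very
    serious in either mode.
    """
    if ov := _override(body, "inconsistency", deltas):
        return ov
    th = thresholds or Thresholds()
    if body.k == 1:
        return _assessment(
            "inconsistency",
            "serious",
            "single study: the literature is not well established in this area",
            deltas,
        )
    if body.clinical_meaningfulness_of_differences is False:
        return _assessment(
            "inconsistency",
            "no_concern",
            "between-study differences judged not clinically meaningful by "
            "the review team; statistical heterogeneity not acted on",
            deltas,
        )
    les = _usable_log_effects(body)
    overlap = meta.ci_overlap_profile(les) if len(les) >= 2 else None
    directions = [_study_direction(s) for s in body.studies]
    sig_straddle = "risk" in directions and "protective" in directions

    if sig_straddle and overlap is not None and overlap.any_disjoint:
        return _assessment(
            "inconsistency",
            "very_serious",
            "significant effects on both sides of the line of no effect with "
            "disjoint confidence intervals",
            deltas,
        )

    if body.synthesis_mode == "meta_analysis" and pooled is not None:
        split = meta.effect_direction_split(les) if les else None
        s_overlap = (
            split is not None
            and split.straddles_null
            and overlap is not None
            and overlap.min_pairwise_overlap_fraction < th.overlap_minimal
        )
        s_qtest = pooled.p_heterogeneity < 0.05
        s_i2 = pooled.i_squared >= th.i2_substantial
        n_signals = sum([s_overlap, s_qtest, s_i2])
        detail = (
            f"signals: straddle+minimal overlap={s_overlap}, "
            f"Q-test p={pooled.p_heterogeneity:.3g} (<0.05: {s_qtest}), "
            f"I2={pooled.i_squared:.1f}% (>= {th.i2_substantial:g}%: {s_i2})"
        )
        if n_signals >= 2:
            return _assessment(
                "inconsistency", "serious", f"unexplained heterogeneity; {detail}", deltas
            )
        return _assessment(
            "inconsistency", "no_concern", f"no material heterogeneity; {detail}", deltas
        )

    # narrative synthesis
    varies = len(set(directions)) > 1
    if varies:
        if overlap is None:
            return _assessment(
                "inconsistency",
                "serious",
                "results vary in direction across studies and confidence "
                "intervals are unavailable to judge overlap",
                deltas,
            )
        if overlap.min_pairwise_overlap_fraction < th.overlap_minimal:
            return _assessment(
                "inconsistency",
                "serious",
                "results vary in direction across studies with minimal or no "
                f"confidence-interval overlap (min pairwise fraction "
                f"{overlap.min_pairwise_overlap_fraction:.2f})",
                deltas,
            )
    return _assessment(
        "inconsistency",
        "no_concern",
        "reported directions are consistent across studies"
        if not varies
        else "directions vary but confidence intervals overlap substantially",
        deltas,
    )


def assess_indirectness(
    body: BodyOfEvidence,
    thresholds: Optional[Thresholds] = None,
    weighting: str = "count",
    deltas: Optional[dict[str, int]] = None,
) -> FactorAssessment:
    """Population / factor / outcome representativeness of the review question."""
    if ov := _override(body, "indirectness", deltas):
        return ov
    th = thresholds or Thresholds()
    w = _weights(body.studies, weighting)
    total = sum(w)
    n_flags = [len(s.indirectness_flags) for s in body.studies]
    w_any = sum(wi for wi, n in zip(w, n_flags) if n >= 1)
    w_two = sum(wi for wi, n in zip(w, n_flags) if n >= 2)
    dims = sorted({d for s in body.studies for d in s.indirectness_flags})
    if _majority(w_two, total, th.rob_majority):
        return _assessment(
            "indirectness",
            "very_serious",
            f"most studies are indirect on two or more dimensions ({', '.join(dims)})",
            deltas,
        )
    if _majority(w_any, total, th.rob_majority):
        return _assessment(
            "indirectness",
            "serious",
            f"most studies do not fully represent the review question "
            f"(indirect in: {', '.join(dims)})",
            deltas,
        )
    return _assessment(
        "indirectness",
        "no_concern",
        "study populations, factors and outcomes represent the review question",
        deltas,
    )


def _sample_size_adequate(s: StudyRecord, th: Thresholds) -> tuple[Optional[bool], str]:
    """Adequacy of a study's sample size, with the rule actually applied."""
    if s.sample_size_justified:
        return True, "sample size justified a priori"
    if (
        s.outcome_type == "dichotomous"
        and s.n_events is not None
        and s.n_prognostic_variables is not None
    ):
        required = th.events_per_variable * s.n_prognostic_variables
        ok = s.n_events >= required
        note = (
            f"{s.n_events} events / {s.n_prognostic_variables} variables "
            f"{'meets' if ok else 'fails'} the {th.events_per_variable:g} "
            f"events-per-variable rule (requires {required:g})"
        )
        if not ok and s.n_events >= th.continuous_endpoint_cases:
            note += (
                f"; note rule-of-thumb conflict: {s.n_events} events would meet "
                f"the {th.continuous_endpoint_cases}-endpoint-case rule"
            )
        return ok, note
    if s.n_events is not None:
        ok = s.n_events >= th.continuous_endpoint_cases
        return ok, (
            f"{s.n_events} cases reaching endpoint "
            f"{'meets' if ok else 'fails'} the {th.continuous_endpoint_cases}-case rule"
        )
    return None, "sample-size adequacy indeterminable (no event/endpoint count)"


def _ci_wide(e: EffectEstimate, th: Thresholds) -> bool:
    """CI contains the null and reaches both appreciable-effect regions."""
    if not e.has_ci:
        return True
    if e.is_ratio:
        return e.ci_low <= 1.0 / th.or_moderate and e.ci_high >= th.or_moderate
    return e.ci_low <= -th.smd_moderate and e.ci_high >= th.smd_moderate


def assess_imprecision(
    body: BodyOfEvidence,
    pooled: Optional[meta.PooledResult] = None,
    thresholds: Optional[Thresholds] = None,
    required_meta_n: Optional[int] = None,
    small_body_participants: int = DEFAULT_SMALL_BODY_PARTICIPANTS,
    weighting: str = "count",
    deltas: Optional[dict[str, int]] = None,
) -> FactorAssessment:
    """Random error in the body of evidence.

    Meta-analysis mode looks at the pooled interval (serious when it spans
    the null together with both appreciable-risk and appreciable-protection
    regions, or when the pooled sample falls short of a reviewer-supplied
    required size). Narrative mode judges each study: a study is imprecise
    when its sample size is inadequate (not justified, and failing the
    events-per-variable or endpoint-case rule) AND its interval is
    excessively wide; studies reporting no interval at all cannot be judged.
    If the majority of studies are precise the body is never downgraded,
    regardless of how few studies there are. When no study reports enough
    to judge, the rating is 'unclear' (recorded, no level change).
    """
    if ov := _override(body, "imprecision", deltas):
        return ov
    th = thresholds or Thresholds()

    if body.synthesis_mode == "meta_analysis" and pooled is not None:
        m = body.measure()
        ratio = m in meta.RATIO_MEASURES if m else True
        import math

        if ratio:
            wide = pooled.ci_low <= -math.log(th.or_moderate) and pooled.ci_high >= math.log(
                th.or_moderate
            )
        else:
            wide = pooled.ci_low <= -th.smd_moderate and pooled.ci_high >= th.smd_moderate
        if wide:
            return _assessment(
                "imprecision",
                "serious",
                "pooled confidence interval includes the null and both "
                "appreciable risk and appreciable protection",
                deltas,
            )
        if required_meta_n is not None and pooled.total_n < required_meta_n:
            return _assessment(
                "imprecision",
                "serious",
                f"pooled sample ({pooled.total_n}) falls short of the required "
                f"meta-analysis size ({required_meta_n})",
                deltas,
            )
        return _assessment(
            "imprecision",
            "no_concern",
            "pooled estimate is precise",
            deltas,
        )

    # narrative mode: per-study judgment
    statuses: list[str] = []
    notes: list[str] = []
    for s in body.studies:
        e = s.preferred_effect()
        adequate, note = _sample_size_adequate(s, th)
        if e is None or not e.has_ci:
            statuses.append("unknown")
            notes.append(
                f"{s.study_id}: no effect size or confidence interval reported; "
                f"imprecision cannot be judged ({note})"
            )
            continue
        wide = _ci_wide(e, th)
        imprecise = (adequate is not True) and wide
        statuses.append("imprecise" if imprecise else "precise")
        notes.append(f"{s.study_id}: {'imprecise' if imprecise else 'precise'} ({note})")
    detail = "; ".join(notes)
    if all(st == "unknown" for st in statuses):
        return _assessment(
            "imprecision",
            "unclear",
            f"no study reports enough to judge imprecision: {detail}",
            deltas,
        )
    w = _weights(body.studies, weighting)
    total = sum(w)
    w_imprecise = sum(wi for wi, st in zip(w, statuses) if st == "imprecise")
    few = body.k <= th.few_studies
    small = body.total_participants < small_body_participants
    if _majority(w_imprecise, total, th.rob_majority) and few and small:
        return _assessment(
            "imprecision",
            "serious",
            f"most studies are imprecise and the body is small "
            f"({body.k} studies, {body.total_participants} participants): {detail}",
            deltas,
        )
    return _assessment(
        "imprecision",
        "no_concern",
        f"the majority of studies are precise (or the body is not small): {detail}",
        deltas,
    )


def assess_publication_bias(
    body: BodyOfEvidence,
    thresholds: Optional[Thresholds] = None,
    deltas: Optional[dict[str, int]] = None,
) -> FactorAssessment:
    """Default-downgrade rule for unregistered prognosis literature.

    With no study registry for prognosis research, publication bias is
    presumed serious until there is evidence to the contrary. The exemption
    is a factor that has been repetitively investigated — at least
    `min_studies_no_pub_bias` cohorts. When the repetition consists only of
    phase-1 studies (already reflected in the moderate starting level), the
    rationale records that the evidence is not downgraded a second time for
    phase of investigation alone.
    """
    if ov := _override(body, "publication_bias", deltas):
        return ov
    th = thresholds or Thresholds()
    if body.k >= th.min_studies_no_pub_bias:
        rationale = (
            f"factor repetitively investigated ({body.k} studies >= "
            f"{th.min_studies_no_pub_bias}); exemption from the default downgrade"
        )
        if all(s.phase == 1 for s in body.studies):
            rationale += (
                "; all studies are phase 1 — no double-downgrade with phase of "
                "investigation"
            )
        return _assessment("publication_bias", "no_concern", rationale, deltas)
    return _assessment(
        "publication_bias",
        "serious",
        f"prognosis research presumed seriously affected by publication bias "
        f"({body.k} studies < {th.min_studies_no_pub_bias}; no registry evidence "
        f"to the contrary)",
        deltas,
    )


# ---------------------------------------------------------------------------
# upgrade factors


def classify_effect_magnitude(
    e: EffectEstimate, thresholds: Optional[Thresholds] = None
) -> str:
    """small / moderate / large by rules of thumb; boundaries inclusive.

    Ratio measures are judged on m = max(point, 1/point), so protective
    effects are classified by their reciprocal; SMDs on |point|.
    """
    th = thresholds or Thresholds()
    if e.is_ratio:
        if e.point <= 0:
            raise ValueError("ratio measure must be positive")
        m = max(e.point, 1.0 / e.point)
        lo, hi = th.or_moderate, th.or_large
    else:
        m = abs(e.point)
        lo, hi = th.smd_moderate, th.smd_large
    if m >= hi:
        return "large"
    if m >= lo:
        return "moderate"
    return "small"


def assess_effect_size_upgrade(
    body: BodyOfEvidence,
    pooled: Optional[meta.PooledResult] = None,
    thresholds: Optional[Thresholds] = None,
    deltas: Optional[dict[str, int]] = None,
) -> FactorAssessment:
    """Upgrade for a moderate or large (pooled or consistently reported) effect."""
    if ov := _override(body, "effect_size", deltas):
        return ov
    th = thresholds or Thresholds()
    if body.synthesis_mode == "meta_analysis" and pooled is not None:
        import math

        m = body.measure() or "OR"
        point = math.exp(pooled.theta_hat) if m in meta.RATIO_MEASURES else pooled.theta_hat
        mag = classify_effect_magnitude(EffectEstimate(measure=m, point=point), th)
        if mag in ("moderate", "large"):
            return _assessment(
                "effect_size",
                "present",
                f"pooled effect is {mag} ({m} {point:.2f})",
                deltas,
            )
        return _assessment(
            "effect_size", "absent", f"pooled effect is {mag} ({m} {point:.2f})", deltas
        )
    # narrative: strict majority of studies with same-direction moderate/large effects
    qual: list[tuple[str, str]] = []  # (direction, magnitude)
    for s in body.studies:
        e = s.preferred_effect()
        if e is None:
            continue
        mag = classify_effect_magnitude(e, th)
        if mag in ("moderate", "large"):
            direction = "risk" if e.point > e.null_value else "protective"
            qual.append((direction, mag))
    same_direction = len({d for d, _ in qual}) == 1 if qual else False
    if len(qual) > body.k / 2 and same_direction:
        return _assessment(
            "effect_size",
            "present",
            f"{len(qual)}/{body.k} studies report same-direction moderate or "
            "large effects",
            deltas,
        )
    return _assessment(
        "effect_size",
        "absent",
        f"only {len(qual)}/{body.k} studies report same-direction moderate or "
        "large effects"
        if qual
        else "no moderate or large effects reported by a majority of studies",
        deltas,
    )


def assess_dose_response(
    body: BodyOfEvidence,
    deltas: Optional[dict[str, int]] = None,
    tolerance: float = 0.0,
) -> FactorAssessment:
    """Exposure-response gradient consistently present within and across studies."""
    if ov := _override(body, "dose_response", deltas):
        return ov
    reporting = [s for s in body.studies if s.exposure_levels]
    if not reporting:
        return _assessment(
            "dose_response",
            "not_applicable",
            "no study reports effects at multiple exposure levels",
            deltas,
        )
    reports = []
    for s in reporting:
        levels = [(lv.dose, lv.effect.point) for lv in s.exposure_levels]
        reports.append((s.study_id, meta.detect_gradient(levels, tolerance)))
    applicable = [(sid, r) for sid, r in reports if r.applicable]
    if not applicable:
        return _assessment(
            "dose_response",
            "not_applicable",
            "no study reports three or more exposure levels",
            deltas,
        )
    all_gradient = all(r.gradient for _, r in applicable)
    directions = {r.direction for _, r in applicable}
    if all_gradient and len(directions) == 1:
        return _assessment(
            "dose_response",
            "present",
            f"a consistent {directions.pop()} exposure-response gradient is "
            f"present in every study reporting exposure levels "
            f"({len(applicable)} study/studies)",
            deltas,
        )
    return _assessment(
        "dose_response",
        "absent",
        "no consistent monotone exposure-response gradient across studies",
        deltas,
    )
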