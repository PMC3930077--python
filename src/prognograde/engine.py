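"""Combine the starting level and factor assessments into a final grade.

The final level is clamp(starting level + sum of level deltas, 1, 4) —
serious concerns subtract one level, very serious two, and each upgrade
factor present adds one, with the result capped at High and floored at
Very low. The ledger preserves every assessment, in the fixed order the
factors are considered: phase, study limitations, inconsistency,
indirectness, imprecision, publication bias, effect size, dose response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from . import assessors, meta
from .model import (
    DOWNGRADE_FACTORS,
    UPGRADE_FACTORS,
    BodyOfEvidence,
    BodyValidationError,
    FactorAssessment,
    QualityGrade,
    validate_body,
)

ADJUSTABLE_FACTORS: tuple[str, ...] = DOWNGRADE_FACTORS + UPGRADE_FACTORS

_DOWNGRADE_RATINGS = frozenset(
    {"no_concern", "serious", "very_serious", "unclear", "not_applicable"}
)
_UPGRADE_RATINGS = frozenset({"present", "absent", "not_applicable"})


@dataclass(frozen=True)
class GradeLevel:
    level: int
    name: str
    notation: str
    definition: str


#: The four-point quality scale with its standard GRADE confidence meanings.
GRADE_SCALE: tuple[GradeLevel, ...] = (
    GradeLevel(1, "very low", "+", "very little confidence in the effect estimate; "
               "the true effect is likely to be substantially different"),
    GradeLevel(2, "low", "++", "limited confidence in the effect estimate; the true "
               "effect may be substantially different"),
    GradeLevel(3, "moderate", "+++", "moderate confidence; the true effect is likely "
               "close to the estimate but may be substantially different"),
    GradeLevel(4, "high", "++++", "high confidence that the true effect lies close "
               "to the estimate"),
)


def _clamp(level: int) -> int:
    return max(1, min(4, level))


def _finalize(
    start: int, ledger: list[FactorAssessment], footnotes: list[str]
) -> QualityGrade:
    level = _clamp(start + sum(a.level_delta for a in ledger))
    return QualityGrade(
        level=level,
        plus_notation="+" * level,
        starting_level=start,
        ledger=ledger,
        footnotes=footnotes,
    )


def attach_pooled(body: BodyOfEvidence) -> BodyOfEvidence:
    """Compute and attach a DerSimonian-Laird pooled result if missing.

    Only applies to meta-analysis bodies with at least two CI-bearing
    effects; narrative bodies and already-pooled bodies pass through.
    """
    if body.synthesis_mode != "meta_analysis" or body.pooled is not None:
        return body
    les = assessors._usable_log_effects(body)
    if len(les) < 2:
        return body
    pooled = meta.pool_random(les, total_n=body.total_participants)
    return body.model_copy(update={"pooled": pooled})


def grade(
    body: BodyOfEvidence,
    thresholds: Optional[assessors.Thresholds] = None,
    *,
    weighting: str = "count",
    deltas: Optional[dict[str, int]] = None,
    required_meta_n: Optional[int] = None,
    small_body_participants: int = assessors.DEFAULT_SMALL_BODY_PARTICIPANTS,
) -> QualityGrade:
    """Run every assessor on a validated body and combine the results.

    Raises :class:`BodyValidationError` with the findings list when the
    body does not validate cleanly.
    """
    th = thresholds or assessors.Thresholds()
    body = attach_pooled(body)
    findings = validate_body(body)
    if findings:
        raise BodyValidationError(findings)
    start, start_rationale = assessors.starting_level(body)
    ledger: list[FactorAssessment] = [
        FactorAssessment(
            factor="phase", rating="not_applicable", level_delta=0,
            rationale=start_rationale,
        )
    ]
    pooled = body.pooled
    ledger.append(
        assessors.assess_study_limitations(body, th, weighting=weighting, deltas=deltas)
    )
    ledger.append(assessors.assess_inconsistency(body, pooled, th, deltas=deltas))
    ledger.append(
        assessors.assess_indirectness(body, th, weighting=weighting, deltas=deltas)
    )
    ledger.append(
        assessors.assess_imprecision(
            body,
            pooled,
            th,
            required_meta_n=required_meta_n,
            small_body_participants=small_body_participants,
            weighting=weighting,
            deltas=deltas,
        )
    )
    ledger.append(assessors.assess_publication_bias(body, th, deltas=deltas))
    ledger.append(assessors.assess_effect_size_upgrade(body, pooled, th, deltas=deltas))
    ledger.append(assessors.assess_dose_response(body, deltas=deltas))
    footnotes = [
        f"{a.factor}: {a.rationale}"
        for a in ledger
        if a.rating in ("serious", "very_serious", "unclear") or a.overridden
    ]
    return _finalize(start, ledger, footnotes)


def grade_from_flags(
    start: int,
    flags: Mapping[str, str],
    deltas: Optional[dict[str, int]] = None,
) -> QualityGrade:
    """Grade directly from per-factor ratings, bypassing the assessors.

    ``flags`` must rate all seven adjustable factors (study_limitations,
    inconsistency, indirectness, imprecision, publication_bias,
    effect_size, dose_response). Identical arithmetic to :func:`grade`.
    """
    if start not in (1, 2, 3, 4):
        raise ValueError(f"starting level must be 1..4, got {start}")
    unknown = set(flags) - set(ADJUSTABLE_FACTORS)
    if unknown:
        raise ValueError(f"unknown factor key(s): {sorted(unknown)}")
    missing = set(ADJUSTABLE_FACTORS) - set(flags)
    if missing:
        raise ValueError(f"missing factor rating(s): {sorted(missing)}")
    ledger: list[FactorAssessment] = []
    for factor in ADJUSTABLE_FACTORS:
        rating = flags[factor]
        valid = _DOWNGRADE_RATINGS if factor in DOWNGRADE_FACTORS else _UPGRADE_RATINGS
        if rating not in valid:
            raise ValueError(f"invalid rating {rating!r} for factor {factor!r}")
        ledger.append(
            FactorAssessment(
                factor=factor,
                rating=rating,
                level_delta=assessors.rating_delta(rating, deltas),
                rationale="rating supplied directly",
            )
        )
    return _finalize(start, ledger, [])
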