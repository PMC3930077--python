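"""Domain types for bodies of prognostic evidence.

A *body of evidence* is everything a review has found about one prognostic
factor for one outcome: per-study effect estimates, QUIPS risk-of-bias
domain ratings, indirectness flags and optional exposure-level series,
plus the synthesis mode (meta-analysis or narrative) and any reviewer
overrides of individual GRADE factor judgments.

Structural constraints (types, enumerations, ranges, the six QUIPS
domains) are enforced at construction by pydantic; content invariants that
a real extraction sheet may violate (CI ordering, event counts, dose
ordering, ratio positivity) are *findings* from :func:`validate_body`, so
that an ill-formed body can still be represented and reported on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .meta import RATIO_MEASURES, PooledResult

logger = logging.getLogger(__name__)

Measure = Literal["OR", "RR", "HR", "SMD"]
RobRating = Literal["low", "moderate", "high", "unclear"]
FactorName = Literal[
    "phase",
    "study_limitations",
    "inconsistency",
    "indirectness",
    "imprecision",
    "publication_bias",
    "effect_size",
    "dose_response",
]
Rating = Literal[
    "no_concern",
    "serious",
    "very_serious",
    "unclear",
    "not_applicable",
    "absent",
    "present",
]

DOWNGRADE_FACTORS: tuple[str, ...] = (
    "study_limitations",
    "inconsistency",
    "indirectness",
    "imprecision",
    "publication_bias",
)
UPGRADE_FACTORS: tuple[str, ...] = ("effect_size", "dose_response")

QUIPS_DOMAINS: tuple[str, ...] = (
    "study_participation",
    "study_attrition",
    "prognostic_factor_measurement",
    "outcome_measurement",
    "confounding",
    "analysis",
)


class EffectEstimate(BaseModel):
    """A point estimate on a named measure scale with its confidence interval.

    ``adjusted`` distinguishes multivariate (covariate-adjusted) from
    univariate estimates; ``n_covariates`` counts the co-variables in the
    model that produced it. CI bounds may be absent — many prognosis
    studies report only a point estimate or a bare significance claim.
    """

    model_config = ConfigDict(extra="forbid")

    measure: Measure
    point: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_level: float = Field(default=0.95, gt=0.0, lt=1.0)
    adjusted: bool = False
    n_covariates: int = Field(default=0, ge=0)

    @property
    def is_ratio(self) -> bool:
        return self.measure in RATIO_MEASURES

    @property
    def null_value(self) -> float:
        """The line of no effect: 1 for ratio measures, 0 for SMD."""
        return 1.0 if self.is_ratio else 0.0

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None and self.ci_high is not None


class RiskOfBiasProfile(BaseModel):
    """QUIPS domain-level risk-of-bias ratings (exactly six, one per domain)."""

    model_config = ConfigDict(extra="forbid")

    study_participation: RobRating
    study_attrition: RobRating
    prognostic_factor_measurement: RobRating
    outcome_measurement: RobRating
    confounding: RobRating
    analysis: RobRating

    @classmethod
    def uniform(cls, rating: RobRating) -> "RiskOfBiasProfile":
        return cls(**{d: rating for d in QUIPS_DOMAINS})

    def ratings(self) -> tuple[RobRating, ...]:
        return tuple(getattr(self, d) for d in QUIPS_DOMAINS)


class ExposureLevel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dose: float
    effect: EffectEstimate


class StudyRecord(BaseModel):
    """One primary study's extracted evidence for the factor-outcome pair."""

    model_config = ConfigDict(extra="forbid")

    study_id: str
    phase: Literal[1, 2, 3]
    design: Literal["prospective_cohort", "retrospective_cohort"] = "prospective_cohort"
    n_participants: int = Field(gt=0)
    n_events: Optional[int] = Field(default=None, ge=0)
    n_prognostic_variables: Optional[int] = Field(default=None, gt=0)
    outcome_type: Literal["dichotomous", "continuous"] = "dichotomous"
    sample_size_justified: bool = False
    effects: list[EffectEstimate] = Field(default_factory=list)
    rob: RiskOfBiasProfile
    indirect_population: bool = False
    indirect_factor: bool = False
    indirect_outcome: bool = False
    exposure_levels: Optional[list[ExposureLevel]] = None
    # Extracted presentation inputs (summary-of-findings tables), never recomputed:
    cohort_id: Optional[str] = None
    vote_univariate: Optional[Literal["positive", "null", "negative"]] = None
    vote_multivariate: Optional[Literal["positive", "null", "negative"]] = None

    def preferred_effect(self) -> Optional[EffectEstimate]:
        """Single estimate for this study: multivariate preferred.

        Falls back to the univariate estimate (with a logged warning) when
        no covariate-adjusted estimate was reported; None when the study
        reported no estimate at all.
        """
        if not self.effects:
            return None
        adjusted = [e for e in self.effects if e.adjusted]
        if adjusted:
            return adjusted[0]
        logger.warning(
            "study %s: no multivariate estimate; falling back to univariate",
            self.study_id,
        )
        return self.effects[0]

    @property
    def indirectness_flags(self) -> tuple[str, ...]:
        return tuple(
            name
            for name, flag in (
                ("population", self.indirect_population),
                ("factor", self.indirect_factor),
                ("outcome", self.indirect_outcome),
            )
            if flag
        )


class Override(BaseModel):
    """Reviewer override of one factor's rating; justification is mandatory."""

    model_config = ConfigDict(extra="forbid")

    rating: Rating
    justification: str


class BodyOfEvidence(BaseModel):
    """Factor x outcome collection of studies plus synthesis context."""

    model_config = ConfigDict(extra="forbid")

    factor_name: str
    outcome_name: str
    studies: list[StudyRecord] = Field(min_length=1)
    synthesis_mode: Literal["meta_analysis", "narrative"] = "narrative"
    pooled: Optional[PooledResult] = None
    clinical_meaningfulness_of_differences: Optional[bool] = None
    overrides: dict[str, Override] = Field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def total_participants(self) -> int:
        return sum(s.n_participants for s in self.studies)

    @property
    def n_cohorts(self) -> int:
        ids = [s.cohort_id for s in self.studies]
        if any(i is None for i in ids):
            return len(self.studies)
        return len(set(ids))

    def measure(self) -> Optional[str]:
        for s in self.studies:
            for e in s.effects:
                return e.measure
        return None


class FactorAssessment(BaseModel):
    """One GRADE factor's rating with its level delta and rationale."""

    model_config = ConfigDict(extra="forbid")

    factor: FactorName
    rating: Rating
    level_delta: int = Field(ge=-2, le=2)
    rationale: str
    overridden: bool = False

    @model_validator(mode="after")
    def _check(self) -> "FactorAssessment":
        if self.rating in ("unclear", "not_applicable") and self.level_delta != 0:
            raise ValueError("unclear/not_applicable assessments carry no delta")
        if self.factor in DOWNGRADE_FACTORS and self.level_delta > 0:
            raise ValueError(f"{self.factor} cannot raise the level")
        if self.factor in UPGRADE_FACTORS and self.level_delta < 0:
            raise ValueError(f"{self.factor} cannot lower the level")
        return self


class QualityGrade(BaseModel):
    """Final quality level (1=very low ... 4=high) with a full audit ledger."""

    model_config = ConfigDict(extra="forbid")

    level: int = Field(ge=1, le=4)
    plus_notation: str
    starting_level: int = Field(ge=1, le=4)
    ledger: list[FactorAssessment]
    footnotes: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "QualityGrade":
        if self.plus_notation != "+" * self.level:
            raise ValueError("plus_notation must repeat '+' level times")
        return self

    @property
    def label(self) -> str:
        return {1: "very low", 2: "low", 3: "moderate", 4: "high"}[self.level]


@dataclass(frozen=True)
class Finding:
    """One violated content invariant, naming the study and field."""

    study_id: Optional[str]
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"study {self.study_id}: " if self.study_id else ""
        return f"{where}{self.field}: {self.message}"


class BodyValidationError(ValueError):
    def __init__(self, findings: list[Finding]):
        self.findings = findings
        super().__init__(
            "body of evidence failed validation:\n"
            + "\n".join(f"  - {f}" for f in findings)
        )


def _validate_effect(study_id: Optional[str], prefix: str, e: EffectEstimate) -> list[Finding]:
    out: list[Finding] = []
    if e.is_ratio:
        vals = [("point", e.point), ("ci_low", e.ci_low), ("ci_high", e.ci_high)]
        for name, v in vals:
            if v is not None and v <= 0:
                out.append(
                    Finding(study_id, f"{prefix}.{name}", "ratio measure must be positive")
                )
    if e.has_ci:
        if e.ci_low > e.point:
            out.append(Finding(study_id, f"{prefix}.ci_low", "ci_low exceeds point"))
        if e.point > e.ci_high:
            out.append(Finding(study_id, f"{prefix}.ci_high", "point exceeds ci_high"))
    return out


def validate_body(body: BodyOfEvidence) -> list[Finding]:
    """Check every content invariant; one finding per violation.

    Returns an empty list for a well-formed body. Never raises, never
    mutates the input, idempotent and order-insensitive over studies.
    """
    findings: list[Finding] = []
    for s in body.studies:
        if s.n_events is not None and s.n_events > s.n_participants:
            findings.append(
                Finding(s.study_id, "n_events", "n_events exceeds n_participants")
            )
        for i, e in enumerate(s.effects):
            findings.extend(_validate_effect(s.study_id, f"effects[{i}]", e))
        if s.exposure_levels:
            doses = [lv.dose for lv in s.exposure_levels]
            if any(b <= a for a, b in zip(doses, doses[1:])):
                findings.append(
                    Finding(
                        s.study_id,
                        "exposure_levels",
                        "dose values must be strictly increasing",
                    )
                )
            for i, lv in enumerate(s.exposure_levels):
                findings.extend(
                    _validate_effect(s.study_id, f"exposure_levels[{i}].effect", lv.effect)
                )
    for factor, ov in body.overrides.items():
        if not ov.justification.strip():
            findings.append(
                Finding(None, f"overrides[{factor}]", "override requires a justification")
            )
        if factor not in DOWNGRADE_FACTORS + UPGRADE_FACTORS:
            findings.append(
                Finding(None, f"overrides[{factor}]", "unknown factor identifier")
            )
    measures = {e.measure for s in body.studies for e in s.effects}
    families = {"ratio" if m in RATIO_MEASURES else "smd" for m in measures}
    if len(families) > 1:
        findings.append(
            Finding(None, "studies", "mixing ratio measures and SMD within one body")
        )
    if body.synthesis_mode == "meta_analysis" and body.pooled is None:
        n_ci = sum(1 for s in body.studies if (e := s.preferred_effect()) and e.has_ci)
        if n_ci < 2:
            findings.append(
                Finding(
                    None,
                    "pooled",
                    "meta_analysis synthesis requires a pooled result "
                    "(fewer than two studies provide a usable CI to compute one)",
                )
            )
    return findings


# ---------------------------------------------------------------------------
# canonical serialization


def body_to_dict(body: BodyOfEvidence) -> dict:
    return body.model_dump(mode="json", exclude_none=True)


def body_to_json(body: BodyOfEvidence) -> str:
    """Canonical JSON serialization (round-trip stable byte-for-byte)."""
    return json.dumps(body_to_dict(body), indent=2, ensure_ascii=False) + "\n"


def body_from_dict(data: dict) -> BodyOfEvidence:
    return BodyOfEvidence.model_validate(data)
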