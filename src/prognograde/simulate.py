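"""Seeded synthetic bodies of evidence with known ground truth.

Each study draws a true log odds ratio theta_i ~ Normal(true_theta, tau^2),
splits its cohort into exposed and unexposed halves, and draws outcome
events binomially with a logistic link: the unexposed arm at the baseline
risk, the exposed arm at odds(baseline) * exp(theta_i). The observed 2x2
table then yields a Woolf odds-ratio estimate, so the generated bodies
share the statistical structure the inconsistency and imprecision rules
assume — per-study estimates with sampling error around a possibly
heterogeneous true effect.

Defaults mirror a large school-cohort prognosis literature: 2,000
participants per study and a 30% baseline risk of outcome persistence.
All randomness flows through explicit seeds; identical spec, identical
body.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .meta import odds_ratio_from_counts
from .model import (
    QUIPS_DOMAINS,
    BodyOfEvidence,
    EffectEstimate,
    ExposureLevel,
    RiskOfBiasProfile,
    StudyRecord,
)

ROB_LEVELS = ("low", "moderate", "high", "unclear")


class RobProfile(BaseModel):
    """Per-domain rating probabilities (normalized at draw time)."""

    model_config = ConfigDict(extra="forbid")

    low: float = Field(default=1.0, ge=0)
    moderate: float = Field(default=0.0, ge=0)
    high: float = Field(default=0.0, ge=0)
    unclear: float = Field(default=0.0, ge=0)

    def probs(self) -> list[float]:
        w = [self.low, self.moderate, self.high, self.unclear]
        total = sum(w)
        if total <= 0:
            raise ValueError("rob_profile weights must sum to a positive value")
        return [x / total for x in w]


class DoseSpec(BaseModel):
    """Planted exposure-level series (dose -> odds-ratio point)."""

    model_config = ConfigDict(extra="forbid")

    doses: list[float]
    points: list[float]

    @model_validator(mode="after")
    def _check(self) -> "DoseSpec":
        if len(self.doses) != len(self.points):
            raise ValueError("doses and points must have equal length")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly increasing")
        return self


class ScenarioSpec(BaseModel):
    """Ground-truth description of one synthetic body of evidence."""

    model_config = ConfigDict(extra="forbid")

    name: str = ""
    k: int = Field(ge=1)
    true_theta: float = 0.0
    tau: float = Field(default=0.0, ge=0)
    n_per_study: Union[int, tuple[int, int]] = 2000
    baseline_risk: float = Field(default=0.3, gt=0, lt=1)
    n_prognostic_variables: int = Field(default=5, gt=0)
    phase_profile: dict[int, float] = Field(default_factory=lambda: {1: 1.0})
    rob_profile: RobProfile = Field(default_factory=RobProfile)
    indirect_rate: float = Field(default=0.0, ge=0, le=1)
    dose_levels: Optional[DoseSpec] = None
    synthesis_mode: str = "meta_analysis"
    clinical_meaningfulness: Optional[bool] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ScenarioSpec":
        if set(self.phase_profile) - {1, 2, 3}:
            raise ValueError("phase_profile keys must be in {1,2,3}")
        if sum(self.phase_profile.values()) <= 0:
            raise ValueError("phase_profile weights must sum to a positive value")
        return self


def _draw_2x2(
    rng: np.random.Generator, n: int, baseline_risk: float, theta: float
) -> tuple[int, int, int, int]:
    n_exp = n // 2
    n_unexp = n - n_exp
    odds1 = baseline_risk / (1.0 - baseline_risk) * math.exp(theta)
    p1 = odds1 / (1.0 + odds1)
    a = int(rng.binomial(n_exp, p1))
    c = int(rng.binomial(n_unexp, baseline_risk))
    return a, n_exp - a, c, n_unexp - c


def _woolf_corrected(a: int, b: int, c: int, d: int) -> EffectEstimate:
    """Unconditional +0.5 Woolf estimate for degenerate tables.

    Used only when an entire margin is zero (no events at all, or every
    participant an event), where the plain estimator is undefined; the
    table is corrected rather than the study dropped.
    """
    a_, b_, c_, d_ = (x + 0.5 for x in (a, b, c, d))
    or_ = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = 1.959963984540054
    return EffectEstimate(
        measure="OR",
        point=or_,
        ci_low=or_ * math.exp(-z * se),
        ci_high=or_ * math.exp(z * se),
    )


def generate_body(
    spec: ScenarioSpec,
    factor_name: Optional[str] = None,
    outcome_name: str = "synthetic outcome",
) -> BodyOfEvidence:
    """Generate a body of evidence per the scenario's ground truth."""
    rng = np.random.default_rng(spec.seed)
    phases = sorted(spec.phase_profile)
    phase_p = np.array([spec.phase_profile[p] for p in phases], dtype=float)
    phase_p /= phase_p.sum()
    rob_probs = spec.rob_profile.probs()
    studies = []
    for i in range(spec.k):
        theta_i = spec.true_theta + spec.tau * rng.standard_normal()
        if isinstance(spec.n_per_study, int):
            n = spec.n_per_study
        else:
            lo, hi = spec.n_per_study
            n = int(rng.integers(lo, hi + 1))
        a, b, c, d = _draw_2x2(rng, n, spec.baseline_risk, theta_i)
        if a + c == 0 or b + d == 0:
            effect = _woolf_corrected(a, b, c, d)
        else:
            effect = odds_ratio_from_counts(a, b, c, d)
        phase = int(rng.choice(phases, p=phase_p))
        rob = RiskOfBiasProfile(
            **{
                dom: str(rng.choice(ROB_LEVELS, p=rob_probs))
                for dom in QUIPS_DOMAINS
            }
        )
        exposure = None
        if spec.dose_levels is not None:
            exposure = [
                ExposureLevel(dose=ds, effect=EffectEstimate(measure="OR", point=pt))
                for ds, pt in zip(spec.dose_levels.doses, spec.dose_levels.points)
            ]
        vote = (
            "positive"
            if effect.ci_low > 1
            else "negative" if effect.ci_high < 1 else "null"
        )
        studies.append(
            StudyRecord(
                study_id=f"synth-{i + 1:02d}",
                phase=phase,
                n_participants=n,
                n_events=a + c,
                n_prognostic_variables=spec.n_prognostic_variables,
                outcome_type="dichotomous",
                effects=[effect],
                rob=rob,
                indirect_population=bool(rng.random() < spec.indirect_rate),
                exposure_levels=exposure,
                vote_univariate=vote,
            )
        )
    return BodyOfEvidence(
        factor_name=factor_name or (spec.name or "synthetic factor"),
        outcome_name=outcome_name,
        studies=studies,
        synthesis_mode=spec.synthesis_mode,
        clinical_meaningfulness_of_differences=spec.clinical_meaningfulness,
    )


@dataclass(frozen=True)
class ScenarioPreset:
    spec: ScenarioSpec
    expected: dict[str, object]  # assessor/engine outcomes the preset plants


def scenario_suite() -> dict[str, ScenarioPreset]:
    """Fixed named presets paired with their expected assessor outcomes."""
    return {
        "homogeneous-null": ScenarioPreset(
            ScenarioSpec(name="homogeneous-null", k=10, true_theta=0.0, tau=0.0,
                         seed=101),
            expected={"inconsistency": "no_concern", "effect_size": "absent"},
        ),
        "homogeneous-large-effect": ScenarioPreset(
            ScenarioSpec(name="homogeneous-large-effect", k=5,
                         true_theta=math.log(6.0), tau=0.0, n_per_study=4000,
                         seed=102),
            expected={"effect_size": "present", "magnitude": "large"},
        ),
        "heterogeneous": ScenarioPreset(
            ScenarioSpec(name="heterogeneous", k=30, true_theta=0.3, tau=0.3,
                         clinical_meaningfulness=True, seed=103),
            expected={"inconsistency": "serious"},
        ),
        "single-small-study": ScenarioPreset(
            ScenarioSpec(name="single-small-study", k=1, true_theta=0.2,
                         n_per_study=150, synthesis_mode="narrative", seed=104),
            expected={"inconsistency": "serious", "publication_bias": "serious"},
        ),
        "gradient-present": ScenarioPreset(
            ScenarioSpec(
                name="gradient-present", k=2, true_theta=0.4,
                dose_levels=DoseSpec(doses=[1, 3, 5], points=[1.2, 1.7, 2.1]),
                synthesis_mode="narrative", seed=105,
            ),
            expected={"dose_response": "present"},
        ),
        "phase2-clean": ScenarioPreset(
            ScenarioSpec(name="phase2-clean", k=5, true_theta=math.log(1.5),
                         tau=0.0, n_per_study=4000, phase_profile={2: 1.0},
                         seed=106),
            expected={"final_level": 4},
        ),
    }
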