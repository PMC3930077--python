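"""Shared fixtures: hand-built bodies of evidence mirroring the worked
examples of a pediatric-headache prognostic-factor review."""

from __future__ import annotations

import pytest

from prognograde.model import (
    QUIPS_DOMAINS,
    BodyOfEvidence,
    EffectEstimate,
    RiskOfBiasProfile,
    StudyRecord,
)


def make_rob(n_moderate: int = 0, n_high: int = 0, n_unclear: int = 0) -> RiskOfBiasProfile:
    """Profile with the given numbers of moderate/high/unclear domains, rest low."""
    ratings = (
        ["moderate"] * n_moderate + ["high"] * n_high + ["unclear"] * n_unclear
    )
    ratings += ["low"] * (6 - len(ratings))
    return RiskOfBiasProfile(**dict(zip(QUIPS_DOMAINS, ratings)))


def make_study(
    study_id: str,
    phase: int = 1,
    n: int = 500,
    or_: float | None = None,
    ci: tuple[float, float] | None = None,
    adjusted: bool = False,
    rob: RiskOfBiasProfile | None = None,
    **kwargs,
) -> StudyRecord:
    effects = []
    if or_ is not None:
        effects.append(
            EffectEstimate(
                measure="OR",
                point=or_,
                ci_low=ci[0] if ci else None,
                ci_high=ci[1] if ci else None,
                adjusted=adjusted,
            )
        )
    return StudyRecord(
        study_id=study_id,
        phase=phase,
        n_participants=n,
        effects=effects,
        rob=rob or make_rob(),
        **kwargs,
    )


@pytest.fixture
def age_body() -> BodyOfEvidence:
    """Three studies of age -> headache persistence: one significant risk
    estimate, two reporting no association without any interval."""
    return BodyOfEvidence(
        factor_name="Age",
        outcome_name="Headache persistence",
        synthesis_mode="narrative",
        studies=[
            make_study(
                "larsson-sund", n=2465, or_=1.88, ci=(1.65, 2.15),
                n_events=700, n_prognostic_variables=5, rob=make_rob(n_moderate=4),
            ),
            make_study("kienbacher", n=227, rob=make_rob(n_moderate=4)),
            make_study("wang-age", n=175, rob=make_rob(n_moderate=4)),
        ],
    )


@pytest.fixture
def menstruation_body() -> BodyOfEvidence:
    """Single study, 134/449 persistent, 14 candidate variables, no interval
    reported; indirect population."""
    return BodyOfEvidence(
        factor_name="Menstruation",
        outcome_name="Headache persistence",
        synthesis_mode="narrative",
        studies=[
            make_study(
                "wang-menses", n=449, n_events=134, n_prognostic_variables=14,
                rob=make_rob(n_moderate=4), indirect_population=True,
            )
        ],
    )


@pytest.fixture
def sex_body() -> BodyOfEvidence:
    """Four phase-1 studies, consistent moderate same-direction effects,
    precise; serious limitations only, effect-size upgrade earned."""
    studies = [
        make_study(
            f"sex-{i}", n=800, or_=o, ci=c, n_events=240,
            n_prognostic_variables=6, rob=make_rob(n_moderate=4),
            vote_univariate="positive" if c[0] > 1 else "null",
        )
        for i, (o, c) in enumerate(
            [(2.8, (2.0, 3.9)), (2.6, (1.9, 3.6)), (3.0, (2.1, 4.3)), (1.6, (0.9, 2.3))],
            start=1,
        )
    ]
    return BodyOfEvidence(
        factor_name="Sex",
        outcome_name="Headache persistence",
        synthesis_mode="narrative",
        studies=studies,
    )


@pytest.fixture
def intensity_body() -> BodyOfEvidence:
    """Three phase-1 studies, consistent small effects, precise; serious
    limitations and the default publication-bias downgrade only."""
    studies = [
        make_study(
            f"int-{i}", n=180, or_=o, ci=c, n_events=70,
            n_prognostic_variables=5, rob=make_rob(n_moderate=4),
        )
        for i, (o, c) in enumerate(
            [(1.5, (1.1, 2.0)), (1.6, (1.2, 2.2)), (1.4, (1.05, 1.9))], start=1
        )
    ]
    return BodyOfEvidence(
        factor_name="Headache intensity",
        outcome_name="Headache persistence",
        synthesis_mode="narrative",
        studies=studies,
    )


#: The six narrative summary-of-findings rows of the published worked
#: example: (factor, flag ratings for the seven adjustable factors,
#: expected overall quality in plus notation). All rows start from
#: phase-1 evidence (level 3).
TABLE_ROWS = [
    ("Headache intensity",
     {"study_limitations": "serious", "inconsistency": "no_concern",
      "indirectness": "no_concern", "imprecision": "no_concern",
      "publication_bias": "serious", "effect_size": "absent",
      "dose_response": "absent"},
     "+"),
    ("Age",
     {"study_limitations": "serious", "inconsistency": "serious",
      "indirectness": "no_concern", "imprecision": "no_concern",
      "publication_bias": "serious", "effect_size": "absent",
      "dose_response": "absent"},
     "+"),
    ("Type of headache diagnosis",
     {"study_limitations": "serious", "inconsistency": "no_concern",
      "indirectness": "serious", "imprecision": "no_concern",
      "publication_bias": "serious", "effect_size": "present",
      "dose_response": "absent"},
     "+"),
    ("Menstruation",
     {"study_limitations": "serious", "inconsistency": "serious",
      "indirectness": "serious", "imprecision": "unclear",
      "publication_bias": "serious", "effect_size": "absent",
      "dose_response": "absent"},
     "+"),
    ("Sex",
     {"study_limitations": "serious", "inconsistency": "no_concern",
      "indirectness": "no_concern", "imprecision": "no_concern",
      "publication_bias": "no_concern", "effect_size": "present",
      "dose_response": "absent"},
     "+++"),
    ("Family history of pain",
     {"study_limitations": "no_concern", "inconsistency": "serious",
      "indirectness": "serious", "imprecision": "no_concern",
      "publication_bias": "serious", "effect_size": "present",
      "dose_response": "absent"},
     "+"),
]


@pytest.fixture
def table_rows():
    return TABLE_ROWS
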