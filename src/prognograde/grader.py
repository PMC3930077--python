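"""Model/Results front end for grading a body of prognostic evidence.

    >>> model = GradeModel.from_file("sex_body.yaml")
    >>> res = model.fit()
    >>> res.grade.level, res.grade.plus_notation
    (3, '+++')
    >>> print(res.summary())

``GradeModel`` holds the body of evidence and the thresholds in force;
``fit()`` validates the body, runs the meta-analytic diagnostics where
applicable, applies every factor assessor and returns a
:class:`GradeResults` carrying the final grade, the full audit ledger and
a formatted summary table.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from . import engine
from .assessors import Thresholds
from .meta import PooledResult
from .model import BodyOfEvidence, QualityGrade


class GradeModel:
    """Adapted-GRADE quality-of-evidence model for one factor x outcome."""

    def __init__(
        self,
        body: BodyOfEvidence,
        thresholds: Optional[Thresholds] = None,
    ):
        self.body = body
        self.thresholds = thresholds or Thresholds()

    @classmethod
    def from_file(cls, path, thresholds: Optional[Thresholds] = None) -> "GradeModel":
        """Build from a JSON/YAML body document or per-study CSV table."""
        from .io import read_body

        return cls(read_body(path), thresholds=thresholds)

    @classmethod
    def from_dict(cls, data: dict, thresholds: Optional[Thresholds] = None) -> "GradeModel":
        from .model import body_from_dict

        return cls(body_from_dict(data), thresholds=thresholds)

    def fit(self, **kwargs) -> "GradeResults":
        """Validate, assess every GRADE factor, and grade the body.

        Keyword arguments are forwarded to :func:`prognograde.engine.grade`
        (``weighting``, ``deltas``, ``required_meta_n``,
        ``small_body_participants``).
        """
        body = engine.attach_pooled(self.body)
        grade = engine.grade(body, self.thresholds, **kwargs)
        return GradeResults(self, body, grade)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        b = self.body
        return (
            f"GradeModel({b.factor_name!r} -> {b.outcome_name!r}, "
            f"k={b.k}, mode={b.synthesis_mode})"
        )


class GradeResults:
    """Fitted grading results: final grade, ledger, pooled diagnostics."""

    def __init__(self, model: GradeModel, body: BodyOfEvidence, grade: QualityGrade):
        self.model = model
        self.body = body
        self.grade = grade

    @property
    def pooled(self) -> Optional[PooledResult]:
        return self.body.pooled

    @property
    def level(self) -> int:
        return self.grade.level

    @property
    def assessments(self):
        return self.grade.ledger

    def to_frame(self) -> pd.DataFrame:
        """The audit ledger as a DataFrame (factor, rating, delta, rationale)."""
        return pd.DataFrame(
            [
                {
                    "factor": a.factor,
                    "rating": a.rating,
                    "level_delta": a.level_delta,
                    "overridden": a.overridden,
                    "rationale": a.rationale,
                }
                for a in self.grade.ledger
            ]
        )

    def summary(self) -> str:
        """Human-readable summary of the grading, statsmodels-style."""
        b, g = self.body, self.grade
        width = 78
        lines = [
            "Adapted GRADE quality of evidence".center(width),
            "=" * width,
            f"Prognostic factor: {b.factor_name}",
            f"Outcome:           {b.outcome_name}",
            f"Studies: {b.k}   Participants: {b.total_participants}   "
            f"Synthesis: {b.synthesis_mode}",
        ]
        if self.pooled is not None:
            p = self.pooled
            lines.append(
                f"Pooled (DL, analysis scale): theta={p.theta_hat:.4f} "
                f"[{p.ci_low:.4f}, {p.ci_high:.4f}]  "
                f"Q={p.q:.2f} (df={p.df}, p={p.p_heterogeneity:.3g})  "
                f"I2={p.i_squared:.1f}%  tau2={p.tau_squared:.4f}"
            )
        lines.append("-" * width)
        lines.append(f"{'factor':<20}{'rating':<16}{'delta':>6}  rationale")
        lines.append("-" * width)
        for a in g.ledger:
            rat = a.rationale if len(a.rationale) <= 44 else a.rationale[:41] + "..."
            mark = "*" if a.overridden else ""
            lines.append(f"{a.factor:<20}{a.rating + mark:<16}{a.level_delta:>+6}  {rat}")
        lines.append("-" * width)
        lines.append(
            f"Starting level: {g.starting_level}   Final level: {g.level} "
            f"({g.label}, {g.plus_notation})"
        )
        if g.footnotes:
            lines.append("Footnotes:")
            for i, fn in enumerate(g.footnotes, 1):
                lines.append(f"  [{i}] {fn}")
        lines.append("=" * width)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GradeResults level={self.grade.level} "
            f"({self.grade.label!r}, {self.grade.plus_notation!r})>"
        )
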