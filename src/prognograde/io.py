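"""Body-of-evidence documents and summary-of-findings tables.

Readers accept one body per JSON or YAML document, or a per-study CSV
table (UTF-8, '.' decimal separator, one row per study with body-level
columns repeated). Writers render the adapted summary-of-findings table
in the meta-analysis layout (pooled effect column) or the narrative
layout (univariate / multivariate vote-count columns), as Markdown or
RFC-4180 CSV. The table is a pure view: every glyph is reconstructible
from the grade ledger alone.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import ValidationError

from .assessors import Thresholds
from .model import (
    BodyOfEvidence,
    QualityGrade,
    body_from_dict,
    body_to_dict,
    body_to_json,
)

logger = logging.getLogger(__name__)

GLYPHS = {
    "no_concern": "✓",      # check mark
    "serious": "✕",         # cross
    "very_serious": "✕✕",
    "unclear": "Unclear",
    "not_applicable": "NA",
    "present": "✓",
    "absent": "✕",
}
ASCII_GLYPHS = {
    "no_concern": "ok",
    "serious": "down",
    "very_serious": "down2",
    "unclear": "unclear",
    "not_applicable": "na",
    "present": "ok",
    "absent": "down",
}

FACTOR_COLUMNS = [
    ("study_limitations", "Study limitations"),
    ("inconsistency", "Inconsistency"),
    ("indirectness", "Indirectness"),
    ("imprecision", "Imprecision"),
    ("publication_bias", "Publication bias"),
    ("effect_size", "Moderate/large effect size"),
    ("dose_response", "Dose effect"),
]

_CSV_COLUMNS = [
    "factor_name", "outcome_name", "synthesis_mode", "study_id", "phase",
    "design", "n_participants", "n_events", "n_prognostic_variables",
    "outcome_type", "sample_size_justified", "rob_study_participation",
    "rob_study_attrition", "rob_prognostic_factor_measurement",
    "rob_outcome_measurement", "rob_confounding", "rob_analysis",
    "indirect_population", "indirect_factor", "indirect_outcome", "measure",
    "uni_point", "uni_ci_low", "uni_ci_high", "uni_n_covariates",
    "multi_point", "multi_ci_low", "multi_ci_high", "multi_n_covariates",
    "cohort_id", "vote_univariate", "vote_multivariate",
]


class BodyParseError(ValueError):
    """Parse/schema failure; lists every offending field, never partial-loads."""


def _wrap_validation_error(path, exc: ValidationError) -> BodyParseError:
    msgs = [
        f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
    ]
    return BodyParseError(
        f"{path}: invalid body document:\n" + "\n".join(f"  - {m}" for m in msgs)
    )


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:12]


def read_body(path, fmt: Optional[str] = None) -> BodyOfEvidence:
    """Read and fully validate a body document (JSON, YAML or CSV).

    The dialect is inferred from the suffix unless ``fmt`` is given.
    Unknown keys are rejected with field-level diagnostics.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    fmt = fmt or path.suffix.lstrip(".").lower()
    logger.info("reading body %s (format=%s, sha256=%s)", path, fmt, _digest(text))
    if fmt == "json":
        data = json.loads(text)
    elif fmt in ("yaml", "yml"):
        data = yaml.safe_load(text)
    elif fmt == "csv":
        return _body_from_csv(path, text)
    else:
        raise BodyParseError(f"{path}: unknown body format {fmt!r}")
    if not isinstance(data, dict):
        raise BodyParseError(f"{path}: expected a mapping at the document root")
    try:
        return body_from_dict(data)
    except ValidationError as exc:
        raise _wrap_validation_error(path, exc) from exc


def write_body(body: BodyOfEvidence, path, fmt: Optional[str] = None) -> None:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "json":
        path.write_text(body_to_json(body), encoding="utf-8")
    elif fmt in ("yaml", "yml"):
        path.write_text(
            yaml.safe_dump(body_to_dict(body), sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )
    elif fmt == "csv":
        path.write_text(_body_to_csv(body), encoding="utf-8", newline="")
    else:
        raise ValueError(f"unknown body format {fmt!r}")


def _body_from_csv(path: Path, text: str) -> BodyOfEvidence:
    rows = list(csv.DictReader(_io.StringIO(text)))
    if not rows:
        raise BodyParseError(f"{path}: nonempty list of StudyRecord required")
    unknown = set(rows[0]) - set(_CSV_COLUMNS)
    if unknown:
        raise BodyParseError(f"{path}: unknown column(s): {sorted(unknown)}")

    def _get(row, key):
        v = row.get(key, "")
        return None if v is None or v == "" else v

    studies = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        effects = []
        measure = _get(row, "measure")
        for prefix, adjusted in (("uni", False), ("multi", True)):
            point = _get(row, f"{prefix}_point")
            if point is None:
                continue
            effects.append(
                {
                    "measure": measure,
                    "point": float(point),
                    "ci_low": (lo := _get(row, f"{prefix}_ci_low")) and float(lo),
                    "ci_high": (hi := _get(row, f"{prefix}_ci_high")) and float(hi),
                    "adjusted": adjusted,
                    "n_covariates": int(_get(row, f"{prefix}_n_covariates") or 0),
                }
            )
        study = {
            "study_id": _get(row, "study_id"),
            "phase": int(_get(row, "phase")),
            "n_participants": int(_get(row, "n_participants")),
            "outcome_type": _get(row, "outcome_type") or "dichotomous",
            "sample_size_justified": (_get(row, "sample_size_justified") or "false").lower()
            == "true",
            "effects": effects,
            "rob": {
                d: _get(row, f"rob_{d}")
                for d in (
                    "study_participation", "study_attrition",
                    "prognostic_factor_measurement", "outcome_measurement",
                    "confounding", "analysis",
                )
            },
        }
        for opt in ("design", "cohort_id", "vote_univariate", "vote_multivariate"):
            if (v := _get(row, opt)) is not None:
                study[opt] = v
        for opt in ("n_events", "n_prognostic_variables"):
            if (v := _get(row, opt)) is not None:
                study[opt] = int(v)
        for flag in ("indirect_population", "indirect_factor", "indirect_outcome"):
            if (v := _get(row, flag)) is not None:
                study[flag] = v.lower() == "true"
        try:
            studies.append(study)
        except ValidationError as exc:  # pragma: no cover - built below
            raise _wrap_validation_error(f"{path}:{i}", exc) from exc
    head = rows[0]
    data = {
        "factor_name": _get(head, "factor_name"),
        "outcome_name": _get(head, "outcome_name"),
        "synthesis_mode": _get(head, "synthesis_mode") or "narrative",
        "studies": studies,
    }
    try:
        return body_from_dict(data)
    except ValidationError as exc:
        raise _wrap_validation_error(path, exc) from exc


def _fmt_cell(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _body_to_csv(body: BodyOfEvidence) -> str:
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(_CSV_COLUMNS)
    for s in body.studies:
        uni = next((e for e in s.effects if not e.adjusted), None)
        multi = next((e for e in s.effects if e.adjusted), None)
        row = {
            "factor_name": body.factor_name,
            "outcome_name": body.outcome_name,
            "synthesis_mode": body.synthesis_mode,
            "study_id": s.study_id,
            "phase": s.phase,
            "design": s.design,
            "n_participants": s.n_participants,
            "n_events": s.n_events,
            "n_prognostic_variables": s.n_prognostic_variables,
            "outcome_type": s.outcome_type,
            "sample_size_justified": s.sample_size_justified,
            "rob_study_participation": s.rob.study_participation,
            "rob_study_attrition": s.rob.study_attrition,
            "rob_prognostic_factor_measurement": s.rob.prognostic_factor_measurement,
            "rob_outcome_measurement": s.rob.outcome_measurement,
            "rob_confounding": s.rob.confounding,
            "rob_analysis": s.rob.analysis,
            "indirect_population": s.indirect_population,
            "indirect_factor": s.indirect_factor,
            "indirect_outcome": s.indirect_outcome,
            "measure": (uni or multi).measure if (uni or multi) else None,
            "uni_point": uni.point if uni else None,
            "uni_ci_low": uni.ci_low if uni else None,
            "uni_ci_high": uni.ci_high if uni else None,
            "uni_n_covariates": uni.n_covariates if uni else None,
            "multi_point": multi.point if multi else None,
            "multi_ci_low": multi.ci_low if multi else None,
            "multi_ci_high": multi.ci_high if multi else None,
            "multi_n_covariates": multi.n_covariates if multi else None,
            "cohort_id": s.cohort_id,
            "vote_univariate": s.vote_univariate,
            "vote_multivariate": s.vote_multivariate,
        }
        w.writerow([_fmt_cell(row[c]) for c in _CSV_COLUMNS])
    return buf.getvalue()


# ---------------------------------------------------------------------------
# summary-of-findings tables


def _modal_phase(body: BodyOfEvidence) -> int:
    phases = [s.phase for s in body.studies]
    return min(sorted(set(phases), key=lambda p: (-phases.count(p), p))[:1])


def _vote_counts(body: BodyOfEvidence, which: str) -> tuple[str, str, str]:
    votes = [getattr(s, f"vote_{which}") for s in body.studies]
    reported = [v for v in votes if v is not None]
    if not reported:
        return "", "", ""  # blanks preserved as "not reported"
    return (
        str(reported.count("positive")),
        str(reported.count("null")),
        str(reported.count("negative")),
    )


def _ledger_map(grade: QualityGrade) -> dict[str, object]:
    return {a.factor: a for a in grade.ledger}


def _glyph_cells(
    grade: QualityGrade, glyphs: dict[str, str], footnotes: list[str]
) -> list[str]:
    lm = _ledger_map(grade)
    cells = []
    for factor, _ in FACTOR_COLUMNS:
        a = lm[factor]
        # upgrade factors render a cross unless earned, even when no study
        # reports the data needed to judge them
        if factor in ("effect_size", "dose_response"):
            cell = glyphs["present" if a.rating == "present" else "absent"]
        else:
            cell = glyphs[a.rating]
        if a.rating in ("serious", "very_serious", "unclear") or a.overridden:
            footnotes.append(f"{factor}: {a.rationale}")
            cell += f"^{len(footnotes)}"
        cells.append(cell)
    return cells


def _pooled_cell(body: BodyOfEvidence) -> str:
    import math

    p = body.pooled
    if p is None:
        return ""
    m = body.measure() or "OR"
    if m in ("OR", "RR", "HR"):
        pt, lo, hi = (math.exp(x) for x in (p.theta_hat, p.ci_low, p.ci_high))
    else:
        pt, lo, hi = p.theta_hat, p.ci_low, p.ci_high
    return f"{m} {pt:.2f} ({lo:.2f} to {hi:.2f})"


def sof_rows(
    bodies: Sequence[BodyOfEvidence],
    grades: Sequence[QualityGrade],
    layout: str,
    ascii_glyphs: bool = False,
) -> tuple[list[str], list[list[str]], list[str]]:
    """Header, rows and footnotes for a summary-of-findings table."""
    if layout not in ("meta", "narrative"):
        raise ValueError(f"unknown layout {layout!r}")
    if len(bodies) != len(grades):
        raise ValueError("one grade per body required")
    for b in bodies:
        if layout == "meta" and b.synthesis_mode != "meta_analysis":
            raise ValueError(
                f"layout 'meta' requires meta_analysis synthesis ({b.factor_name})"
            )
        if layout == "narrative" and b.synthesis_mode != "narrative":
            raise ValueError(
                f"layout 'narrative' requires narrative synthesis ({b.factor_name})"
            )
    glyphs = ASCII_GLYPHS if ascii_glyphs else GLYPHS
    header = ["Prognostic factor", "Participants", "Studies", "Cohorts"]
    if layout == "meta":
        header += ["Estimated effect (95% CI)"]
    else:
        header += ["Uni +", "Uni 0", "Uni -", "Multi +", "Multi 0", "Multi -"]
    header += ["Phase"] + [label for _, label in FACTOR_COLUMNS] + ["Overall quality"]
    rows: list[list[str]] = []
    footnotes: list[str] = []
    for body, grade in zip(bodies, grades):
        row = [
            body.factor_name,
            f"{body.total_participants:,}",
            str(body.k),
            str(body.n_cohorts),
        ]
        if layout == "meta":
            row.append(_pooled_cell(body))
        else:
            row += list(_vote_counts(body, "univariate"))
            row += list(_vote_counts(body, "multivariate"))
        row.append(str(_modal_phase(body)))
        row += _glyph_cells(grade, glyphs, footnotes)
        row.append(grade.plus_notation)
        rows.append(row)
    return header, rows, footnotes


def write_sof(
    bodies: Sequence[BodyOfEvidence],
    grades: Sequence[QualityGrade],
    layout: str = "narrative",
    fmt: str = "markdown",
    outcome_name: Optional[str] = None,
) -> str:
    """Render the summary-of-findings document (Markdown or CSV).

    Every cross/override glyph carries a footnote marker linking to its
    rationale below the table; output is byte-stable across runs.
    """
    outcome = outcome_name or (bodies[0].outcome_name if bodies else "")
    if fmt == "markdown":
        header, rows, footnotes = sof_rows(bodies, grades, layout, ascii_glyphs=False)
        lines = [f"**Outcome: {outcome}**", ""]
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "|".join(["---"] * len(header)) + "|")
        for row in rows:
            lines.append("| " + " | ".join(row) + " |")
        if footnotes:
            lines.append("")
            for i, fn in enumerate(footnotes, 1):
                lines.append(f"^{i}: {fn}")
        return "\n".join(lines) + "\n"
    if fmt == "csv":
        header, rows, footnotes = sof_rows(bodies, grades, layout, ascii_glyphs=True)
        buf = _io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow(row)
        for i, fn in enumerate(footnotes, 1):
            w.writerow(["footnote", str(i), fn])
        return buf.getvalue()
    raise ValueError(f"unknown format {fmt!r}")


def read_thresholds(path) -> Thresholds:
    """Load a thresholds config (JSON or YAML mapping of field -> value)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    try:
        th = Thresholds.model_validate(data or {})
    except ValidationError as exc:
        raise _wrap_validation_error(path, exc) from exc
    logger.info("thresholds loaded from %s (sha256=%s)", path, _digest(text))
    return th
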