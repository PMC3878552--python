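"""Reading and writing audit corpora.

Two containers are supported:

* ``json`` — a single file mirroring the corpus schema under the keys
  ``reviews``, ``reference_review_id``, ``study_units``, ``extractions``,
  ``annotations`` and ``analysis_exclusions``.
* ``csv`` — a directory holding ``extractions.csv``, ``annotations.csv``,
  ``study_units.csv`` and ``meta.json`` (reference review and analysis
  exclusions).  Count columns carry the literal ``NR`` for cells a review
  did not report.

Round-trips are lossless for every field, including NR status markers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .types import (
    AnalysisExclusion,
    ArmExtraction,
    AuditCorpus,
    DiscrepancyAnnotation,
    Label,
    OutcomeId,
    StudyOutcomeExtraction,
    StudyUnit,
    Timepoint,
    Variable,
)

EXTRACTION_COLUMNS = [
    "review_id",
    "study_unit_id",
    "outcome_id",
    "timepoint",
    "arm_a_events",
    "arm_a_total",
    "arm_b_events",
    "arm_b_total",
    "status",
]
ANNOTATION_COLUMNS = [
    "review_id",
    "study_unit_id",
    "outcome_id",
    "variable",
    "label",
    "rationale",
]


class CorpusFormatError(ValueError):
    """Raised when a corpus file does not conform to the schema."""


def _arm_from_cells(events: str, total: str, row: int, arm: str) -> ArmExtraction:
    if events == "NR" and total == "NR":
        return ArmExtraction.nr()
    try:
        return ArmExtraction.reported(events=int(events), total=int(total))
    except (TypeError, ValueError) as exc:
        raise CorpusFormatError(f"row {row}: bad {arm} cells ({events!r}/{total!r}): {exc}")


def _extraction_from_row(row: pd.Series, idx: int) -> StudyOutcomeExtraction:
    try:
        outcome = OutcomeId(row["outcome_id"])
        timepoint = Timepoint(row["timepoint"])
    except ValueError as exc:
        raise CorpusFormatError(f"row {idx}: {exc}")
    arm_a = _arm_from_cells(row["arm_a_events"], row["arm_a_total"], idx, "arm A")
    arm_b = _arm_from_cells(row["arm_b_events"], row["arm_b_total"], idx, "arm B")
    status = row.get("status", "reported")
    if status not in ("reported", "not_reported"):
        raise CorpusFormatError(f"row {idx}: unknown status {status!r}")
    declared_nr = status == "not_reported"
    actual_nr = not (arm_a.is_reported and arm_b.is_reported)
    if declared_nr != actual_nr:
        raise CorpusFormatError(
            f"row {idx}: status {status!r} inconsistent with count cells"
        )
    try:
        return StudyOutcomeExtraction(
            review_id=row["review_id"],
            study_unit_id=row["study_unit_id"],
            outcome_id=outcome,
            timepoint=timepoint,
            arm_a=arm_a,
            arm_b=arm_b,
        )
    except ValueError as exc:
        raise CorpusFormatError(f"row {idx}: {exc}")


def _extraction_to_row(rec: StudyOutcomeExtraction) -> dict:
    def cell(v: Optional[int]) -> str:
        return "NR" if v is None else str(v)

    return {
        "review_id": rec.review_id,
        "study_unit_id": rec.study_unit_id,
        "outcome_id": rec.outcome_id.value,
        "timepoint": rec.timepoint.value,
        "arm_a_events": cell(rec.arm_a.events),
        "arm_a_total": cell(rec.arm_a.total),
        "arm_b_events": cell(rec.arm_b.events),
        "arm_b_total": cell(rec.arm_b.total),
        "status": "reported" if rec.is_reported else "not_reported",
    }


def _annotation_from_row(row: pd.Series, idx: int) -> DiscrepancyAnnotation:
    try:
        return DiscrepancyAnnotation(
            review_id=row["review_id"],
            study_unit_id=row["study_unit_id"],
            outcome_id=OutcomeId(row["outcome_id"]),
            variable=Variable(row["variable"]),
            label=Label(row["label"]),
            rationale=row.get("rationale", "") or "",
        )
    except ValueError as exc:
        raise CorpusFormatError(f"annotation row {idx}: {exc}")


def read_extractions_csv(path: Union[str, Path]) -> list[StudyOutcomeExtraction]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(EXTRACTION_COLUMNS) - set(df.columns)
    if missing:
        raise CorpusFormatError(f"{path}: missing columns {sorted(missing)}")
    return [_extraction_from_row(row, i) for i, row in df.iterrows()]


def read_annotations_csv(path: Union[str, Path]) -> list[DiscrepancyAnnotation]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise CorpusFormatError(f"{path}: missing columns {sorted(missing)}")
    return [_annotation_from_row(row, i) for i, row in df.iterrows()]


def _corpus_from_parts(
    reviews, reference, units, extractions, annotations, exclusions
) -> AuditCorpus:
    try:
        return AuditCorpus(
            reviews=tuple(reviews),
            reference_review_id=reference,
            study_units=tuple(units),
            extractions=tuple(extractions),
            annotations=tuple(annotations),
            analysis_exclusions=tuple(exclusions),
        )
    except ValueError as exc:
        raise CorpusFormatError(str(exc))


def read_corpus(path: Union[str, Path], format: str = "json") -> AuditCorpus:
    """Read a validated :class:`AuditCorpus` from ``path``.

    ``format="json"`` expects a single file; ``format="csv"`` expects the
    directory layout written by :func:`write_corpus`.
    """
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}: invalid JSON ({exc})")
        try:
            return AuditCorpus.model_validate(payload)
        except ValueError as exc:
            raise CorpusFormatError(f"{path}: {exc}")
    if format == "csv":
        if not path.is_dir():
            raise CorpusFormatError(f"{path}: CSV corpus must be a directory")
        extractions = read_extractions_csv(path / "extractions.csv")
        ann_path = path / "annotations.csv"
        annotations = read_annotations_csv(ann_path) if ann_path.exists() else []
        units_df = pd.read_csv(path / "study_units.csv", dtype=str, keep_default_na=False)
        units = [
            StudyUnit(
                unit_id=row["unit_id"],
                member_publications=tuple(
                    p for p in row.get("member_publications", "").split(";") if p
                ),
                notes=row.get("notes", "") or "",
            )
            for _, row in units_df.iterrows()
        ]
        with open(path / "meta.json") as fh:
            meta = json.load(fh)
        exclusions = [
            AnalysisExclusion.model_validate(e)
            for e in meta.get("analysis_exclusions", [])
        ]
        return _corpus_from_parts(
            meta["reviews"],
            meta["reference_review_id"],
            units,
            extractions,
            annotations,
            exclusions,
        )
    raise ValueError(f"unknown corpus format {format!r}")


def write_corpus(corpus: AuditCorpus, path: Union[str, Path], format: str = "json") -> None:
    """Write ``corpus`` so that :func:`read_corpus` round-trips it exactly."""
    path = Path(path)
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(corpus.model_dump(mode="json"), fh, indent=1)
            fh.write("\n")
        return
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [_extraction_to_row(r) for r in corpus.extractions],
            columns=EXTRACTION_COLUMNS,
        ).to_csv(path / "extractions.csv", index=False)
        pd.DataFrame(
            [
                {
                    "review_id": a.review_id,
                    "study_unit_id": a.study_unit_id,
                    "outcome_id": a.outcome_id.value,
                    "variable": a.variable.value,
                    "label": a.label.value,
                    "rationale": a.rationale,
                }
                for a in corpus.annotations
            ],
            columns=ANNOTATION_COLUMNS,
        ).to_csv(path / "annotations.csv", index=False)
        pd.DataFrame(
            [
                {
                    "unit_id": u.unit_id,
                    "member_publications": ";".join(u.member_publications),
                    "notes": u.notes,
                }
                for u in corpus.study_units
            ],
            columns=["unit_id", "member_publications", "notes"],
        ).to_csv(path / "study_units.csv", index=False)
        with open(path / "meta.json", "w") as fh:
            json.dump(
                {
                    "reviews": list(corpus.reviews),
                    "reference_review_id": corpus.reference_review_id,
                    "analysis_exclusions": [
                        e.model_dump(mode="json") for e in corpus.analysis_exclusions
                    ],
                },
                fh,
                indent=1,
            )
            fh.write("\n")
        return
    raise ValueError(f"unknown corpus format {format!r}")
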