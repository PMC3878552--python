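"""Domain types for multi-review binary-outcome extraction corpora.

The unit of audit is the 2x2 table a systematic review extracted for one
trial and one outcome: events/total in the index arm (THA, arm A) and in
the comparator arm (HA, arm B).  Several reviews extract the same trials,
one of them is designated the reference standard, and a human-adjudicated
annotation layer classifies each variable-level difference as an outright
*error* or a *selection* of alternative but genuine data.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator


class OutcomeId(str, enum.Enum):
    dislocation = "dislocation"
    mortality_1y = "mortality_1y"
    revision = "revision"


class Timepoint(str, enum.Enum):
    one_year = "one_year"
    thirteen_year = "thirteen_year"
    unspecified = "unspecified"


#: Preference order used when a review holds several records for one
#: study unit and outcome: the earliest follow-up is the primary dataset.
TIMEPOINT_ORDER = (Timepoint.one_year, Timepoint.unspecified, Timepoint.thirteen_year)


class ExtractionStatus(str, enum.Enum):
    reported = "reported"
    not_reported = "not_reported"


class Variable(str, enum.Enum):
    arm_a_events = "arm_a_events"
    arm_a_total = "arm_a_total"
    arm_b_events = "arm_b_events"
    arm_b_total = "arm_b_total"


class Label(str, enum.Enum):
    """Taxonomy of a variable-level comparison against the reference."""

    identical = "identical"
    error = "error"
    selection = "selection"
    not_reported = "not_reported"


class ArmExtraction(BaseModel):
    """Events/total for one trial arm as recorded by one review.

    A cell a review did not report is stored explicitly with
    ``status=not_reported`` (and no counts) so that "review omitted the
    study" is distinguishable from "file lacks a row".
    """

    model_config = ConfigDict(frozen=True)

    events: Optional[int] = None
    total: Optional[int] = None
    status: ExtractionStatus = ExtractionStatus.reported

    @model_validator(mode="after")
    def _check(self) -> "ArmExtraction":
        if self.status is ExtractionStatus.reported:
            if self.events is None or self.total is None:
                raise ValueError("reported arm requires events and total")
            if self.total <= 0:
                raise ValueError(f"total must be positive, got {self.total}")
            if not 0 <= self.events <= self.total:
                raise ValueError(
                    f"events must satisfy 0 <= events <= total, "
                    f"got {self.events}/{self.total}"
                )
        else:
            if self.events is not None or self.total is not None:
                raise ValueError("not_reported arm must not carry counts")
        return self

    @classmethod
    def reported(cls, events: int, total: int) -> "ArmExtraction":
        return cls(events=events, total=total, status=ExtractionStatus.reported)

    @classmethod
    def nr(cls) -> "ArmExtraction":
        return cls(status=ExtractionStatus.not_reported)

    @property
    def is_reported(self) -> bool:
        return self.status is ExtractionStatus.reported


class StudyOutcomeExtraction(BaseModel):
    """The 4-variable extraction unit: two arms x (events, total)."""

    model_config = ConfigDict(frozen=True)

    review_id: str
    study_unit_id: str
    outcome_id: OutcomeId
    timepoint: Timepoint = Timepoint.unspecified
    arm_a: ArmExtraction
    arm_b: ArmExtraction

    @property
    def is_reported(self) -> bool:
        """True if both arms carry data; an all-NR record marks omission."""
        return self.arm_a.is_reported and self.arm_b.is_reported

    def value(self, variable: Variable) -> Optional[int]:
        arm = self.arm_a if variable.value.startswith("arm_a") else self.arm_b
        return arm.events if variable.value.endswith("events") else arm.total


class StudyUnit(BaseModel):
    """A trial cohort; may aggregate several publications (e.g. an index
    trial report plus its long-term follow-up paper)."""

    model_config = ConfigDict(frozen=True)

    unit_id: str
    member_publications: tuple[str, ...] = ()
    notes: str = ""


class DiscrepancyAnnotation(BaseModel):
    """Human adjudication of one variable of one review's extraction.

    Annotations are keyed without a timepoint: they refer to the dataset
    the review actually analysed for that outcome.
    """

    model_config = ConfigDict(frozen=True)

    review_id: str
    study_unit_id: str
    outcome_id: OutcomeId
    variable: Variable
    label: Label
    rationale: str = ""


class AnalysisExclusion(BaseModel):
    """A study dropped from one review's pooled analysis of one outcome
    (over and above the automatic double-zero exclusion)."""

    model_config = ConfigDict(frozen=True)

    review_id: str
    study_unit_id: str
    outcome_id: OutcomeId
    reason: str = ""


class AuditCorpus(BaseModel):
    """All reviews' extractions over shared study units, the reference
    designation, the annotation layer and any analysis exclusions."""

    reviews: tuple[str, ...]
    reference_review_id: str
    study_units: tuple[StudyUnit, ...]
    extractions: tuple[StudyOutcomeExtraction, ...]
    annotations: tuple[DiscrepancyAnnotation, ...] = ()
    analysis_exclusions: tuple[AnalysisExclusion, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "AuditCorpus":
        if self.reference_review_id not in self.reviews:
            raise ValueError(
                f"unknown reference_review_id {self.reference_review_id!r}"
            )
        unit_ids = [u.unit_id for u in self.study_units]
        if len(set(unit_ids)) != len(unit_ids):
            raise ValueError("duplicate study_unit_id")
        units = set(unit_ids)
        seen: set[tuple[str, str, OutcomeId, Timepoint]] = set()
        for rec in self.extractions:
            if rec.review_id not in self.reviews:
                raise ValueError(f"extraction references unknown review {rec.review_id!r}")
            if rec.study_unit_id not in units:
                raise ValueError(
                    f"extraction references unknown study unit {rec.study_unit_id!r}"
                )
            key = (rec.review_id, rec.study_unit_id, rec.outcome_id, rec.timepoint)
            if key in seen:
                raise ValueError(f"duplicate extraction record for {key}")
            seen.add(key)
        for ann in self.annotations:
            if ann.review_id not in self.reviews or ann.study_unit_id not in units:
                raise ValueError(
                    f"annotation references unknown review/unit "
                    f"({ann.review_id!r}, {ann.study_unit_id!r})"
                )
        return self

    # -- lookup helpers -------------------------------------------------

    def records(
        self,
        review_id: str,
        outcome_id: OutcomeId,
        study_unit_id: Optional[str] = None,
    ) -> list[StudyOutcomeExtraction]:
        return [
            r
            for r in self.extractions
            if r.review_id == review_id
            and r.outcome_id == outcome_id
            and (study_unit_id is None or r.study_unit_id == study_unit_id)
        ]

    def get_extraction(
        self,
        review_id: str,
        study_unit_id: str,
        outcome_id: OutcomeId,
        timepoint: Optional[Timepoint] = None,
    ) -> Optional[StudyOutcomeExtraction]:
        recs = self.records(review_id, outcome_id, study_unit_id)
        if timepoint is not None:
            recs = [r for r in recs if r.timepoint == timepoint]
        if not recs:
            return None
        recs.sort(key=lambda r: TIMEPOINT_ORDER.index(r.timepoint))
        return recs[0]

    def analysed_record(
        self, review_id: str, study_unit_id: str, outcome_id: OutcomeId
    ) -> Optional[StudyOutcomeExtraction]:
        """The dataset the review analysed for this unit and outcome: its
        earliest-timepoint fully reported record, or None if the review
        did not report the outcome for this unit."""
        recs = [
            r
            for r in self.records(review_id, outcome_id, study_unit_id)
            if r.is_reported
        ]
        if not recs:
            return None
        recs.sort(key=lambda r: TIMEPOINT_ORDER.index(r.timepoint))
        return recs[0]

    def analysed_units(self, review_id: str, outcome_id: OutcomeId) -> list[str]:
        """Study units for which the review reported data for the outcome,
        in corpus unit order."""
        out = []
        for unit in self.study_units:
            if self.analysed_record(review_id, unit.unit_id, outcome_id) is not None:
                out.append(unit.unit_id)
        return out

    def annotations_for(
        self, review_id: str, study_unit_id: str, outcome_id: OutcomeId
    ) -> dict[Variable, DiscrepancyAnnotation]:
        out: dict[Variable, DiscrepancyAnnotation] = {}
        for ann in self.annotations:
            if (
                ann.review_id == review_id
                and ann.study_unit_id == study_unit_id
                and ann.outcome_id == outcome_id
            ):
                if ann.variable in out:
                    raise ValueError(
                        f"duplicate annotation for ({review_id}, {study_unit_id}, "
                        f"{outcome_id.value}, {ann.variable.value})"
                    )
                out[ann.variable] = ann
        return out

    def is_excluded(
        self, review_id: str, study_unit_id: str, outcome_id: OutcomeId
    ) -> bool:
        return any(
            e.review_id == review_id
            and e.study_unit_id == study_unit_id
            and e.outcome_id == outcome_id
            for e in self.analysis_exclusions
        )
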