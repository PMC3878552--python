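"""Variable-level concordance between each review and the reference.

Each review's analysed dataset for a study unit and outcome is compared,
variable by variable (two arms x events, total), against the reference
standard's *primary* dataset for that unit (its earliest-timepoint
record).  A review that analysed an alternative follow-up therefore shows
its timepoint choice as numerator differences — this is how the audit's
printed difference rates arise.  Classification into errors and selection
differences comes from the annotation layer; the engine only decides
*whether* values differ, mirroring the division of labour between
arithmetic and human adjudication.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .types import (
    AuditCorpus,
    DiscrepancyAnnotation,
    Label,
    OutcomeId,
    StudyOutcomeExtraction,
    Timepoint,
    Variable,
)

logger = logging.getLogger(__name__)

#: Compare the review's analysed record against the reference's primary
#: record (default; reproduces the published difference rates), or against
#: the reference record at the review's own timepoint when one exists.
TIMEPOINT_POLICIES = ("as_analysed", "matched")


def round_half_up_pct(count: int, denom: int) -> int:
    """Integer percentage with ties rounded up (2/16 -> 13%)."""
    if denom == 0:
        return 0
    return int(math.floor(100.0 * count / denom + 0.5))


@dataclass(frozen=True)
class VariableComparison:
    variable: Variable
    review_value: Optional[int]
    reference_value: Optional[int]
    differs: bool
    label: Label
    annotated: bool = False


@dataclass(frozen=True)
class DifferenceRateSummary:
    review_id: str
    outcome_id: OutcomeId
    n_units_analysed: int
    n_variables: int
    n_error: int
    n_selection: int

    @property
    def pct_error(self) -> int:
        return round_half_up_pct(self.n_error, self.n_variables)

    @property
    def pct_selection(self) -> int:
        return round_half_up_pct(self.n_selection, self.n_variables)


@dataclass(frozen=True)
class Inconsistency:
    review_id: str
    study_unit_id: str
    outcome_id: OutcomeId
    variable: Variable
    message: str


def compare_study(
    review_rec: StudyOutcomeExtraction,
    reference_rec: Optional[StudyOutcomeExtraction],
    annotations: Iterable[DiscrepancyAnnotation] = (),
) -> list[VariableComparison]:
    """Compare one review record against the reference record.

    Returns one comparison per variable.  The two records must belong to
    the same study unit and outcome (their timepoints may deliberately
    differ: a review may have analysed an alternative follow-up).

    * both values reported: ``differs`` is value inequality; the label
      comes from the annotation when present, else defaults to
      ``identical``/``error`` (the default difference, without human
      adjudication, is treated as an error and logged).
    * review reported, reference NR: the comparison is adjudicated — the
      annotation's label decides (``identical`` meaning the value matches
      the primary publication); unannotated cells default to ``error``
      with a warning.
    * review NR: label ``not_reported``.
    """
    ann_by_var: dict[Variable, DiscrepancyAnnotation] = {}
    for ann in annotations:
        if (
            ann.review_id == review_rec.review_id
            and ann.study_unit_id == review_rec.study_unit_id
            and ann.outcome_id == review_rec.outcome_id
        ):
            ann_by_var[ann.variable] = ann
    if reference_rec is not None and (
        reference_rec.study_unit_id != review_rec.study_unit_id
        or reference_rec.outcome_id != review_rec.outcome_id
    ):
        raise ValueError(
            "compare_study requires records for the same study unit and outcome"
        )

    out = []
    for var in Variable:
        rv = review_rec.value(var)
        fv = None if reference_rec is None else reference_rec.value(var)
        ann = ann_by_var.get(var)
        if rv is None:
            out.append(VariableComparison(var, None, fv, False, Label.not_reported))
            continue
        if fv is None:
            # reference NR: adjudicated against the primary publications
            if ann is not None:
                label = ann.label
                differs = label is not Label.identical
            else:
                label, differs = Label.error, True
                logger.warning(
                    "unannotated reference-NR cell (%s, %s, %s, %s) defaulted to error",
                    review_rec.review_id,
                    review_rec.study_unit_id,
                    review_rec.outcome_id.value,
                    var.value,
                )
            out.append(VariableComparison(var, rv, None, differs, label, ann is not None))
            continue
        differs = rv != fv
        if ann is not None:
            label = ann.label
        elif not differs:
            label = Label.identical
        else:
            label = Label.error
            logger.warning(
                "unannotated difference (%s, %s, %s, %s): %s vs %s defaulted to error",
                review_rec.review_id,
                review_rec.study_unit_id,
                review_rec.outcome_id.value,
                var.value,
                rv,
                fv,
            )
        out.append(VariableComparison(var, rv, fv, differs, label, ann is not None))
    return out


def _reference_record(
    corpus: AuditCorpus,
    unit_id: str,
    outcome_id: OutcomeId,
    review_rec: StudyOutcomeExtraction,
    timepoint_policy: str,
) -> Optional[StudyOutcomeExtraction]:
    ref = corpus.reference_review_id
    if timepoint_policy == "matched" and review_rec.timepoint is not Timepoint.unspecified:
        rec = corpus.get_extraction(ref, unit_id, outcome_id, review_rec.timepoint)
        if rec is not None and rec.is_reported:
            return rec
    return corpus.analysed_record(ref, unit_id, outcome_id)


def unit_comparisons(
    corpus: AuditCorpus,
    review_id: str,
    outcome_id: OutcomeId,
    timepoint_policy: str = "as_analysed",
) -> dict[str, list[VariableComparison]]:
    """Per-analysed-unit variable comparisons for one review and outcome."""
    if timepoint_policy not in TIMEPOINT_POLICIES:
        raise ValueError(f"unknown timepoint_policy {timepoint_policy!r}")
    out: dict[str, list[VariableComparison]] = {}
    for unit_id in corpus.analysed_units(review_id, outcome_id):
        review_rec = corpus.analysed_record(review_id, unit_id, outcome_id)
        ref_rec = _reference_record(corpus, unit_id, outcome_id, review_rec, timepoint_policy)
        anns = corpus.annotations_for(review_id, unit_id, outcome_id).values()
        out[unit_id] = compare_study(review_rec, ref_rec, anns)
    return out


def audit_outcome(
    corpus: AuditCorpus,
    review_id: str,
    outcome_id: OutcomeId,
    timepoint_policy: str = "as_analysed",
) -> DifferenceRateSummary:
    """Aggregate error/selection difference rates for one review/outcome.

    The denominator counts 4 variables per study unit the review reported
    data for (units the review omitted do not enter the denominator).
    """
    if review_id == corpus.reference_review_id:
        raise ValueError("cannot audit the reference review against itself")
    if review_id not in corpus.reviews:
        raise ValueError(f"unknown review {review_id!r}")
    comps = unit_comparisons(corpus, review_id, outcome_id, timepoint_policy)
    n_err = sum(c.label is Label.error for cs in comps.values() for c in cs)
    n_sel = sum(c.label is Label.selection for cs in comps.values() for c in cs)
    return DifferenceRateSummary(
        review_id=review_id,
        outcome_id=outcome_id,
        n_units_analysed=len(comps),
        n_variables=4 * len(comps),
        n_error=n_err,
        n_selection=n_sel,
    )


def audit_all(
    corpus: AuditCorpus, timepoint_policy: str = "as_analysed"
) -> list[DifferenceRateSummary]:
    """Difference-rate summaries for every non-reference review x outcome."""
    out = []
    for outcome in OutcomeId:
        for review in corpus.reviews:
            if review == corpus.reference_review_id:
                continue
            out.append(audit_outcome(corpus, review, outcome, timepoint_policy))
    return out


def check_annotation_consistency(
    corpus: AuditCorpus, timepoint_policy: str = "as_analysed"
) -> list[Inconsistency]:
    """Verify each annotation label against the computed ``differs`` flag.

    Rules: for two reported values, ``identical`` iff equal and
    ``error``/``selection`` only on differing values; on a review-reported,
    reference-NR cell any of identical/error/selection is admissible (the
    adjudication lives outside the corpus); ``not_reported`` only on
    review-NR cells.  Inconsistencies are reported, never raised.
    """
    issues: list[Inconsistency] = []
    for outcome in OutcomeId:
        for review in corpus.reviews:
            if review == corpus.reference_review_id:
                continue
            for unit in corpus.study_units:
                review_rec = corpus.analysed_record(review, unit.unit_id, outcome)
                anns = corpus.annotations_for(review, unit.unit_id, outcome)
                if review_rec is None:
                    for var, ann in anns.items():
                        if ann.label is not Label.not_reported:
                            issues.append(
                                Inconsistency(
                                    review,
                                    unit.unit_id,
                                    outcome,
                                    var,
                                    f"label {ann.label.value!r} on a cell the review "
                                    "did not report",
                                )
                            )
                    continue
                ref_rec = _reference_record(
                    corpus, unit.unit_id, outcome, review_rec, timepoint_policy
                )
                for comp in compare_study(review_rec, ref_rec, anns.values()):
                    if not comp.annotated:
                        continue
                    ok = _label_compatible(comp)
                    if not ok:
                        issues.append(
                            Inconsistency(
                                review,
                                unit.unit_id,
                                outcome,
                                comp.variable,
                                f"label {comp.label.value!r} incompatible with values "
                                f"{comp.review_value!r} vs {comp.reference_value!r}",
                            )
                        )
    return issues


def _label_compatible(comp: VariableComparison) -> bool:
    if comp.review_value is None:
        return comp.label is Label.not_reported
    if comp.reference_value is None:
        return comp.label is not Label.not_reported
    if comp.label is Label.identical:
        return not comp.differs
    if comp.label in (Label.error, Label.selection):
        return comp.differs
    return False  # not_reported on a reported cell


def render_rate_table(summaries: list[DifferenceRateSummary]) -> str:
    """Aligned-text table of difference rates, one row per review/outcome."""
    header = f"{'outcome':<14}{'review':<10}{'units':>6}{'vars':>6}{'errors':>12}{'selection':>14}"
    lines = [header, "-" * len(header)]
    for s in summaries:
        lines.append(
            f"{s.outcome_id.value:<14}{s.review_id:<10}{s.n_units_analysed:>6}"
            f"{s.n_variables:>6}"
            f"{f'{s.n_error}/{s.n_variables} = {s.pct_error}%':>12}"
            f"{f'{s.n_selection}/{s.n_variables} = {s.pct_selection}%':>14}"
        )
    return "\n".join(lines)


def summaries_to_json(summaries: list[DifferenceRateSummary]) -> list[dict]:
    return [
        {
            "review_id": s.review_id,
            "outcome_id": s.outcome_id.value,
            "n_units_analysed": s.n_units_analysed,
            "n_variables": s.n_variables,
            "n_error": s.n_error,
            "n_selection": s.n_selection,
            "pct_error": s.pct_error,
            "pct_selection": s.pct_selection,
        }
        for s in summaries
    ]
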