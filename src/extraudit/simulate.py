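"""Synthetic multi-review extraction corpora with known ground truth.

A reference review's (correct) extraction of a set of two-arm trials is
simulated first; each further review is then a perturbed copy in which
typed discrepancies are planted independently per study and type:

* ``transposition`` — the two arm denominators are swapped (an *error*);
* ``percent_recalc`` — numerators are recalculated from the rounded event
  percentage on an off-by-one denominator (an *error*);
* ``alt_arm`` — the comparator arm is replaced by a second simulated arm
  of the same trial (a *selection* difference);
* ``alt_timepoint`` — event counts are re-simulated at a shorter
  follow-up horizon with risk scaled down (a *selection* difference);
* ``denominator_policy`` — a small number of per-protocol exclusions is
  subtracted from each arm total, events unchanged (a *selection*
  difference, e.g. ITT vs per-protocol denominators);
* ``nr_mask`` — the study is marked not reported by the review.

Every planted perturbation is logged as a :class:`PerturbationRecord`
carrying its ground-truth label, and annotations are derived so that the
concordance checker is consistent by construction.  A single random
stream drives the whole corpus: trials first, then each review's
perturbations in review order, so a seed fully determines the output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import (
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


class PerturbationKind(str, enum.Enum):
    transposition = "transposition"
    percent_recalc = "percent_recalc"
    alt_arm = "alt_arm"
    alt_timepoint = "alt_timepoint"
    denominator_policy = "denominator_policy"
    nr_mask = "nr_mask"


#: Fixed mapping from perturbation mechanism to ground-truth label.
KIND_TO_LABEL = {
    PerturbationKind.transposition: Label.error,
    PerturbationKind.percent_recalc: Label.error,
    PerturbationKind.alt_arm: Label.selection,
    PerturbationKind.alt_timepoint: Label.selection,
    PerturbationKind.denominator_policy: Label.selection,
    PerturbationKind.nr_mask: Label.not_reported,
}

#: Application order within a study (NR masking last, overriding the rest).
_APPLY_ORDER = (
    PerturbationKind.transposition,
    PerturbationKind.percent_recalc,
    PerturbationKind.alt_arm,
    PerturbationKind.alt_timepoint,
    PerturbationKind.denominator_policy,
    PerturbationKind.nr_mask,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic corpus.

    Defaults mirror the audited case study: six two-arm trials per
    outcome, three parallel reviews, arm sizes spanning the printed
    trials (17–111 participants), comparator event risks in a moderate
    5–25% band and a null treatment effect.  Per-study perturbation
    rates default to 10% per type, the order of magnitude of the
    published per-variable error rates.
    """

    n_studies: int = 6
    arm_size_range: tuple[int, int] = (17, 111)
    baseline_risk_range: tuple[float, float] = (0.05, 0.25)
    true_rr: float = 1.0
    rate_transposition: float = 0.1
    rate_percent_recalc: float = 0.1
    rate_alt_arm: float = 0.1
    rate_alt_timepoint: float = 0.1
    rate_denominator_policy: float = 0.1
    rate_nr: float = 0.1
    n_reviews: int = 3
    seed: int = 0
    outcome_id: OutcomeId = OutcomeId.dislocation
    alt_timepoint_risk_scale: float = 0.5

    def __post_init__(self):
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.n_reviews < 1:
            raise ValueError("n_reviews must be >= 1")
        lo, hi = self.arm_size_range
        if lo < 2 or hi < lo:
            raise ValueError("arm_size_range must be a nonempty range with sizes >= 2")
        rlo, rhi = self.baseline_risk_range
        if not (0.0 <= rlo <= rhi <= 1.0):
            raise ValueError("baseline_risk_range must lie in [0, 1]")
        if self.true_rr <= 0:
            raise ValueError("true_rr must be positive")
        for name in (
            "rate_transposition",
            "rate_percent_recalc",
            "rate_alt_arm",
            "rate_alt_timepoint",
            "rate_denominator_policy",
            "rate_nr",
        ):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def rate(self, kind: PerturbationKind) -> float:
        return {
            PerturbationKind.transposition: self.rate_transposition,
            PerturbationKind.percent_recalc: self.rate_percent_recalc,
            PerturbationKind.alt_arm: self.rate_alt_arm,
            PerturbationKind.alt_timepoint: self.rate_alt_timepoint,
            PerturbationKind.denominator_policy: self.rate_denominator_policy,
            PerturbationKind.nr_mask: self.rate_nr,
        }[kind]


@dataclass(frozen=True)
class PerturbationRecord:
    """Ground truth for one planted discrepancy."""

    review_id: str
    study_unit_id: str
    outcome_id: OutcomeId
    kind: PerturbationKind
    variables: tuple[Variable, ...]
    true_label: Label
    effective: bool = True


REFERENCE_ID = "R0"


def _review_id(index: int) -> str:
    return f"R{index}"


def _unit_id(index: int) -> str:
    return f"study_{index:03d}"


def generate_truth_trials(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list[StudyOutcomeExtraction]:
    """Simulate the reference review's (correct) extractions.

    Per study: arm totals uniform over ``arm_size_range``, comparator
    risk uniform over ``baseline_risk_range``, index-arm risk
    ``min(1, true_rr * comparator risk)``, events binomial.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.arm_size_range
    rlo, rhi = config.baseline_risk_range
    out = []
    for i in range(config.n_studies):
        n1 = int(rng.integers(lo, hi + 1))
        n2 = int(rng.integers(lo, hi + 1))
        risk_b = float(rng.uniform(rlo, rhi))
        risk_a = min(1.0, config.true_rr * risk_b)
        a = int(rng.binomial(n1, risk_a))
        c = int(rng.binomial(n2, risk_b))
        out.append(
            StudyOutcomeExtraction(
                review_id=REFERENCE_ID,
                study_unit_id=_unit_id(i),
                outcome_id=config.outcome_id,
                timepoint=Timepoint.unspecified,
                arm_a=ArmExtraction.reported(a, n1),
                arm_b=ArmExtraction.reported(c, n2),
            )
        )
    return out


def _percent_recalc_arm(arm: ArmExtraction, shift: int = 1) -> ArmExtraction:
    """Numerator recalculated from the rounded percentage on an
    off-by-one denominator, emulating a review that rebuilt counts from
    printed percentages and its own (wrong) arm sizes."""
    pct = round(100.0 * arm.events / arm.total) / 100.0
    total = arm.total + shift
    events = int(round(total * pct))
    return ArmExtraction.reported(min(events, total), total)


def _perturb_study(
    rec: StudyOutcomeExtraction,
    config: SimulationConfig,
    review_id: str,
    rng: np.random.Generator,
) -> tuple[StudyOutcomeExtraction, list[PerturbationRecord]]:
    new = replace_review(rec, review_id)
    records: list[PerturbationRecord] = []
    for kind in _APPLY_ORDER:
        if rng.uniform() >= config.rate(kind):
            continue
        before = new
        if kind is PerturbationKind.transposition:
            new = new.model_copy(
                update={
                    "arm_a": ArmExtraction.reported(
                        min(new.arm_a.events, new.arm_b.total), new.arm_b.total
                    ),
                    "arm_b": ArmExtraction.reported(
                        min(new.arm_b.events, new.arm_a.total), new.arm_a.total
                    ),
                }
            )
            variables = (Variable.arm_a_total, Variable.arm_b_total)
        elif kind is PerturbationKind.percent_recalc:
            new = new.model_copy(
                update={
                    "arm_a": _percent_recalc_arm(new.arm_a),
                    "arm_b": _percent_recalc_arm(new.arm_b),
                }
            )
            variables = tuple(Variable)
        elif kind is PerturbationKind.alt_arm:
            lo, hi = config.arm_size_range
            n2 = int(rng.integers(lo, hi + 1))
            risk = new.arm_b.events / new.arm_b.total
            c = int(rng.binomial(n2, risk))
            new = new.model_copy(update={"arm_b": ArmExtraction.reported(c, n2)})
            variables = (Variable.arm_b_events, Variable.arm_b_total)
        elif kind is PerturbationKind.alt_timepoint:
            scale = config.alt_timepoint_risk_scale
            a = int(rng.binomial(new.arm_a.total, scale * new.arm_a.events / new.arm_a.total))
            c = int(rng.binomial(new.arm_b.total, scale * new.arm_b.events / new.arm_b.total))
            new = new.model_copy(
                update={
                    "arm_a": ArmExtraction.reported(a, new.arm_a.total),
                    "arm_b": ArmExtraction.reported(c, new.arm_b.total),
                }
            )
            variables = (Variable.arm_a_events, Variable.arm_b_events)
        elif kind is PerturbationKind.denominator_policy:
            excl_a = int(rng.integers(1, 4))
            excl_b = int(rng.integers(1, 4))
            n1 = max(new.arm_a.events, new.arm_a.total - excl_a, 1)
            n2 = max(new.arm_b.events, new.arm_b.total - excl_b, 1)
            new = new.model_copy(
                update={
                    "arm_a": ArmExtraction.reported(new.arm_a.events, n1),
                    "arm_b": ArmExtraction.reported(new.arm_b.events, n2),
                }
            )
            variables = (Variable.arm_a_total, Variable.arm_b_total)
        else:  # nr_mask
            new = new.model_copy(
                update={"arm_a": ArmExtraction.nr(), "arm_b": ArmExtraction.nr()}
            )
            variables = tuple(Variable)
        effective = new != before
        records.append(
            PerturbationRecord(
                review_id=review_id,
                study_unit_id=rec.study_unit_id,
                outcome_id=rec.outcome_id,
                kind=kind,
                variables=variables,
                true_label=KIND_TO_LABEL[kind],
                effective=effective,
            )
        )
        if kind is PerturbationKind.nr_mask:
            break
    return new, records


def replace_review(rec: StudyOutcomeExtraction, review_id: str) -> StudyOutcomeExtraction:
    return rec.model_copy(update={"review_id": review_id})


def perturb_review(
    truth: list[StudyOutcomeExtraction],
    config: SimulationConfig,
    review_index: int,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[StudyOutcomeExtraction], list[PerturbationRecord]]:
    """Perturbed copy of the reference extractions for one review.

    Each study x perturbation type is sampled independently at its
    configured rate.  When called standalone the stream is seeded from
    ``(config.seed, review_index)``; :func:`generate_corpus` passes its
    single corpus-wide stream instead.
    """
    if not truth:
        raise ValueError("truth extraction list is empty")
    if rng is None:
        rng = np.random.default_rng([config.seed, review_index])
    review_id = _review_id(review_index)
    extractions: list[StudyOutcomeExtraction] = []
    records: list[PerturbationRecord] = []
    for rec in truth:
        new, recs = _perturb_study(rec, config, review_id, rng)
        extractions.append(new)
        records.extend(recs)
    return extractions, records


def _derive_annotations(
    truth: list[StudyOutcomeExtraction],
    reviews: dict[str, list[StudyOutcomeExtraction]],
    records: list[PerturbationRecord],
) -> list[DiscrepancyAnnotation]:
    """Annotation layer implied by the planted perturbations.

    A variable is annotated with its perturbation's ground-truth label
    only when the stored value actually differs from the truth (an
    ineffective perturbation, e.g. a transposition of equal denominators,
    leaves the value identical and must not be labelled a difference).
    When several perturbations touch the same variable the one applied
    last wins, matching the stored value.
    """
    truth_by_unit = {t.study_unit_id: t for t in truth}
    labels: dict[tuple[str, str, OutcomeId, Variable], tuple[Label, str]] = {}
    for rec in records:
        review_recs = {r.study_unit_id: r for r in reviews[rec.review_id]}
        stored = review_recs[rec.study_unit_id]
        true_rec = truth_by_unit[rec.study_unit_id]
        if rec.kind is PerturbationKind.nr_mask:
            continue  # review-NR cells are computed, not annotated
        for var in rec.variables:
            if stored.value(var) is None:
                continue
            if stored.value(var) != true_rec.value(var):
                key = (rec.review_id, rec.study_unit_id, rec.outcome_id, var)
                labels[key] = (rec.true_label, rec.kind.value)
    return [
        DiscrepancyAnnotation(
            review_id=review_id,
            study_unit_id=unit_id,
            outcome_id=outcome_id,
            variable=var,
            label=label,
            rationale=f"planted perturbation: {kind}",
        )
        for (review_id, unit_id, outcome_id, var), (label, kind) in labels.items()
    ]


def generate_corpus(
    config: SimulationConfig,
) -> tuple[AuditCorpus, list[PerturbationRecord]]:
    """Simulate a full corpus: reference review plus perturbed reviews.

    Review 0 is the reference; reviews 1..n-1 are perturbed
    independently.  The derived annotation layer is consistent with the
    concordance checker by construction.
    """
    if config.n_reviews < 2:
        raise ValueError("generate_corpus requires n_reviews >= 2")
    rng = np.random.default_rng(config.seed)
    truth = generate_truth_trials(config, rng)
    extractions = list(truth)
    reviews_map: dict[str, list[StudyOutcomeExtraction]] = {REFERENCE_ID: truth}
    all_records: list[PerturbationRecord] = []
    for idx in range(1, config.n_reviews):
        recs, records = perturb_review(truth, config, idx, rng)
        reviews_map[_review_id(idx)] = recs
        extractions.extend(recs)
        all_records.extend(records)
    annotations = _derive_annotations(truth, reviews_map, all_records)
    corpus = AuditCorpus(
        reviews=tuple(_review_id(i) for i in range(config.n_reviews)),
        reference_review_id=REFERENCE_ID,
        study_units=tuple(
            StudyUnit(unit_id=_unit_id(i)) for i in range(config.n_studies)
        ),
        extractions=tuple(extractions),
        annotations=tuple(annotations),
    )
    return corpus, all_records
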