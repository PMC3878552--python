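"""Cross-review sensitivity of the pooled estimates.

For each outcome (and follow-up timepoint where one applies) the pooled
random-effects relative risk obtained from a review's extraction dataset
is compared against the one obtained from the reference standard's
dataset: how far apart are the pooled log RRs, and does the qualitative
conclusion (95% CI excluding the null) flip between the two?  No formal
test of the difference is computed — the comparison is descriptive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

from .meta import MetaAnalysisError, PooledResult, available_timepoints, pooled_from_corpus
from .types import AuditCorpus, OutcomeId, Timepoint

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImpactComparison:
    outcome_id: OutcomeId
    timepoint: Optional[Timepoint]
    review_a: str
    review_b: str
    rr_a: float
    rr_b: float
    significant_a: bool
    significant_b: bool

    @property
    def ratio_of_rrs(self) -> float:
        return self.rr_a / self.rr_b

    @property
    def log_rr_difference(self) -> float:
        return abs(math.log(self.rr_a) - math.log(self.rr_b))

    @property
    def flip(self) -> bool:
        return self.significant_a != self.significant_b


def compare_pooled(
    a: PooledResult,
    b: PooledResult,
    outcome_id: OutcomeId,
    review_a: str,
    review_b: str,
    timepoint: Optional[Timepoint] = None,
) -> ImpactComparison:
    """Compare two pooled results for the same outcome and timepoint.

    Significance is judged by the 95% CI excluding 1 (the CI bounds are
    reported to more precision than the rounded p-values).
    """
    return ImpactComparison(
        outcome_id=outcome_id,
        timepoint=timepoint,
        review_a=review_a,
        review_b=review_b,
        rr_a=a.rr,
        rr_b=b.rr,
        significant_a=a.significant,
        significant_b=b.significant,
    )


def impact_report(
    corpus: AuditCorpus, estimator: str = "dl", continuity: str = "half"
) -> list[ImpactComparison]:
    """All reference-vs-review comparisons, per outcome and timepoint.

    Each non-reference review is compared at the timepoints its dataset
    supports (a review that analysed only the long follow-up is compared
    there).  Pairs where either side has no poolable studies are skipped
    and logged.
    """
    out: list[ImpactComparison] = []
    ref = corpus.reference_review_id
    for outcome in OutcomeId:
        for review in corpus.reviews:
            if review == ref:
                continue
            tps = available_timepoints(corpus, review, outcome)
            ref_tps = set(available_timepoints(corpus, ref, outcome))
            for tp in tps:
                if tp not in ref_tps:
                    logger.info(
                        "skipping %s/%s at %s: reference lacks the timepoint",
                        review, outcome.value, tp,
                    )
                    continue
                try:
                    pa = pooled_from_corpus(corpus, ref, outcome, tp, estimator, continuity)
                    pb = pooled_from_corpus(corpus, review, outcome, tp, estimator, continuity)
                except MetaAnalysisError as exc:
                    logger.info(
                        "skipping %s/%s at %s: %s", review, outcome.value, tp, exc
                    )
                    continue
                out.append(compare_pooled(pa, pb, outcome, ref, review, tp))
    return out


def render_impact_markdown(comparisons: list[ImpactComparison]) -> str:
    lines = [
        "| outcome | timepoint | reference | review | RR ref | RR review | ratio | abs log-RR diff | sig ref | sig review | flip |",
        "|---|---|---|---|---|---|---|---|---|---|---|",
    ]
    for c in comparisons:
        tp = c.timepoint.value if c.timepoint else "-"
        lines.append(
            f"| {c.outcome_id.value} | {tp} | {c.review_a} | {c.review_b} "
            f"| {c.rr_a:.2f} | {c.rr_b:.2f} | {c.ratio_of_rrs:.3f} "
            f"| {c.log_rr_difference:.4f} | {c.significant_a} | {c.significant_b} "
            f"| {'YES' if c.flip else 'no'} |"
        )
    return "\n".join(lines)


def impact_to_json(comparisons: list[ImpactComparison]) -> list[dict]:
    return [
        {
            "outcome_id": c.outcome_id.value,
            "timepoint": c.timepoint.value if c.timepoint else None,
            "review_a": c.review_a,
            "review_b": c.review_b,
            "rr_a": c.rr_a,
            "rr_b": c.rr_b,
            "ratio_of_rrs": c.ratio_of_rrs,
            "log_rr_difference": c.log_rr_difference,
            "significant_a": c.significant_a,
            "significant_b": c.significant_b,
            "flip": c.flip,
        }
        for c in comparisons
    ]
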