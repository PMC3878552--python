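"""Random-effects meta-analysis of relative risks from 2x2 tables.

The estimator is the DerSimonian–Laird (DL) moment estimator: per-study
log risk ratios y_i = ln[(a/n1)/(c/n2)] with variances
v_i = 1/a − 1/n1 + 1/c − 1/n2 are pooled by inverse-variance weighting;
the between-study variance is

    tau² = max(0, (Q − (k − 1)) / (Σw − Σw²/Σw)),   w_i = 1/v_i,

with Q the fixed-effect heterogeneity statistic, and the random-effects
weights are w*_i = 1/(v_i + tau²).  Zero cells are handled by the
standard continuity policy for risk ratios: a study with zero events in
both arms carries no information about the ratio and is excluded; a study
with a zero in exactly one arm has 0.5 added to both event cells and 1 to
both totals.  Confidence intervals use the normal 1.96 multiplier.

A Mantel–Haenszel fixed-effect estimator (Greenland–Robins variance) is
provided as a cross-check mode, since published tables rarely name the
software that produced them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .types import AuditCorpus, OutcomeId, Timepoint

Z_95 = 1.96

CONTINUITY_POLICIES = ("half", "none")
ESTIMATORS = ("dl", "mh-fixed")


class MetaAnalysisError(ValueError):
    """No poolable studies."""


@dataclass(frozen=True)
class TwoByTwo:
    """Events and totals for the two arms of one trial (a/n1 vs c/n2)."""

    a: int
    n1: int
    c: int
    n2: int
    label: str = ""

    def __post_init__(self):
        if not (self.n1 > 0 and self.n2 > 0):
            raise ValueError("arm totals must be positive")
        if not (0 <= self.a <= self.n1 and 0 <= self.c <= self.n2):
            raise ValueError("events must lie in [0, total]")


@dataclass(frozen=True)
class EffectEstimate:
    log_rr: float
    var_log_rr: float
    corrected: bool
    excluded: bool
    exclusion_reason: str = ""
    label: str = ""

    @property
    def rr(self) -> float:
        return math.exp(self.log_rr)


@dataclass(frozen=True)
class PooledResult:
    rr: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    tau2: float
    q: float
    k: int

    @property
    def significant(self) -> bool:
        """95% CI excludes the null ratio of 1."""
        return self.ci_low > 1.0 or self.ci_high < 1.0


def effect_from_table(t: TwoByTwo, correction: str = "half") -> EffectEstimate:
    """Log risk ratio and variance for one study, applying the zero-cell
    policy (``half``: single-zero correction, double-zero exclusion;
    ``none``: exclude any study with a zero event cell)."""
    if correction not in CONTINUITY_POLICIES:
        raise ValueError(f"unknown continuity policy {correction!r}")
    a, n1, c, n2 = float(t.a), float(t.n1), float(t.c), float(t.n2)
    corrected = False
    if t.a == 0 and t.c == 0:
        return EffectEstimate(0.0, 0.0, False, True, "double_zero", t.label)
    if t.a == 0 or t.c == 0:
        if correction == "none":
            return EffectEstimate(0.0, 0.0, False, True, "zero_cell", t.label)
        a, c, n1, n2 = a + 0.5, c + 0.5, n1 + 1.0, n2 + 1.0
        corrected = True
    log_rr = math.log((a / n1) / (c / n2))
    var = 1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n2
    return EffectEstimate(log_rr, var, corrected, False, "", t.label)


def dl_tau_squared(estimates: Sequence[EffectEstimate]) -> tuple[float, float]:
    """DerSimonian–Laird between-study variance and the Q statistic."""
    included = [e for e in estimates if not e.excluded]
    if not included:
        raise MetaAnalysisError("all studies excluded; nothing to pool")
    y = np.array([e.log_rr for e in included])
    w = 1.0 / np.array([e.var_log_rr for e in included])
    k = len(included)
    if k == 1:
        return 0.0, 0.0
    y_fixed = float((w * y).sum() / w.sum())
    q = float((w * (y - y_fixed) ** 2).sum())
    denom = float(w.sum() - (w**2).sum() / w.sum())
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    return tau2, q


def pool_random_effects(
    estimates: Sequence[EffectEstimate], tau2: Optional[float] = None
) -> PooledResult:
    """Inverse-variance random-effects pooling of log risk ratios.

    ``tau2=0`` reduces to the fixed-effect inverse-variance estimate.
    """
    included = [e for e in estimates if not e.excluded]
    if not included:
        raise MetaAnalysisError("all studies excluded; nothing to pool")
    est_tau2, q = dl_tau_squared(estimates)
    if tau2 is None:
        tau2 = est_tau2
    y = np.array([e.log_rr for e in included])
    w = 1.0 / (np.array([e.var_log_rr for e in included]) + tau2)
    mu = float((w * y).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = mu / se
    p = float(2.0 * norm.sf(abs(z)))
    return PooledResult(
        rr=math.exp(mu),
        ci_low=math.exp(mu - Z_95 * se),
        ci_high=math.exp(mu + Z_95 * se),
        z=z,
        p=p,
        tau2=tau2,
        q=q,
        k=len(included),
    )


def pool_mantel_haenszel(tables: Sequence[TwoByTwo]) -> PooledResult:
    """Mantel–Haenszel fixed-effect pooled risk ratio (cross-check mode).

    Uses the Greenland–Robins variance; double-zero studies drop out of
    the sums naturally and no continuity correction is applied.
    """
    usable = [t for t in tables if not (t.a == 0 and t.c == 0)]
    if not usable:
        raise MetaAnalysisError("all studies excluded; nothing to pool")
    num = sum(t.a * t.n2 / (t.n1 + t.n2) for t in usable)
    den = sum(t.c * t.n1 / (t.n1 + t.n2) for t in usable)
    if num == 0 or den == 0:
        raise MetaAnalysisError("MH pooled ratio undefined (zero margin)")
    rr = num / den
    # Greenland-Robins variance of log RR_MH
    p_sum = sum(
        ((t.a + t.c) * t.n1 * t.n2 / (t.n1 + t.n2) ** 2 - t.a * t.c / (t.n1 + t.n2))
        for t in usable
    )
    var = p_sum / (num * den)
    se = math.sqrt(var)
    mu = math.log(rr)
    z = mu / se
    return PooledResult(
        rr=rr,
        ci_low=math.exp(mu - Z_95 * se),
        ci_high=math.exp(mu + Z_95 * se),
        z=z,
        p=float(2.0 * norm.sf(abs(z))),
        tau2=0.0,
        q=float("nan"),
        k=len(usable),
    )


# ---------------------------------------------------------------------------
# corpus assembly


def tables_from_corpus(
    corpus: AuditCorpus,
    review_id: str,
    outcome_id: OutcomeId,
    timepoint: Optional[Timepoint] = None,
) -> list[TwoByTwo]:
    """Assemble one 2x2 table per analysed study unit.

    A unit that distinguishes follow-up timepoints contributes its record
    at the requested timepoint (and is skipped when the review did not
    report that timepoint); a unit with a single dataset contributes it to
    any requested timepoint.  Units listed in the corpus's analysis
    exclusions are dropped.
    """
    tables = []
    for unit_id in corpus.analysed_units(review_id, outcome_id):
        if corpus.is_excluded(review_id, unit_id, outcome_id):
            continue
        recs = [
            r for r in corpus.records(review_id, outcome_id, unit_id) if r.is_reported
        ]
        distinguishes = any(r.timepoint is not Timepoint.unspecified for r in recs) or (
            corpus.get_extraction(review_id, unit_id, outcome_id, Timepoint.one_year)
            is not None
            or corpus.get_extraction(
                review_id, unit_id, outcome_id, Timepoint.thirteen_year
            )
            is not None
        )
        if distinguishes and timepoint is not None:
            recs = [r for r in recs if r.timepoint == timepoint]
        if not recs:
            continue
        recs.sort(key=lambda r: (Timepoint.one_year, Timepoint.unspecified,
                                 Timepoint.thirteen_year).index(r.timepoint))
        rec = recs[0]
        tables.append(
            TwoByTwo(
                a=rec.arm_a.events,
                n1=rec.arm_a.total,
                c=rec.arm_b.events,
                n2=rec.arm_b.total,
                label=unit_id,
            )
        )
    return tables


def pooled_from_corpus(
    corpus: AuditCorpus,
    review_id: str,
    outcome_id: OutcomeId,
    timepoint: Optional[Timepoint] = None,
    estimator: str = "dl",
    continuity: str = "half",
) -> PooledResult:
    """Pool one review's extraction dataset for one outcome."""
    model = RiskRatioMetaAnalysis.from_corpus(
        corpus, review_id, outcome_id, timepoint, estimator=estimator, continuity=continuity
    )
    return model.fit().pooled


def available_timepoints(
    corpus: AuditCorpus, review_id: str, outcome_id: OutcomeId
) -> list[Optional[Timepoint]]:
    """Timepoints at which the review's dataset is complete.

    If any analysed unit distinguishes timepoints, the review can be
    pooled at each specific timepoint for which every such unit has a
    reported record; otherwise the single undifferentiated dataset is
    pooled (returned as ``[None]``).
    """
    specific: Optional[set[Timepoint]] = None
    for unit_id in corpus.analysed_units(review_id, outcome_id):
        recs = corpus.records(review_id, outcome_id, unit_id)
        tps = {
            r.timepoint
            for r in recs
            if r.is_reported and r.timepoint is not Timepoint.unspecified
        }
        if any(r.timepoint is not Timepoint.unspecified for r in recs):
            specific = tps if specific is None else (specific & tps)
    if specific is None:
        return [None] if corpus.analysed_units(review_id, outcome_id) else []
    order = (Timepoint.one_year, Timepoint.thirteen_year)
    return [tp for tp in order if tp in specific]


# ---------------------------------------------------------------------------
# model / results objects


class RiskRatioMetaAnalysis:
    """Meta-analysis model for a set of 2x2 tables.

    Parameters
    ----------
    tables : sequence of TwoByTwo
        One table per study.
    estimator : {"dl", "mh-fixed"}
        DerSimonian–Laird inverse-variance random effects (default) or the
        Mantel–Haenszel fixed-effect cross-check.
    continuity : {"half", "none"}
        Zero-cell policy for the DL estimator.
    """

    def __init__(
        self,
        tables: Sequence[TwoByTwo],
        estimator: str = "dl",
        continuity: str = "half",
        description: str = "",
    ):
        if estimator not in ESTIMATORS:
            raise ValueError(f"unknown estimator {estimator!r}")
        if continuity not in CONTINUITY_POLICIES:
            raise ValueError(f"unknown continuity policy {continuity!r}")
        self.tables = list(tables)
        self.estimator = estimator
        self.continuity = continuity
        self.description = description

    @classmethod
    def from_corpus(
        cls,
        corpus: AuditCorpus,
        review_id: str,
        outcome_id: OutcomeId,
        timepoint: Optional[Timepoint] = None,
        estimator: str = "dl",
        continuity: str = "half",
    ) -> "RiskRatioMetaAnalysis":
        if review_id not in corpus.reviews:
            raise ValueError(f"unknown review {review_id!r}")
        tables = tables_from_corpus(corpus, review_id, outcome_id, timepoint)
        if not tables:
            raise MetaAnalysisError(
                f"no analysable studies for ({review_id}, {outcome_id.value}, "
                f"{timepoint.value if timepoint else 'any'})"
            )
        desc = f"{outcome_id.value}, {review_id}" + (
            f", {timepoint.value}" if timepoint else ""
        )
        return cls(tables, estimator=estimator, continuity=continuity, description=desc)

    def fit(self) -> "MetaAnalysisResults":
        estimates = [effect_from_table(t, self.continuity) for t in self.tables]
        if self.estimator == "mh-fixed":
            pooled = pool_mantel_haenszel(self.tables)
        else:
            pooled = pool_random_effects(estimates)
        return MetaAnalysisResults(self, estimates, pooled)


class MetaAnalysisResults:
    """Fitted pooled estimate with per-study effects and diagnostics."""

    def __init__(
        self,
        model: RiskRatioMetaAnalysis,
        estimates: list[EffectEstimate],
        pooled: PooledResult,
    ):
        self.model = model
        self.estimates = estimates
        self.pooled = pooled

    # convenience passthroughs
    @property
    def rr(self) -> float:
        return self.pooled.rr

    @property
    def ci(self) -> tuple[float, float]:
        return (self.pooled.ci_low, self.pooled.ci_high)

    @property
    def p(self) -> float:
        return self.pooled.p

    @property
    def tau2(self) -> float:
        return self.pooled.tau2

    def summary(self) -> str:
        p = self.pooled
        lines = []
        title = "Risk-ratio meta-analysis"
        if self.model.description:
            title += f" ({self.model.description})"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(
            f"estimator: {self.model.estimator}   continuity: {self.model.continuity}"
        )
        lines.append(f"{'study':<20}{'RR':>9}{'log RR':>10}{'var':>9}  note")
        for t, e in zip(self.model.tables, self.estimates):
            name = t.label or f"{t.a}/{t.n1} vs {t.c}/{t.n2}"
            if e.excluded:
                lines.append(f"{name:<20}{'-':>9}{'-':>10}{'-':>9}  excluded ({e.exclusion_reason})")
            else:
                note = "corrected" if e.corrected else ""
                lines.append(
                    f"{name:<20}{e.rr:>9.4f}{e.log_rr:>10.4f}{e.var_log_rr:>9.4f}  {note}"
                )
        lines.append("-" * 56)
        lines.append(
            f"pooled RR = {p.rr:.2f}  95% CI ({p.ci_low:.2f}, {p.ci_high:.2f})  "
            f"p = {p.p:.2f}"
        )
        lines.append(f"k = {p.k}  tau^2 = {p.tau2:.4f}  Q = {p.q:.4f}")
        return "\n".join(lines)

    def forest(self, ax=None):
        """Forest plot of per-study and pooled risk ratios (log scale)."""
        from .plotting import forest_plot

        return forest_plot(self, ax=ax)

    def to_dict(self) -> dict:
        p = self.pooled
        return {
            "rr": p.rr,
            "ci_low": p.ci_low,
            "ci_high": p.ci_high,
            "z": p.z,
            "p": p.p,
            "tau2": p.tau2,
            "q": p.q,
            "k": p.k,
        }
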