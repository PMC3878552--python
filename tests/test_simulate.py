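"""Synthetic corpus generation: determinism, perturbation mechanics,
detection completeness and statistical calibration."""

from collections import Counter

import numpy as np
import pytest

from extraudit import (
    TwoByTwo,
    check_annotation_consistency,
    effect_from_table,
    pool_random_effects,
)
from extraudit.concordance import unit_comparisons
from extraudit.simulate import (
    PerturbationKind,
    SimulationConfig,
    generate_corpus,
    generate_truth_trials,
    perturb_review,
)


def null_rates():
    return dict(
        rate_transposition=0, rate_percent_recalc=0, rate_alt_arm=0,
        rate_alt_timepoint=0, rate_denominator_policy=0, rate_nr=0,
    )


class TestConfigValidation:
    def test_empty_arm_size_range_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(arm_size_range=(10, 5))

    def test_arm_sizes_below_two_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(arm_size_range=(1, 5))

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(rate_nr=1.5)


class TestTruthTrials:
    def test_same_seed_same_corpus(self):
        cfg = SimulationConfig(seed=99)
        c1, r1 = generate_corpus(cfg)
        c2, r2 = generate_corpus(cfg)
        assert c1 == c2 and r1 == r2

    def test_zero_baseline_risk_gives_zero_events(self):
        cfg = SimulationConfig(baseline_risk_range=(0.0, 0.0), seed=3)
        trials = generate_truth_trials(cfg)
        assert all(t.arm_a.events == 0 and t.arm_b.events == 0 for t in trials)

    def test_arm_sizes_respect_range(self):
        cfg = SimulationConfig(n_studies=50, arm_size_range=(20, 30), seed=4)
        for t in generate_truth_trials(cfg):
            assert 20 <= t.arm_a.total <= 30
            assert 20 <= t.arm_b.total <= 30

    def test_null_effect_unbiased(self):
        """With true RR = 1 the mean observed per-study log RR over many
        replicates is near zero (continuity-corrected where needed)."""
        logs = []
        for rep in range(200):
            cfg = SimulationConfig(seed=20_000 + rep)
            for t in generate_truth_trials(cfg):
                e = effect_from_table(
                    TwoByTwo(t.arm_a.events, t.arm_a.total, t.arm_b.events, t.arm_b.total)
                )
                if not e.excluded:
                    logs.append(e.log_rr)
        assert abs(np.mean(logs)) < 0.05


class TestPerturbations:
    def test_null_rates_leave_reviews_identical(self):
        cfg = SimulationConfig(seed=11, **null_rates())
        truth = generate_truth_trials(cfg)
        perturbed, records = perturb_review(truth, cfg, 1)
        assert records == []
        for t, p in zip(truth, perturbed):
            assert p.arm_a == t.arm_a and p.arm_b == t.arm_b

    def test_forced_transposition_swaps_all_denominators(self):
        cfg = SimulationConfig(
            n_studies=20, seed=21, baseline_risk_range=(0.05, 0.15),
            **{**null_rates(), "rate_transposition": 1.0},
        )
        truth = generate_truth_trials(cfg)
        perturbed, records = perturb_review(truth, cfg, 1)
        assert all(r.kind is PerturbationKind.transposition for r in records)
        assert len(records) == 20
        for t, p in zip(truth, perturbed):
            if t.arm_a.total != t.arm_b.total:
                assert p.arm_a.total == t.arm_b.total
                assert p.arm_b.total == t.arm_a.total

    def test_transposition_of_equal_totals_flagged_ineffective(self):
        cfg = SimulationConfig(
            n_studies=30, seed=22, arm_size_range=(40, 40),
            baseline_risk_range=(0.0, 0.0),
            **{**null_rates(), "rate_transposition": 1.0},
        )
        truth = generate_truth_trials(cfg)
        _, records = perturb_review(truth, cfg, 1)
        assert all(not r.effective for r in records)

    def test_nr_mask_produces_unreported_records(self):
        cfg = SimulationConfig(
            n_studies=10, seed=23, **{**null_rates(), "rate_nr": 1.0}
        )
        truth = generate_truth_trials(cfg)
        perturbed, records = perturb_review(truth, cfg, 1)
        assert all(not p.is_reported for p in perturbed)
        assert all(r.kind is PerturbationKind.nr_mask for r in records)

    def test_denominator_policy_keeps_events_and_caps_totals(self):
        cfg = SimulationConfig(
            n_studies=40, seed=24,
            **{**null_rates(), "rate_denominator_policy": 1.0},
        )
        truth = generate_truth_trials(cfg)
        perturbed, _ = perturb_review(truth, cfg, 1)
        for t, p in zip(truth, perturbed):
            assert p.arm_a.events == t.arm_a.events
            assert p.arm_a.total <= t.arm_a.total
            assert p.arm_a.events <= p.arm_a.total

    def test_empirical_rates_near_configured(self):
        cfg = SimulationConfig(
            n_studies=300, n_reviews=2, seed=7,
            rate_transposition=0.2, rate_percent_recalc=0.2, rate_alt_arm=0.2,
            rate_alt_timepoint=0.2, rate_denominator_policy=0.2, rate_nr=0.2,
        )
        _, records = generate_corpus(cfg)
        counts = Counter(r.kind for r in records)
        for kind in PerturbationKind:
            assert abs(counts[kind] / 300 - 0.2) <= 0.05

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            perturb_review([], SimulationConfig(), 1)


class TestDetection:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_planted_perturbations_fully_recalled(self, seed):
        """Every planted variable whose stored value differs from truth is
        flagged by the concordance engine; unperturbed studies show no
        differences (no false positives)."""
        cfg = SimulationConfig(n_studies=30, n_reviews=3, seed=seed,
                               rate_transposition=0.15, rate_percent_recalc=0.15,
                               rate_alt_arm=0.15, rate_alt_timepoint=0.15,
                               rate_denominator_policy=0.15, rate_nr=0.1)
        corpus, records = generate_corpus(cfg)
        truth = {
            r.study_unit_id: r
            for r in corpus.extractions
            if r.review_id == corpus.reference_review_id
        }
        perturbed_units = {(r.review_id, r.study_unit_id) for r in records}
        for review in corpus.reviews[1:]:
            comps = unit_comparisons(corpus, review, cfg.outcome_id)
            for unit_id, cs in comps.items():
                detected = {c.variable for c in cs if c.differs}
                stored = {
                    c.variable: c.review_value for c in cs
                }
                expected = {
                    v
                    for r in records
                    if r.review_id == review and r.study_unit_id == unit_id
                    and r.kind is not PerturbationKind.nr_mask
                    for v in r.variables
                    if stored[v] is not None
                    and stored[v] != truth[unit_id].value(v)
                }
                assert detected >= expected  # complete recall
                if (review, unit_id) not in perturbed_units:
                    assert detected == set()  # no false positives

    @pytest.mark.parametrize("seed", [1, 13])
    def test_derived_annotations_are_checker_consistent(self, seed):
        cfg = SimulationConfig(n_studies=25, n_reviews=3, seed=seed,
                               rate_transposition=0.2, rate_percent_recalc=0.2,
                               rate_alt_arm=0.2, rate_alt_timepoint=0.2,
                               rate_denominator_policy=0.2, rate_nr=0.2)
        corpus, _ = generate_corpus(cfg)
        assert check_annotation_consistency(corpus) == []

    def test_selection_only_rates_give_zero_error_pct(self):
        from extraudit import audit_outcome

        cfg = SimulationConfig(n_studies=40, n_reviews=2, seed=31,
                               **{**null_rates(), "rate_alt_arm": 0.5,
                                  "rate_denominator_policy": 0.5})
        corpus, _ = generate_corpus(cfg)
        s = audit_outcome(corpus, "R1", cfg.outcome_id)
        assert s.pct_error == 0
        assert s.n_selection > 0


class TestCalibration:
    def test_ci_coverage_under_null(self):
        """With true RR = 1 and no perturbations, ~95% of pooled 95% CIs
        contain 1 across 500 replicate meta-analyses (tolerance +/- 3
        percentage points)."""
        covered = 0
        for rep in range(500):
            cfg = SimulationConfig(seed=1 + rep)
            ests = [
                effect_from_table(
                    TwoByTwo(t.arm_a.events, t.arm_a.total, t.arm_b.events, t.arm_b.total)
                )
                for t in generate_truth_trials(cfg)
            ]
            p = pool_random_effects([e for e in ests if not e.excluded])
            covered += p.ci_low <= 1.0 <= p.ci_high
        assert abs(covered / 500 - 0.95) <= 0.03

    def test_pooled_rr_recovers_true_rr_at_scale(self):
        cfg = SimulationConfig(
            n_studies=80, arm_size_range=(200, 400),
            baseline_risk_range=(0.1, 0.3), true_rr=1.5, seed=77, **null_rates()
        )
        ests = [
            effect_from_table(
                TwoByTwo(t.arm_a.events, t.arm_a.total, t.arm_b.events, t.arm_b.total)
            )
            for t in generate_truth_trials(cfg)
        ]
        p = pool_random_effects(ests)
        assert p.rr == pytest.approx(1.5, rel=0.05)
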