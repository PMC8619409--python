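import math

import pytest
from hypothesis import given, strategies as st

import copycall as cc
from copycall import synthetic as syn
from copycall.quantification import (
    PfafflInput,
    aggregate_replicates,
    analyze_t0_batch,
    call_copy_class,
    pfaffl_copy_number,
)


class TestAggregateReplicates:
    def test_identical_values(self):
        s = aggregate_replicates([20.0, 20.0, 20.0])
        assert (s.mean_ct, s.sd_ct, s.cv_percent) == (20.0, 0.0, 0.0)

    def test_hand_calculation(self):
        s = aggregate_replicates([1.0, 2.0, 3.0], sd_mode="sample")
        assert s.mean_ct == pytest.approx(2.0)
        assert s.sd_ct == pytest.approx(1.0)
        assert s.cv_percent == pytest.approx(50.0)

    def test_cv_definition(self):
        # CV = 100*SD/mean as defined, not as printed in legacy tables
        s = aggregate_replicates([15.02 - 0.28, 15.02 + 0.28], sd_mode="population")
        assert s.cv_percent == pytest.approx(100 * 0.28 / 15.02)

    def test_population_mode(self):
        s = aggregate_replicates([1.0, 3.0], sd_mode="population")
        assert s.sd_ct == pytest.approx(1.0)

    def test_single_value_sd_zero(self):
        assert aggregate_replicates([21.5]).sd_ct == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])


class TestPfaffl:
    def test_calibrator_self_comparison(self):
        inp = PfafflInput(0.95, 1.0, 24.0, 24.0, 22.0, 22.0)
        assert pfaffl_copy_number(inp) == 2.0

    def test_one_extra_cycle_halves(self):
        inp = PfafflInput(1.0, 1.0, 24.0, 25.0, 22.0, 22.0)
        assert pfaffl_copy_number(inp) == pytest.approx(1.0)

    def test_unequal_efficiencies(self):
        inp = PfafflInput(0.993, 1.000, 25.0, 24.0, 23.0, 22.0)
        assert pfaffl_copy_number(inp) == pytest.approx(2 * 1.993 / 2)

    @given(
        st.floats(min_value=-3, max_value=3),
        st.floats(min_value=-3, max_value=3),
        st.floats(min_value=-5, max_value=5),
    )
    def test_channel_shift_invariance(self, d_target, d_ref, shift):
        base = PfafflInput(0.97, 1.02, 24.0, 24.0 + d_target, 22.0, 22.0 + d_ref)
        shifted = PfafflInput(
            0.97, 1.02, 24.0 + shift, 24.0 + d_target + shift, 22.0, 22.0 + d_ref
        )
        assert pfaffl_copy_number(shifted) == pytest.approx(
            pfaffl_copy_number(base), rel=1e-12
        )

    def test_equal_efficiency_reduces_to_ddct_form(self):
        e = 1.0
        inp = PfafflInput(e, e, 25.0, 23.5, 22.0, 21.0)
        ddct = (25.0 - 23.5) - (22.0 - 21.0)
        assert pfaffl_copy_number(inp) == pytest.approx(2 * 2.0**ddct, rel=1e-12)

    def test_monotone_in_test_cts(self):
        base = PfafflInput(1.0, 1.0, 24.0, 24.0, 22.0, 22.0)
        later_target = PfafflInput(1.0, 1.0, 24.0, 24.5, 22.0, 22.0)
        later_ref = PfafflInput(1.0, 1.0, 24.0, 24.0, 22.0, 22.5)
        assert pfaffl_copy_number(later_target) < pfaffl_copy_number(base)
        assert pfaffl_copy_number(later_ref) > pfaffl_copy_number(base)

    def test_efficiency_bounds_enforced(self):
        with pytest.raises(ValueError):
            PfafflInput(0.0, 1.0, 24, 24, 22, 22)
        with pytest.raises(ValueError):
            PfafflInput(1.0, 1.0, math.nan, 24, 22, 22)


class TestCallCopyClass:
    @pytest.mark.parametrize(
        "estimate, cls, ambiguous",
        [
            (0.98, 1, False),
            (1.52, 2, True),   # inside the dead zone around midpoint 1.5
            (1.36, 1, True),
            (0.0, 0, False),
            (0.2, 0, False),
            (3.7, "gt2", False),
            (2.7, "gt2", False),
            (2.2, 2, False),
        ],
    )
    def test_rule(self, estimate, cls, ambiguous):
        assert call_copy_class(estimate, 0.15) == (cls, ambiguous)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            call_copy_class(-0.1)

    @given(st.floats(min_value=0, max_value=10))
    def test_class_consistent_with_estimate(self, estimate):
        cls, _ = call_copy_class(estimate)
        if cls == "gt2":
            assert estimate > 2.4
        else:
            assert abs(estimate - cls) <= 0.5 + 1e-9


class TestBatchAnalysis:
    def test_test_equal_to_calibrator_gives_two(self, noiseless_cfg):
        cfg = noiseless_cfg
        records, layout, truth = syn.simulate_t0_cohort(cfg, 5)
        calls, _ = analyze_t0_batch(records, layout, cfg.curves(), "CAL01")
        two_copy = [c for c in calls if truth[c.sample_id] == 2]
        for c in two_copy:
            assert c.estimate == pytest.approx(2.0, abs=1e-9)

    def test_escape_called_zero(self, noiseless_cfg):
        records, layout, truth = syn.simulate_t0_cohort(noiseless_cfg, 60)
        calls, _ = analyze_t0_batch(records, layout, noiseless_cfg.curves(), "CAL01")
        escapes = [c for c in calls if truth[c.sample_id] == 0]
        assert escapes, "cohort should contain escapes at this seed"
        for c in escapes:
            assert c.copy_class == 0 and "escape" in c.notes[0]

    def test_cohort_counts_recovered_with_low_noise(self):
        cfg = syn.SimulationConfig(
            seed=3,
            ct_noise_sd=0.05,
            class_distribution={0: 2 / 45, 1: 33 / 45, 2: 6 / 45, "gt2": 4 / 45},
        )
        records, layout, truth = syn.simulate_t0_cohort(cfg, 45)
        calls, report = analyze_t0_batch(records, layout, cfg.curves(), "CAL01")
        called = {c.sample_id: c.copy_class for c in calls}
        assert called == truth
        assert report.n_samples == 45

    def test_missing_calibrator_rejected(self, noiseless_cfg):
        records, layout, _ = syn.simulate_t0_cohort(noiseless_cfg, 5)
        with pytest.raises(ValueError, match="calibrator"):
            analyze_t0_batch(records, layout, noiseless_cfg.curves(), "NOSUCH")

    def test_control_failure_blocks_unless_forced(self, noiseless_cfg):
        records, layout, _ = syn.simulate_t0_cohort(noiseless_cfg, 5)
        # contaminate the NTC transgene channel
        bad = [
            syn.replace_sample(r, r.sample_id) if r.sample_id != "NTC"
            else cc.CtRecord(r.well, "NTC", r.target, r.reporter,
                             30.0 if r.target == "transgene" else None, r.run_id)
            for r in records
        ]
        with pytest.raises(ValueError, match="control validation"):
            analyze_t0_batch(bad, layout, noiseless_cfg.curves(), "CAL01")
        calls, report = analyze_t0_batch(
            bad, layout, noiseless_cfg.curves(), "CAL01", force=True
        )
        assert report.notes and "force" in report.notes[0]
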