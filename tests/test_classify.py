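"""Spike detection and regime classification rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hcoscan.classify import (BurstStats, InsufficientCyclesError, Regime,
                              SpikeTrain, burst_stats, classify_regime,
                              detect_spikes, hco_functional, is_robust_burster,
                              relative_phase, split_bursts)
from hcoscan.integrate import Trajectory
from hcoscan.synthetic import (burst_pattern_times, make_spike_trace,
                               tonic_pattern_times)


def constant_trace(v=-50.0, duration=10.0):
    t = np.arange(0.0, duration, 1e-3)
    return Trajectory(t, np.full((t.size, 1), v))


class TestDetectSpikes:
    def test_constant_trace_has_no_spikes(self):
        assert len(detect_spikes(constant_trace())) == 0

    def test_five_peaks_reaching_zero(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        trace = make_spike_trace(times, peak=0.0)
        spikes = detect_spikes(trace)
        assert len(spikes) == 5
        assert spikes.spike_times == pytest.approx(times, abs=1.5e-3)

    def test_subthreshold_peaks_ignored(self):
        # peaks at -20 mV stay below the -10 mV threshold
        trace = make_spike_trace(np.array([1.0, 2.0, 3.0]), peak=-20.0)
        assert len(detect_spikes(trace)) == 0

    def test_threshold_is_strict(self):
        trace = make_spike_trace(np.array([1.0]), peak=-10.0)
        assert len(detect_spikes(trace)) == 0

    def test_segment_concatenation_conserves_spikes(self):
        times = np.array([1.0, 2.5, 4.0, 5.5, 7.0])
        full = make_spike_trace(times, duration=8.0)
        mid = 3.25
        left = full.window(0.0, mid)
        right = full.window(mid, 8.0)
        merged = np.concatenate([detect_spikes(left).spike_times,
                                 detect_spikes(right).spike_times])
        assert merged == pytest.approx(detect_spikes(full).spike_times)


class TestBurstStatistics:
    def periodic_train(self, n_bursts=10, spikes_per_burst=5, isi=0.1, gap=1.5):
        return SpikeTrain(burst_pattern_times(n_bursts, spikes_per_burst,
                                              isi, gap))

    def test_periodic_burst_arithmetic(self):
        stats = burst_stats(self.periodic_train())
        assert stats.burst_durations == pytest.approx(np.full(10, 0.4))
        assert stats.interburst_intervals == pytest.approx(np.full(9, 1.5))
        assert stats.periods == pytest.approx(np.full(9, 1.9))
        assert stats.cv_period == pytest.approx(0.0, abs=1e-12)
        assert stats.cv_ibi == pytest.approx(0.0, abs=1e-12)

    def test_period_consistency_invariant(self):
        stats = burst_stats(self.periodic_train())
        assert stats.periods == pytest.approx(
            stats.burst_durations[:-1] + stats.interburst_intervals)

    def test_single_burst_raises(self):
        train = SpikeTrain(np.array([1.0, 1.1, 1.2]))
        with pytest.raises(InsufficientCyclesError):
            burst_stats(train)

    def test_gap_of_exactly_one_second_splits(self):
        # the 1 s boundary counts as a burst gap, not an intra-burst ISI
        train = SpikeTrain(np.array([0.0, 1.0, 2.0, 3.0]))
        assert len(split_bursts(train)) == 4


class TestClassification:
    def test_all_isis_half_second_is_tonic(self):
        times = tonic_pattern_times(0.5, 100)
        trace = make_spike_trace(times)
        label, stats = classify_regime(detect_spikes(trace), trace)
        assert label is Regime.TONIC
        assert stats is None

    def test_periodic_bursts_classify_bursting(self):
        trace = make_spike_trace(burst_pattern_times(10, 5, 0.1, 1.5))
        label, stats = classify_regime(detect_spikes(trace), trace)
        assert label is Regime.BURSTING
        assert stats.cv_period == pytest.approx(0.0, abs=1e-12)

    def test_alternating_periods_is_irregular(self):
        # periods alternating 1.9 / 2.5 s -> CV ~ 0.136 > 5 %
        onsets = np.cumsum([1.0] + [1.9, 2.5] * 6)
        times = np.concatenate([o + 0.1 * np.arange(5) for o in onsets])
        trace = make_spike_trace(np.sort(times))
        label, stats = classify_regime(detect_spikes(trace), trace)
        assert label is Regime.IRREGULAR
        assert stats.cv_period == pytest.approx(0.136, abs=0.01)

    def test_silent_trace(self):
        label, stats = classify_regime(detect_spikes(constant_trace()),
                                       constant_trace())
        assert label is Regime.SILENT

    def test_subthreshold_oscillations_count_as_silent(self):
        t = np.arange(0.0, 20.0, 1e-3)
        v = -50.0 + 10.0 * np.sin(2 * np.pi * t)   # peaks at -40 mV
        trace = Trajectory(t, v[:, None])
        label, _ = classify_regime(detect_spikes(trace), trace)
        assert label is Regime.SILENT

    def test_plateau_like_flagged(self):
        # V pinned above -10 mV for 2 s without spike maxima
        t = np.arange(0.0, 10.0, 1e-3)
        v = np.full(t.size, -50.0)
        v[(t > 4.0) & (t < 6.0)] = -5.0
        trace = Trajectory(t, v[:, None])
        label, _ = classify_regime(detect_spikes(trace), trace)
        assert label is Regime.PLATEAU

    def test_classification_is_a_partition(self):
        # every constructed trace gets exactly one label
        traces = [
            constant_trace(),
            make_spike_trace(tonic_pattern_times(0.5, 30)),
            make_spike_trace(burst_pattern_times(8, 4, 0.1, 1.5)),
        ]
        for trace in traces:
            label, _ = classify_regime(detect_spikes(trace), trace)
            assert label in Regime


class TestTimeShiftInvariance:
    @settings(max_examples=20, deadline=None)
    @given(shift=st.floats(min_value=0.0, max_value=50.0))
    def test_shift_changes_nothing(self, shift):
        times = burst_pattern_times(6, 4, 0.1, 1.4)
        trace = make_spike_trace(times)
        shifted = Trajectory(trace.times + shift, trace.states)
        l0, s0 = classify_regime(detect_spikes(trace), trace)
        l1, s1 = classify_regime(detect_spikes(shifted), shifted)
        assert l0 == l1
        assert s0.cv_period == pytest.approx(s1.cv_period, abs=1e-12)
        assert np.mean(s1.periods) == pytest.approx(np.mean(s0.periods))


class TestRobustBursterRule:
    @pytest.mark.parametrize("cv_p,cv_i,expected", [
        (0.0, 0.0, True),
        (0.04, 0.09, True),
        (0.04, 0.12, False),   # interburst-interval CV rule
        (0.06, 0.0, False),    # period CV rule
        (0.05, 0.0, False),    # boundary: strict comparison
        (0.0, 0.10, False),    # boundary: strict comparison
    ])
    def test_cv_rules(self, cv_p, cv_i, expected):
        stats = BurstStats(
            burst_onsets=np.array([0.0, 2.0]), burst_ends=np.array([0.5, 2.5]),
            burst_durations=np.array([0.5, 0.5]),
            interburst_intervals=np.array([1.5]), periods=np.array([2.0]),
            cv_period=cv_p, cv_ibi=cv_i)
        assert is_robust_burster(stats) is expected


class TestHCOFunctional:
    def pair(self, offset_fraction, n=12, period=2.0):
        onsets_a = 1.0 + period * np.arange(n)
        onsets_b = onsets_a + offset_fraction * period
        ta = np.concatenate([o + 0.1 * np.arange(4) for o in onsets_a])
        tb = np.concatenate([o + 0.1 * np.arange(4) for o in onsets_b])
        tr_a = make_spike_trace(ta, duration=n * period + 4)
        tr_b = make_spike_trace(tb, duration=n * period + 4)
        return detect_spikes(tr_a), detect_spikes(tr_b), tr_a, tr_b

    def test_antiphase_is_functional(self):
        sa, sb, ta, tb = self.pair(0.5)
        ok, phase = hco_functional(sa, sb, ta, tb)
        assert ok
        assert phase == pytest.approx(0.5, abs=0.01)

    def test_offset_outside_window_not_functional(self):
        sa, sb, ta, tb = self.pair(0.3)
        ok, phase = hco_functional(sa, sb, ta, tb)
        assert not ok
        assert phase == pytest.approx(0.3, abs=0.01)

    def test_phase_window_boundaries(self):
        ok_45, _ = hco_functional(*self.pair(0.45))
        ok_44, _ = hco_functional(*self.pair(0.44))
        assert ok_45 and not ok_44

    def test_irregular_partner_not_functional(self):
        rng = np.random.default_rng(0)
        onsets_a = 1.0 + 2.0 * np.arange(12)
        # jitter one train until its period CV exceeds 5 %
        onsets_b = np.sort(onsets_a + 1.0 + rng.normal(0, 0.25, 12))
        assert np.std(np.diff(onsets_b)) / np.mean(np.diff(onsets_b)) > 0.05
        ta = np.concatenate([o + 0.1 * np.arange(4) for o in onsets_a])
        tb = np.concatenate([o + 0.1 * np.arange(4) for o in onsets_b])
        tr_a = make_spike_trace(ta, duration=30.0)
        tr_b = make_spike_trace(np.sort(tb), duration=30.0)
        ok, phase = hco_functional(detect_spikes(tr_a), detect_spikes(tr_b),
                                   tr_a, tr_b)
        assert not ok

    def test_silent_cell_is_a_precondition_error(self):
        sa, _, ta, _ = self.pair(0.5)
        silent = constant_trace(duration=30.0)
        with pytest.raises(ValueError):
            hco_functional(sa, detect_spikes(silent), ta, silent)
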