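import numpy as np
import pytest
from scipy import stats

from replaylab.spectral import ResponseHistogram
from replaylab.cycles import (
    ReplayCycle,
    cycle_metrics,
    cycle_trend_anova,
    lowpass_zero_phase,
    mean_crossings,
    replay_extent,
    segment_cycles,
    stimulation_reference,
)
from replaylab.stimulus import LDProtocol
from replaylab.synthetic_cells import CellSpec, ReplaySchedule, make_cell


def sinusoid_hist(freq, total_s, bin_s=0.2, base=10.0, amp=5.0):
    t = bin_s * (np.arange(int(total_s / bin_s)) + 0.5)
    rates = base + amp * np.sin(2 * np.pi * freq * t)
    return ResponseHistogram(bin_s, rates * bin_s)


class TestLowpass:
    def test_passband_amplitude_and_phase_preserved(self):
        h = sinusoid_hist(0.005, 2000.0)
        filt = lowpass_zero_phase(h, cutoff_hz=0.05)
        raw = h.rates
        core = slice(500, -500)
        assert (filt[core].max() - filt[core].min()) == pytest.approx(
            raw[core].max() - raw[core].min(), rel=0.01)
        # zero-phase: the peak inside one period shifts by less than one bin
        one_period = slice(900, 1600)
        assert abs(np.argmax(filt[one_period]) - np.argmax(raw[one_period])) <= 1

    def test_stopband_attenuation(self):
        h = sinusoid_hist(0.5, 600.0)
        filt = lowpass_zero_phase(h, cutoff_hz=0.05)
        assert filt.std() < 0.05 * h.rates.std()

    def test_constant_trace_unchanged(self):
        h = ResponseHistogram(0.2, np.full(500, 3.0))
        assert np.allclose(lowpass_zero_phase(h, 0.1), 15.0)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_zero_phase(sinusoid_hist(0.01, 600.0), cutoff_hz=3.0)


class TestSegmentation:
    def test_sinusoid_cycles_have_period_duration(self):
        h = sinusoid_hist(1.0 / 120.0, 600.0)
        filt = lowpass_zero_phase(h, 0.05)
        cycles = segment_cycles(filt, h)
        assert len(cycles) >= 3
        for c in cycles:
            assert c.duration_s == pytest.approx(120.0, abs=h.bin_s)
            assert c.peak_rate >= c.mean_rate >= c.trough_rate

    def test_constant_trace_yields_no_cycles(self):
        h = ResponseHistogram(0.2, np.full(500, 3.0))
        assert segment_cycles(lowpass_zero_phase(h, 0.1), h) == []

    def test_crossing_direction(self):
        x = np.sin(2 * np.pi * (np.arange(150) - 10.0) / 50.0)
        ups = mean_crossings(x, direction="up")
        downs = mean_crossings(x, direction="down")
        assert len(ups) == 3 and len(downs) == 3
        assert ups[0] < downs[0] < ups[1]

    def test_generator_boundaries_recovered_within_two_bins(
            self, noiseless_replay_record):
        rec = noiseless_replay_record
        p = rec.protocol
        f = 1.0 / p.cycle_s
        # start at the last (inactive) dark half-cycle so the first replay
        # bump is not at the filter edge, as the analysis pipeline does
        h = rec.histogram(t_start=p.offset_s - p.dark_s, t_end=rec.t_end)
        # cutoff comfortably above the first (shortest) cycle's fundamental,
        # so the filter does not distort its flanks
        filt = lowpass_zero_phase(h, 4.0 * f)
        cycles = segment_cycles(filt, h)
        # truth boundaries: analytic mean crossings of the unfiltered
        # noiseless rate trace at its own mean level
        truth_idx = mean_crossings(h.rates, direction="up")
        truth_t = h.t0 + truth_idx * h.bin_s
        bounds = np.array([c.start_s for c in cycles] + [cycles[-1].end_s])
        for t in truth_t:
            assert np.min(np.abs(bounds - t)) <= 2 * h.bin_s

    def test_generator_duration_and_peak_orderings(self, noiseless_replay_record):
        rec = noiseless_replay_record
        p = rec.protocol
        h = rec.histogram(t_start=p.offset_s, t_end=rec.t_end)
        filt = lowpass_zero_phase(h, 3.0 / p.cycle_s)
        cycles = segment_cycles(filt, h)[:rec.truth.n_cycles]
        durs = [c.duration_s for c in cycles]
        peaks = [c.peak_rate for c in cycles]
        assert stats.spearmanr(durs, rec.truth.durations_s[:len(durs)]).statistic > 0.9
        assert stats.spearmanr(peaks, np.arange(len(peaks))).statistic < -0.9

    def test_cycle_durations_bounded_by_post_epoch(self, noiseless_replay_record):
        rec = noiseless_replay_record
        p = rec.protocol
        h = rec.histogram(t_start=p.offset_s, t_end=rec.t_end)
        cycles = segment_cycles(lowpass_zero_phase(h, 3.0 / p.cycle_s), h)
        assert sum(c.duration_s for c in cycles) <= rec.t_end - p.offset_s


class TestCycleMetrics:
    def _analysis(self, record):
        p = record.protocol
        stim = record.histogram(t_start=p.onset_s, t_end=p.offset_s)
        post = record.histogram(t_start=p.offset_s, t_end=record.t_end)
        filt = lowpass_zero_phase(post, 3.0 / p.cycle_s)
        cycles = segment_cycles(filt, post)
        return cycles, stim, p

    def test_first_cycle_normalized_duration(self):
        # a cell whose first replay cycle spans 1.24 LD cycles
        sched = ReplaySchedule(first_cycle_ratio=1.24, rel_jitter=0.0)
        spec = CellSpec(is_replay=True, replay=sched, seed=2)
        rec = make_cell(spec, LDProtocol(60.0, 60.0, 10), noiseless=True)
        cycles, stim, p = self._analysis(rec)
        m = cycle_metrics(cycles, stim, p, spec.polarity)
        assert m.norm_durations[0] == pytest.approx(1.24, abs=0.03)

    def test_reference_is_active_phase_mean(self, noiseless_replay_record):
        rec = noiseless_replay_record
        p = rec.protocol
        stim = rec.histogram(t_start=p.onset_s, t_end=p.offset_s)
        ref = stimulation_reference(stim, p, rec.spec.polarity)
        assert ref == pytest.approx(rec.spec.active_rate, rel=0.01)

    def test_normalization_scale_invariant(self, noiseless_replay_record):
        rec = noiseless_replay_record
        cycles, stim, p = self._analysis(rec)
        m1 = cycle_metrics(cycles, stim, p, rec.spec.polarity)
        scaled = ResponseHistogram(stim.bin_s, stim.counts * 3.0, stim.t0)
        post = rec.histogram(t_start=p.offset_s, t_end=rec.t_end)
        post3 = ResponseHistogram(post.bin_s, post.counts * 3.0, post.t0)
        cycles3 = segment_cycles(lowpass_zero_phase(post3, 3.0 / p.cycle_s), post3)
        m3 = cycle_metrics(cycles3, scaled, p, rec.spec.polarity)
        assert np.allclose(m1.norm_peaks, m3.norm_peaks, rtol=1e-6)


class TestReplayExtent:
    @staticmethod
    def _cycle(i, start, dur, peak, trough=0.0):
        return ReplayCycle(index=i, start_s=start, end_s=start + dur,
                           peak_rate=peak, mean_rate=peak / 2,
                           trough_rate=trough, peak_time_s=start + dur / 2,
                           filt_peak=peak, filt_trough=trough)

    def test_sixteen_cycle_generator_cell_counted_exactly(self):
        spec = CellSpec(is_replay=True, replay=ReplaySchedule(rel_jitter=0.0),
                        seed=4)
        rec = make_cell(spec, LDProtocol(60.0, 60.0, 39), noiseless=True)
        p = rec.protocol
        stim = rec.histogram(t_start=p.onset_s, t_end=p.offset_s)
        post = rec.histogram(t_start=p.offset_s, t_end=rec.t_end)
        cycles = segment_cycles(lowpass_zero_phase(post, 3.0 / p.cycle_s), post)
        ref = stimulation_reference(stim, p, spec.polarity)
        n, extent = replay_extent(cycles, ref, p.cycle_s, p.offset_s)
        assert n == rec.truth.n_cycles == 16
        assert extent == pytest.approx(rec.truth.replay_end_s - p.offset_s, rel=0.1)

    def test_empty_cycle_list(self):
        assert replay_extent([], 10.0, 120.0, 0.0) == (0, 0.0)

    def test_sub_floor_first_cycle_gives_zero(self):
        cycles = [self._cycle(1, 0.0, 100.0, peak=1.0)]
        assert replay_extent(cycles, 100.0, 120.0, 0.0) == (0, 0.0)

    def test_count_stops_at_first_failure(self):
        cycles = [
            self._cycle(1, 0.0, 100.0, peak=50.0),
            self._cycle(2, 100.0, 100.0, peak=50.0),
            self._cycle(3, 200.0, 100.0, peak=0.5),   # below floor
            self._cycle(4, 300.0, 100.0, peak=50.0),  # not consecutive
        ]
        n, extent = replay_extent(cycles, 100.0, 120.0, 0.0, peak_floor=0.2)
        assert n == 2 and extent == pytest.approx(200.0)

    def test_duration_cap_excludes_marathon_cycles(self):
        cycles = [self._cycle(1, 0.0, 1000.0, peak=50.0)]
        n, _ = replay_extent(cycles, 100.0, 120.0, 0.0, duration_cap=4.0)
        assert n == 0


class TestCycleTrendAnova:
    def test_hand_worked_three_group_example(self):
        # groups {1,2},{2,3},{3,4}: SSB = 4 (df 2), SSW = 1.5 (df 3)
        # -> F = (4/2)/(1.5/3) = 4.0
        f, p = cycle_trend_anova([[1, 2], [2, 3], [3, 4]])
        assert f == pytest.approx(4.0)
        sp = stats.f_oneway([1, 2], [2, 3], [3, 4])
        assert f == pytest.approx(sp.statistic) and p == pytest.approx(sp.pvalue)

    def test_identical_constant_groups_rejected(self):
        with pytest.raises(ValueError):
            cycle_trend_anova([[1.0, 1.0], [1.0, 1.0]])

    def test_zero_within_variance_infinite_f(self):
        f, p = cycle_trend_anova([[0.0, 0.0], [1.0, 1.0]])
        assert np.isinf(f) and p == 0.0

    def test_degenerate_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            cycle_trend_anova([[1.0], [2.0, 3.0]])

    def test_detects_duration_growth_across_cohort(self):
        """First-3 vs last-3 cycle positions from generator truth show the
        slow duration increase as a significant one-way ANOVA trend."""
        rng = np.random.default_rng(0)
        sched = ReplaySchedule(rel_jitter=0.0)
        groups = [[] for _ in range(6)]
        for seed in range(12):
            spec = CellSpec(is_replay=True, replay=sched, seed=seed)
            rec = make_cell(spec, LDProtocol(30.0, 30.0, 25), noiseless=True)
            d = rec.truth.durations_s / rec.protocol.cycle_s
            vals = np.concatenate([d[:3], d[-3:]]) * (1 + 0.05 * rng.standard_normal(6))
            for g, v in zip(groups, vals):
                g.append(v)
        f, p = cycle_trend_anova(groups)
        assert p < 0.001
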