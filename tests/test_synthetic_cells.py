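import numpy as np
import pytest

from replaylab.stimulus import LDProtocol
from replaylab.synthetic_cells import (
    CellSpec,
    LIGHT_ACTIVATED,
    LIGHT_SUPPRESSED,
    ReplaySchedule,
    generate_cohort,
    rate_profile,
    replay_truth,
    sample_spike_train,
)

NOJIT = ReplaySchedule(rel_jitter=0.0)


class TestRateProfile:
    def test_non_replay_cell_constant_after_stimulation(self, protocol_60):
        spec = CellSpec(is_replay=False, seed=1)
        t = np.arange(protocol_60.offset_s, protocol_60.offset_s + 600.0, 0.2)
        rate = rate_profile(spec, protocol_60, t)
        assert np.allclose(rate, spec.baseline_rate)

    def test_pre_epoch_constant_baseline(self):
        p = LDProtocol(60.0, 60.0, 10, onset_s=120.0)
        spec = CellSpec(is_replay=True, seed=1)
        t = np.arange(0.0, 120.0, 0.2)
        assert np.allclose(rate_profile(spec, p, t), spec.baseline_rate)

    def test_entrained_square_wave_polarity(self, protocol_60):
        t_light = protocol_60.onset_s + 5.0   # light half-cycle
        t_dark = protocol_60.onset_s + 65.0   # dark half-cycle
        for pol, hi, lo in [(LIGHT_ACTIVATED, t_light, t_dark),
                            (LIGHT_SUPPRESSED, t_dark, t_light)]:
            spec = CellSpec(polarity=pol, seed=1)
            r = rate_profile(spec, protocol_60, np.array([hi, lo]))
            assert r[0] == pytest.approx(spec.active_rate)
            assert r[1] == pytest.approx(spec.inactive_rate)

    def test_first_replay_cycle_duration_follows_calibration(self):
        # a first-cycle ratio of 1.24 on a 120-s LD cycle spans 148.8 s
        sched = ReplaySchedule(first_cycle_ratio=1.24, rel_jitter=0.0)
        spec = CellSpec(is_replay=True, replay=sched, seed=1)
        truth = replay_truth(spec, LDProtocol(60.0, 60.0, 10))
        assert truth.durations_s[0] == pytest.approx(148.8)

    def test_no_replay_below_minimum_ld_cycle(self):
        spec = CellSpec(is_replay=True, replay=NOJIT, seed=1)
        truth = replay_truth(spec, LDProtocol(5.0, 5.0, 10))
        assert not truth.is_replay
        p = LDProtocol(5.0, 5.0, 10)
        t = np.arange(p.offset_s, p.offset_s + 300.0, 0.2)
        assert np.allclose(rate_profile(spec, p, t), spec.baseline_rate)

    def test_rate_non_negative_everywhere(self, protocol_60):
        spec = CellSpec(is_replay=True, seed=3, modulation_depth=1.0)
        t = np.arange(0.0, protocol_60.offset_s + 2000.0, 0.2)
        assert np.all(rate_profile(spec, protocol_60, t) >= 0.0)


class TestReplayTruth:
    def test_cycle_durations_grow_and_peaks_decay(self, protocol_60):
        spec = CellSpec(is_replay=True, replay=NOJIT, seed=1)
        truth = replay_truth(spec, LDProtocol(30.0, 30.0, 25))
        assert truth.n_cycles == round(0.41 * 25)
        # growth applies from the second cycle on; the first is calibrated
        # separately (and shorter)
        assert np.all(np.diff(truth.durations_s[1:]) >= 0)
        assert truth.durations_s[0] < truth.durations_s[1]
        assert np.all(np.diff(truth.peak_rates) <= 0)

    def test_truth_frequency_ratio(self):
        spec = CellSpec(is_replay=True, replay=NOJIT, seed=1)
        p = LDProtocol(60.0, 60.0, 10)
        truth = replay_truth(spec, p)
        assert truth.freq_hz == pytest.approx(0.62 / 120.0)

    def test_sixteen_cycle_replay_ends_near_printed_decay_figures(self):
        # 39 LD cycles -> round(0.41 * 39) = 16 replay cycles
        spec = CellSpec(is_replay=True, replay=NOJIT, seed=1)
        truth = replay_truth(spec, LDProtocol(60.0, 60.0, 39))
        assert truth.n_cycles == 16
        ref = spec.active_rate
        assert truth.peak_rates[0] / ref == pytest.approx(1.09)
        assert truth.peak_rates[-1] / ref == pytest.approx(0.43, abs=0.01)


class TestSpikeSampling:
    def test_poisson_count_within_four_sigma(self):
        spec = CellSpec(is_replay=False, baseline_rate=10.0, seed=5)
        p = LDProtocol(60.0, 60.0, 1, onset_s=1000.0)  # never reached
        train = sample_spike_train(spec, p, 0.0, 100.0, seed=5)
        expected = 10.0 * 100.0
        assert abs(len(train) - expected) < 4 * np.sqrt(expected)

    def test_same_seed_identical_trains(self, protocol_60):
        spec = CellSpec(is_replay=True, seed=9)
        a = sample_spike_train(spec, protocol_60, 0.0, 500.0, seed=9)
        b = sample_spike_train(spec, protocol_60, 0.0, 500.0, seed=9)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_spikes_within_bounds_and_sorted(self, noisy_replay_record):
        st = noisy_replay_record.train.spike_times
        assert np.all(np.diff(st) >= 0)
        assert st[0] >= noisy_replay_record.t_start
        assert st[-1] < noisy_replay_record.t_end

    def test_stimulation_epoch_rate_is_periodic(self, noisy_replay_record):
        """Autocorrelation of the stimulation-epoch histogram peaks at the
        LD period."""
        rec = noisy_replay_record
        p = rec.protocol
        h = rec.histogram(bin_s=1.0, t_start=p.onset_s, t_end=p.offset_s)
        x = h.rates - h.rates.mean()
        ac = np.correlate(x, x, mode="full")[len(x) - 1:]
        lag = p.cycle_s  # bins of 1 s
        search = ac[30:300]  # skip the zero-lag peak
        assert abs((30 + np.argmax(search)) - lag) <= 2


class TestCohort:
    def test_replay_fraction_and_polarity_split(self):
        cohort = generate_cohort(100, replay_fraction=0.28, master_seed=1,
                                 noiseless=True)
        labels = [r.spec.is_replay for r in cohort]
        assert sum(labels) == 28
        pol = [r.spec.polarity for r in cohort]
        assert abs(pol.count(LIGHT_ACTIVATED) - 50) <= 1

    def test_zero_fraction_all_non_replay(self):
        cohort = generate_cohort(10, replay_fraction=0.0, master_seed=1,
                                 noiseless=True)
        assert not any(r.spec.is_replay for r in cohort)

    def test_same_master_seed_identical_cohorts(self, protocol_60):
        a = generate_cohort(6, master_seed=7, protocols=[protocol_60])
        b = generate_cohort(6, master_seed=7, protocols=[protocol_60])
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.train.spike_times, rb.train.spike_times)


@pytest.mark.parametrize("polarity,sign", [(LIGHT_ACTIVATED, 1), (LIGHT_SUPPRESSED, -1)])
def test_staircase_monotone_with_polarity(polarity, sign):
    spec = CellSpec(polarity=polarity, seed=1)
    resp = spec.staircase_responses([0.0, 20.0, 50.0, 100.0, 200.0, 400.0])
    assert np.all(sign * np.diff(resp) >= 0)
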