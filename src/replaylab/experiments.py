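"""Reproduction experiments: synthetic cohorts run through the full pipeline.

Each experiment generates a labelled synthetic cohort under the study
conditions (protocol ranges, cycle counts, Poisson spiking, default
replay calibration), runs the package's detection/segmentation stages,
and reports the population regression slope that the corresponding
figure of the source study prints. Because the cohorts are generated
with the calibrated parameters, these are parameter-recovery runs: the
pipeline should return the calibration values.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .stimulus import LDProtocol, protocol_frequency
from .spectral import significant_frequencies
from .cycles import lowpass_zero_phase, segment_cycles, replay_extent, stimulation_reference
from .cohort import RegressionSummary, fit_linear, post_stimulus_frequency, _protocol_means
from .synthetic_cells import (
    CellRecord, CellSpec, LIGHT_ACTIVATED, LIGHT_SUPPRESSED, make_cell,
)

__all__ = [
    "entrainment_slope",
    "replay_regressions",
    "replay_count_slope",
]

POST_WINDOW_S = 14 * 60.0
# segmentation cutoff floor (x stimulus frequency): passes the shortest
# calibrated replay cycle (fundamental ~1.9 x f_stim) without attenuation
CUTOFF_FLOOR = 3.0


def _cells_for(
    cycle_durations: Sequence[float],
    n_cycles_map,
    n_per: int,
    master_seed: int,
    is_replay: bool,
) -> List[CellRecord]:
    seeds = np.random.SeedSequence(master_seed).generate_state(
        len(cycle_durations) * n_per)
    records = []
    k = 0
    for T in cycle_durations:
        nc = n_cycles_map(T) if callable(n_cycles_map) else n_cycles_map
        proto = LDProtocol(T / 2.0, T / 2.0, nc)
        for j in range(n_per):
            spec = CellSpec(
                polarity=LIGHT_ACTIVATED if k % 2 == 0 else LIGHT_SUPPRESSED,
                is_replay=is_replay,
                seed=int(seeds[k] % (2 ** 31)),
                cell_id=f"T{T:g}_c{j}",
            )
            records.append(make_cell(spec, proto))
            k += 1
    return records


def _boot_seed(master_seed: int, record: CellRecord, salt: int) -> int:
    ss = np.random.SeedSequence([master_seed, record.spec.seed, salt])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _segmentation_hist(rec: CellRecord):
    """Post-stimulus histogram, starting at the last inactive half-cycle for
    light-activated cells so their first replay bump avoids the filter edge."""
    p = rec.protocol
    lead = p.dark_s if rec.spec.polarity == LIGHT_ACTIVATED else 0.0
    return rec.histogram(t_start=p.offset_s - lead, t_end=rec.t_end)


def entrainment_slope(
    seed: int = 0,
    cycle_durations: Sequence[float] = (2.0, 10.0, 60.0, 120.0, 480.0),
    n_per: int = 5,
    n_resamples: int = 1000,
) -> RegressionSummary:
    """Detected stimulation-epoch frequency regressed on stimulus frequency.

    Entrained (non-replay) cells across the tested stimulus-frequency range
    0.002-0.5 Hz; short protocols use 25 LD cycles, long ones 10, within
    the study's 5-25 cycle range. Perfect 1:1 entrainment corresponds to a
    slope of 1.
    """
    records = _cells_for(cycle_durations, lambda T: 25 if T <= 10 else 10,
                         n_per, seed, is_replay=False)
    pairs = []
    for rec in records:
        p = rec.protocol
        hist = rec.histogram(t_start=p.onset_s, t_end=p.offset_s)
        res = significant_frequencies(hist, n_resamples=n_resamples,
                                      seed=_boot_seed(seed, rec, 1))
        if res.peak_freq is not None:
            pairs.append((protocol_frequency(p), res.peak_freq))
    xs, ys = _protocol_means(pairs)
    return fit_linear(xs, ys)


def replay_regressions(
    seed: int = 0,
    cycle_durations: Sequence[float] = (20.0, 60.0, 120.0, 240.0, 480.0),
    n_cycles: int = 25,
    n_per: int = 5,
    n_resamples: int = 1000,
) -> Dict[str, RegressionSummary]:
    """Post-stimulus frequency and first-cycle-duration regressions.

    A replay cohort with the default calibration across LD-cycle durations
    20-480 s. The sliding-window bootstrap FFT over the first 14 min after
    stimulation gives the post-stimulus frequency (and the Butterworth
    cutoff); zero-phase filtering + mean-crossing segmentation gives the
    first replay-cycle duration. Returns ``{"post_freq": ...,
    "first_cycle": ...}`` with slopes that recover the calibration
    (0.62 and 0.58).
    """
    records = _cells_for(cycle_durations, n_cycles, n_per, seed, is_replay=True)
    freq_pairs, dur_pairs = [], []
    for rec in records:
        p = rec.protocol
        f_stim = protocol_frequency(p)
        post_hist = rec.histogram(t_start=p.offset_s, t_end=rec.t_end)
        pf = post_stimulus_frequency(post_hist, p, n_resamples=n_resamples,
                                     seed=_boot_seed(seed, rec, 2))
        if pf is not None:
            freq_pairs.append((f_stim, pf))
        seg_hist = _segmentation_hist(rec)
        cycles = segment_cycles(
            lowpass_zero_phase(seg_hist, CUTOFF_FLOOR * f_stim), seg_hist)
        if cycles:
            dur_pairs.append((p.cycle_s, cycles[0].duration_s))
    return {
        "post_freq": fit_linear(*_protocol_means(freq_pairs)),
        "first_cycle": fit_linear(*_protocol_means(dur_pairs)),
    }


def replay_count_slope(
    seed: int = 0,
    n_cycles_list: Sequence[int] = (5, 10, 15, 20, 25),
    n_per: int = 5,
    n_resamples: int = 1000,
) -> RegressionSummary:
    """Segmented replay-cycle count regressed on LD-cycle count (L/D 30 s/30 s).

    Recovers the default calibration of 0.41 replay cycles per LD cycle.
    """
    seeds = np.random.SeedSequence(seed).generate_state(len(n_cycles_list) * n_per)
    pairs = []
    k = 0
    for nc in n_cycles_list:
        proto = LDProtocol(30.0, 30.0, int(nc))
        for j in range(n_per):
            spec = CellSpec(
                polarity=LIGHT_ACTIVATED if k % 2 == 0 else LIGHT_SUPPRESSED,
                is_replay=True,
                seed=int(seeds[k] % (2 ** 31)),
                cell_id=f"N{nc}_c{j}",
            )
            rec = make_cell(spec, proto)
            k += 1
            p = rec.protocol
            f_stim = protocol_frequency(p)
            stim_hist = rec.histogram(t_start=p.onset_s, t_end=p.offset_s)
            seg_hist = _segmentation_hist(rec)
            cycles = segment_cycles(
                lowpass_zero_phase(seg_hist, CUTOFF_FLOOR * f_stim), seg_hist)
            ref = stimulation_reference(stim_hist, p, spec.polarity)
            n_rep, _ = replay_extent(cycles, ref, p.cycle_s, p.offset_s)
            pairs.append((float(p.n_cycles), float(n_rep)))
    return fit_linear(*_protocol_means(pairs))
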