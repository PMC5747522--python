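"""Cohort-level classification, normalization and regression summaries.

Ties the detection and segmentation stages into a per-cell analysis
(:func:`analyze_cell`) and reproduces the population regressions of the
source study: entrained frequency vs stimulus frequency, post-stimulus
frequency vs stimulus frequency, first replay-cycle duration vs LD-cycle
duration, and replay-cycle count vs LD-cycle count. Regressions are
ordinary least squares on linear-scale values of per-protocol means
(population figures plot log-log axes but fit a linear function).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .stimulus import LDProtocol, protocol_frequency
from .spectral import significant_frequencies, sliding_max_frequency
from .cycles import CycleMetrics, cycle_metrics, lowpass_zero_phase, segment_cycles
from .synthetic_cells import CellRecord

__all__ = [
    "CellAnalysis",
    "RegressionSummary",
    "preference_index",
    "normalize_luminance_responses",
    "classify_replay",
    "fit_linear",
    "analyze_cell",
    "fig2_summaries",
]

POST_WINDOW_S = 14 * 60.0     # summary window after stimulation offset
SLIDE_WINDOW_S = 7 * 60.0     # sliding analysis window
SLIDE_STEP_S = 60.0
REPLAY_FREQ_BAND = 2.0        # replay call: detected freq within this factor of f_stim
CUTOFF_FLOOR = 3.0            # segmentation cutoff floor, x stimulus frequency


def post_stimulus_frequency(
    post_hist,
    p: LDProtocol,
    n_resamples: int = 1000,
    seed: int = 0,
    band: float = REPLAY_FREQ_BAND,
) -> Optional[float]:
    """Post-stimulus summary oscillation frequency in the first 14 min.

    Candidate frequencies are band-limited to within a factor ``band`` of
    the stimulus frequency (the replay band; this also excludes the slow
    on/off envelope of the replay epoch). When a 7-min window can hold at
    least two expected replay cycles (~1.6 LD cycles each) the window
    slides in 1-min steps and the significant peak from the window with
    the strongest oscillation amplitude is reported; for slower protocols
    the whole 14-min segment is analysed as a single window.
    """
    f_stim = protocol_frequency(p)
    t0 = post_hist.t0
    t_end = min(t0 + POST_WINDOW_S, post_hist.t_end)
    ss = np.random.SeedSequence(seed)
    if 2 * 1.6 * p.cycle_s <= SLIDE_WINDOW_S and t_end - t0 > SLIDE_WINDOW_S:
        starts = np.arange(t0, t_end - SLIDE_WINDOW_S + 1e-9, SLIDE_STEP_S)
        best, best_amp = None, -np.inf
        for child, s in zip(ss.spawn(len(starts)), starts):
            win = post_hist.slice(s, s + SLIDE_WINDOW_S)
            res = significant_frequencies(
                win, n_resamples=n_resamples,
                seed=int(child.generate_state(1)[0] % (2 ** 31)),
                fmin=f_stim / band, fmax=f_stim * band)
            if res.peak_freq is not None:
                amp = float(res.amplitude[np.argmin(np.abs(res.freqs - res.peak_freq))])
                if amp > best_amp:
                    best_amp, best = amp, res.peak_freq
        return best
    win = post_hist.slice(t0, t_end)
    res = significant_frequencies(
        win, n_resamples=n_resamples,
        seed=int(ss.generate_state(1)[0] % (2 ** 31)),
        fmin=f_stim / band, fmax=f_stim * band)
    return res.peak_freq


def preference_index(r_light: float, r_dark: float) -> float:
    """Signed light/dark response contrast (R_L - R_D) / (R_L + R_D) in [-1, 1]."""
    if r_light < 0 or r_dark < 0:
        raise ValueError("responses must be non-negative")
    total = r_light + r_dark
    if total == 0:
        raise ValueError("preference index undefined for two zero responses")
    return (r_light - r_dark) / total


def normalize_luminance_responses(responses: Sequence[float]) -> np.ndarray:
    """Divide staircase responses by the maximal response across levels."""
    r = np.asarray(responses, dtype=float)
    if len(r) < 2:
        raise ValueError("need responses at >= 2 luminance levels")
    m = r.max()
    if m <= 0:
        raise ValueError("maximal response must be positive")
    return r / m


@dataclass(frozen=True)
class RegressionSummary:
    """Ordinary least-squares line fit."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def fit_linear(x: Sequence[float], y: Sequence[float]) -> RegressionSummary:
    """OLS slope/intercept with r^2 = 1 - SSE/SST (0 when y is constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0:
        raise ValueError("x values are all equal; slope undefined")
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    sst = ((y - y.mean()) ** 2).sum()
    sse = ((y - slope * x - intercept) ** 2).sum()
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst
    return RegressionSummary(float(slope), float(intercept), float(r2), len(x))


@dataclass(frozen=True)
class CellAnalysis:
    """Per-cell analysis outcome."""

    cell_id: str
    polarity: str
    stim_freq_hz: float
    ld_cycle_s: float
    n_ld_cycles: int
    preference_index: float
    entrained_freq: Optional[float]
    post_freq_14min: Optional[float]
    metrics: Optional[CycleMetrics]
    is_replay_called: bool

    @property
    def first_cycle_duration_s(self) -> Optional[float]:
        if self.metrics is None or self.metrics.n_replay_cycles == 0:
            return None
        return float(self.metrics.norm_durations[0] * self.ld_cycle_s)

    @property
    def n_replay_cycles(self) -> int:
        return 0 if self.metrics is None else self.metrics.n_replay_cycles


def classify_replay(
    post_freq: Optional[float], p: LDProtocol, band: float = REPLAY_FREQ_BAND
) -> bool:
    """Replay call: a significant post-stimulus frequency exists in the first
    14-min window and lies within a factor ``band`` of the stimulus frequency.

    The call should be based on the 14-min segment analysed as a single
    window (see :func:`replay_call_frequency`); sliding sub-windows
    multiply the number of bootstrap comparisons and inflate the false-call
    rate on non-oscillating cells.
    """
    if post_freq is None:
        return False
    f = protocol_frequency(p)
    return f / band <= post_freq <= f * band


def replay_call_frequency(
    post_hist,
    p: LDProtocol,
    n_resamples: int = 1000,
    seed: int = 0,
    band: float = REPLAY_FREQ_BAND,
) -> Optional[float]:
    """Peak significant frequency of the first 14 min as one window,
    band-limited to the replay band; the basis of the replay call."""
    f_stim = protocol_frequency(p)
    win = post_hist.slice(post_hist.t0, min(post_hist.t0 + POST_WINDOW_S,
                                            post_hist.t_end))
    res = significant_frequencies(win, n_resamples=n_resamples, seed=seed,
                                  fmin=f_stim / band, fmax=f_stim * band)
    return res.peak_freq


def analyze_cell(
    record: CellRecord,
    n_resamples: int = 1000,
    seed: int = 0,
    bin_s: float = 0.2,
) -> CellAnalysis:
    """Run the full detection/segmentation pipeline on one cell.

    Stages: (1) peak significant FFT frequency of the stimulation epoch
    (entrainment); (2) sliding-window bootstrap FFT over the first 14 min
    after stimulation, band-limited to twice the stimulus frequency, whose
    maximal significant frequency is both the post-stimulus summary
    frequency and the Butterworth cutoff (falling back to 2 x stimulus
    frequency); (3) zero-phase filtering + mean-crossing segmentation of
    the whole post-stimulus epoch and normalization against the
    stimulation reference response.
    """
    p = record.protocol
    f_stim = protocol_frequency(p)
    ss = np.random.SeedSequence([seed, record.spec.seed])
    s_ent, s_post = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))

    stim_hist = record.histogram(bin_s=bin_s, t_start=p.onset_s, t_end=p.offset_s)
    ent = significant_frequencies(stim_hist, n_resamples=n_resamples, seed=s_ent)

    r_light = float(stim_hist.rates[_half_mask(stim_hist, p, light=True)].mean())
    r_dark = float(stim_hist.rates[_half_mask(stim_hist, p, light=False)].mean())
    pref = preference_index(r_light, r_dark)

    post_hist = record.histogram(bin_s=bin_s, t_start=p.offset_s, t_end=record.t_end)
    call_freq = replay_call_frequency(post_hist, p, n_resamples=n_resamples,
                                      seed=s_post)
    is_replay = classify_replay(call_freq, p)
    post_freq = post_stimulus_frequency(post_hist, p, n_resamples=n_resamples,
                                        seed=s_post) if is_replay else call_freq
    # Butterworth cutoff: maximal significant frequency over sliding 7-min
    # windows, floored at CUTOFF_FLOOR x stimulus frequency so that replay
    # cycles shorter than the entrained period stay inside the passband
    win = post_hist.slice(p.offset_s, min(p.offset_s + POST_WINDOW_S, record.t_end))
    cutoff = sliding_max_frequency(
        win, n_resamples=n_resamples, seed=s_post, fmax=REPLAY_FREQ_BAND * f_stim
    )
    cutoff = max(cutoff or 0.0, CUTOFF_FLOOR * f_stim)
    # start segmentation at the last (inactive) half-cycle so the first
    # replay bump of a light-activated cell is not at the filter edge
    seg_start = p.offset_s - (p.dark_s if record.spec.polarity == "light-activated" else 0.0)
    seg_hist = record.histogram(bin_s=bin_s, t_start=seg_start, t_end=record.t_end)
    filt = lowpass_zero_phase(seg_hist, cutoff)
    cycles = segment_cycles(filt, seg_hist)
    metrics = cycle_metrics(cycles, stim_hist, p, record.spec.polarity) if cycles else None

    return CellAnalysis(
        cell_id=record.spec.cell_id,
        polarity=record.spec.polarity,
        stim_freq_hz=f_stim,
        ld_cycle_s=p.cycle_s,
        n_ld_cycles=p.n_cycles,
        preference_index=pref,
        entrained_freq=ent.peak_freq,
        post_freq_14min=post_freq,
        metrics=metrics,
        is_replay_called=is_replay,
    )


def _half_mask(hist, p: LDProtocol, light: bool) -> np.ndarray:
    t = hist.times + hist.bin_s / 2.0
    rel = t - p.onset_s
    in_stim = (rel >= 0) & (rel < p.n_cycles * p.cycle_s)
    is_light = np.mod(rel, p.cycle_s) < p.light_s
    return in_stim & (is_light if light else ~is_light)


def _protocol_means(pairs: List[tuple]) -> tuple:
    """Average y per distinct x, mirroring mean +/- SEM presentation."""
    by_x: Dict[float, List[float]] = {}
    for x, y in pairs:
        by_x.setdefault(x, []).append(y)
    xs = sorted(by_x)
    return xs, [float(np.mean(by_x[x])) for x in xs]


def fig2_summaries(analyses: Sequence[CellAnalysis]) -> Dict[str, RegressionSummary]:
    """The four population regressions over per-protocol means.

    entrainment:   detected stimulation-epoch frequency vs stimulus frequency
    post_freq:     post-stimulus (first 14 min) frequency vs stimulus frequency
    first_cycle:   first replay-cycle duration vs LD-cycle duration
    replay_count:  segmented replay-cycle count vs LD-cycle count
    """
    out: Dict[str, RegressionSummary] = {}
    ent = [(a.stim_freq_hz, a.entrained_freq) for a in analyses
           if a.entrained_freq is not None]
    post = [(a.stim_freq_hz, a.post_freq_14min) for a in analyses
            if a.is_replay_called]
    first = [(a.ld_cycle_s, a.first_cycle_duration_s) for a in analyses
             if a.is_replay_called and a.first_cycle_duration_s is not None]
    count = [(float(a.n_ld_cycles), float(a.n_replay_cycles)) for a in analyses
             if a.is_replay_called]
    for name, pairs in [("entrainment", ent), ("post_freq", post),
                        ("first_cycle", first), ("replay_count", count)]:
        if len({x for x, _ in pairs}) >= 2:
            out[name] = fit_linear(*_protocol_means(pairs))
    return out
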