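"""Replay-cycle segmentation and decay quantification.

The post-stimulus response histogram is smoothed with a zero-phase
low-pass Butterworth filter (the analysis pipeline uses the maximal
significant oscillation frequency from the sliding-window FFT stage as
the cutoff, floored at a small multiple of the stimulus frequency so
the shortest replay cycles stay in the passband). Replay-cycle
boundaries are the same-direction crossings of the filtered trace with
its own mean: consecutive upward crossings delimit one cycle for cells
whose replay appears as activity peaks (the default for both polarities;
the crossing direction is configurable). Peak and mean rates of each
cycle are read from the unfiltered histogram.

Cycle durations are normalized by the LD-cycle duration and cycle peaks
by the reference response: the mean rate over all light (light-activated)
or dark (light-suppressed) half-cycles of the stimulation epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal, stats

from .stimulus import LDProtocol, protocol_duration
from .spectral import ResponseHistogram
from .synthetic_cells import LIGHT_ACTIVATED

__all__ = [
    "ReplayCycle",
    "CycleMetrics",
    "lowpass_zero_phase",
    "mean_crossings",
    "segment_cycles",
    "stimulation_reference",
    "cycle_metrics",
    "replay_extent",
    "cycle_trend_anova",
]


@dataclass(frozen=True)
class ReplayCycle:
    """One segmented post-stimulus cycle.

    ``peak_rate``/``mean_rate``/``trough_rate`` come from the unfiltered
    histogram; ``filt_peak``/``filt_trough`` are the smoothed-trace extremes
    within the cycle span, which is what amplitude criteria should use
    (raw 0.2-s-bin extremes are dominated by counting noise).
    """

    index: int  # 1-based
    start_s: float
    end_s: float
    peak_rate: float
    mean_rate: float
    trough_rate: float
    peak_time_s: float
    filt_peak: float = 0.0
    filt_trough: float = 0.0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class CycleMetrics:
    """Normalized per-cycle durations and peaks plus the replay extent."""

    norm_durations: np.ndarray
    norm_peaks: np.ndarray
    reference: float
    n_replay_cycles: int
    replay_extent_s: float


def lowpass_zero_phase(
    hist: ResponseHistogram, cutoff_hz: float, order: int = 4
) -> np.ndarray:
    """Forward-backward (zero net phase shift) Butterworth low-pass of the rates."""
    nyq = 1.0 / (2.0 * hist.bin_s)
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyq} Hz)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=1.0 / hist.bin_s, output="sos")
    return signal.sosfiltfilt(sos, hist.rates)


def mean_crossings(
    values: np.ndarray, level: Optional[float] = None, direction: str = "up"
) -> np.ndarray:
    """Indices (fractional, linearly interpolated) where a trace crosses a level."""
    values = np.asarray(values, dtype=float)
    level = float(values.mean()) if level is None else level
    above = values > level
    if direction == "up":
        idx = np.where(~above[:-1] & above[1:])[0]
    elif direction == "down":
        idx = np.where(above[:-1] & ~above[1:])[0]
    else:
        raise ValueError("direction must be 'up' or 'down'")
    if len(idx) == 0:
        return np.empty(0)
    frac = (level - values[idx]) / (values[idx + 1] - values[idx])
    return idx + frac


def segment_cycles(
    filtered: np.ndarray,
    hist: ResponseHistogram,
    direction: str = "up",
    min_bins: int = 2,
) -> List[ReplayCycle]:
    """Cut the filtered trace into cycles at same-direction mean crossings.

    Each cycle spans one crossing to the next; cycles shorter than
    ``min_bins`` bins are discarded. Peak/mean/trough rates come from the
    unfiltered histogram within the cycle span.
    """
    if len(filtered) != len(hist.counts):
        raise ValueError("filtered trace and histogram length mismatch")
    # an effectively constant trace has no cycles; the guard keeps numerical
    # ripple (~1e-13 of the mean) from producing zero-amplitude crossings
    span = float(filtered.max() - filtered.min())
    if span <= 1e-6 * max(abs(float(np.mean(filtered))), 1e-12):
        return []
    crossings = mean_crossings(filtered, direction=direction)
    cycles: List[ReplayCycle] = []
    rates = hist.rates
    for k, (a, b) in enumerate(zip(crossings[:-1], crossings[1:])):
        if b - a < min_bins:
            continue
        i0, i1 = int(np.ceil(a)), int(np.ceil(b))
        seg = rates[i0:i1]
        if len(seg) == 0:
            continue
        fseg = filtered[i0:i1]
        pk = int(np.argmax(seg))
        cycles.append(
            ReplayCycle(
                index=len(cycles) + 1,
                start_s=hist.t0 + a * hist.bin_s,
                end_s=hist.t0 + b * hist.bin_s,
                peak_rate=float(seg.max()),
                mean_rate=float(seg.mean()),
                trough_rate=float(seg.min()),
                peak_time_s=hist.t0 + (i0 + pk + 0.5) * hist.bin_s,
                filt_peak=float(fseg.max()),
                filt_trough=float(fseg.min()),
            )
        )
    return cycles


def stimulation_reference(
    hist: ResponseHistogram, p: LDProtocol, polarity: str
) -> float:
    """Mean response over the preferred half-cycles of the stimulation epoch.

    Light periods for light-activated cells, dark periods for
    light-suppressed cells; this is the normalization reference for replay
    peak/mean responses.
    """
    t = hist.times + hist.bin_s / 2.0
    rel = t - p.onset_s
    in_stim = (rel >= 0) & (rel < protocol_duration(p))
    is_light = np.mod(rel, p.cycle_s) < p.light_s
    sel = in_stim & (is_light if polarity == LIGHT_ACTIVATED else ~is_light)
    if not sel.any():
        raise ValueError("histogram does not cover the stimulation epoch")
    ref = float(hist.rates[sel].mean())
    if ref <= 0:
        raise ValueError("zero reference response")
    return ref


def replay_extent(
    cycles: Sequence[ReplayCycle],
    reference: float,
    ld_cycle_s: float,
    stim_offset_s: float,
    peak_floor: float = 0.2,
    duration_cap: float = 4.0,
) -> Tuple[int, float]:
    """Count consecutive genuine replay cycles and the time they span.

    A cycle counts while its normalized peak prominence (filtered-trace
    peak minus trough, over the stimulation reference) exceeds
    ``peak_floor`` and its duration stays below ``duration_cap`` LD
    cycles; counting starts at the first qualifying cycle and stops at the
    first failure. The extent is the end of the last counted cycle minus
    the stimulation offset.
    """
    n = 0
    end = stim_offset_s
    started = False
    for c in cycles:
        ok = ((c.filt_peak - c.filt_trough) / reference > peak_floor
              and c.duration_s < duration_cap * ld_cycle_s)
        if ok:
            started = True
            n += 1
            end = c.end_s
        elif started:
            break
    if n == 0:
        return 0, 0.0
    return n, end - stim_offset_s


def cycle_metrics(
    cycles: Sequence[ReplayCycle],
    stim_hist: ResponseHistogram,
    p: LDProtocol,
    polarity: str,
    peak_floor: float = 0.2,
    duration_cap: float = 4.0,
) -> CycleMetrics:
    """Normalized cycle durations/peaks and the end-of-replay summary."""
    ref = stimulation_reference(stim_hist, p, polarity)
    n_rep, extent = replay_extent(cycles, ref, p.cycle_s, p.offset_s,
                                  peak_floor=peak_floor, duration_cap=duration_cap)
    kept = cycles[:n_rep]
    return CycleMetrics(
        norm_durations=np.array([c.duration_s / p.cycle_s for c in kept]),
        norm_peaks=np.array([c.peak_rate / ref for c in kept]),
        reference=ref,
        n_replay_cycles=n_rep,
        replay_extent_s=extent,
    )


def cycles_table(
    cycles: Sequence[ReplayCycle],
    cell_id: str = "cell",
    ld_cycle_s: Optional[float] = None,
    reference: Optional[float] = None,
):
    """Cycle table as a pandas DataFrame (one row per segmented cycle)."""
    import pandas as pd

    rows = []
    for c in cycles:
        row = {
            "cell_id": cell_id,
            "cycle_index": c.index,
            "start_s": c.start_s,
            "end_s": c.end_s,
            "duration_s": c.duration_s,
            "peak_rate": c.peak_rate,
            "mean_rate": c.mean_rate,
        }
        if ld_cycle_s:
            row["norm_duration"] = c.duration_s / ld_cycle_s
        if reference:
            row["norm_peak"] = c.peak_rate / reference
        rows.append(row)
    return pd.DataFrame(rows)


def cycle_trend_anova(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """One-way ANOVA over per-cycle-position groups (e.g. first 3 and last 3).

    Returns the F statistic with df (k-1, N-k) and its p-value. Degenerate
    input (fewer than two groups, a group with fewer than two values, or
    zero variance everywhere) raises ``ValueError``; zero within-group
    variance with distinct group means yields an infinite F.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    means = [g.mean() for g in groups]
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (m - grand) ** 2 for g, m in zip(groups, means))
    ss_within = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    df_b = len(groups) - 1
    df_w = sum(len(g) for g in groups) - len(groups)
    if ss_within == 0:
        if ss_between == 0:
            raise ValueError("all groups are identical constants; F undefined")
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(f), float(stats.f.sf(f, df_b, df_w))
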