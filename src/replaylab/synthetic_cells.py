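"""Synthetic luminance-cell spike trains with ground-truth labels.

No public recordings are deposited for the experiments this package
models, so this module generates spike trains with the statistical
structure the analysis pipeline assumes:

* steady baseline firing under constant photic conditions,
* 1:1 entrainment to the LD stimulus (square-wave rate modulation,
  light-activated cells high in light, light-suppressed cells high in
  dark),
* for replay cells, a post-stimulus oscillation that continues the
  entrained rhythm: raised-cosine activity bumps whose repetition period
  is a fixed fraction of the LD cycle, whose first cycle is calibrated
  separately, and whose period grows / peak decays over successive cycles
  until the cell returns to baseline.

The default :class:`ReplaySchedule` is calibrated to the population
regression slopes and single-cell decay figures of the source study:
post-stimulus frequency = 0.62 x stimulus frequency, first replay-cycle
duration = 0.58 x LD-cycle duration, 0.41 replay cycles per LD cycle, no
replay for LD cycles shorter than 10 s, and per-cycle duration growth /
peak decay such that a 16-cycle replay ends near a duration ratio of 2.21
and a normalized peak of 0.43 (from first-cycle values 1.0 x period and
1.09 x reference response).

A note on the two frequency calibrations: the repetition period of the
bump train (cycles 2 onward) is set by ``freq_ratio``, which is what an
FFT of the post-stimulus epoch measures; the spacing between the first
and second bumps is set separately by ``first_cycle_ratio``, which is
what boundary segmentation of the first replay cycle measures. Population
regressions report these two quantities from different measurements and
they are not mutually consistent as properties of a single stationary
waveform; the generator therefore assigns each parameter to the waveform
feature its regression actually measures.

Spikes are drawn from an inhomogeneous Poisson process by thinning. The
recorded cells fire steadily and no ISI statistics are reported, so
Poisson is the minimal assumption; the sampler is isolated behind
:func:`sample_spike_train` and is replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence

import numpy as np

from .stimulus import LDProtocol, protocol_duration

__all__ = [
    "ReplaySchedule",
    "CellSpec",
    "SpikeTrain",
    "ReplayTruth",
    "CellRecord",
    "rate_profile",
    "sample_spike_train",
    "generate_cohort",
    "DEFAULT_SCHEDULE",
]

LIGHT_ACTIVATED = "light-activated"
LIGHT_SUPPRESSED = "light-suppressed"


@dataclass(frozen=True)
class ReplaySchedule:
    """Calibration of the post-stimulus replay oscillation.

    freq_ratio:
        Post-stimulus oscillation frequency divided by stimulus frequency;
        sets the repetition period of replay cycles 2 onward.
    first_cycle_ratio:
        First replay-cycle duration divided by the LD-cycle duration.
    n_replay_per_ld:
        Replay cycles generated per LD stimulation cycle (count slope).
    duration_growth:
        Multiplicative period growth per replay cycle (>= 1).
    peak_decay:
        Multiplicative peak-amplitude decay per replay cycle (<= 1).
    min_ld_cycle_s:
        No post-stimulus oscillation when the LD cycle is shorter than this.
    first_peak_norm:
        First-cycle peak rate divided by the stimulation reference response.
    width_frac:
        Activity-bump width as a fraction of the first-cycle period.
    rel_jitter:
        Per-cell multiplicative jitter SD applied to freq_ratio and
        first_cycle_ratio (mean-one, so population slopes are unbiased).
    """

    freq_ratio: float = 0.62
    first_cycle_ratio: float = 0.58
    n_replay_per_ld: float = 0.41
    duration_growth: float = (2.21 * 0.62) ** (1.0 / 14.0)
    peak_decay: float = (0.43 / 1.09) ** (1.0 / 15.0)
    min_ld_cycle_s: float = 10.0
    first_peak_norm: float = 1.09
    width_frac: float = 0.9
    rel_jitter: float = 0.05

    def __post_init__(self) -> None:
        for name in ("freq_ratio", "first_cycle_ratio", "n_replay_per_ld",
                     "duration_growth", "peak_decay", "min_ld_cycle_s",
                     "first_peak_norm", "width_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.duration_growth < 1.0:
            raise ValueError("duration_growth must be >= 1")
        if self.peak_decay > 1.0:
            raise ValueError("peak_decay must be <= 1")
        if not 0 < self.width_frac <= 1.0:
            raise ValueError("width_frac must be in (0, 1]")


DEFAULT_SCHEDULE = ReplaySchedule()


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth description of one synthetic luminance cell.

    ``baseline_rate`` is the steady rate under the cell's constant pre- and
    post-stimulus photic condition (light for light-activated cells, dark
    for light-suppressed ones). During stimulation the rate is a square
    wave: baseline*(1+modulation_depth) in the cell's preferred half-cycle
    and baseline*(1-modulation_depth) in the other.
    """

    polarity: str = LIGHT_ACTIVATED
    # baseline anchored so the driven reference response baseline*(1+m)
    # matches the study's printed 37.19 spikes/s stimulation mean
    baseline_rate: float = 37.19 / 1.9
    modulation_depth: float = 0.9
    is_replay: bool = False
    replay: Optional[ReplaySchedule] = None
    luminance_gain: Optional[Callable[[np.ndarray], np.ndarray]] = None
    seed: int = 0
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        if self.polarity not in (LIGHT_ACTIVATED, LIGHT_SUPPRESSED):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not 0 < self.modulation_depth <= 1:
            raise ValueError("modulation_depth must be in (0, 1]")
        if self.is_replay and self.replay is None:
            object.__setattr__(self, "replay", DEFAULT_SCHEDULE)

    @property
    def active_rate(self) -> float:
        return self.baseline_rate * (1.0 + self.modulation_depth)

    @property
    def inactive_rate(self) -> float:
        return self.baseline_rate * (1.0 - self.modulation_depth)

    def staircase_responses(self, lux_levels: Sequence[float]) -> np.ndarray:
        """Mean response at each luminance level of a staircase test.

        Monotone non-decreasing in lux for light-activated cells and
        non-increasing for light-suppressed ones.
        """
        lux = np.asarray(lux_levels, dtype=float)
        if self.luminance_gain is not None:
            return np.asarray(self.luminance_gain(lux), dtype=float)
        rel = lux / max(lux.max(), 1e-12)
        drive = rel if self.polarity == LIGHT_ACTIVATED else 1.0 - rel
        return self.baseline_rate * (1.0 + self.modulation_depth * (2.0 * drive - 1.0))


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times within a half-open recording span."""

    spike_times: np.ndarray
    t_start: float
    t_end: float
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", st)
        if len(st):
            if np.any(np.diff(st) < 0):
                raise ValueError("spike times must be sorted ascending")
            if st[0] < self.t_start or st[-1] >= self.t_end:
                raise ValueError("spike times must lie within [t_start, t_end)")

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class ReplayTruth:
    """Generator-side labels for one cell."""

    is_replay: bool
    freq_hz: Optional[float] = None
    n_cycles: int = 0
    onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    durations_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_rates: np.ndarray = field(default_factory=lambda: np.empty(0))
    bump_width_s: float = 0.0
    replay_end_s: float = 0.0


@dataclass(frozen=True)
class CellRecord:
    """One synthetic cell: spec, protocol, spike train (or noiseless rates), truth."""

    spec: CellSpec
    protocol: LDProtocol
    truth: ReplayTruth
    train: Optional[SpikeTrain] = None
    t_start: float = 0.0
    t_end: float = 0.0

    def histogram(self, bin_s: float = 0.2, t_start: Optional[float] = None,
                  t_end: Optional[float] = None):
        """Response histogram of the cell over ``[t_start, t_end)``.

        Noisy records bin the sampled spike train; noiseless records return
        the expected counts of the underlying rate profile.
        """
        from .spectral import ResponseHistogram, bin_psth

        t0 = self.t_start if t_start is None else t_start
        t1 = self.t_end if t_end is None else t_end
        if self.train is not None:
            return bin_psth(self.train, bin_s=bin_s, t_start=t0, t_end=t1)
        n = int(round((t1 - t0) / bin_s))
        centers = t0 + bin_s * (np.arange(n) + 0.5)
        counts = rate_profile(self.spec, self.protocol, centers) * bin_s
        return ResponseHistogram(bin_s=bin_s, counts=counts, t0=t0)


def _effective_schedule(spec: CellSpec) -> ReplaySchedule:
    """Apply the per-cell mean-one jitter to the frequency calibrations."""
    sched = spec.replay or DEFAULT_SCHEDULE
    if sched.rel_jitter <= 0:
        return sched
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA5]))
    f1, f2 = np.clip(1.0 + sched.rel_jitter * rng.standard_normal(2), 0.5, 1.5)
    return replace(
        sched,
        freq_ratio=sched.freq_ratio * f1,
        first_cycle_ratio=sched.first_cycle_ratio * f2,
        rel_jitter=0.0,
    )


def replay_truth(spec: CellSpec, p: LDProtocol) -> ReplayTruth:
    """Ground-truth replay-cycle plan for a cell under a protocol."""
    # an LD cycle of exactly 10 s (L/D 5 s/5 s) does not induce replay either
    if not spec.is_replay or p.cycle_s <= (spec.replay or DEFAULT_SCHEDULE).min_ld_cycle_s:
        return ReplayTruth(is_replay=False)
    sched = _effective_schedule(spec)
    n_rep = int(round(sched.n_replay_per_ld * p.n_cycles))
    if n_rep < 1:
        return ReplayTruth(is_replay=False)
    T = p.cycle_s
    spacings = np.empty(n_rep)
    spacings[0] = sched.first_cycle_ratio * T
    if n_rep > 1:
        # freq_ratio calibrates the frequency a 14-min post-stimulus window
        # measures, i.e. the mean cycle period inside that window; the
        # growth sequence is therefore normalized by its window-mean so the
        # windowed average period equals T / freq_ratio
        base = T / sched.freq_ratio
        growth = sched.duration_growth ** np.arange(n_rep - 1)
        k = int(np.searchsorted(spacings[0] + base * np.cumsum(growth), 14 * 60.0))
        norm = growth[:max(k, 1)].mean()
        spacings[1:] = (base / norm) * growth
    start = p.offset_s if spec.polarity == LIGHT_ACTIVATED else p.offset_s + p.light_s
    onsets = start + np.concatenate([[0.0], np.cumsum(spacings[:-1])])
    ref = spec.active_rate
    peaks = sched.first_peak_norm * ref * sched.peak_decay ** np.arange(n_rep)
    width = sched.width_frac * spacings[0]
    replay_end = onsets[-1] + spacings[-1]
    return ReplayTruth(
        is_replay=True,
        freq_hz=sched.freq_ratio / T,
        n_cycles=n_rep,
        onsets_s=onsets,
        durations_s=spacings,
        peak_rates=peaks,
        bump_width_s=width,
        replay_end_s=replay_end,
    )


def rate_profile(spec: CellSpec, p: LDProtocol, t: np.ndarray) -> np.ndarray:
    """Instantaneous firing rate (spikes/s) of the cell at times ``t``.

    Pre-stimulus: constant baseline. Stimulation: square-wave entrainment
    with the cell's polarity. Post-stimulus: for replay cells, the bump
    train described by :func:`replay_truth` riding on the inactive-phase
    floor, followed by a smooth return to baseline; otherwise constant
    baseline. The rate is non-negative everywhere.
    """
    t = np.asarray(t, dtype=float)
    rate = np.full(t.shape, spec.baseline_rate)

    # stimulation epoch: square wave, light first
    rel = t - p.onset_s
    in_stim = (rel >= 0) & (rel < protocol_duration(p))
    is_light = np.mod(rel[in_stim], p.cycle_s) < p.light_s
    active = is_light if spec.polarity == LIGHT_ACTIVATED else ~is_light
    rate[in_stim] = np.where(active, spec.active_rate, spec.inactive_rate)

    truth = replay_truth(spec, p)
    if not truth.is_replay:
        return rate

    floor = spec.inactive_rate
    post = t >= p.offset_s
    tp = t[post]
    out = np.full(tp.shape, spec.baseline_rate)
    # between stimulation offset and the bump train / between bumps: floor
    ramp = truth.bump_width_s / 2.0
    in_replay = tp < truth.replay_end_s
    out[in_replay] = floor
    for onset, peak in zip(truth.onsets_s, truth.peak_rates):
        w = truth.bump_width_s
        m = (tp >= onset) & (tp < onset + w)
        ph = (tp[m] - onset) / w
        out[m] = floor + (peak - floor) * 0.5 * (1.0 - np.cos(2.0 * np.pi * ph))
    # cosine ramp from the floor back up to baseline after the last cycle
    m = (tp >= truth.replay_end_s) & (tp < truth.replay_end_s + ramp)
    ph = (tp[m] - truth.replay_end_s) / ramp
    out[m] = floor + (spec.baseline_rate - floor) * 0.5 * (1.0 - np.cos(np.pi * ph))
    rate[post] = out
    return np.maximum(rate, 0.0)


def sample_spike_train(
    spec: CellSpec,
    p: LDProtocol,
    t_start: float,
    t_end: float,
    seed: Optional[int] = None,
) -> SpikeTrain:
    """Draw spikes from the cell's rate profile by Poisson thinning.

    Candidate spikes are drawn from a homogeneous Poisson process at the
    profile's maximum rate and kept with probability rate(t)/max_rate.
    Identical seeds give identical trains.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51]))
    probe = np.linspace(t_start, t_end, 4096)
    rmax = float(rate_profile(spec, p, probe).max())
    rmax = max(rmax, spec.active_rate, spec.baseline_rate)
    if rmax <= 0:
        return SpikeTrain(np.empty(0), t_start, t_end, spec.cell_id)
    n_cand = rng.poisson(rmax * (t_end - t_start))
    cand = np.sort(rng.uniform(t_start, t_end, size=n_cand))
    keep = rng.uniform(0.0, 1.0, size=n_cand) * rmax < rate_profile(spec, p, cand)
    return SpikeTrain(cand[keep], t_start, t_end, spec.cell_id)


def _auto_post_s(spec: CellSpec, p: LDProtocol, minimum: float = 14 * 60.0) -> float:
    """Post-stimulus epoch long enough for a 14-min window and the full replay."""
    truth = replay_truth(spec, p)
    tail = 600.0
    need = minimum
    if truth.is_replay:
        need = max(need, truth.replay_end_s - p.offset_s + tail)
    return float(np.ceil(need / 60.0) * 60.0)


def make_cell(
    spec: CellSpec,
    p: LDProtocol,
    pre_s: float = 120.0,
    post_s: Optional[float] = None,
    noiseless: bool = False,
) -> CellRecord:
    """Build one cell record: protocol-aligned epochs, truth labels, spikes."""
    if p.onset_s < pre_s:
        p = LDProtocol(p.light_s, p.dark_s, p.n_cycles, p.light_lux, p.dark_lux,
                       onset_s=pre_s)
    post_s = _auto_post_s(spec, p) if post_s is None else post_s
    t_start, t_end = 0.0, p.offset_s + post_s
    truth = replay_truth(spec, p)
    train = None if noiseless else sample_spike_train(spec, p, t_start, t_end)
    return CellRecord(spec=spec, protocol=p, truth=truth, train=train,
                      t_start=t_start, t_end=t_end)


def generate_cohort(
    n_cells: int,
    replay_fraction: float = 0.28,
    protocols: Optional[Sequence[LDProtocol]] = None,
    calibration: ReplaySchedule = DEFAULT_SCHEDULE,
    master_seed: int = 0,
    baseline_rate: float = 37.19 / 1.9,
    modulation_depth: float = 0.9,
    pre_s: float = 120.0,
    post_s: Optional[float] = None,
    noiseless: bool = False,
) -> List[CellRecord]:
    """Generate a labelled cohort of synthetic luminance cells.

    ``round(n_cells * replay_fraction)`` cells are replay-labelled (default
    28%, the fraction observed in the source study); polarity alternates
    light-activated / light-suppressed (~50/50, mirroring the observed 25
    vs 29 split). Protocols are assigned round-robin. Per-cell seeds are
    derived deterministically from ``master_seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 <= replay_fraction <= 1:
        raise ValueError("replay_fraction must be in [0, 1]")
    protocols = list(protocols) if protocols else [LDProtocol(60.0, 60.0, 10)]
    n_replay = int(round(n_cells * replay_fraction))
    seeds = np.random.SeedSequence(master_seed).generate_state(n_cells)
    records = []
    for i in range(n_cells):
        spec = CellSpec(
            polarity=LIGHT_ACTIVATED if i % 2 == 0 else LIGHT_SUPPRESSED,
            baseline_rate=baseline_rate,
            modulation_depth=modulation_depth,
            is_replay=i < n_replay,
            replay=calibration if i < n_replay else None,
            seed=int(seeds[i] % (2 ** 31)),
            cell_id=f"cell{i:03d}",
        )
        records.append(make_cell(spec, protocols[i % len(protocols)],
                                 pre_s=pre_s, post_s=post_s, noiseless=noiseless))
    return records
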