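# Methods

This note documents the models, the synthetic-data calibration, the
numerical choices, and the limits of what the test suite shows.

## 1. The synthetic luminance-cell generator

No recordings are publicly deposited for the phenomenon this package
analyses, so `synthetic_cells` generates spike trains with the
statistical structure the analysis assumes, with ground-truth labels.

**Rate model.** A cell is described by a spontaneous `baseline_rate` b
(its steady rate under the constant pre/post photic condition — light for
light-activated, dark for light-suppressed cells) and a
`modulation_depth` m. During LD stimulation the rate is a square wave:
b·(1+m) in the cell's preferred half-cycle and b·(1−m) in the other.
Defaults: m = 0.9 and b = 37.19/1.9 ≈ 19.6 spikes/s, chosen so the
stimulation reference response b·(1+m) equals 37.19 spikes/s, the
reported stimulation-epoch mean response of a representative cell. The
stimulation waveform is square (plateau-like histograms); the
post-stimulus replay is smooth (raised cosine), matching the shapes the
filtering/segmentation stage consumes.

**Replay calibration** (`ReplaySchedule` defaults):

| parameter | default | meaning |
|---|---|---|
| `freq_ratio` | 0.62 | post-stimulus frequency ÷ stimulus frequency, as measured in a 14-min window |
| `first_cycle_ratio` | 0.58 | first replay-cycle duration ÷ LD-cycle duration |
| `n_replay_per_ld` | 0.41 | replay cycles per LD stimulation cycle (count truncated by `round`) |
| `duration_growth` | (2.21·0.62)^(1/14) ≈ 1.023 | per-cycle period growth; a 16-cycle replay ends near duration ratio 2.21 |
| `peak_decay` | (0.43/1.09)^(1/15) ≈ 0.940 | per-cycle peak decay; normalized peaks 1.09 → 0.43 over 16 cycles |
| `first_peak_norm` | 1.09 | first-cycle peak ÷ stimulation reference |
| `min_ld_cycle_s` | 10 | no replay for LD cycles of 10 s or shorter (5 s/5 s never replays) |
| `width_frac` | 0.9 | activity-bump width ÷ first-cycle period |
| `rel_jitter` | 0.05 | per-cell mean-one jitter on the two frequency ratios |

The post-stimulus waveform is a train of raised-cosine activity bumps on
the inactive-phase floor b·(1−m), followed by a smooth return to
baseline. Bump onsets continue the entrained phase (at stimulation
offset for light-activated cells, one light half-cycle later for
light-suppressed ones, whose active phase is dark).

**Why two frequency calibrations.** The population statistics this
generator is calibrated to come from two different measurements: an FFT
of the first 14 post-stimulus minutes (frequency ratio 0.62) and
boundary segmentation of the first replay cycle (duration ratio 0.58).
No single stationary oscillation can satisfy both (0.58 ≠ 1/0.62), and
single-cell reports confirm the replay is not stationary: its period
grows from cycle to cycle. The generator therefore assigns each
parameter to the waveform feature its measurement actually probes: the
spacing between bumps 1 and 2 is `first_cycle_ratio`·T, and the spacing
sequence from bump 2 on is geometric with ratio `duration_growth`,
normalized so that the *mean* period inside the 14-min summary window is
T/`freq_ratio` (the quantity an FFT of that window reports). Cycle
durations still grow and peaks still decay cycle-by-cycle.

**Spiking.** Spikes are drawn from an inhomogeneous Poisson process by
thinning against the profile maximum. The modelled cells are described
as steady-firing and no ISI statistics are available; Poisson is the
minimal assumption and the sampler is isolated behind
`sample_spike_train`, hence replaceable. A `noiseless=True` record
carries expected-rate histograms instead of spikes; such records are
used wherever a test needs exact ground truth.

**What the generator does not emulate.** Slow drifts of excitability,
adaptation within half-cycles, burstiness/refractoriness, the
re-entrainment protocol, and any dependence of replay probability on the
cell (every generated replay cell replays deterministically when the LD
cycle exceeds 10 s). Passing tests demonstrate that the pipeline
recovers known structure of this form; they cannot certify behaviour on
features the generator lacks.

## 2. Oscillation detection

Response histograms use 0.2-s bins (counts conserved, half-open bins).
For detection the histogram is mean-subtracted, Hanning-tapered and
zero-padded to 4× the next power of two — enough grid resolution to
localize ~0.005–0.01 Hz rhythms inside a 7-min window; frequencies below
the unpadded resolution 1/(n·bin) are never called significant. The
null is built from 1000 histograms obtained by resampling bins with
replacement (temporal order destroyed, marginal rate distribution kept);
an amplitude is significant above the null mean + 4 SD at its frequency.

**False positives scale with spectrum size.** Null amplitudes are
Rayleigh-like, so the per-frequency exceedance of the mean + 4 SD rule is
about 5·10⁻⁴, and the probability that *some* frequency in a full
spectrum crosses the threshold grows with histogram length: measured
~5% per histogram at 150 bins (30 s), ~10% at 250 bins, ~26% at 600 bins
and ~60% for a 7-min window. The pipeline therefore never scans the full
spectrum when making calls about a cell: candidate frequencies are
restricted to the physiologically meaningful band within a factor 2 of
the stimulus frequency (the same band that defines a replay call), which
brings the per-cell false replay-call rate on constant-rate Poisson
cells to ≤ 2% (measured over 100 seeded cells).

**Post-stimulus summary frequency.** The replay call is based on the
first 14 post-stimulus minutes analysed as a single window (peak
significant amplitude in the replay band). The summary *value* uses
7-min windows sliding in 1-min steps when such a window can hold at
least two expected replay cycles (LD cycles up to ~130 s), taking the
significant peak from the window with the strongest oscillation;
otherwise the single 14-min window is used. The sliding variant avoids
a bias of the single long window: when the replay occupies only the
start of the window, the Hanning taper down-weights it and can favour a
harmonic over the fundamental. `sliding_max_frequency` (the maximal
significant frequency over sliding windows) serves to pick the filter
cutoff, where detecting a harmonic is harmless.

## 3. Cycle segmentation and decay metrics

The post-stimulus histogram is low-pass filtered with a zero-phase
(forward–backward) Butterworth filter of order 4. The cutoff is the
maximal significant sliding-window frequency, floored at 3× the stimulus
frequency: the floor keeps the shortest calibrated replay cycle
(0.58 T, fundamental ≈ 1.7× the stimulus frequency) inside the passband.
For light-activated cells segmentation starts at the last dark
half-cycle so the first replay bump is not at the filter's array edge.

Boundaries are same-direction crossings of the filtered trace with its
own mean. Both polarities replay as activity *peaks* (light-suppressed
cells burst in their preferred dark phase), so upward crossings are the
default for both; the direction is a parameter. Cycles shorter than 2
bins are discarded, and an effectively constant filtered trace (range
below 10⁻⁶ of its mean) yields no cycles. Peak/mean/trough rates per
cycle come from the unfiltered histogram; the filtered-trace extremes
are kept separately because raw 0.2-s-bin extremes are dominated by
counting noise.

Durations are normalized by the LD-cycle duration; peaks by the
stimulation reference response (mean rate over the preferred half-cycles
of the stimulation epoch). The end of replay is operationalized (the
source description — a return to non-oscillatory activity — states no
rule): a cycle counts while its filtered peak prominence exceeds 20% of
the reference *and* its duration stays below 4 LD cycles, counting
consecutively from the first qualifying cycle. Prominence (peak −
trough of the smoothed trace) rather than the raw normalized peak is
used because the post-replay baseline itself sits at ~0.5 of the
reference, which would never fall below a 0.2 peak floor. Both
thresholds are parameters.

Boundary accuracy on noiseless cells: with the cutoff comfortably above
the first-cycle fundamental (4× the stimulus frequency) every recovered
boundary lies within 2 bins (0.4 s) of the analytic mean-crossing of the
underlying rate profile; at the pipeline's 3× floor the first boundary
can shift by ~0.5 s because the filter trims the short first bump's
harmonics — an accepted trade for noise robustness.

The first-3 vs last-3 cycle trend uses a standard one-way ANOVA
(F = between-group MS / within-group MS, df = (k−1, N−k)); zero
within-group variance with distinct means reports F = ∞.

## 4. Cohort analyses

The preference index is (R_L − R_D)/(R_L + R_D) from the
stimulation-epoch half-cycle means. A cell is called a replay cell when
a significant post-stimulus frequency exists in the first 14-min window
within a factor 2 of the stimulus frequency. On noiseless labelled
cells the call is exact; on default-noise cohorts accuracy is ≥ 90%.
One known miss: very short protocols with few cycles (e.g. 10 s LD cycle
× 10 cycles) put only ~100 s of replay into a 14-min window, which a
stationary spectral test cannot detect — the experimental design this
emulates used up to 25 cycles for short stimuli, and the cohort
experiments do the same.

Population regressions are ordinary least squares on linear-scale
per-protocol means (the corresponding figures plot log-log axes but fit
a linear function; per-protocol averaging mirrors their mean ± SEM
presentation). The cohort experiments (`experiments.py`) use 5 cells
per protocol; LD-cycle durations 2–480 s for entrainment (25 stimulation
cycles for the two shortest, 10 otherwise), 20–480 s × 25 cycles for the
replay regressions, and 30 s/30 s × {5,10,15,20,25} cycles for the count
regression. With the default calibration the recovered slopes are
≈ 1.0 (entrainment), ≈ 0.60 (post-stimulus frequency), ≈ 0.57
(first-cycle duration) and 0.40 (count). Two known, small biases: at
very long LD cycles (≥ 240 s) the 14-min window holds barely one replay
period, so the detected frequency partly reflects the short first-cycle
spacing (these points carry little leverage in the linear fit); and the
count slope is 0.40 rather than 0.41 because `round(0.41·n)` at
n ∈ {5,…,25} produces exactly {2,4,6,8,10}.

## 5. The two-neuron model

Each unit is a dimensionless Morris–Lecar-type oscillator (fast
depolarizing current gated by m∞(V), delayed-rectifier current with gate
s, leak) plus a slow hyperpolarizing Ca²⁺ current gated by the recovery
variable u. With u fixed the unit fires repetitively; with
u̇ = μ(w∞(V) − u), u integrates depolarization and periodically silences
the cell. The R-neuron additionally receives inhibitory synaptic current
I_syn = σ_R·w_R,NR·(E_syn − V_R) with weight dynamics
ẇ = arctan[V_R(V_NR − V_R·w)] (w clipped to [0, 1] — the raw rule is
unbounded in time).

Phase rules: before stimulation both u's are fixed at 0.075 (σ_R =
0.036); during stimulation both follow u̇ with μ = 0.01 and the applied
current switches I_light = 0.06 / I_dark = 0.1 with the protocol
(identical drive to both units — the minimal assumption); after
stimulation the R-neuron follows the slow schedules σ_R(t), μ_R(t) while
the NR-neuron's u is frozen at its stimulation-end value (≈ 0.075).
Freezing rather than resetting matters: the system is bistable near
u = 0.075, and a hard reset can drop the NR unit into the coexisting
rest state instead of the documented steady post-stimulus firing.

**Parameter readings.** Three printed values admit more than one
reading, and the defaults are the readings under which the model
actually produces the documented behaviours (each alternative is
selectable by a flag):

* *Capacitance.* Read as reciprocal: V̇ = 3.33·ΣI. Linear stability
  of the printed set shows the depolarized state is a stable focus for
  every relevant current when C·V̇ = ΣI with C = 3.33 (trace condition
  F_V/C − λ < 0 needs C < ~0.44), i.e. the literal reading cannot spike
  at all (`literal_capacitance=True` reproduces that quiescence).
* *Gating rate.* λ(V) = (1/3)·cosh((V−V1)/(2V2)), the standard
  Morris–Lecar form (the printed constants map closely onto the classic
  dimensionless ML set). The reciprocal reading 1/(3 cosh·) abolishes
  spiking (`reciprocal_rate=True` for sensitivity tests).
* *Post-stimulus σ_R schedule.* Default σ_R(t) = 10·(0.0091 −
  0.0005·e^(−0.00008t)): scaled ×10 so σ_R is continuous across the
  stimulation/post boundary (0.086), and signed so inhibition slowly
  strengthens. Under this reading replay periods grow (simulated ISIs
  285 → 1206 over ~3 h) and the oscillation eventually dies — matching
  the described phenomenology — whereas the literal typeset form
  (σ_R(0) = 0.0086, decreasing) makes replay cycles shorten.
  μ_R(t) = 0.008 + 0.001·log(0.005 t)/log 0.05 as printed (base-free),
  clamped below one integration step near t = 0.

One model time unit maps to one second (`seconds_per_unit = 1.0`): the
simulated rhythm entrains 1:1 to a 120-unit LD cycle and the schedule
time constants are consistent with seconds.

**Dynamical picture.** At I_dark with dynamic u the intrinsic dynamics
sit at a SNIC-like boundary: tonic spiking whose period diverges as the
effective current drops. During stimulation the switched drive gates
firing (spiking in dark halves, silence in light) — the bursting regime,
with bimodal ISIs. After stimulation the NR-neuron's steady inhibition
holds the R-neuron just above threshold, producing one burst event per
replay cycle at a slow, μ_R- and σ_R-controlled period; as inhibition
strengthens the period grows and the mean activity per cycle falls.
Ablating the synapse (σ_R = 0, and post μ_R held at the stimulation
value 0.01, the "[u] only" condition) leaves fast tonic spiking whose
cycle durations and activities are constant to within a few percent.

**Numerics.** Fixed-step RK4 (numba-compiled), default dt = 0.005 time
units; spike counts change by far less than 1% under dt-halving, and
divergence raises an explicit instability error naming dt. Spikes are
upward crossings of V = 0, the midpoint of the simulated voltage range
[−0.34, 0.34]. The cycle analysis of the model bins post-stimulus spikes
at 0.5 s (Nyquist above the tonic spike rate) and uses a deterministic
cutoff of 1.5× the dominant spike rhythm (1.5/median ISI), so exactly
the fundamental of the oscillation survives; the replay/oscillation
*calls* still use the bootstrap-FFT stage, band-limited as in the cell
pipeline.

## 6. Problem sizes

Cohort experiments use 5 cells per protocol with 1000 bootstrap
resamples (the analysis default); the model experiments integrate
pre 600 + stimulation 1200 + post 3600–7200 time units at dt = 0.005.
These sizes put every recovered slope within a few percent of its
calibration across independent master seeds.

## 7. Known limitations

* The generator's replay is deterministic given the label; it models no
  cell-to-cell variability in replay probability or extent beyond the
  two jittered frequency ratios.
* The mean + 4 SD rule is only meaningful per frequency or in a
  restricted band; whole-spectrum scans of long histograms will flag
  spurious frequencies at substantial per-histogram rates (section 2).
* Replay detection fails for protocols whose total replay span is a
  small fraction of the 14-min analysis window (short LD cycles with few
  stimulation cycles).
* The model reproduces the replay phenomenology with single-spike burst
  events; it was not fitted to data, and several printed parameters
  required the documented re-readings to produce the described dynamics.
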