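# Methods notes

This note records the models, parameter choices and numerical decisions
behind `sostim`, and what the synthetic-data tests do and do not show
about real sleep EEG.

## Synthetic deep-sleep EEG

The generator (`sostim.synth`) emulates the features of NREM3
polysomnography that the detection/stimulation chain actually consumes:

- **Slow oscillations.** A sinusoid with per-cycle frequency jitter:
  cycle *c* runs at `so_freq + ε_c` with `ε_c` a truncated Gaussian
  (SD `so_freq_jitter`, clipped at ±2 SD), and the phase is piecewise
  linear between cycle boundaries.  Trough times are therefore known
  analytically (half a cycle after each boundary) and stored as ground
  truth.  Defaults: 0.8 Hz, 100 µV peak — troughs at −100 µV reliably
  cross the −80 µV detection threshold.  Real SOs have asymmetric
  down/up states; the sinusoid is sufficient because the detector and
  all phase metrics depend only on trough morphology and band placement.
- **Background noise.** White Gaussian noise spectrally shaped to
  1/f^α (α = 1), scaled to `noise_rms` (default 15 µV) per channel.
  Half of the noise *power* (configurable) is a common-mode component
  shared by all electrodes; linked-mastoid re-referencing cancels it,
  which is what makes the reference derivation a meaningful step.
  Mastoids carry noise only.
- **Optional confounds.** Poisson spindle bursts (13 Hz, Gaussian
  envelope) and a sub-0.5 Hz sinusoidal drift.
- **Stage labels.** The whole record is labeled N3 (one label per 30 s
  epoch); full-night hypnogram simulation is out of scope.

Identical parameters (including the seed) give bit-identical records;
all random streams are spawned from one `SeedSequence`.

### The evoked (stimulation-night) model

`generate_stim_sham_pair` adds a stimulus-locked **phase reset** to the
SO component: from `latency_s` (0.5 s) after each stimulus the SO phase
is pulled toward a canonical trajectory (`target_phase_deg` advancing at
`so_freq`) with weight `gain·(1 − e^{−u/rise_s})·e^{−u/decay_s}`
(gain 0.9, rise 1 s, decay 1.5 s).  Contributions of overlapping stimuli
add linearly, as does the optional K-complex-like transient (off by
default).

Two details make the reset *pure* (phase-only):

1. the per-stimulus phase offset is continuous in time (the wrapped
   target−actual difference is unwrapped along the record), and
2. the finite rise time bounds the pull's instantaneous-frequency
   excursion to roughly `gain/(2·rise_s)` Hz around `so_freq`, keeping
   the swept SO inside the flat passband of the 0.25–4 Hz analysis
   filter.

Without these, the reset transiently sweeps the SO toward ~0.25 Hz where
the analysis filter rolls off, which dents the per-trial Hilbert
envelope by several µV — an amplitude artifact that contradicts the
model's defining property (raising phase alignment without touching
amplitude).

## Real-time detection

- Reference: `mean(F3, F4) − mean(M1, M2)`, computed causally per
  sample; a pre-derived single reference channel is accepted.
- Filter: Chebyshev type-I, 3rd order, 1 dB passband ripple, 4 Hz
  cut-off, run as second-order sections with persistent state.  The
  ripple value is a convention choice (only "Chebyshev, 3rd order" is
  fixed by the protocol); type I at this order is stable at all
  supported rates.  State is initialized to the step-response steady
  state of the first sample so the start-up transient cannot fire the
  detector.
- Trough rule: emit at x₀ when x₀ < −80 µV, x₀ < x₋₁ and x₀ ≤ x₊₁
  (strict against the past, non-strict against the future: a flat-bottom
  trough fires exactly once).  Latency is one sample.
- Re-arming: after a detection (and after any scheduler pause) the
  detector stays disarmed until the filtered signal rises above
  `rearm_uV` (default −40 µV).  The protocol mentions such an
  amplitude-difference threshold without a value; −40 µV is half the
  detection threshold and suppresses double-firing inside noisy troughs.
  `rearm_uV=None` restores the bare three-sample rule.
- The causal filter delays 0.8 Hz content by ≈97 ms at 250 Hz.
  `filter_delay_at` exposes this analytic phase delay; ground-truth
  comparisons compensate it.

## Phase evaluation convention

Phase 0° is the positive peak, 180° the trough, (180°, 360°) the rising
phase.  Event phases are read from the Hilbert transform of the
**causally** filtered reference by default — the evaluation then shares
the detection path's filter lag, so a detected trough is by construction
a local minimum of the evaluated signal and reads ≈180°.  (Zero-phase
filtering is available; with it, detection phases shift by the filter's
phase lag, ≈28° at 0.8 Hz.)  Circular statistics use the
resultant-vector estimators: mean = arg(m₁), variance V = 1 − R,
angular deviation √(2(1−R)), SEM = std/√n, and the Fisher/Pewsey
moment forms of skewness and kurtosis.  When R = 0 the mean is flagged
undefined rather than silently reported.

## Stimulation schedulers

Fixed-step: stimulus 1 at detection + 0.350 s, stimulus 2 at +1.075 s,
pause 2.5 s; the detection gate spans delay1 + isi + pause = 3.925 s.
Stimulus times snap to the nearest sample; all timing tests declare a
one-sample tolerance.  The pause gates *detection only* — the filter
keeps running so its state is warm when the gate reopens.

PLL trigger: a detection arms the trigger; the first sample whose PLL
phase (0° at the VCO positive peak) enters [310°, 360°) fires, with the
trigger phase recorded.  If the phase jumps over the window between two
samples (fast PLL), that cycle is skipped.  Warm-up before the first
allowed stimulus defaults to N samples (XOR) or the FIR group delay
(integral).

PLL-XOR readings that the original description leaves open, fixed here:
buffer sums are unnormalized (only this reproduces the stated twofold
memory-vs-present influence, k·N/L = 2); ω is rad/s and the output
phase accumulates by ω·T_s per sample; the output fed back to the XOR
gate is the square wave sign(sin φ); buffers start at zero and ω at
2π·0.8 rad/s; ω is recomputed every L = 50 samples.  The published XOR
truth table's first row (1,0→0) is inconsistent with rows 2–3;
standard XOR is implemented on the reading that the row is a typo for
(0,0→0).

Integral PLL: the 0.03 Hz pre-filter is a causal linear-phase FIR with
4·Fs + 1 taps (group delay 2 s at Fs = 100 Hz); a stable IIR at this
cut-off is impractical.  At this length the transition band is wide, so
SO-band energy is only partially attenuated — a property, not a bug, of
the published design.  The recursion is implemented both per-sample and
as an exact vectorized cumulative-sum form (tested equal); the grid
search uses the fast path.

## PLL tuning

Grid: 20×20 log-spaced points per gain axis over [10⁻⁴, 10²] by default
(tests and examples use smaller grids).  Events are pooled across
training records before averaging.  Angular errors are wrapped to
(−180°, 180°] before squaring — the raw-difference reading would
penalize 360° offsets.  The time-phase criterion's reference time is the
earliest desired-phase crossing *after* the detection (the literal
pre-detection reading is selectable), with a 5 s search horizon;
events without a crossing are excluded and counted.

Note that this PLL has no phase-detector feedback — φ is a double
integral of the filtered input — so no tuning criterion selects
"locking" as such.  On a clean 0.8 Hz tone all three criteria choose
fast (≈5 Hz) PLLs whose window crossings can match any target delay:
the over-fitting failure mode that makes fixed-step scheduling the more
robust choice in practice.  The spectral diagnostics (dominant output
frequency and −6 dB range) exist to expose exactly this; a *suitable*
tuned PLL is one whose output frequency matches f_VCO, and only for such
frequency-matched candidates is a locking trend (settling of the
FIR/integrator transient) meaningful.

## Effect quantification

Band-filtering uses zero-phase FIR filters (mne's firwin design) applied
to the continuous channel *before* cutting — a 0.25 Hz high-pass kernel
is longer than a segment.  Transforms (Hilbert, STFT) run on the full
7 s segments; metric time courses are trimmed to [−1, +3] s afterwards,
so method boundary effects stay outside the analyzed window.  Artifact
limits (A_max = 300, A_min = 10 µV, peak absolute amplitude) are
evaluated on the wide-band signal over the trimmed window; one rejection
mask serves both the narrow-band and TF paths.

ITPC excludes samples with zero instantaneous amplitude from that time
point's average (counted on the result).  The TF maps use Hanning
windows whose length interpolates **linearly in frequency** from 1 s at
0.1 Hz to 0.1 s at 25 Hz.  Linear (not log-frequency) interpolation is
deliberate: with log interpolation the mid-band windows are short enough
that the 100 µV SO leaks coherently into 5–15 Hz ITPC bins and the
phase-locking contrast is no longer band-confined.  Power is reported in
dB relative to the per-frequency mean over the baseline window
(−0.5 to −0.35 s); the TF time grid spans [−1.5, 4.5] s so every window
fits inside its segment.  The frequency grid starts at 0.25 Hz (the
0.1 Hz start is selectable via the band setting).

## Cluster statistics

Paired per-point t across subjects; two-sided forming threshold
|t| > t_crit(α/2, n−1) with α = 0.05; clusters by 1-D runs or 2-D
4-neighborhood (positive and negative excursions separately); cluster
mass = summed t; null = maximum |mass| under per-subject sign flips of
the paired difference.  With 2^n_subjects ≤ n_permutations the null is
enumerated exactly (the identity flip included); sampled nulls use the
add-one p estimator.  Subjects are the statistical unit throughout:
per-subject metric time courses are computed first and only then
compared across subjects.

## What the synthetic tests show — and what they don't

The end-to-end mechanism test builds six heterogeneous subjects (SO
amplitude ~U[85, 115] µV, SO frequency ~U[0.7, 0.9] Hz, noise rms
~U[12, 18] µV), each with an *independent* stimulation night (pure
phase-reset evoked model) and sham night, mirroring a two-night paired
design.  On this cohort the pipeline finds a significant post-stimulus
ITPC cluster confined to the SWA band (up to the STFT's ~1.2 Hz
frequency resolution at the 4 Hz edge) while the baseline-corrected
amplitude shows no cluster — the phase metric is the more sensitive
readout, by construction of the evoked model.  The shared-background
mode of `generate_stim_sham_pair` is kept for controlled unit tests; it
is *not* used for the cohort because sharing the noise between
conditions shrinks the paired amplitude variance to ~0.2 µV and promotes
sub-µV filter-passband effects to significance, an artifact no real
two-night design exhibits.

Passing these tests shows the chain is internally correct and that the
metrics separate phase from amplitude effects under the stated model.
It does **not** show performance on real sleep EEG: real SOs are
asymmetric and non-stationary, arousals and stage transitions interrupt
detection, real evoked responses mix phase resets with K-complexes and
spindle responses, and inter-subject variability is far richer than
three scalar traits.  Problem sizes in the test suite (minutes-long
records, 6-subject cohorts, hundreds of permutation replicates, 7–8
point gain grids) are the package's chosen verification scale; all
scale linearly if enlarged.

## Known limitations

- EDF support is 16-bit with 1 s records and integer sampling rates;
  trailing partial seconds are padded.
- The real-time path assumes the record's own sampling rate; it is
  tested at 100, 250 and 1000 Hz.
- Sleep staging is taken from labels (synthetic or sidecar), never
  inferred; detection is not stage-gated by default.
- The integral PLL reproduces the published open-loop P+I structure; it
  will not phase-lock in the control-theoretic sense, and its tuning
  inherits the published criteria's over-fitting behavior.
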