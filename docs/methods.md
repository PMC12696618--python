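# Methods

This note documents the generative model, the measurement conventions, the
statistical procedures, and the design choices behind `srpt`, in the spirit
of a simulator/stats package's model documentation.  Nothing here reports a
number that the test suite or `scripts/acceptance.py` does not itself
compute.

## Stimulus protocols

All protocols express the same session skeleton: 200 trials in four blocks
of 50, trials separated by a 1.5 s gray screen and blocks by a 30 s gray
screen, with the first stimulus onset one gray period after session start.
Sequence trials are four gratings that abut in time (no gap between
elements).  Canonical orientations are A 45°, B 105°, C 15°, D 75°,
E 135°, with 165° as the novel lead for pseudorandom sequences and 135° as
the novel single-orientation stimulus.  Pseudorandom (AXXX/NXXX) tails are
drawn without replacement from {B, C, D, E} minus the lead, so no
orientation repeats within a sequence; the draw is seeded and
reproducible.  Phase-reversal sessions contain 400 reversals at 2 Hz in
four blocks of 100 with no intervening gray.  Stimulus durations are
restricted to the three session types actually used (150, 300, 1500 ms).

## The synthetic LFP forward model

The generator exists to make every downstream stage falsifiable by
parameter recovery; it is deliberately a superposition model, not a
biophysical one.

**Evoked kernels.**  Each component is a sum of Gaussian lobes truncated at
4σ: a negative lobe (latency, amplitude, width) and an optional later
positive lobe.  Sequence-initial ("lead") stimuli drive N1 + N2 + the N2
positivity; within-sequence stimuli drive only N1.  Day-1 ACC defaults:
N1 at 60 ms (30 µV lead / 25 µV follow), N2 at 185 ms / 25 µV with a
positivity at N2 + 75 ms / 15 µV (σ 25 ms).  V1 stimuli drive a large fast
component (75 ms / 100 µV, positivity at +65 ms / 40 µV).  Amplitudes in
microvolts are conventions chosen to sit in the plausible LFP range — the
phenomenon constrains latencies far more than magnitudes — and are
configurable per subject.

**Component widths.**  Negative-lobe widths default to σ = 5 ms (8 ms in
V1).  The width controls the curvature of the trough and therefore the
sampling jitter of an argmin latency estimator at a given noise level: with
200-trial averages of 20 µV white noise, σ = 5 ms keeps single-session
latency errors almost entirely within ±1–2 ms, which is what makes
millisecond-scale plasticity measurable at all under this design.  Much
wider troughs would need either more trials or smoothing before peak
picking, neither of which is part of this pipeline.

**Plasticity schedules** (absolute per day, applied to the Day-1 baseline):

* wild-type (WT): familiar-orientation ACC N2 latency shift
  {Day 1: 0, Days 2–4: −20 ms} — the full shift is expressed between Day 1
  and Day 2, matching the observation that the largest latency changes
  occur early in training;
* AS model (the Angelman-syndrome regime): no latency shift; the N2
  positivity amplitude scales ×{1, 1.33, 1.67, 2} across days;
* V1, both genotypes: all kernel amplitudes for *trained* orientations
  scale ×{1, 1.2, 1.35, 1.5} (stimulus-selective response potentiation);
* a null rule (no changes at all) backs the statistical-calibration
  scenario.

ACC effects are restricted to the familiar orientation when the
specificity flag is set (default); V1 gains apply to all trained
orientations, which is why a novel-order sequence of familiar elements
(DCBA) still shows potentiated V1 responses while a truly novel
orientation does not.

**Noise.**  Per channel: white Gaussian noise (SD 20 µV per sample at
1 kHz) plus a 1/f-power "pink" component (SD 10 µV).  At these levels a
single trial does not show a visible VEP but a 200-trial average does, and
sub-50-trial averages are marginal — consistent with how many trials this
preparation needs.  The pink component is synthesized spectrally at
quarter rate and linearly upsampled, i.e. it is band-limited below 125 Hz;
slow-drift statistics are unaffected and the white component supplies the
broadband floor.

**Oscillation.**  In the long-duration (1.5 s) single-stimulus scenario,
V1 channels receive a 10 Hz sinusoid in the 0.5–1.5 s post-onset window
(amplitude 50 µV, exponential decay τ = 1.5 s, random phase per trial),
whose amplitude scales ×{1, 1.6, 2.3, 3} across days for the familiar
orientation only.  Band power therefore grows by roughly the squared gain;
the ratio falls slightly short of gain² because the noise floor contributes
additively to both days.  ACC receives no oscillation — the programmed
regional dissociation.

**Cohorts.**  `simulate_cohort` draws per-subject models from population
distributions (N2 latency ~ N(185, 6) clipped to [170, 200] ms, N1 ~
N(60, 3), V1 ~ N(75, 4), a log-normal amplitude factor with σ = 0.12) and
derives per-session seeds from one cohort seed, so datasets are
reproducible and lazily synthesized (recordings are never all held in
memory).  The truth table (one row per subject/day/channel/role/component)
is emitted alongside, and the pipeline log records it, so recovery checks
are self-contained.

## What the generator does — and does not — emulate

It emulates: component overlap between a slow lead-N2 and the next
stimulus' N1 at short stimulus durations; across-day latency and amplitude
plasticity with orientation specificity; hemispheric duplication of V1;
trial-count-limited SNR; a familiarity-locked stationary-window
oscillation.  It does not emulate: spiking or laminar structure, artifacts
and electrode drift, behavioral state (locomotion, arousal), day-to-day
physiological latency wobble, or any nonlinearity between stimuli
(superposition is exact).  Passing recovery tests therefore shows the
*analysis* is correct and well-calibrated at realistic SNR; it does not
validate the forward model against biology.

## VEP measurement conventions

Times are in ms with 0 at the driving stimulus onset; sample windows are
half-open `[start, end)` at 1 kHz.  Epochs are aligned to sequence-initial
events.  Latency is the time of the minimum sample in the search window,
ties to the earliest sample (deterministic, condition-symmetric bias).
Magnitude searches the positivity only after the trough, so pre-stimulus
artifacts cannot masquerade as peak-to-peak amplitude; a trough on the
window's last sample is unquantifiable.  No baseline subtraction is
applied anywhere: the N2 positivity is defined relative to the voltage at
onset, which makes it DC-invariant by construction, and latency/magnitude
are DC-invariant as defined.  Unquantifiable measures (flat window,
average below 3× the pre-stimulus noise SD, fewer than 50 trials)
propagate as missing values with `valid = False`, never as zeros.

Default search windows (configurable): ACC N1 20–120 ms and N2 120–320 ms
post-lead-onset (the N2 window is capped at the next stimulus onset
+ 20 ms for sub-300 ms stimuli, where the components are not separable and
only a composite window is reported); follow-stimulus N1 20–120 ms post
its own onset; V1 20–200 ms per stimulus.  Component latencies are
reported relative to their own driving stimulus onset, with the
lead-onset-referenced value kept as an auxiliary column since both
conventions appear in this literature.

Hemisphere averaging takes the mean of valid V1 measures and falls back to
the single valid hemisphere; the 3×-noise validity rule is a repository
convention (the exclusion criterion for a "poor signal" hemisphere is
otherwise unspecified in practice).  The biphasic detector requires two
local minima, each at least half the depth of the global minimum
(prominence ≥ 0.25 of depth), separated by ≥ 15 ms; these thresholds are
likewise conventions, chosen to reject single-trough responses with
shoulder noise.

## Spectral conventions

The continuous record is high-pass filtered (9th-order Butterworth,
0.5 Hz) with forward–backward application — zero phase, so evoked
latencies measured elsewhere are not skewed; filtering precedes epoching.
Per-trial spectra use the raw rectangular window on the 1 s stationary
segment (0.5–1.5 s post onset): with no taper, 1 s at 1 kHz gives exactly
1 Hz bins and integer-frequency test tones land in single bins.  Reported
power per bin is `|X_k / N|²` (amplitude-normalized coefficient, squared),
cropped one-sided to 1–100 Hz *without* doubling: a sinusoid of amplitude
*a* yields `a²/4` in its bin, and the two-sided sum equals the mean square
of the segment (Parseval) to machine precision.  Band power sums bins with
both edges inclusive (1–30 Hz default).

## Statistics

The one-way repeated-measures ANOVA uses the classical within-subject
decomposition; the two-way mixed design crosses a between-subjects group
factor with the within-subjects session factor (between term tested
against subjects-within-groups, within terms against the
subject × session residual).  Greenhouse–Geisser ε is computed from the
double-centered (pooled within-group, for mixed designs) covariance of the
within-subject scores, clipped to [1/(k−1), 1], and applied
*unconditionally* to both dfs of every within-subject F — hence the
fractional degrees of freedom in all outputs.  Both ANOVAs are verified
against an independent reference implementation (pingouin) in the test
suite; ε on the mixed design's within terms uses the pooled covariance,
a deliberate estimation choice that can differ slightly from references
that pool differently.

Degenerate inputs follow fixed conventions: zero condition variance gives
F = 0, p = 1; a zero residual with nonzero condition variance gives
F = ∞, p = 0.

Unconditional GG correction is conservative when sphericity actually
holds, increasingly so at small n because ε̂ is biased downward; at n = 8,
k = 4 the realized Type-I rate of the full pipeline sits near 3%, and near
4% at n = 16.  The null-calibration suite therefore uses 16-subject
cohorts, where the realized rate is comfortably inside the 2.5–7.5% band
that unconditional correction can honestly achieve.

Post hoc comparisons use paired/unpaired t tests with Šidák
(`1 − (1−p)^m`) or Holm step-down adjustment.  Exact Dunnett and Tukey
studentized-range distributions are not implemented: the package's
validation surface is parameter recovery and calibration, not replication
of any specific published p value, and Šidák/Holm control the familywise
rate for the comparisons made here.  All tests are two-sided.

## Problem sizes and numerical choices

The Monte-Carlo validation suites use: 100 subjects for latency-shift
recovery; 20 subjects for composite-response mechanics; 50 cohorts of
8 + 8 for the genotype dissociation; 400 null cohorts of 16 in the test
suite (300 in `scripts/acceptance.py`) for Type-I calibration — sizes
chosen to give stable rates while keeping a full run in the tens of
minutes on one CPU.  Voltage is synthesized and stored as float32
(microvolts); FFT lengths are padded to fast sizes.  All randomness flows
from explicit seeds through `numpy.random.SeedSequence` spawning, making
every dataset and every reported number bit-reproducible.

## Known limitations

Latency estimation is raw argmin on the trial average — no smoothing, no
interpolation below the 1 ms sample grid, no single-trial estimates.  The
mixed ANOVA requires complete, balanced within-subject data (missing cells
must be handled upstream).  The generator's amplitude scale is
conventional, so magnitude-valued outputs should be read in relative
terms.  The spectral stage offers only the rectangular-window FFT used
here — no multitaper or wavelet estimators, no phase or coherence metrics.
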