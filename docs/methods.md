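# Methods notes

This note records the models, conventions and numerical choices behind
`flashsleep`, and what the synthetic-data tests do and do not establish about
real recordings.

## Time axis and protocol constants

All clock times are normalized once, at ingest, to continuous hours relative
to each night's habitual sleep onset (HSOn), wrapping clock times into
[−12 h, +12 h) around HSOn. This keeps evening saliva sampling (which starts
up to 9 h before HSOn) and the post-sleep-onset analysis windows on one
monotone axis with no midnight arithmetic anywhere downstream.

Protocol defaults, all overridable in the study config: stimulus from
HSOn + 0.5 h to HSOn + 1.5 h; analysis windows `intervention` = [0.5, 1.5) h
and `post` = [1.5, 8.0) h; 15-s hypnogram epochs; 30-min saliva sampling;
DLMO threshold multiplier 2 over the first 3 daytime samples.

## DLMO estimation

The threshold rule (2 × mean of the first three daytime concentrations) does
not by itself define *where* the onset is between two 30-min samples, nor how
to treat a single noisy sample above threshold. Choices made here:

* **Sustained crossing (default).** The onset is the first exceedance whose
  following sample, when present, is also at/above threshold; a lone spike is
  skipped. `require_sustained=False` gives the plain first-crossing rule.
* **Linear interpolation** between the bracketing samples. A sample exactly
  at threshold is itself the onset.
* A series starting at/above threshold raises (`rise not captured`); a series
  never crossing raises (`no onset detected`). The pipeline converts these to
  NaN records with warnings so one unresolvable visit does not abort a cohort.

## Phase shifts and PRC correction

Δϕ = DLMO_baseline − DLMO_post, so a delay is negative. The net shift
subtracts the placebo visit's Δϕ from the flash visit's, removing
within-participant protocol drift (circadian period ≠ 24 h).

The phase-angle correction is implemented **multiplicatively**:
corrected = observed × PRC(ψ̄)/PRC(ψᵢ), i.e. each shift is rescaled to the
magnitude the phase response curve predicts at the cohort-mean phase angle.
An additive reading ("percentage of change" applied as an offset) is also
defensible; the multiplicative form is scale-equivariant, is the identity at
ψᵢ = ψ̄, and preserves zero shifts, which we consider the better-behaved
choice. The decision is recorded in each run's provenance block. Queries
outside the tabulated PRC domain are errors — the curve never extrapolates —
and PRC(ψᵢ) = 0 makes the correction undefined (error), as division by a
predicted null response should be.

The package ships **no physiological PRC**. `synthetic.toy_prc()` is a
smooth, delay-only synthetic curve (−0.6 − 0.9·sin(πψ/12) h over ψ ∈ [0, 12])
used for simulation and tests; real analyses must supply their own table
(CSV: `phase_h_after_dlmo, shift_h`).

## Sleep architecture

Boundary epochs are assigned to windows by epoch *start* time (half-open
windows), which makes windowing deterministic and additive. ARTIFACT epochs
are excluded from durations and probability scores and break adjacency for
transition counting — no transition is counted into, out of, or across an
artifact gap; whether counting across artifacts would be more faithful to any
given scorer's convention is unknowable from labels alone, and the
conservative choice never invents a transition.

Two deep-to-light taxonomies circulate: N3→{N2,N1} and {N2,N3}→N1. The former
is the default; the latter is available as `taxonomy="n2n3_to_n1"` (CLI
`--transition-def n2n3-to-n1`).

Probability scoring summarizes scorer confidence as the mean p(stage) over
epochs *scored as* that stage; a stage absent from a window yields a missing
value, not zero, mirroring the reduced degrees of freedom short windows
produce for rare stages (N1, REM early in the night).

## Spectral analysis

* Preprocessing: polyphase resampling to 100 Hz, then a 4th-order Butterworth
  0.2–49 Hz applied forward–backward (zero phase). Only corner frequencies
  are standard; the realization is our choice. Upsampling must be requested
  explicitly. NaN samples are an error listing indices.
* Welch PSD: 3-s (300-sample) Hamming windows, 0% overlap, one-sided density
  normalized so its integral approximates the variance. Frequency resolution
  is 1/3 Hz.
* Band powers are trapezoidal integrals with the density interpolated at the
  exact band edges (no bin snapping). The alpha/sigma overlap (12–13 Hz) is
  integrated as defined in both bands, with no de-overlap correction.
* A 15-s epoch contains exactly five 3-s windows, so pooling a stage's epochs
  by concatenation never lets a window straddle an epoch boundary. Welch
  averaging is done within stage pools across epochs; C3 and C4 PSDs are
  averaged *after* PSD computation, then integrated.

## Power analysis

Power of the two-sided paired t-test is P(|T′| > t_crit) with T′ noncentral t
(df = n−1, noncentrality d·√n). Sidedness is assumed two-sided throughout.
The minimal detectable difference root-finds this function in the outcome's
units; the required sample size scans n upward from 2. scipy's noncentral-t
CDF returns NaN at extreme noncentrality, where true power is 1 to machine
precision; that case is clamped. The reverse-power default of n = 6 pairs
reflects a 7-recording PSG set minus one participant excluded as already
awake during the stimulus.

## Synthetic-data generator

The generator reproduces the *design* of the study: 10 participants, two
visits in randomized order, 30-min saliva sampling, 8 h of scored sleep, two
central EEG channels at 100 Hz.

* **Melatonin**: baseline B + A·σ((t−t₀)/r) with B = 2 pg/mL, A = 40 pg/mL
  (inside the assay's 0.78–50 pg/mL reportable range; the amplitude is a
  design choice, since only the assay range is constrained), r = 0.5 h, times
  lognormal noise with CV 0.054 (the intra-assay CV; all of a participant's
  samples are assumed assayed on one plate). Sigmoid midpoints vary between
  participants as N(−1.0 h, 1.0 h) truncated at ±2.5 SD, putting the
  noise-free threshold crossing ≈2.5 h before HSOn (phase angle ≈ 3 h). The
  truncation and the slightly tightened SD keep every onset inside the
  sampled windows; they narrow the tails relative to the target population.
* **Sampling windows**: baseline evening [−9, 0] h; post-stimulus evening
  [−9, +4] h, extended past the strict protocol end so that delays of up to
  ~6 h — which this intervention can produce — remain measurable. Samples at
  or before −6.5 h are flagged daytime.
* **Shifts**: the flash visit's true change is s + e with s ~ N(−1.13 h,
  1.27 h) (the flash effect; the ground-truth net shift) and e ~ N(−0.2 h,
  0.33 h) protocol drift; the placebo visit gets an independent drift draw.
  "Noise-free" recovery tests therefore set both the assay CV and the drift
  SD to zero: drift is part of the simulated physiology, not of the
  estimator.
* **Hypnograms**: first-order Markov chains at 15-s epochs with high
  self-transition and N2/N3 dominance, started in N1. No ultradian REM
  cycling, no circadian modulation of sleep propensity.
* **Stage probabilities**: Dirichlet draws (concentration 50) centred on a
  scorer-confusion row per epoch; means equal the confusion rows exactly,
  zero-mass entries stay zero, identity confusion gives one-hot vectors.
* **EEG**: per band, unit-RMS band-pass-filtered Gaussian noise spanning the
  recording, scaled per epoch by stage-specific RMS weights (N3
  delta-dominant, N2 sigma-rich). This exercises the spectral pipeline's
  ranking and scaling behaviour; it contains no spindles, K-complexes or
  evoked responses, so passing tests say nothing about morphology-sensitive
  analyses.

Everything is deterministic given the config seed: all draws flow from
`SeedSequence(seed, stream, participant, visit)`, and the EDF writer emits
fixed header timestamps, so simulated studies are byte-reproducible.

## EDF handling

Reading uses mne. Writing uses a minimal EDF writer (16-bit samples,
1-second records, per-channel symmetric physical scaling rounded to 0.1 µV);
quantization error is below 0.01 µV for typical EEG amplitudes, and the
mne round-trip is itself part of the test suite.

## Problem sizes in the test suite

Oracle-equivalence sweeps use 1000 random series/hypnograms; cohort recovery
uses 200 participants (melatonin only) and the default 10-participant study
for the end-to-end determinism check; Monte-Carlo validation of the power
function uses 100 000 replicates. These sizes make the checked bounds tight
(CLT error ≲ 0.1 h at n = 200; binomial SE ≈ 0.0013 at 10⁵ reps) while the
whole suite stays desk-scale.

## Known limitations

* The PRC correction's additive variant is not implemented.
* Melatonin methods other than threshold crossing (hockey-stick fits,
  amplitude/offset markers) are out of scope, as are sleep-onset latency,
  WASO and sleep-efficiency summaries, occipital-channel spectra, and any
  automatic sleep-staging.
* Group inference via mixed-effects models or Bayes factors is deliberately
  not reimplemented; the report's tidy tables are designed to feed such fits
  in external statistical software.
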