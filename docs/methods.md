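# Methods

`swdlab` re-implements, as a tested pipeline, the signal-analysis procedures
used to quantify hyperventilation-provoked spike-wave seizures (SWS) in
seizure-prone rats: event boundary refinement against an RMS threshold,
event-level spectral characterization, windowed-FFT respiratory-rate
estimation, peristimulus time histograms (PSTHs), and a normality-gated
paired-statistics layer.  Because group-level results from in-vivo cohorts
cannot be reproduced at desk scale, every stage is validated against a
synthetic session generator whose injected ground truth serves as the
oracle.  This note records the models, the defaults and their rationale,
and the limits of what the synthetic validation shows.

## Signal model and conventions

Recordings are synchronized multi-channel sessions (ECoG, EMG, respiratory
flow, chamber O₂/CO₂, laser TTL) at a common sampling rate, 200 Hz by
default.  All times are seconds on the session clock with t = 0 at the
recording start; all intervals — condition epochs, PSTH bins, event
windows — are half-open `[t0, t1)` so that partitions never double-count,
and a time exactly at a boundary belongs to the right-hand side (an event
at the stimulus onset counts as post-stimulus).  Windows are mean-subtracted
before every RMS and FFT; no other filtering is applied, since acquisition
hardware is assumed to have band-passed the signals already.

## Event boundary refinement

Candidate SWS windows arrive as coarse, human-style annotations.  For each
candidate:

1. **Baseline.**  The pre-event RMS baseline is the RMS of the
   mean-subtracted ECoG over the 10 s immediately before the candidate
   window.  The window shrinks to avoid overlap with the previous accepted
   event and truncates at the recording start, down to a 2 s floor below
   which the candidate is rejected.  Ten seconds is long enough for a
   stable RMS at 200 Hz and matches the respiratory analysis window scale;
   the floor keeps ≥ 400 samples in the estimate.
2. **Threshold.**  `threshold = multiplier × baseline RMS`, multiplier 2.5
   by default.
3. **Sections.**  The discharge occupies the *sections* of the candidate
   window where the running RMS — a centered 0.5 s moving RMS of the
   mean-subtracted trace — exceeds the threshold.  The section criterion is
   what separates a discharge from background: Gaussian background crosses
   2.5× its own RMS at isolated samples about 1% of the time, but almost
   never sustains that amplitude for half a second, so a pure-background
   window yields no section and the candidate is rejected (a typed
   no-event result, not an exception).  0.5 s is two to three cycles of
   the 5–8 Hz fundamental: long enough to suppress background crests,
   short enough that the section edge smear (± half the window) stays
   near one cycle.
4. **Peaks.**  A *peak* is a local maximum of the absolute mean-subtracted
   ECoG — strictly greater than both neighbors, plateaus taking their
   first sample — evaluated at sample precision.  Absolute value is used
   because montage polarity is arbitrary.  The refined onset and offset
   are the first and last peak that lies inside a supra-threshold section
   and itself exceeds the threshold; duration is offset − onset.

At multiplier 0 the bounds degenerate to the first and last local maxima of
the window; raising the multiplier never lengthens an event; and scaling
the trace by any c > 0 leaves the bounds unchanged because the threshold
scales with the baseline.  These three properties are enforced by tests.

Events shorter than 2.0 s (inclusive bound: ≥ 2.0 s survives) are removed.
Behavioral arrest is operationalized as EMG atonia: the event is kept when
EMG RMS during the event falls to ≤ 0.5 × the pre-event EMG RMS.  The 0.5
drop fraction is a package choice standing in for a behavioral/visual
criterion and is deliberately overridable (including a strict mode that
rejects events when no EMG channel exists; by default the check is skipped
with a warning).

## Event spectral characterization

**Dominant frequency** is the argmax of FFT power density over the event
segment, zero-padded to a 0.1 Hz grid and searched within 3–12 Hz — a band
bracketing the 4.6–7.9 Hz range these events occupy while excluding DC and
harmonics.  Ties break toward the lower frequency.  Segments shorter than
one cycle of the band's low edge are flagged low-confidence rather than
rejected.

**Harmonic score.**  SWS are distinguished from non-REM sleep by 5–8 Hz
harmonics in the spectrogram (Hann window, 1 s, 50% overlap, power spectral
density).  The event-averaged spectrum is peak-picked for the fundamental
f̂₀ within 5–8 Hz; for each harmonic k = 2..3 the mean power within
f̂₀·k ± tol (tol = max(0.5 Hz, resolution)) is divided by the local
background, the median power in the two flanking 1 Hz bands; the score is
the mean ratio over harmonics below Nyquist, and the event is called
harmonic when the score exceeds 2.0.  The median background makes the
score robust to ridge width; a pure sinusoid or band-limited slow-wave
surrogate has no harmonic energy and scores near 1.

## Respiratory rate

The flow trace is cut into consecutive, non-overlapping 10 s windows
(hop = window — "individual windows" read literally).  Each window is
mean-subtracted, Fourier-transformed, and assigned the frequency of
maximal power density within 0.5–4 Hz, a band bracketing rat breathing
(~0.8–2 Hz) with margin while excluding drift and movement artifact.  By
default the FFT is zero-padded ×4 for sub-bin argmax refinement (ties
toward the lower frequency); disabling it recovers strict 0.1 Hz native
bins.  A 30 s moving average — centered over 3 windows, truncated at the
edges, skipping missing windows with renormalization — smooths the trace.
Centered (not trailing) averaging is a documented choice.  All-zero
windows yield NaN and are excluded.  Rates are Hz internally;
breaths/minute is an exact ×60 at the reporting surface.

## Peristimulus histograms

Refined event onsets are aligned to the stimulus origin t₀ (gas-exchange
or laser onset) and counted in 3 half-open 5-min bins per side covering
±15 min; an event is assigned by onset only, so an event straddling t₀
counts on the side where it began.  Per animal, pre/post totals are the
bin sums over [−15, 0) and [0, +15) min and the mean count per bin is the
total divided by 3; the group summary is the mean ± SE (SD/√n, animals as
the experimental unit) across animals.  The stacked-histogram table is the
long-format (animal, bin, count) view whose per-bin sums equal the matrix
column sums.

## Statistics

All data are tested for normality before testing: Shapiro–Wilk on the
paired differences at α = 0.05 (the standard small-n choice; constant
difference vectors pass trivially).  Parametric data use the paired
t-test; otherwise the Wilcoxon signed-rank test with exact p for n ≤ 25
and no zero differences, and the continuity-corrected normal approximation
above.  All-zero differences are reported as a degenerate no-effect result
(statistic 0, p = 1).  An explicit method override exists for analysts who
fix the test family a priori.

Multi-condition designs use a one-way repeated-measures ANOVA on a
complete animals × conditions matrix (missing cells are an error — no
imputation).  F = MS_condition/MS_error from within-subject sums of
squares; degrees of freedom are scaled by the Greenhouse–Geisser epsilon
computed from the double-centered condition covariance matrix
(ε = tr(CSC)²/[(k−1)·tr((CSC)²)], clipped to [1/(k−1), 1]); Huynh–Feldt is
available as an option.  At k = 2, ε = 1 exactly and F equals the paired
t².  Pairwise post-hocs are Holm-corrected paired comparisons — the
multiplicity procedure is a package decision.  SE is always SD/√n across
animals (mean ± SEM convention); significance is α = 0.05.

## Synthetic sessions and ground truth

The generator emulates the statistical structure the analysis relies on,
not the biophysics:

- **ECoG background**: Gaussian noise with power spectrum ∝ 1/f^α, α = 2
  by default — the textbook cortical field-potential slope over 1–50 Hz —
  scaled to 50 µV RMS.  Frequencies below 1 Hz share the 1 Hz weight so
  the variance is finite.
- **SWS morphology**: a harmonic comb, Σₖ A·d^(k−1)·cos(2πkf₀t + φₖ) with
  4 harmonics, geometric decay d = 0.6, random phases, and 0.1 s cosine
  on/off ramps.  The comb is chosen because the analysis identifies SWS by
  their harmonic spectrogram signature, not by a morphological template.
  The default fundamental amplitude is 500 µV, i.e. an SNR (fundamental
  amplitude / background RMS) of 10; no amplitude statistics are published
  for these events relative to background, so the SNR is a package choice
  and recovery tests are parameterized over it.
- **Event placement**: a piecewise-homogeneous Poisson process with
  per-condition rates expressed in events per 5-min bin (defaults 0.89
  normoxia, 1.73 hypoxia, 0.95 hypercapnia, 0.84 hypoxia+CO₂, 2.27
  photostimulation), durations lognormal with arithmetic mean 5.3 s and
  SD 2 s, f₀ uniform on 5–8 Hz, overlap rejection with a 100-redraw cap
  per event.  These rate defaults are configuration, not assertions.
- **EMG**: white noise at 30 µV RMS, multiplied by an atonia fraction
  (default 0.2) during events.
- **Respiration**: a unit sinusoid whose instantaneous frequency follows
  the per-condition schedule (1.03 Hz normoxia, 1.33 hypoxia, 1.78
  hypercapnia, 1.88 hypoxia+CO₂, 1.24 photostimulation) plus slow
  zero-mean jitter (SD 0.02 Hz, 10 s nodes).  A sinusoid suffices because
  the estimator only uses spectral peak location; it shares nothing with a
  real flow waveform's shape.
- **Chamber gas**: first-order exponential relaxation (τ = 30 s) to each
  epoch's target (21% / 10% O₂; 0% / 5% CO₂).
- **Laser**: 10 ms pulses at 20 Hz gated 2 s on / 2 s off, emitted during
  photostimulation epochs; the default protocol length is 15 min, matching
  the ±15 min PSTH analysis window.
- **Protocol**: by default two epochs, normoxia then hypoxia in a 2:1
  split with the alignment origin at the boundary (40/20 min for a 60-min
  session).

A single 64-bit seed feeds one master `SeedSequence`; per-channel
sub-streams are derived deterministically, so identical configuration
yields bitwise-identical sessions.  The `GroundTruth` record (injected
events with f₀, the piecewise-constant breathing schedule, the condition
timeline) is the oracle for every downstream test.

### What the synthetic validation does and does not show

Passing recovery tests show the implemented procedures are correct and
well-calibrated *under the generative model*: harmonic events in Gaussian
1/f² background, sinusoidal breathing, Poisson event times.  They do not
show robustness to movement artifact, electrode drift, state-dependent
background (sleep spindles, theta), non-stationary breathing waveforms, or
human variability in the coarse annotations beyond the ±1 s jitter model.
Two quantitative gaps are worth noting.  First, with a Gaussian
background even the running-RMS section criterion admits rare false
sections (≈ 1–2% of 4 s windows), so boundary recovery saturates near
97%, not 100%.  Second, Poisson placement makes between-animal count
dispersion exactly Poisson; published cohort SEs for this preparation are
*smaller* than Poisson predicts, so statistical power measured on the
synthetic cohorts (≈ 0.87–0.92 for the 0.89 vs 1.73 per-bin contrast at
n = 15, two-sided α = 0.05) underestimates what the equivalent in-vivo
contrast achieves; the generator nevertheless stays Poisson because the
count statistics downstream assume it.

## Numerical choices and degenerate inputs

- FFT grids: event frequency on a ≤ 0.1 Hz zero-padded grid; respiratory
  argmax on the ×4 zero-padded grid; ties always break toward the lower
  frequency (the first argmax).
- Sample-precision peak times; no sub-sample interpolation.
- Harmonics above Nyquist are skipped and the score is averaged over the
  harmonics actually evaluated.
- Empty epochs in the respiratory summary give NaN with a warning;
  all-zero windows give NaN rates excluded from smoothing.
- The EDF writer quantizes each signal to 16 bits over its own physical
  span (round-trip error ≤ span/65534) and requires whole-second sessions
  at integer rates; the CSV dialect (`%.17g`, round-trip float parsing) is
  bit-exact and is the canonical format for fixtures.
- Monte-Carlo sizes in the routine test suite are chosen to keep the
  default run fast (e.g. 50 random placement configs, 10 spectral-slope
  seeds); the acceptance checks use the full stated sizes (200 events, 200
  cohorts, 2000 statistic replicates, 1000 PSTH sets).

## Known limitations

- No de-novo event detection: the pipeline refines human-supplied coarse
  windows and cannot find events outside them.
- Candidates whose pre-event window overlaps the previous event by more
  than 8 s are rejected rather than re-baselined; discharges closer than
  ~2 s to their predecessor are therefore not independently measurable.
- The atonia criterion is a quantitative stand-in for a behavioral
  judgment; its 0.5 drop fraction has no published counterpart.
- EDF support covers continuous EDF/EDF+ with identical per-signal rates;
  proprietary acquisition formats are out of scope.
- The rm-ANOVA is one-way within-subject only; mixed designs and missing
  data are not handled.
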