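# Methods

## Stimulus model

The artificial language is fully specified by a lexicon (four trisyllabic
words over twelve distinct syllables) and a syllable duration (default
0.300 s).  Streams are ideal: onsets are exact multiples of the syllable
duration and no audio is rendered, because every downstream computation
needs onset times only.  The pseudorandom word order satisfies two
constraints — each word appears exactly `repetitions_per_word` times and no
word follows itself.  The sampler draws uniformly among words with
remaining quota, excluding the previous word and any choice that would
strand the remaining counts in an unsatisfiable state.  Feasibility uses
the standard rearrangement bound: counts `c` with total `T` can be ordered
without adjacent repeats after previous word `p` iff `max(c) ≤ ceil(T/2)`
and not (`T` odd and `c[p] = ceil(T/2)`).  This is exact, so generation
always completes for feasible inputs and is deterministic per seed.  At the
full scale (4 × 200 words) the stream has 2400 syllables over 12 minutes,
tagging syllables at 3.33 Hz and words at 1.11 Hz.

## Synthetic EEG generator

The generator emulates exactly the features the analysis is sensitive to;
it is a measurement test-bed, not a biophysical simulation.

Per channel, the signal is a sum of:

- **1/f^α noise** (α = 1 by default, RMS `noise_scale` = 10 µV), built by
  spectral shaping of white noise.  A fraction `noise_shared_frac` (0.8) of
  the noise power is a single process common to all channels.  Scalp
  channels are strongly correlated through volume conduction, and this
  matters statistically: a subject's channel-averaged zITC keeps roughly
  unit spread under the null only because channels are correlated; with
  independent channel noise that spread would shrink as `1/√C`.
- **A syllable-locked component**: a deterministic sinusoid at the syllable
  rate (amplitude `syllable_amp` = 2 µV).  Because the stream is
  isochronous from t = 0, a global sinusoid is locked to every onset.
- **A word-locked component**: one cycle of a word-rate sinusoid per word
  window, mixed as `p·locked + (1−p)·phase-jittered` where the jittered
  copy gets an independent uniform phase per word.  `p` is
  `word_phase_lock` scaled linearly between the `learning_ramp` endpoints
  across the stream, so a rising ramp emulates entrainment growth over
  learning.  At `p = 1` with no noise every epoch is identical (ITC = 1);
  at `p = 0` the word response carries no consistent phase.
- **Artifact transients**: Poisson-timed smooth biphasic pulses (Gaussian
  first derivative, ~0.4 s, default 150 µV) on random single channels,
  exercising the artifact attenuator.

All evoked components ride on a fixed alternating-polarity channel
topography.  ITC is a phase statistic, so per-channel polarity is
irrelevant to it, but the topography must have zero channel mean for the
signal to survive common-average referencing (as dipolar fields do in real
recordings).

Group presets encode the qualitative pattern under study and are not fitted
values: the control-like (TDC) preset has `word_phase_lock` 0.8 with a
rising ramp (0.45 → 1.0); the Fragile-X-like (FXS) preset has 0.12 with a
flat ramp; the syllable amplitude is identical in both, so any group
difference at the syllable bin is a false positive by construction.
Cohorts share one stream (a predefined order, as in the paradigm) and
derive per-subject seeds deterministically from a master seed.

What the generator does **not** emulate: realistic head geometry or
channel covariance beyond the single shared-noise fraction, non-stationary
noise, co-articulation, evoked-response morphology, or eye/muscle artifact
spectra.  Passing tests therefore validate the measurement chain — they do
not certify performance on real recordings.

## Preprocessing

Fixed order: (1) 60 Hz IIR notch (Q = 30) and 4th-order Butterworth
band-pass 0.5–20 Hz, both applied forward–backward for zero phase (phase
integrity is the whole point of an ITC pipeline); (2) artifact
attenuation; (3) common-average reference; (4) epoching.

Artifact attenuation is a smooth soft limiter: samples within ±threshold
(50 µV) pass through bit-identically, and the excess beyond the threshold
is compressed through `tanh` with a 5 µV knee, bounding output at
±55 µV with a C¹ transfer curve.  This deliberately simple rule implements
the contract downstream analysis needs — bounded output, clean data
untouched, no introduced discontinuities — rather than any particular
published artifact-correction algorithm.

Epochs are half-open windows `[onset, onset + 9.0 s)` at every 10th word
onset, snapped to the nearest sample (alignment error ≤ half a sample);
onsets whose full window does not fit inside the recording are dropped.
For a recording that covers the full 12-minute stream exactly, all 80
candidate onsets fit.  Published applications of this design sometimes
retain slightly fewer epochs; the window-fit rule here is explicit rather
than tuned to any particular count.

## ITC, surrogates, zITC, WPI

ITC per channel and FFT bin is the magnitude of the mean unit-normalized
complex FFT coefficient across epochs (rectangular window, no padding —
the tagged periods divide the 9 s epoch exactly, so leakage at the tagged
bins is nil).  Bins with exactly zero amplitude have undefined phase and
contribute a zero phasor.

Raw ITC has a positive chance level, `E[ITC] ≈ √π/(2√N)` for uniform
phases, so observed values are standardized per channel/bin against a
subject-specific null: 100 surrogates, each re-extracting epochs from the
continuous cleaned recording at onsets independently jittered by
U(−0.9, +0.9) s (snapped to the sample grid; out-of-range windows redraw
the jitter up to 100 times).  The null sd uses `ddof = 1`.  Bins where the
null sd collapses to zero (e.g. zero jitter) are flagged as degenerate and
carry NaN instead of silently becoming infinite.

The word and syllable bins are identified as the nearest FFT bin to the
nominal rates; with 9 s epochs they land exactly on bins 10 and 30, and
identification errors of more than half a bin raise.

`WPI = z_word − mean(z_{word±1}, z_{word±2})`, computed after averaging
zITC over a channel selection (default all channels; the original
region-of-interest notion is source-level and not modeled here).  WPI is
invariant to adding a constant across bins and measures spectral
selectivity, not amplitude.

## Jackknife time-course

Because ITC is undefined for one epoch, per-epoch estimates come from
leave-one-out jackknife replications, computed via the phasor-sum identity
`|S − u_i|/(N−1)` so all N replications cost one FFT pass (an explicit
recomputation oracle verifies the identity in the tests).  Replications are
normalized by subtracting the mean replication over baseline bins
(0.66–5.0 Hz excluding the word rate and its 2nd–4th harmonics; at 9 s
epochs: bins 6–45 minus {10, 20, 30, 40}), converted to pseudovalues
`N·ITC_all − (N−1)·JK_i` with `ITC_all` normalized by the same rule, and
smoothed with a centered 5-point moving average that drops the first and
last two epochs.

Channel aggregation defaults to averaging per-channel ITC across the
selection before the jackknife algebra; the channel-selection parameter
allows the alternative of restricting to any subset first.  The group model
is `smoothed_pv ~ epoch_index × group + (1 | subject)` (treatment coding,
control group as reference), restricted to epochs whose onset lies in the
first half of exposure, where entrainment growth is approximately linear
before saturating.  Fitting is delegated to statsmodels MixedLM (REML,
default optimizer with a Powell retry).  p-values use a t distribution on
residual degrees of freedom — a documented approximation, as is standard
when no exact small-sample df method is specified.  If the mixed model
fails (non-convergence or non-finite standard errors — common when the
random-intercept variance is genuinely near zero, since normalization
removes subject offsets), the code falls back to per-subject OLS slopes
with one-sample and two-sample t-tests, flagged in the result's `method`
field.

## Group statistics

One-sample two-tailed t against 0 per group and frequency; one-way
between-group ANOVA on subject-level scalp-averaged zITC (for two groups,
F must equal the squared pooled two-sample t — asserted internally at
1e−8); WPI compared by a two-sample t, pooled variance by default with a
Welch option.  No multiple-testing correction is applied across the two
planned frequencies.  Degenerate inputs (zero variance, missing group,
n < 2) raise rather than returning NaN.

## Problem sizes and numerical choices

Default generator parameters mirror the acquisition design (1000 Hz,
128 channels, 12-minute stream, 100 surrogates, ±900 ms jitter).  The test
suite, analysis scripts and acceptance script run a reduced configuration —
250 Hz, 2–4 channels, a 180 s stream giving 20 epochs per subject, cohorts
of 8–20 subjects — chosen so the full suite completes in a few minutes
while keeping every structural property intact (the 9 s epoch still puts
the tagged frequencies exactly on bins 10 and 30).  Monte-Carlo
calibration claims use ≥30–50 simulated subjects and fixed seeds;
simulation-based claims in tests are majority-of-replicates criteria, not
single-run assertions.

Recordings round-trip through FIF (MNE's native format, float32 volts);
events through BIDS-style TSV whose reader reconstructs onsets from the
isochronous grid so round-trips are exact despite text formatting.

## Known limitations

- The synthetic word component concentrates energy in the tagged bin; real
  word-evoked responses spread energy over harmonics, which would make WPI
  differences less clean than here.
- The artifact attenuator bounds amplitudes but does not reconstruct the
  underlying signal during an artifact, unlike dedicated correction
  algorithms.
- Source-level analyses (cortical parcellation, region × hemisphere
  models) are out of scope; the WPI channel selection is a free parameter
  at scalp level.
- The mixed model's df approximation is anti-conservative for very small
  cohorts; the OLS fallback is the more cautious read in that regime.
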