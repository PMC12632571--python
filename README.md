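# entrainkit

Frequency-tagged EEG analysis of statistical word learning: inter-trial
phase coherence (ITC), surrogate-based z-scoring, the word precision index,
and jackknife pseudovalue learning time-courses — with a synthetic-EEG
generator so the whole pipeline is testable end to end against known ground
truth.

## The problem

In auditory statistical-learning paradigms, listeners hear a continuous
stream of syllables presented isochronously (here 300 ms per syllable,
3.33 Hz) that conceals four trisyllabic nonsense words (*tafuko*, *rugeme*,
*repuni*, *fetisu*) repeating in pseudorandom order without immediate
repetition, so hidden words arrive at 1.11 Hz.  If the brain segments the
stream into words, EEG phase-locks not only at the syllable rate but also at
the word rate.  This package implements that measurement chain for
group comparisons (e.g. typically developing controls, "TDC", versus a
clinical group, "FXS"):

1. **Stream construction** — token order and onset times for the artificial
   language (`entrainkit.stream`).
2. **Synthetic EEG** — 1/f background noise plus syllable- and word-locked
   components with a controllable trial-to-trial phase-locking level and an
   optional learning ramp (`entrainkit.synth`).
3. **Preprocessing** — 60 Hz notch + 0.5–20 Hz zero-phase Butterworth
   band-pass, ±50 µV artifact attenuation, common-average reference, and
   non-overlapping 9.0 s epochs time-locked to every 10th word onset
   (`entrainkit.preprocess`).  With 9 s epochs the tagged frequencies fall
   exactly on FFT bins 10 (1.11 Hz) and 30 (3.33 Hz).
4. **Entrainment** — per-channel ITC
   `ITC_f = |mean_k exp(i·phi_k(f))|`, standardized per channel/bin against
   a null of 100 surrogates whose epoch onsets are jittered uniformly within
   ±900 ms (`zITC = (ITC − mean_surr)/sd_surr`), and the word precision
   index `WPI = z_word − (z_{w−2}+z_{w−1}+z_{w+1}+z_{w+2})/4`
   (`entrainkit.entrainment`).
5. **Learning time-course** — leave-one-out jackknife ITC, baseline
   normalization over 0.66–5.0 Hz (excluding 1.11/2.22/3.33/4.44 Hz),
   pseudovalues `N·ITC_all − (N−1)·JK_i`, span-5 smoothing, and the mixed
   model `pv ~ epoch × group + (1 | subject)` (`entrainkit.timecourse`).
6. **Group statistics** — one-sample entrainment tests, between-group
   ANOVA (F = t² cross-checked), WPI two-sample t
   (`entrainkit.stats`), and an orchestrating pipeline with TOML configs
   and hashed manifests (`entrainkit.pipeline`).

## Worked example

The numbered scripts under `analysis/` run the study at reduced scale
(180 s stream → 20 epochs/subject, 250 Hz, 4 channels, 12 + 8 subjects)
and write their tables under `results/analysis/`:

```bash
python analysis/01_build_stream.py
python analysis/02_cohort_entrainment.py
python analysis/03_group_stats.py
python analysis/04_timecourse.py
```

Output of the last two (seed 1):

```
zitc_word: group ANOVA F(1,18) = 73.25, p = 0.0000
  TDC: mean 3.79, t(11) = 13.57, p = 3.253e-08
  FXS: mean 0.36, t(7) = 1.41, p = 0.2023
zitc_syllable: group ANOVA F(1,18) = 4.21, p = 0.0551
  TDC: mean 7.13, t(11) = 66.54, p = 1.095e-15
  FXS: mean 7.57, t(7) = 35.60, p = 3.584e-09
WPI: TDC 3.78 vs FXS 0.15, t(18) = 7.59, p = 5.111e-07

word: model = mixedlm, n_obs = 160
  TDC marginal slope +0.0202 (SE 0.0074), t = 2.73, p = 0.007046
  FXS marginal slope +0.0034 (SE 0.0091), t = 0.37, p = 0.7112
```

Read: the control-like cohort shows strong word-rate entrainment that is
absent in the Fragile-X-like cohort (the group effect at the word bin),
while syllable-rate entrainment is equally strong in both groups — a
selective deficit in chunking syllables into words, not in auditory
tracking.  The word precision index separates the groups the same way, and
only the control-like group shows a positive learning slope across epochs.

The same machinery is available as a library call:

```python
import entrainkit as ek

cfg = ek.RunConfig(seed=1, out_dir="results/run", repetitions_per_word=50,
                   n_tdc=12, n_fxs=8, n_channels=4, sampling_rate=250.0)
bundle = ek.run_full_pipeline(cfg)
print(bundle["group_stats"]["zitc_word"]["anova"])
```

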