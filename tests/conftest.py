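import numpy as np
import pytest

import entrainkit as ek

# Reduced-scale study conditions used throughout the suite: 250 Hz sampling
# and a 180 s stream (200 words -> 20 nonoverlapping 9 s epochs) keep every
# tagged frequency on an exact FFT bin while staying fast.
FS = 250.0
N_CH = 4


@pytest.fixture(scope="session")
def lexicon():
    return ek.Lexicon()


@pytest.fixture(scope="session")
def stream_small(lexicon):
    """200-word stream: 20 word-locked epochs at the default every-10 design."""
    return ek.generate_stream(lexicon, repetitions_per_word=50, seed=3)


@pytest.fixture(scope="session")
def stream_full(lexicon):
    """Full-scale 800-word stream (2400 syllables, 12 minutes)."""
    return ek.generate_stream(lexicon, repetitions_per_word=200, seed=3)


@pytest.fixture(scope="session")
def preproc_config():
    return ek.PreprocConfig()


@pytest.fixture(scope="session")
def tdc_subject(stream_small, preproc_config):
    """One control-like synthetic subject, cleaned and epoched."""
    params = ek.tdc_preset(n_channels=N_CH, sampling_rate=FS, seed=42)
    rec = ek.synthesize(stream_small, params)
    cleaned, epochs = ek.preprocess(rec, stream_small, preproc_config,
                                    subject_id="tdc-42")
    return cleaned, epochs


@pytest.fixture(scope="session")
def noise_subject(stream_small, preproc_config):
    """A subject with no word-locked component (null at the word bin)."""
    params = ek.SynthParams(n_channels=N_CH, sampling_rate=FS,
                            word_amp=0.0, seed=7)
    rec = ek.synthesize(stream_small, params)
    cleaned, epochs = ek.preprocess(rec, stream_small, preproc_config,
                                    subject_id="null-7")
    return cleaned, epochs


def make_sinusoid_epochs(phases, freq_hz=10.0 / 9.0, fs=FS, duration=9.0,
                         amplitude=1.0):
    """Epochs of a single sinusoid with prescribed per-epoch phases.

    With 9 s epochs the word frequency 10/9 Hz sits exactly on bin 10, so
    these epochs give analytically known ITC values.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    amplitude = np.broadcast_to(np.asarray(amplitude, float), (len(phases),))
    data = np.stack(
        [a * np.cos(2 * np.pi * freq_hz * t + p)
         for p, a in zip(phases, amplitude)]
    )[:, None, :]
    return ek.EpochSet(
        data=data,
        onsets=np.arange(len(phases)) * duration,
        sampling_rate=fs,
        epoch_duration=duration,
        channel_labels=["E1"],
    )
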