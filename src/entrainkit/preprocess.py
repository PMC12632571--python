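"""Continuous EEG cleaning and word-locked epoching.

The fixed pipeline order is: notch + band-pass filtering, artifact
attenuation, common-average re-referencing, then extraction of
non-overlapping epochs time-locked to every k-th word onset.  With the
default 9.0 s epochs the tagged word and syllable frequencies fall exactly
on FFT bins (10 word cycles and 30 syllable cycles per epoch), which is
what makes rectangular-window ITC leak-free at those bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .stream import StreamSpec, word_onsets
from .synth import Recording

__all__ = [
    "PreprocConfig",
    "EpochSet",
    "filter_recording",
    "attenuate_artifacts",
    "rereference_average",
    "extract_epochs",
    "clean_recording",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocConfig:
    """Cleaning and epoching parameters.

    ``ab_threshold`` is the artifact-attenuation bound in microvolts:
    samples beyond it are compressed back toward the bound.  ``exclude_channels``
    mirrors the practice of dropping the outer ring of a dense electrode net
    before artifact correction; default empty for synthetic data.
    """

    notch_hz: float = 60.0
    bandpass: tuple[float, float] = (0.5, 20.0)
    ab_threshold: float = 50.0
    epoch_duration: float = 9.0
    every_k_words: int = 10
    filter_order: int = 4
    notch_quality: float = 30.0
    exclude_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        low, high = self.bandpass
        if not 0 < low < high:
            raise ValueError("bandpass must satisfy 0 < low < high")
        if self.ab_threshold <= 0:
            raise ValueError("ab_threshold must be positive")
        if self.epoch_duration <= 0:
            raise ValueError("epoch_duration must be positive")
        if self.every_k_words < 1:
            raise ValueError("every_k_words must be >= 1")


@dataclass
class EpochSet:
    """Epochs x channels x samples, aligned to selected word onsets."""

    data: np.ndarray
    onsets: np.ndarray  # seconds, strictly increasing
    sampling_rate: float
    epoch_duration: float
    channel_labels: list[str]
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.data.shape[0] != self.onsets.size:
            raise ValueError("one onset per epoch required")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def freqs(self) -> np.ndarray:
        """FFT bin frequencies (Hz); spacing = 1/epoch_duration."""
        return np.fft.rfftfreq(self.n_samples, 1.0 / self.sampling_rate)


def filter_recording(rec: Recording, config: PreprocConfig) -> Recording:
    """Zero-phase notch + Butterworth band-pass (forward-backward)."""
    nyq = rec.sampling_rate / 2.0
    low, high = config.bandpass
    if high >= nyq or config.notch_hz >= nyq:
        raise ValueError(
            f"filter edges ({high} Hz band-pass, {config.notch_hz} Hz notch) "
            f"must lie below Nyquist ({nyq} Hz)"
        )
    b_notch, a_notch = signal.iirnotch(
        config.notch_hz, config.notch_quality, fs=rec.sampling_rate
    )
    sos = signal.butter(
        config.filter_order, [low, high], btype="bandpass",
        fs=rec.sampling_rate, output="sos",
    )
    data = signal.filtfilt(b_notch, a_notch, rec.data, axis=-1)
    data = signal.sosfiltfilt(sos, data, axis=-1)
    out = rec.copy()
    out.data = data
    return out


def attenuate_artifacts(
    rec: Recording, threshold: float = 50.0, knee: float = 5.0
) -> Recording:
    """Bound amplitudes to ~±threshold with a smooth soft limiter.

    Samples within ±threshold pass through unchanged; the excess beyond the
    threshold is compressed through a tanh with a ``knee``-microvolt scale,
    so output never exceeds ±(threshold + knee) and the transfer curve is
    continuously differentiable (no introduced discontinuities).  This is a
    deliberately simple stand-in for dedicated artifact-correction
    algorithms: it guarantees bounded output and leaves clean data untouched,
    which is the contract the downstream spectral analysis relies on.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = rec.data
    excess = np.abs(x) - threshold
    over = excess > 0
    y = x.copy()
    y[over] = np.sign(x[over]) * (threshold + knee * np.tanh(excess[over] / knee))
    out = rec.copy()
    out.data = y
    return out


def rereference_average(rec: Recording) -> Recording:
    """Re-reference to the common average: per-sample channel mean becomes 0."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires >= 2 channels")
    out = rec.copy()
    out.data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return out


def extract_epochs(
    rec: Recording,
    stream: StreamSpec,
    config: PreprocConfig,
    subject_id: str | None = None,
) -> EpochSet:
    """Cut epochs at every k-th word onset whose full window fits.

    Windows are half-open [onset, onset + duration); onsets are snapped to
    the nearest sample (alignment error <= half a sample).  Onsets whose
    window would run past the end of the recording are dropped.
    """
    fs = rec.sampling_rate
    n_samp = int(round(config.epoch_duration * fs))
    onsets = word_onsets(stream, config.every_k_words)
    rel = onsets - rec.start_time
    starts = np.round(rel * fs).astype(int)
    keep = (starts >= 0) & (starts + n_samp <= rec.n_samples)
    starts, onsets = starts[keep], onsets[keep]
    if starts.size == 0:
        raise ValueError("no epoch window fits inside the recording")
    idx = starts[:, None] + np.arange(n_samp)[None, :]
    data = rec.data[:, idx]  # channels x epochs x samples
    return EpochSet(
        data=np.ascontiguousarray(np.swapaxes(data, 0, 1)),
        onsets=onsets,
        sampling_rate=fs,
        epoch_duration=config.epoch_duration,
        channel_labels=list(rec.channel_labels),
        subject_id=subject_id,
    )


def clean_recording(rec: Recording, config: PreprocConfig) -> Recording:
    """Filtering, artifact attenuation and average reference, in that order."""
    if config.exclude_channels:
        keep = [i for i, ch in enumerate(rec.channel_labels)
                if ch not in config.exclude_channels]
        rec = Recording(
            data=rec.data[keep],
            sampling_rate=rec.sampling_rate,
            channel_labels=[rec.channel_labels[i] for i in keep],
            start_time=rec.start_time,
        )
    rec = filter_recording(rec, config)
    rec = attenuate_artifacts(rec, config.ab_threshold)
    rec = rereference_average(rec)
    return rec


def preprocess(
    rec: Recording,
    stream: StreamSpec,
    config: PreprocConfig | None = None,
    subject_id: str | None = None,
) -> tuple[Recording, EpochSet]:
    """Full cleaning pipeline; returns the cleaned continuous recording
    (needed for surrogate re-epoching) and the word-locked epochs."""
    config = config or PreprocConfig()
    cleaned = clean_recording(rec, config)
    epochs = extract_epochs(cleaned, stream, config, subject_id=subject_id)
    return cleaned, epochs
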