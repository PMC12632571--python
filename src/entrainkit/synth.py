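"""Synthetic multichannel EEG with known ground-truth entrainment.

The generator emulates the features of a frequency-tagged statistical
learning recording that the downstream pipeline is sensitive to: pink
(1/f^alpha) background noise, a deterministic syllable-locked response at
the syllable rate, a word-locked component at the word rate whose
trial-to-trial phase consistency is an explicit parameter (optionally
ramping up over exposure, emulating learning), and occasional high-amplitude
smooth artifact transients.  Nothing biophysical is modeled: channel
structure reduces to a fixed zero-mean topography plus a scalar
shared-noise fraction standing in for volume-conduction correlation.  The
point is a ground truth against which ITC, surrogate z-scoring and the
pseudovalue time-course can be validated end to end.

Phase locking is implemented by mixing, within each word window, a
deterministic word-locked one-cycle sinusoid with an independently
phase-jittered copy in proportion ``word_phase_lock``: at 1 the word
response is identical in every epoch (ITC -> 1), at 0 its phase is uniform
across words (ITC -> chance level).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .stream import StreamSpec

__all__ = [
    "SynthParams",
    "Recording",
    "SubjectRecording",
    "synthesize",
    "make_cohort",
    "tdc_preset",
    "fxs_preset",
    "write_recording",
    "read_recording",
]


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters, amplitudes in microvolts.

    ``learning_ramp`` linearly scales ``word_phase_lock`` from
    ``ramp[0] * word_phase_lock`` at stream onset to ``ramp[1] *
    word_phase_lock`` at stream offset, emulating the growth of word-level
    entrainment over exposure.

    ``noise_shared_frac`` is the fraction of background-noise power common
    to all channels.  Volume conduction makes scalp channels strongly
    correlated, which is why a subject's channel-averaged zITC keeps
    roughly unit spread under the null; with fully independent channel
    noise that spread would shrink as 1/sqrt(n_channels).
    """

    n_channels: int = 128
    sampling_rate: float = 1000.0
    noise_exponent: float = 1.0
    noise_scale: float = 10.0
    syllable_amp: float = 2.0
    word_amp: float = 1.5
    noise_shared_frac: float = 0.8
    word_phase_lock: float = 0.5
    learning_ramp: tuple[float, float] = (1.0, 1.0)
    artifact_rate: float = 0.0  # events per minute
    artifact_amp: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_scale", "syllable_amp", "word_amp", "artifact_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.word_phase_lock <= 1.0:
            raise ValueError("word_phase_lock must be in [0, 1]")
        if not 0.0 <= self.noise_shared_frac <= 1.0:
            raise ValueError("noise_shared_frac must be in [0, 1]")
        if not all(0.0 <= r <= 1.0 for r in self.learning_ramp):
            raise ValueError("learning_ramp fractions must be in [0, 1]")
        if self.sampling_rate < 250.0:
            raise ValueError("sampling_rate must be >= 250 Hz")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")


@dataclass
class Recording:
    """Continuous multichannel EEG, channels x samples, in microvolts."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            sampling_rate=self.sampling_rate,
            channel_labels=list(self.channel_labels),
            start_time=self.start_time,
        )


@dataclass(frozen=True)
class SubjectRecording:
    subject_id: str
    group: str  # "TDC" | "FXS"
    recording: Recording
    stream: StreamSpec
    params: SynthParams


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                exponent: float, scale: float, fs: float) -> np.ndarray:
    """1/f^alpha noise, RMS-normalized to ``scale`` microvolts per channel."""
    if scale == 0:
        return np.zeros((n_ch, n_samp))
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samp, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    noise = np.fft.irfft(spec * shaping, n=n_samp, axis=-1)
    rms = np.sqrt(np.mean(noise**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return noise / rms * scale


def _word_component(stream: StreamSpec, t: np.ndarray, params: SynthParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Word-rate component: one cycle of a word-rate sinusoid per word window,
    phase-locked in proportion to the (possibly ramping) lock fraction."""
    out = np.zeros_like(t)
    if params.word_amp == 0:
        return out
    fs = params.sampling_rate
    w_rate = stream.word_rate
    word_dur = stream.word_duration
    onsets = stream.all_word_onsets()
    duration = stream.duration
    r0, r1 = params.learning_ramp
    n_win = int(round(word_dur * fs))
    for onset in onsets:
        i0 = int(round(onset * fs))
        i1 = min(i0 + n_win, t.size)
        if i1 <= i0:
            continue
        tt = t[i0:i1] - onset
        frac = onset / duration if duration > 0 else 0.0
        p = params.word_phase_lock * (r0 + (r1 - r0) * frac)
        locked = np.sin(2 * np.pi * w_rate * tt)
        phi = rng.uniform(0, 2 * np.pi)
        jittered = np.sin(2 * np.pi * w_rate * tt + phi)
        out[i0:i1] = params.word_amp * (p * locked + (1 - p) * jittered)
    return out


def _artifacts(rng: np.random.Generator, n_ch: int, n_samp: int, fs: float,
               rate_per_min: float, amp: float) -> np.ndarray:
    """Smooth biphasic transients (Gaussian first derivative, ~400 ms)."""
    out = np.zeros((n_ch, n_samp))
    if rate_per_min <= 0 or amp == 0:
        return out
    duration_min = n_samp / fs / 60.0
    n_events = rng.poisson(rate_per_min * duration_min)
    half = int(round(0.2 * fs))
    tau = 0.06 * fs
    k = np.arange(-half, half + 1, dtype=float)
    shape = -k / tau * np.exp(0.5 - (k / tau) ** 2 / 2.0)
    shape /= np.max(np.abs(shape))
    for _ in range(n_events):
        ch = int(rng.integers(n_ch))
        center = int(rng.integers(half, max(half + 1, n_samp - half)))
        lo, hi = center - half, center + half + 1
        seg = slice(max(lo, 0), min(hi, n_samp))
        out[ch, seg] += amp * shape[seg.start - lo: seg.stop - lo]
    return out


def synthesize(stream: StreamSpec, params: SynthParams) -> Recording:
    """Render a continuous recording for one subject; deterministic per seed."""
    if stream.duration <= 0:
        raise ValueError("stream duration must be positive")
    fs = params.sampling_rate
    n_samp = int(round(stream.duration * fs))
    t = np.arange(n_samp) / fs
    rng = np.random.default_rng(params.seed)

    # Background noise: a channel-shared 1/f process (volume-conduction-like
    # correlation, carried on the same zero-mean topography as the evoked
    # components so it survives average referencing) plus independent 1/f
    # noise per channel, mixed so total power stays at noise_scale^2.
    gain = np.where(np.arange(params.n_channels) % 2 == 0, 1.0, -1.0)
    shared = _pink_noise(rng, 1, n_samp, params.noise_exponent,
                         params.noise_scale, fs)
    indep = _pink_noise(rng, params.n_channels, n_samp,
                        params.noise_exponent, params.noise_scale, fs)
    c = params.noise_shared_frac
    noise = np.sqrt(c) * gain[:, None] * shared + np.sqrt(1 - c) * indep
    # Deterministic syllable-locked response: the stream is isochronous from
    # t=0, so a global sinusoid at the syllable rate is locked to every onset.
    syllable = params.syllable_amp * np.sin(2 * np.pi * stream.syllable_rate * t)
    word = _word_component(stream, t, params, rng)
    artifacts = _artifacts(rng, params.n_channels, n_samp, fs,
                           params.artifact_rate, params.artifact_amp)

    # The same alternating-polarity topography carries the evoked components:
    # per-channel polarity leaves ITC untouched (phase statistic), but a
    # zero-mean topography is required for the signal to survive
    # common-average re-referencing, as dipolar scalp fields do.
    data = noise + gain[:, None] * (syllable + word)[None, :] + artifacts
    labels = [f"E{i + 1}" for i in range(params.n_channels)]
    return Recording(data=data, sampling_rate=fs, channel_labels=labels)


def tdc_preset(**overrides) -> SynthParams:
    """Control-like preset: substantial word-rate phase locking that grows
    over exposure (learning ramp)."""
    base = SynthParams(
        word_phase_lock=0.8,
        learning_ramp=(0.45, 1.0),
        syllable_amp=2.0,
        word_amp=1.5,
        noise_scale=10.0,
        artifact_rate=2.0,
    )
    return replace(base, **overrides)


def fxs_preset(**overrides) -> SynthParams:
    """Fragile-X-like preset: strongly reduced word-rate phase locking with a
    flat learning ramp; syllable response equal to the control preset."""
    base = SynthParams(
        word_phase_lock=0.12,
        learning_ramp=(1.0, 1.0),
        syllable_amp=2.0,
        word_amp=1.5,
        noise_scale=10.0,
        artifact_rate=2.0,
    )
    return replace(base, **overrides)


def make_cohort(
    n_tdc: int,
    n_fxs: int,
    stream: StreamSpec,
    tdc_params: SynthParams | None = None,
    fxs_params: SynthParams | None = None,
    seed: int = 0,
) -> list[SubjectRecording]:
    """Simulate a two-group cohort sharing one predefined stimulus stream.

    Per-subject seeds are drawn from a generator seeded with the master seed,
    so any subject can be regenerated in isolation from the master seed and
    its index.
    """
    if n_tdc < 0 or n_fxs < 0:
        raise ValueError("cohort counts must be non-negative")
    tdc_params = tdc_params if tdc_params is not None else tdc_preset()
    fxs_params = fxs_params if fxs_params is not None else fxs_preset()
    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_tdc + n_fxs)
    cohort: list[SubjectRecording] = []
    for i in range(n_tdc + n_fxs):
        group = "TDC" if i < n_tdc else "FXS"
        base = tdc_params if group == "TDC" else fxs_params
        params = replace(base, seed=int(subject_seeds[i]))
        rec = synthesize(stream, params)
        cohort.append(
            SubjectRecording(
                subject_id=f"sub-{i + 1:02d}",
                group=group,
                recording=rec,
                stream=stream,
                params=params,
            )
        )
    return cohort


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording to a FIF file (microvolts stored as volts)."""
    import mne

    path = Path(path)
    info = mne.create_info(
        ch_names=list(rec.channel_labels),
        sfreq=rec.sampling_rate,
        ch_types="eeg",
    )
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    raw.save(path, overwrite=True, verbose="error")
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a FIF recording written by :func:`write_recording`."""
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise ValueError(f"cannot parse recording file {path}: {exc}") from exc
    return Recording(
        data=raw.get_data() * 1e6,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        start_time=0.0,
    )
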