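"""Inter-trial phase coherence, surrogate nulls, zITC and the word precision index.

ITC at a frequency bin is the magnitude of the mean, across epochs, of the
unit-normalized complex FFT coefficient at that bin: 0 for uniformly random
phase, 1 for perfect phase locking.  Because raw ITC has a positive,
N-dependent chance level (E[ITC] ~ sqrt(pi)/(2 sqrt(N)) for uniform phases),
observed values are standardized per channel and bin against a
subject-specific null built by re-extracting epochs at onsets jittered
uniformly within ±jitter seconds — this destroys stimulus alignment while
preserving the signal's spectral content and the epochs' coarse timing.

The word precision index (WPI) quantifies the spectral selectivity of
word-rate locking:  WPI = z_word − (z_{word−2} + z_{word−1} + z_{word+1} +
z_{word+2}) / 4, computed after averaging zITC over a channel selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EpochSet, PreprocConfig
from .stream import StreamSpec
from .synth import Recording

__all__ = [
    "ItcSpectrum",
    "SurrogateNull",
    "ZitcSpectrum",
    "WpiResult",
    "unit_phasors",
    "itc_from_phasors",
    "compute_itc",
    "surrogate_null",
    "z_itc",
    "identify_bin",
    "word_precision_index",
    "scalp_average",
]


@dataclass(frozen=True)
class ItcSpectrum:
    """Per-channel ITC over FFT bins; values in [0, 1]."""

    values: np.ndarray  # channels x bins
    freqs: np.ndarray  # Hz
    n_epochs: int


@dataclass(frozen=True)
class SurrogateNull:
    """Null ITC distribution summary from onset-jittered surrogates."""

    mean: np.ndarray  # channels x bins
    sd: np.ndarray  # channels x bins, sample sd (ddof=1)
    freqs: np.ndarray
    n_surrogates: int
    jitter: float  # seconds (half-range of the uniform jitter)
    seed: int


@dataclass(frozen=True)
class ZitcSpectrum:
    """z-scored ITC with the tagged word/syllable bins identified.

    Bins where the surrogate sd collapsed to zero carry NaN and are listed
    in ``degenerate_bins`` rather than silently becoming infinite.
    """

    values: np.ndarray  # channels x bins
    freqs: np.ndarray
    word_bin: int
    syllable_bin: int
    channel_labels: list[str]
    degenerate_bins: tuple[int, ...] = ()


@dataclass(frozen=True)
class WpiResult:
    wpi: float
    word_bin: int
    neighbor_bins: tuple[int, int, int, int]


def unit_phasors(epochs: EpochSet) -> np.ndarray:
    """Unit-magnitude FFT coefficients, epochs x channels x bins.

    Rectangular window, no padding.  Bins with exactly zero amplitude have
    undefined phase and contribute a zero phasor.
    """
    spec = np.fft.rfft(epochs.data, axis=-1)
    mag = np.abs(spec)
    with np.errstate(invalid="ignore", divide="ignore"):
        phasors = np.where(mag > 0, spec / np.where(mag > 0, mag, 1.0), 0.0)
    return phasors


def itc_from_phasors(phasors: np.ndarray, axis: int = 0) -> np.ndarray:
    """|mean unit phasor| along ``axis`` — the ITC statistic itself."""
    return np.abs(np.mean(phasors, axis=axis))


def compute_itc(epochs: EpochSet) -> ItcSpectrum:
    """ITC per channel and frequency bin across all epochs."""
    if epochs.n_epochs < 2:
        raise ValueError("ITC requires at least 2 epochs")
    values = itc_from_phasors(unit_phasors(epochs), axis=0)
    return ItcSpectrum(values=values, freqs=epochs.freqs, n_epochs=epochs.n_epochs)


def _jittered_onsets(
    onsets: np.ndarray,
    rec: Recording,
    n_samp: int,
    jitter: float,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> np.ndarray:
    """Each onset independently shifted by U(−jitter, +jitter); redraws any
    jitter that pushes the epoch window outside the recording."""
    fs = rec.sampling_rate
    out = np.empty_like(onsets)
    for i, onset in enumerate(onsets):
        for _ in range(max_retries):
            shifted = onset + rng.uniform(-jitter, jitter)
            start = int(round((shifted - rec.start_time) * fs))
            if start >= 0 and start + n_samp <= rec.n_samples:
                out[i] = shifted
                break
        else:
            raise ValueError(
                f"no jittered window fits for onset {onset:.3f}s "
                f"after {max_retries} redraws"
            )
    return out


def surrogate_null(
    rec: Recording,
    onsets: np.ndarray,
    config: PreprocConfig | None = None,
    n_surrogates: int = 100,
    jitter: float = 0.9,
    seed: int = 0,
) -> SurrogateNull:
    """Null ITC distribution from epochs re-extracted at jittered onsets.

    The recording should already be cleaned; surrogates re-cut epochs from
    the continuous data so that each surrogate preserves everything about
    the signal except its alignment to the stimulus stream.
    """
    config = config or PreprocConfig()
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates for a null sd")
    fs = rec.sampling_rate
    n_samp = int(round(config.epoch_duration * fs))
    onsets = np.asarray(onsets, dtype=float)
    rng = np.random.default_rng(seed)
    window = np.arange(n_samp)

    itcs = np.empty((n_surrogates, rec.n_channels, n_samp // 2 + 1))
    for s in range(n_surrogates):
        jit = _jittered_onsets(onsets, rec, n_samp, jitter, rng)
        starts = np.round((jit - rec.start_time) * fs).astype(int)
        data = rec.data[:, starts[:, None] + window[None, :]]
        eps = EpochSet(
            data=np.ascontiguousarray(np.swapaxes(data, 0, 1)),
            onsets=np.sort(jit),
            sampling_rate=fs,
            epoch_duration=config.epoch_duration,
            channel_labels=list(rec.channel_labels),
        )
        itcs[s] = itc_from_phasors(unit_phasors(eps), axis=0)

    freqs = np.fft.rfftfreq(n_samp, 1.0 / fs)
    return SurrogateNull(
        mean=itcs.mean(axis=0),
        sd=itcs.std(axis=0, ddof=1),
        freqs=freqs,
        n_surrogates=n_surrogates,
        jitter=jitter,
        seed=seed,
    )


def identify_bin(freqs: np.ndarray, target_hz: float) -> int:
    """Nearest FFT bin to a nominal frequency; errors if off by > half a bin.

    With 9.0 s epochs the spacing is 1/9 Hz and the tagged frequencies
    (10/9 and 30/9 Hz) fall exactly on bins 10 and 30.
    """
    idx = int(np.argmin(np.abs(freqs - target_hz)))
    spacing = freqs[1] - freqs[0] if freqs.size > 1 else np.inf
    if abs(freqs[idx] - target_hz) > spacing / 2 + 1e-9:
        raise ValueError(f"no FFT bin within half a bin of {target_hz} Hz")
    return idx


def z_itc(
    observed: ItcSpectrum,
    null: SurrogateNull,
    stream: StreamSpec,
    channel_labels: list[str] | None = None,
) -> ZitcSpectrum:
    """Standardize observed ITC against the surrogate null, per channel/bin."""
    if observed.values.shape != null.mean.shape:
        raise ValueError("observed and null shapes differ")
    degenerate = null.sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(degenerate, np.nan,
                     (observed.values - null.mean) / np.where(degenerate, 1.0, null.sd))
    word_bin = identify_bin(observed.freqs, stream.word_rate)
    syllable_bin = identify_bin(observed.freqs, stream.syllable_rate)
    degenerate_bins = tuple(np.nonzero(degenerate.any(axis=0))[0].tolist())
    n_ch = observed.values.shape[0]
    labels = channel_labels if channel_labels is not None else [
        f"E{i + 1}" for i in range(n_ch)
    ]
    return ZitcSpectrum(
        values=z,
        freqs=observed.freqs,
        word_bin=word_bin,
        syllable_bin=syllable_bin,
        channel_labels=list(labels),
        degenerate_bins=degenerate_bins,
    )


def _channel_indices(z: ZitcSpectrum, channels) -> np.ndarray:
    if channels is None:
        return np.arange(len(z.channel_labels))
    idx = []
    for ch in channels:
        if isinstance(ch, str):
            idx.append(z.channel_labels.index(ch))
        else:
            idx.append(int(ch))
    if not idx:
        raise ValueError("empty channel selection")
    return np.asarray(idx)


def word_precision_index(z: ZitcSpectrum, channels=None) -> WpiResult:
    """WPI: word-bin z minus the mean of the four flanking bins."""
    wb = z.word_bin
    n_bins = z.values.shape[1]
    if wb < 2 or wb + 2 >= n_bins:
        raise ValueError("word bin too close to the spectrum edge for WPI")
    idx = _channel_indices(z, channels)
    mean_z = z.values[idx].mean(axis=0)
    neighbors = (wb - 2, wb - 1, wb + 1, wb + 2)
    wpi = float(mean_z[wb] - np.mean([mean_z[b] for b in neighbors]))
    return WpiResult(wpi=wpi, word_bin=wb, neighbor_bins=neighbors)


def scalp_average(z: ZitcSpectrum, bin_index: int, channels=None) -> float:
    """Mean zITC across a channel selection at one frequency bin."""
    idx = _channel_indices(z, channels)
    return float(z.values[idx, bin_index].mean())
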