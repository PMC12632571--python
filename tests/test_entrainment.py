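"""ITC, surrogate nulls, zITC and WPI against analytic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import entrainkit as ek
from entrainkit.entrainment import (
    identify_bin,
    itc_from_phasors,
    surrogate_null,
    unit_phasors,
    word_precision_index,
    z_itc,
)
from conftest import FS, make_sinusoid_epochs

WORD_HZ = 10.0 / 9.0


def _word_bin(epochs):
    return identify_bin(epochs.freqs, WORD_HZ)


class TestItc:
    def test_identical_epochs_perfect_locking(self):
        eps = make_sinusoid_epochs([0.3] * 8)
        itc = ek.compute_itc(eps)
        assert itc.values[0, _word_bin(eps)] == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_phases_cancel(self):
        eps = make_sinusoid_epochs([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        itc = ek.compute_itc(eps)
        assert itc.values[0, _word_bin(eps)] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("phi", [0.0, np.pi / 3, np.pi / 2, np.pi])
    def test_two_epoch_closed_form(self, phi):
        """ITC of two epochs with phase difference phi is |cos(phi/2)|."""
        eps = make_sinusoid_epochs([0.0, phi])
        itc = ek.compute_itc(eps)
        # independent oracle: direct complex arithmetic
        oracle = np.abs((np.exp(0j) + np.exp(1j * phi)) / 2)
        assert itc.values[0, _word_bin(eps)] == pytest.approx(oracle, abs=1e-9)
        assert oracle == pytest.approx(np.abs(np.cos(phi / 2)), abs=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 100))
    def test_amplitude_invariance(self, scale, seed):
        """Scaling any epoch by a positive factor leaves ITC unchanged."""
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(5, 2, 180))  # broadband: every bin has power
        eps = ek.EpochSet(data=data, onsets=np.arange(5) * 0.9,
                          sampling_rate=200.0, epoch_duration=0.9,
                          channel_labels=["E1", "E2"])
        base = ek.compute_itc(eps).values
        scaled_data = data.copy()
        scaled_data[seed % 5] *= scale
        eps2 = ek.EpochSet(data=scaled_data, onsets=np.arange(5) * 0.9,
                           sampling_rate=200.0, epoch_duration=0.9,
                           channel_labels=["E1", "E2"])
        assert np.allclose(ek.compute_itc(eps2).values, base, atol=1e-9)

    def test_uniform_phase_expectation(self):
        """E[ITC] ~ sqrt(pi)/(2 sqrt(N)) for uniform phases (N=78)."""
        rng = np.random.default_rng(0)
        n, draws = 78, 2000
        phasors = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(draws, n)))
        itcs = itc_from_phasors(phasors, axis=1)
        expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
        sem = itcs.std(ddof=1) / np.sqrt(draws)
        assert abs(itcs.mean() - expected) < 3 * sem

    def test_requires_two_epochs(self):
        eps = make_sinusoid_epochs([0.0])
        with pytest.raises(ValueError):
            ek.compute_itc(eps)


class TestSurrogates:
    def test_zero_jitter_degenerate(self, noise_subject):
        cleaned, epochs = noise_subject
        null = surrogate_null(cleaned, epochs.onsets, ek.PreprocConfig(),
                              n_surrogates=5, jitter=0.0, seed=0)
        observed = ek.compute_itc(epochs)
        assert np.allclose(null.mean, observed.values, atol=1e-12)
        assert np.allclose(null.sd, 0.0)

    def test_null_covers_noise_recording(self, noise_subject):
        """Observed ITC of a non-entrained recording falls inside the null."""
        cleaned, epochs = noise_subject
        observed = ek.compute_itc(epochs)
        null = surrogate_null(cleaned, epochs.onsets, ek.PreprocConfig(),
                              n_surrogates=100, jitter=0.9, seed=1)
        inside = np.abs(observed.values - null.mean) <= 3 * null.sd
        # ignore band edges the 0.5-20 Hz filter empties
        band = (observed.freqs >= 0.6) & (observed.freqs <= 19.0)
        assert inside[:, band].mean() >= 0.99

    def test_word_locked_recording_exceeds_null(self, stream_small):
        p = ek.SynthParams(n_channels=2, sampling_rate=FS, word_amp=3.0,
                           word_phase_lock=1.0, seed=11)
        rec = ek.synthesize(stream_small, p)
        cleaned, epochs = ek.preprocess(rec, stream_small, ek.PreprocConfig())
        observed = ek.compute_itc(epochs)
        null = surrogate_null(cleaned, epochs.onsets, ek.PreprocConfig(),
                              n_surrogates=100, jitter=0.9, seed=2)
        b = identify_bin(observed.freqs, WORD_HZ)
        assert np.all(observed.values[:, b] > null.mean[:, b] + 3 * null.sd[:, b])

    def test_deterministic_given_seed(self, noise_subject):
        cleaned, epochs = noise_subject
        kwargs = dict(n_surrogates=10, jitter=0.9)
        a = surrogate_null(cleaned, epochs.onsets, ek.PreprocConfig(),
                           seed=3, **kwargs)
        b = surrogate_null(cleaned, epochs.onsets, ek.PreprocConfig(),
                           seed=3, **kwargs)
        assert np.array_equal(a.mean, b.mean) and np.array_equal(a.sd, b.sd)


class TestZitc:
    def test_observed_equal_to_null_mean(self, noise_subject, stream_small):
        cleaned, epochs = noise_subject
        null = surrogate_null(cleaned, epochs.onsets, ek.PreprocConfig(),
                              n_surrogates=20, jitter=0.9, seed=4)
        fake = ek.ItcSpectrum(values=null.mean.copy(), freqs=null.freqs,
                              n_epochs=epochs.n_epochs)
        z = z_itc(fake, null, stream_small)
        finite = ~np.isnan(z.values)
        assert np.allclose(z.values[finite], 0.0, atol=1e-12)

    def test_two_sigma_above_mean(self, noise_subject, stream_small):
        cleaned, epochs = noise_subject
        null = surrogate_null(cleaned, epochs.onsets, ek.PreprocConfig(),
                              n_surrogates=20, jitter=0.9, seed=4)
        vals = null.mean.copy()
        b = identify_bin(null.freqs, WORD_HZ)
        vals[:, b] += 2 * null.sd[:, b]
        fake = ek.ItcSpectrum(values=vals, freqs=null.freqs,
                              n_epochs=epochs.n_epochs)
        z = z_itc(fake, null, stream_small)
        assert np.allclose(z.values[:, b], 2.0, atol=1e-9)

    def test_degenerate_sd_flagged_not_infinite(self, noise_subject,
                                                stream_small):
        cleaned, epochs = noise_subject
        null = surrogate_null(cleaned, epochs.onsets, ek.PreprocConfig(),
                              n_surrogates=5, jitter=0.0, seed=0)
        z = z_itc(ek.compute_itc(epochs), null, stream_small)
        assert not np.any(np.isinf(z.values))
        assert z.word_bin in z.degenerate_bins

    def test_tagged_bin_indices_at_nine_seconds(self, tdc_subject,
                                                stream_small):
        cleaned, epochs = tdc_subject
        null = surrogate_null(cleaned, epochs.onsets, ek.PreprocConfig(),
                              n_surrogates=2, jitter=0.9, seed=0)
        z = z_itc(ek.compute_itc(epochs), null, stream_small)
        assert z.word_bin == 10 and z.syllable_bin == 30
        assert z.freqs[1] - z.freqs[0] == pytest.approx(1.0 / 9.0)

    def test_frequency_beyond_axis_rejected(self):
        freqs = np.arange(0, 5, 0.5)
        with pytest.raises(ValueError):
            identify_bin(freqs, 6.0)


def _flat_z(values_by_bin, n_ch=2, n_bins=46, word_bin=10):
    vals = np.zeros((n_ch, n_bins))
    for b, v in values_by_bin.items():
        vals[:, b] = v
    freqs = np.arange(n_bins) / 9.0
    return ek.ZitcSpectrum(values=vals, freqs=freqs, word_bin=word_bin,
                           syllable_bin=30,
                           channel_labels=[f"E{i+1}" for i in range(n_ch)])


class TestWpi:
    def test_flat_spectrum_zero(self):
        z = _flat_z({b: 1.7 for b in range(8, 13)})
        assert word_precision_index(z).wpi == pytest.approx(0.0, abs=1e-12)

    def test_isolated_peak(self):
        z = _flat_z({10: 2.0})
        assert word_precision_index(z).wpi == pytest.approx(2.0)

    def test_peak_over_uniform_neighbors(self):
        z = _flat_z({10: 3.0, 8: 1.0, 9: 1.0, 11: 1.0, 12: 1.0})
        assert word_precision_index(z).wpi == pytest.approx(2.0)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(3, 46))
        freqs = np.arange(46) / 9.0
        z1 = ek.ZitcSpectrum(values=vals, freqs=freqs, word_bin=10,
                             syllable_bin=30, channel_labels=list("abc"))
        z2 = ek.ZitcSpectrum(values=vals + 5.0, freqs=freqs, word_bin=10,
                             syllable_bin=30, channel_labels=list("abc"))
        assert word_precision_index(z1).wpi == pytest.approx(
            word_precision_index(z2).wpi, abs=1e-9
        )

    def test_edge_word_bin_rejected(self):
        z = _flat_z({}, word_bin=1)
        with pytest.raises(ValueError):
            word_precision_index(z)


class TestScalpAverage:
    def test_identical_channels(self):
        z = _flat_z({10: 1.5}, n_ch=4)
        assert ek.scalp_average(z, 10) == pytest.approx(1.5)

    def test_two_channel_mean(self):
        z = _flat_z({}, n_ch=2)
        z.values[0, 10], z.values[1, 10] = 1.0, 3.0
        assert ek.scalp_average(z, 10) == pytest.approx(2.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(8, 46))
        freqs = np.arange(46) / 9.0
        z = ek.ZitcSpectrum(values=vals, freqs=freqs, word_bin=10,
                            syllable_bin=30,
                            channel_labels=[f"E{i}" for i in range(8)])
        assert ek.scalp_average(z, 17) == pytest.approx(
            sum(vals[c, 17] for c in range(8)) / 8
        )

    def test_empty_selection_rejected(self):
        z = _flat_z({})
        with pytest.raises(ValueError):
            ek.scalp_average(z, 10, channels=[])


def test_zitc_monotone_in_phase_lock(stream_small):
    """zITC at the word bin increases with the generator's phase-lock level."""
    cfg = ek.PreprocConfig()
    means = []
    for lock in (0.0, 0.4, 0.8):
        zs = []
        for seed in range(4):
            p = ek.SynthParams(n_channels=2, sampling_rate=FS,
                               word_phase_lock=lock, seed=10 + seed)
            rec = ek.synthesize(stream_small, p)
            cleaned, epochs = ek.preprocess(rec, stream_small, cfg)
            null = surrogate_null(cleaned, epochs.onsets, cfg,
                                  n_surrogates=40, jitter=0.9, seed=seed)
            z = z_itc(ek.compute_itc(epochs), null, stream_small)
            zs.append(ek.scalp_average(z, z.word_bin))
        means.append(np.mean(zs))
    assert means[0] < means[1] < means[2]
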