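"""Morse wavelet transform, z-scoring, and individual-band selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thetanav import spectral
from thetanav.exceptions import BandNotFoundError, DegenerateInputError
from thetanav.spectral import (BandDefinition, band_amplitude_series,
                               band_average, find_individual_band,
                               morse_frequency_grid, morse_tf_amplitude,
                               zscore_amplitude)

FS = 250.0


def _tone(freq, dur=10.0, amp=1.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestMorseTransform:
    def test_frequency_grid_ten_voices_1_to_90(self):
        f = morse_frequency_grid()
        assert f[0] == 1.0 and f[-1] <= 90.0
        np.testing.assert_allclose(np.diff(np.log2(f)), 0.1, atol=1e-12)

    def test_pure_tone_peaks_at_nearest_bin(self):
        tf = morse_tf_amplitude(_tone(8.0), FS)
        mid = slice(tf.amp.shape[2] // 4, 3 * tf.amp.shape[2] // 4)
        peak_bins = tf.amp[0, :, mid].argmax(axis=0)
        expected = np.argmin(np.abs(tf.freqs - 8.0))
        assert np.all(peak_bins == expected)
        # amplitude at the peak bin approximates the tone amplitude
        assert abs(np.median(tf.amp[0, expected, mid]) - 1.0) < 0.05

    def test_zero_signal_gives_zero_amplitude(self):
        tf = morse_tf_amplitude(np.zeros(1000), FS)
        assert np.allclose(tf.amp, 0.0)

    def test_two_tones_give_two_local_maxima(self):
        tf = morse_tf_amplitude(_tone(4.0) + _tone(16.0), FS)
        spec = tf.amp[0, :, tf.amp.shape[2] // 2]
        interior = np.arange(1, len(spec) - 1)
        maxima = interior[(spec[interior] > spec[interior - 1])
                          & (spec[interior] > spec[interior + 1])]
        peak_freqs = sorted(tf.freqs[m] for m in maxima
                            if spec[m] > 0.1 * spec.max())
        assert len(peak_freqs) == 2
        assert abs(peak_freqs[0] - 4.0) < 0.5
        assert abs(peak_freqs[1] - 16.0) < 1.5

    def test_nan_rejected(self):
        x = np.ones(500)
        x[3] = np.nan
        with pytest.raises(ValueError):
            morse_tf_amplitude(x, FS)

    def test_energy_monotone_in_amplitude(self):
        e = [morse_tf_amplitude(_tone(6.0, amp=a), FS).amp.sum()
             for a in (0.5, 1.0, 2.0)]
        assert e[0] < e[1] < e[2]

    def test_peak_frequency_agrees_with_pywavelets(self):
        """Independent CWT (complex Morlet) locates the same spectral peak."""
        pywt = pytest.importorskip("pywt")
        sig = _tone(7.0)
        tf = morse_tf_amplitude(sig, FS)
        own_peak = tf.freqs[tf.amp[0, :, tf.amp.shape[2] // 2].argmax()]
        freqs = tf.freqs
        scales = pywt.frequency2scale("cmor1.5-1.0", freqs / FS)
        coef, _ = pywt.cwt(sig, scales, "cmor1.5-1.0", sampling_period=1 / FS)
        ref_peak = freqs[np.abs(coef[:, len(sig) // 2]).argmax()]
        assert abs(np.log2(own_peak) - np.log2(ref_peak)) <= 0.11


class TestZscore:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        tf = morse_tf_amplitude(rng.standard_normal((2, int(20 * FS))), FS,
                                freqs=np.array([4.0, 8.0]))
        z = zscore_amplitude(tf)
        edge = int(2 * FS)
        core = z.amp[..., edge:-edge]
        np.testing.assert_allclose(core.mean(axis=2), 0.0, atol=1e-10)
        np.testing.assert_allclose(core.std(axis=2), 1.0, atol=1e-10)
        assert z.zscored

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(15 * FS))
        f = np.array([5.0, 10.0])
        z1 = zscore_amplitude(morse_tf_amplitude(x, FS, freqs=f))
        z2 = zscore_amplitude(morse_tf_amplitude(2.0 * x, FS, freqs=f))
        np.testing.assert_allclose(z1.amp, z2.amp, atol=1e-9)

    def test_constant_channel_degenerate(self):
        tf = morse_tf_amplitude(np.zeros(int(10 * FS)), FS,
                                freqs=np.array([6.0]))
        with pytest.raises(DegenerateInputError):
            zscore_amplitude(tf)

    def test_double_zscore_rejected(self):
        rng = np.random.default_rng(2)
        tf = morse_tf_amplitude(rng.standard_normal(int(10 * FS)), FS,
                                freqs=np.array([6.0]))
        z = zscore_amplitude(tf)
        with pytest.raises(ValueError):
            zscore_amplitude(z)


class TestIndividualBand:
    def _spectrum_with_bump(self, centre, width=0.15, height=2.0):
        f = morse_frequency_grid()
        floor = f ** -1.0
        bump = height * floor * np.exp(-0.5 * ((np.log2(f / centre)) / width) ** 2)
        return f, floor + bump

    def test_gaussian_bump_recovered(self):
        f, s = self._spectrum_with_bump(8.0)
        band = find_individual_band(s, f)
        assert abs(np.log2(band.f_peak / 8.0)) < 0.15
        assert band.f_lo < band.f_peak < band.f_hi

    def test_monotone_spectrum_not_found(self):
        f = morse_frequency_grid()
        with pytest.raises(BandNotFoundError):
            find_individual_band(f ** -1.5, f)

    def test_taller_bump_wins(self):
        f = morse_frequency_grid()
        floor = f ** -1.0
        bump = lambda c, a: a * np.exp(-0.5 * (np.log2(f / c) / 0.15) ** 2)
        s = floor + bump(4.0, 0.3) + bump(8.0, 1.0)   # 8 Hz peak is taller
        band = find_individual_band(s, f)
        assert abs(np.log2(band.f_peak / 8.0)) < 0.2

    def test_band_definition_invariant(self):
        with pytest.raises(ValueError):
            BandDefinition(f_peak=5.0, f_lo=6.0, f_hi=7.0)


class TestBandAverage:
    def test_single_bin_band_equals_that_bin(self):
        rng = np.random.default_rng(3)
        tf = morse_tf_amplitude(rng.standard_normal(2000), FS,
                                freqs=np.array([4.0, 6.0, 9.0]))
        band = BandDefinition(f_peak=6.0, f_lo=5.5, f_hi=6.5)
        np.testing.assert_array_equal(band_average(tf, band), tf.amp[:, 1, :])

    def test_full_band_is_grand_mean(self):
        rng = np.random.default_rng(4)
        tf = morse_tf_amplitude(rng.standard_normal(2000), FS,
                                freqs=np.array([4.0, 6.0, 9.0]))
        band = BandDefinition(f_peak=6.0, f_lo=4.0, f_hi=9.0)
        np.testing.assert_allclose(band_average(tf, band),
                                   tf.amp.mean(axis=1))

    def test_empty_band_rejected(self):
        tf = morse_tf_amplitude(np.random.default_rng(0).standard_normal(1000),
                                FS, freqs=np.array([4.0, 8.0]))
        with pytest.raises(ValueError):
            band_average(tf, BandDefinition(f_peak=20.0, f_lo=18.0, f_hi=25.0))


class TestBandSeriesFastPath:
    def test_matches_full_composition(self):
        """The streaming/downsampled path equals the explicit three-step
        composition at full rate."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal((2, int(30 * FS)))
        band = BandDefinition(f_peak=6.0, f_lo=4.5, f_hi=8.0)
        full, fs_eff = band_amplitude_series(x, FS, band, fs_out=None)
        assert fs_eff == FS
        grid = morse_frequency_grid()
        sel = grid[(grid >= band.f_lo) & (grid <= band.f_hi)]
        tf = zscore_amplitude(morse_tf_amplitude(x, FS, freqs=sel))
        np.testing.assert_allclose(full, band_average(tf, band), atol=1e-9)

    def test_downsampled_path_tracks_full_rate(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((1, int(30 * FS)))
        band = BandDefinition(f_peak=6.0, f_lo=4.5, f_hi=8.0)
        full, _ = band_amplitude_series(x, FS, band, fs_out=None)
        low, fs_eff = band_amplitude_series(x, FS, band, fs_out=62.5)
        t_low = np.arange(low.shape[1]) / fs_eff
        ref = np.interp(t_low, np.arange(full.shape[1]) / FS, full[0])
        # agreement away from the edges
        core = slice(int(3 * fs_eff), -int(3 * fs_eff))
        assert np.corrcoef(low[0, core], ref[core])[0, 1] > 0.999


@settings(max_examples=20, deadline=None)
@given(st.floats(min_value=3.0, max_value=20.0))
def test_tone_frequency_recovered_property(freq):
    """Any tone in the analysis range maps to its nearest grid bin."""
    tf = morse_tf_amplitude(_tone(freq, dur=8.0), FS)
    mid = tf.amp.shape[2] // 2
    got = tf.freqs[tf.amp[0, :, mid].argmax()]
    assert abs(np.log2(got / freq)) <= 0.051  # within half a voice
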