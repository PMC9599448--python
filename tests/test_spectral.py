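"""Spectral math against independent definition oracles.

The FFT path is checked against an O(L^2) direct DFT evaluated from the
definition sum; band membership against bin-by-bin interval rules; and the
brain rate against a literal evaluation of its defining double sum.
"""

import numpy as np
import pytest

from brainrate.spectral import (Band, BandScheme, ChannelSpectrum, ZeroSpectrumError,
                                band_centroid, band_power_matrix, band_weights,
                                brain_rate, window_spectrum)

FS = 128.0
L = 256
SCHEME = BandScheme()


def naive_spectrum(x, fs):
    """One-sided DFT magnitude by the definition sum, restricted to 0.5-45 Hz."""
    n = len(x)
    ks = np.arange(n // 2 + 1)
    comps = np.array([np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n)) for k in ks])
    freqs = ks * fs / n
    keep = (freqs >= 0.5) & (freqs <= 45.0)
    return freqs[keep], np.abs(comps[keep]) * 2 / n


def band_members(freqs, band):
    """Brute-force membership under the [.]/(.]-style boundary rules."""
    out = []
    for i, f in enumerate(freqs):
        lo_ok = f >= band.lo if band.lo_inclusive else f > band.lo
        hi_ok = f <= band.hi if band.hi_inclusive else f < band.hi
        if lo_ok and hi_ok:
            out.append(i)
    return out


class TestBandScheme:
    def test_weights_are_band_midpoints(self):
        expected = {"delta": 2.25, "theta": 6.0, "alpha": 10.0, "beta": 21.0, "gamma": 37.5}
        for band in SCHEME.bands:
            assert band.weight == expected[band.name]
            assert band.weight == (band.lo + band.hi) / 2

    def test_bands_partition_the_grid(self):
        freqs = np.arange(1, 91) * 0.5
        counts = [len(band_members(freqs, b)) for b in SCHEME.bands]
        assert counts == [8, 8, 8, 36, 30]
        assert sum(counts) == 90

    def test_config_roundtrip(self):
        assert BandScheme.from_config(SCHEME.to_config()) == SCHEME

    def test_non_contiguous_bands_rejected(self):
        with pytest.raises(ValueError):
            BandScheme(bands=(Band("a", 0.5, 4, True, True), Band("b", 5, 45, False, True)))


class TestWindowSpectrum:
    def test_two_second_window_has_90_bins(self, rng):
        spec = window_spectrum(rng.normal(size=(1, L)), FS)[0]
        assert len(spec.freqs) == 90
        assert spec.freqs[0] == 0.5 and spec.freqs[-1] == 45.0
        assert np.allclose(np.diff(spec.freqs), 0.5)

    def test_exact_bin_sinusoid_concentrates_in_one_bin(self):
        t = np.arange(L) / FS
        spec = window_spectrum(np.sin(2 * np.pi * 10 * t)[None, :], FS)[0]
        at_10 = spec.amps[spec.freqs == 10.0][0]
        assert at_10 == pytest.approx(1.0, abs=1e-9)
        assert np.delete(spec.amps, np.argmax(spec.amps)).max() < 1e-12

    def test_matches_naive_dft_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(size=L)
            spec = window_spectrum(x[None, :], FS)[0]
            freqs, amps = naive_spectrum(x, FS)
            assert np.allclose(spec.freqs, freqs)
            assert np.allclose(spec.amps, amps, rtol=1e-9, atol=1e-12)

    def test_all_zero_window_gives_zero_spectrum(self):
        spec = window_spectrum(np.zeros((1, L)), FS)[0]
        assert spec.is_zero

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            window_spectrum(np.zeros((1, 1)), FS)


class TestBandCentroid:
    def test_constant_band_returns_the_constant(self):
        spec = ChannelSpectrum(np.arange(1, 91) * 0.5, np.full(90, 7.5))
        for band in SCHEME.bands:
            assert band_centroid(spec, band) == pytest.approx(7.5)

    def test_small_example_mean(self):
        freqs = np.array([0.5, 1.0, 1.5])
        spec = ChannelSpectrum(freqs, np.array([1.0, 2.0, 3.0]))
        assert band_centroid(spec, SCHEME["delta"]) == pytest.approx(2.0)

    def test_matches_membership_oracle(self, rng):
        freqs = np.arange(1, 91) * 0.5
        for _ in range(100):
            amps = rng.uniform(0, 5, 90)
            spec = ChannelSpectrum(freqs, amps)
            for band in SCHEME.bands:
                expected = amps[band_members(freqs, band)].mean()
                assert band_centroid(spec, band) == pytest.approx(expected, rel=1e-12)

    def test_empty_band_on_grid_is_an_error(self):
        spec = ChannelSpectrum(np.array([20.0, 25.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            band_centroid(spec, SCHEME["delta"])


class TestBandWeights:
    def test_flat_spectrum_gives_unit_mean_ratio_weights(self):
        spec = ChannelSpectrum(np.arange(1, 91) * 0.5, np.full(90, 3.0))
        assert np.allclose(band_weights(spec, SCHEME), np.ones(5))

    def test_delta_only_spectrum(self):
        """Energy in 8 of 90 bins: P_delta = 90/8 = 11.25, all others zero."""
        amps = np.zeros(90)
        amps[:8] = 4.2
        spec = ChannelSpectrum(np.arange(1, 91) * 0.5, amps)
        assert np.allclose(band_weights(spec, SCHEME), [11.25, 0, 0, 0, 0])

    def test_pure_alpha_tone_power_fraction(self):
        t = np.arange(L) / FS
        spec = window_spectrum(np.sin(2 * np.pi * 10 * t)[None, :], FS)[0]
        w = band_weights(spec, SCHEME, variant="power_fraction")
        assert np.allclose(w, [0, 0, 1, 0, 0], atol=1e-12)

    def test_power_fraction_sums_to_one(self, rng):
        for _ in range(20):
            spec = window_spectrum(rng.normal(size=(1, L)), FS)[0]
            w = band_weights(spec, SCHEME, variant="power_fraction")
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_spectrum_error_names_channel(self):
        spec = ChannelSpectrum(np.arange(1, 91) * 0.5, np.zeros(90))
        with pytest.raises(ZeroSpectrumError, match="channel 3"):
            band_weights(spec, SCHEME, channel=3)


class TestBrainRate:
    def test_flat_spectrum_gives_sum_of_band_weights(self):
        """All P = 1, so per-channel BR = 2.25 + 6 + 10 + 21 + 37.5 = 76.75 Hz."""
        imp = np.zeros((3, L))
        imp[:, 0] = 1.0  # impulse: flat magnitude spectrum
        assert brain_rate(imp, FS, mode="mean_channels").value == pytest.approx(76.75)
        assert brain_rate(imp, FS, mode="sum_channels").value == pytest.approx(3 * 76.75)

    def test_pure_tone_power_fraction_recovers_the_tone(self):
        t = np.arange(L) / FS
        w = np.tile(np.sin(2 * np.pi * 10 * t), (5, 1))
        br = brain_rate(w, FS, mode="mean_channels", variant="power_fraction")
        assert br.value == pytest.approx(10.0, abs=1e-9)

    @pytest.mark.parametrize("variant", ["mean_ratio", "power_fraction"])
    def test_matches_defining_double_sum_oracle(self, rng, variant):
        """BR equals a literal per-channel evaluation of sum_ch sum_b f_b P(b,ch)."""
        for _ in range(30):
            w = rng.normal(size=(4, L))
            expected = 0.0
            for ch in range(4):
                spec = window_spectrum(w[ch][None, :], FS)[0]
                P = band_weights(spec, SCHEME, variant=variant)
                for b, band in enumerate(SCHEME.bands):
                    expected += band.weight * P[b]
            got = brain_rate(w, FS, variant=variant).value
            assert got == pytest.approx(expected, rel=1e-9)

    def test_scale_invariance(self, rng):
        w = rng.normal(size=(4, L))
        for variant in ("mean_ratio", "power_fraction"):
            a = brain_rate(w, FS, variant=variant).value
            b = brain_rate(17.3 * w, FS, variant=variant).value
            assert a == pytest.approx(b, rel=1e-12)

    def test_power_fraction_mean_channels_is_bounded_by_band_weights(self, rng):
        for _ in range(20):
            w = rng.normal(size=(3, L))
            v = brain_rate(w, FS, mode="mean_channels", variant="power_fraction").value
            assert 2.25 <= v <= 37.5

    def test_centroids_and_weights_matrix_shapes(self, rng):
        bpm = band_power_matrix(rng.normal(size=(6, L)), FS, SCHEME)
        assert bpm.centroids.shape == (6, 5) and bpm.weights.shape == (6, 5)
        assert (bpm.centroids >= 0).all() and np.isfinite(bpm.weights).all()
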