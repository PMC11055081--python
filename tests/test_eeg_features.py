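"""FIR preprocessing, wavelet decomposition and the ten spectral features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drowsekit.eeg_features import (
    DWT_BAND_MAP,
    FEATURE_NAMES,
    FeatureConfig,
    PreprocessConfig,
    SpectrumEstimate,
    band_power,
    design_apply_fir,
    dwt_decompose,
    episode_features,
    resample_to,
    slice_by_episode,
    spectral_centroid,
    spectral_entropy,
    spectral_rolloff,
    spectral_spread,
    welch_spectrum,
)
from drowsekit.io_formats import EegRecording, EpisodeRecord, EpisodeTable

FS = 200.0


def _tone(freq, seconds=30.0, fs=FS, amplitude=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


def _rms_gain(signal_in, filtered):
    m = slice(len(signal_in) // 4, -len(signal_in) // 4)
    return np.sqrt(np.mean(filtered[m] ** 2)) / np.sqrt(np.mean(signal_in[m] ** 2))


class TestFirPreprocessing:
    def _apply(self, x):
        rec = EegRecording(["F4"], FS, x[None, :])
        return design_apply_fir(rec).data[0]

    def test_passband_tone_preserved(self):
        x = _tone(10.0)
        assert _rms_gain(x, self._apply(x)) == pytest.approx(1.0, abs=0.1)

    def test_50hz_attenuated_20db_below_passband(self):
        g10 = _rms_gain(_tone(10.0), self._apply(_tone(10.0)))
        g50 = _rms_gain(_tone(50.0), self._apply(_tone(50.0)))
        assert 20 * np.log10(g50 / g10) <= -20.0

    def test_dc_gain_strictly_below_passband_gain(self):
        # an order-25 high-pass at 1 Hz/200 Hz cannot reject DC outright;
        # the contract is relative attenuation only
        x = _tone(10.0) + 5.0
        y = self._apply(x)
        m = slice(len(x) // 4, -len(x) // 4)
        dc_out = abs(np.mean(y[m]))
        g10 = _rms_gain(_tone(10.0), self._apply(_tone(10.0)))
        assert dc_out / 5.0 < g10

    def test_output_length_and_channels_preserved(self, rng):
        rec = EegRecording(["F3", "F4"], FS, rng.standard_normal((2, 1000)))
        out = design_apply_fir(rec)
        assert out.data.shape == (2, 1000)
        assert out.channel_labels == ["F3", "F4"]

    def test_cutoff_beyond_nyquist_rejected(self):
        rec = EegRecording(["F4"], 50.0, np.zeros((1, 100)))
        with pytest.raises(ValueError):
            design_apply_fir(rec, PreprocessConfig(lp_cutoff=30.0))


class TestSliceByEpisode:
    def _table(self, spans):
        return EpisodeTable(
            [
                EpisodeRecord(i + 1, "wake" if i % 2 == 0 else "drowsy", a, b)
                for i, (a, b) in enumerate(spans)
            ]
        )

    def test_sample_counts(self):
        rec = EegRecording(["F4"], FS, np.zeros((1, 6000)))
        segments = slice_by_episode(rec, self._table([(10.0, 20.0)]))
        assert segments[0].shape == (1, 2000)

    def test_adjacent_episodes_partition_samples(self):
        rec = EegRecording(["F4"], FS, np.arange(4000.0)[None, :])
        segments = slice_by_episode(rec, self._table([(0.0, 7.5), (7.5, 20.0)]))
        joined = np.concatenate([s[0] for s in segments])
        assert np.array_equal(joined, rec.data[0])

    def test_episode_outside_recording_names_index(self):
        rec = EegRecording(["F4"], FS, np.zeros((1, 1000)))
        with pytest.raises(ValueError, match="episode 2"):
            slice_by_episode(rec, self._table([(0.0, 2.0), (2.0, 9.0)]))

    def test_offset_shifts_slices(self):
        rec = EegRecording(["F4"], FS, np.arange(2000.0)[None, :])
        (seg,) = slice_by_episode(rec, self._table([(0.0, 1.0)]), offset=2.0)
        assert seg[0][0] == 400.0


class TestDwtDecomposition:
    def test_perfect_reconstruction_and_energy(self, rng):
        for _ in range(20):
            x = rng.standard_normal(rng.integers(64, 600))
            decomp = dwt_decompose(x)
            total = sum(decomp.reconstructions.values())
            trimmed = x[: total.size]  # length clipped to a multiple of 2**level
            assert np.max(np.abs(total - trimmed)) < 1e-8 * max(1.0, np.max(np.abs(x)))
            coeff_energy = sum(np.sum(c**2) for c in decomp.coefficients.values())
            assert coeff_energy == pytest.approx(np.sum(trimmed**2), rel=1e-8)

    def test_alpha_tone_lands_in_d2(self):
        """A 10 Hz tone at 60 Hz sampling concentrates in D2 (7.5-15 Hz).

        db2's short filters leak into the neighboring subbands; the
        band-energy oracle puts 71% of the energy in D2, far above any other
        subband."""
        t = np.arange(600) / 60.0
        decomp = dwt_decompose(np.sin(2 * np.pi * 10 * t))
        energies = {k: np.sum(v**2) for k, v in decomp.reconstructions.items()}
        total = sum(energies.values())
        shares = {k: v / total for k, v in energies.items()}
        assert shares["D2"] == pytest.approx(0.712, abs=0.02)
        assert all(shares["D2"] > s for k, s in shares.items() if k != "D2")

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            dwt_decompose(np.ones(5))

    def test_band_map_edges(self):
        assert DWT_BAND_MAP["D2"] == ("alpha", (7.5, 15.0))
        assert DWT_BAND_MAP["A3"] == ("delta", (0.0, 3.75))


class TestBandPower:
    def test_unit_sinusoid_alpha_power(self):
        x = _tone(10.0)
        assert band_power(x, "alpha", FS) == pytest.approx(0.5, rel=0.05)
        for other in ("delta", "theta", "beta"):
            assert band_power(x, other, FS) < 0.01

    def test_zero_signal(self):
        for name in ("delta", "theta", "alpha", "beta"):
            assert band_power(np.zeros(2000), name, FS) == 0.0

    def test_welch_and_dwt_agree_on_white_noise(self):
        x = np.random.default_rng(2).standard_normal(int(60 * FS))
        for _, (name, (lo, hi)) in DWT_BAND_MAP.items():
            welch = band_power(x, (lo, hi), FS, method="welch")
            dwt = band_power(x, name, FS, method="dwt")
            assert dwt == pytest.approx(welch, rel=0.25)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_power(np.zeros(100), (10.0, 40.0), 60.0)

    def test_resample_preserves_tone(self):
        x = _tone(5.0, seconds=10.0)
        y = resample_to(x, FS, 60.0)
        assert y.size == pytest.approx(x.size * 60 / FS, abs=2)
        assert band_power(y, "theta", 60.0) == pytest.approx(0.5, rel=0.1)


class TestSpectralFeatures:
    def test_entropy_single_bin_zero(self):
        s = SpectrumEstimate(np.array([3.0]), np.array([2.5]))
        assert spectral_entropy(s) == 0.0

    def test_entropy_flat_is_log2_l(self):
        s = SpectrumEstimate(np.arange(8.0), np.ones(8))
        assert spectral_entropy(s) == pytest.approx(3.0)

    def test_entropy_worked_example(self):
        s = SpectrumEstimate(np.arange(3.0), np.array([0.5, 0.25, 0.25]))
        assert spectral_entropy(s) == pytest.approx(1.5)

    def test_entropy_zero_bins_contribute_nothing(self):
        s = SpectrumEstimate(np.arange(4.0), np.array([0.5, 0.25, 0.25, 0.0]))
        assert spectral_entropy(s) == pytest.approx(1.5)

    def test_centroid_examples(self):
        equal = SpectrumEstimate(np.array([2.0, 4.0, 6.0]), np.ones(3))
        assert spectral_centroid(equal) == pytest.approx(4.0)
        single = SpectrumEstimate(np.array([10.0]), np.array([1.0]))
        assert spectral_centroid(single) == pytest.approx(10.0)
        weighted = SpectrumEstimate(np.array([2.0, 10.0]), np.array([1.0, 3.0]))
        assert spectral_centroid(weighted) == pytest.approx(8.0)

    def test_spread_examples_and_bruteforce(self, rng):
        single = SpectrumEstimate(np.array([5.0]), np.array([2.0]))
        assert spectral_spread(single) == 0.0
        two = SpectrumEstimate(np.array([4.0, 8.0]), np.ones(2))
        assert spectral_spread(two) == pytest.approx(2.0)
        freqs = np.sort(rng.uniform(1, 30, 40))
        power = rng.uniform(0, 1, 40)
        s = SpectrumEstimate(freqs, power)
        centroid = np.sum(freqs * power) / np.sum(power)
        expected = np.sqrt(np.sum((freqs - centroid) ** 2 * power) / np.sum(power))
        assert spectral_spread(s) == pytest.approx(expected)

    def test_rolloff_examples(self):
        flat = SpectrumEstimate(np.arange(1.0, 11.0), np.ones(10))
        assert spectral_rolloff(flat, 0.9) == pytest.approx(9.0)
        assert spectral_rolloff(flat, 1.0) == pytest.approx(10.0)
        single = SpectrumEstimate(np.array([1.0, 7.0, 20.0]), np.array([0.0, 1.0, 0.0]))
        for c in (0.1, 0.5, 0.9, 1.0):
            assert spectral_rolloff(single, c) == pytest.approx(7.0)

    def test_all_zero_spectrum_rejected(self):
        s = SpectrumEstimate(np.arange(3.0), np.zeros(3))
        for fn in (spectral_entropy, spectral_centroid, spectral_spread):
            with pytest.raises(ValueError):
                fn(s)
        with pytest.raises(ValueError):
            spectral_rolloff(s, 0.9)

    def test_magnitude_weighting_changes_weights_not_frequencies(self):
        s = SpectrumEstimate(np.array([2.0, 10.0]), np.array([1.0, 9.0]))
        assert spectral_centroid(s, "power") == pytest.approx(9.2)
        assert spectral_centroid(s, "magnitude") == pytest.approx((2 + 30) / 4)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    data=st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=2, max_size=30),
    c1=st.floats(min_value=0.05, max_value=1.0),
    c2=st.floats(min_value=0.05, max_value=1.0),
)
def test_rolloff_monotone_in_c(data, c1, c2):
    power = np.asarray(data)
    if power.sum() <= 0:
        return
    s = SpectrumEstimate(np.arange(1.0, power.size + 1), power)
    lo, hi = sorted((c1, c2))
    assert spectral_rolloff(s, lo) <= spectral_rolloff(s, hi)


class TestEpisodeFeatures:
    def _recording_and_table(self, freq):
        x = _tone(freq, seconds=33.0)
        rec = EegRecording(["F4"], FS, x[None, :])
        table = EpisodeTable(
            [
                EpisodeRecord(1, "wake", 0.0, 11.0),
                EpisodeRecord(2, "drowsy", 11.0, 22.0),
                EpisodeRecord(3, "wake", 22.0, 33.0),
            ]
        )
        return rec, table

    def test_pure_alpha_tone(self):
        rec, table = self._recording_and_table(10.0)
        feats = episode_features(rec, table)
        row = feats.iloc[0]
        assert row.theta_alpha < 0.05
        assert row.spectral_centroid == pytest.approx(10.0, abs=0.5)

    def test_pure_theta_tone(self):
        rec, table = self._recording_and_table(5.0)
        feats = episode_features(rec, table)
        assert feats.iloc[0].theta_alpha > 20

    def test_identical_episodes_identical_rows(self):
        # tile one 11 s block so episodes 1 and 3 contain bitwise-identical
        # samples; the features must then be bit-identical too
        block = _tone(10.0, seconds=11.0)
        rec = EegRecording(["F4"], FS, np.tile(block, 3)[None, :])
        table = EpisodeTable(
            [
                EpisodeRecord(1, "wake", 0.0, 11.0),
                EpisodeRecord(2, "drowsy", 11.0, 22.0),
                EpisodeRecord(3, "wake", 22.0, 33.0),
            ]
        )
        feats = episode_features(rec, table)
        first = feats[feats.episode == 1][list(FEATURE_NAMES)].to_numpy()
        third = feats[feats.episode == 3][list(FEATURE_NAMES)].to_numpy()
        assert np.array_equal(first, third)  # bit-identical determinism

    def test_short_episode_flagged_missing(self):
        rec = EegRecording(["F4"], FS, _tone(10.0, 10.0)[None, :])
        table = EpisodeTable(
            [EpisodeRecord(1, "wake", 0.0, 0.5), EpisodeRecord(2, "drowsy", 0.5, 10.0)]
        )
        feats = episode_features(rec, table, FeatureConfig(min_length=1.0))
        assert feats[feats.episode == 1][list(FEATURE_NAMES)].isna().all().all()
        assert not feats[feats.episode == 2][list(FEATURE_NAMES)].isna().any().any()

    def test_dwt_band_power_method_runs(self):
        rec, table = self._recording_and_table(10.0)
        feats = episode_features(rec, table, FeatureConfig(band_power_method="dwt"))
        assert feats.iloc[0].theta_alpha < 0.2

    def test_welch_spectrum_bins_uniform(self, rng):
        spec = welch_spectrum(rng.standard_normal(1000), FS)
        steps = np.diff(spec.freqs)
        assert np.allclose(steps, steps[0])
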