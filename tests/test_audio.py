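"""Acoustic descriptors: WAV ingest, framing, and the five features."""

import numpy as np
import pandas as pd
import pytest
from scipy.io import wavfile

from phyloacoustics.audio import (
    AudioFormatError,
    CallFeatureExtractor,
    InputTooShortError,
    Recording,
    compute_frames,
    cva,
    dominant_frequency,
    extract_features,
    read_wav,
    species_trait_table,
    spectral_flux,
    spectral_irregularity,
    tonality,
)
from phyloacoustics.simulate import synth_call


def sine(freq, duration=1.0, rate=44100.0, amp=1.0):
    t = np.arange(int(duration * rate)) / rate
    return Recording(amp * np.sin(2 * np.pi * freq * t), rate)


class TestReadWav:
    def test_sample_count_and_rate(self, tmp_path):
        p = tmp_path / "a.wav"
        wavfile.write(p, 44100, (np.sin(np.linspace(0, 100, 44100)) * 32000).astype(np.int16))
        rec = read_wav(p)
        assert len(rec.samples) == 44100
        assert rec.sample_rate == 44100
        assert np.abs(rec.samples).max() <= 1.0

    def test_stereo_identical_channels_average_to_either(self, tmp_path):
        p = tmp_path / "s.wav"
        mono = (np.sin(np.linspace(0, 50, 8000)) * 20000).astype(np.int16)
        wavfile.write(p, 8000, np.stack([mono, mono], axis=1))
        rec = read_wav(p)
        np.testing.assert_allclose(rec.samples, mono / 32768.0)

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.wav"
        p.write_bytes(b"")
        with pytest.raises((AudioFormatError, ValueError)):
            read_wav(p)

    def test_non_wav_bytes_is_format_error(self, tmp_path):
        p = tmp_path / "x.wav"
        p.write_bytes(b"not a wav file at all, sorry....")
        with pytest.raises((AudioFormatError, ValueError)):
            read_wav(p)


class TestFraming:
    def test_frame_count_formula(self):
        rec = Recording(np.zeros(44100) + 0.5, 44100)
        fs = compute_frames(rec, 40.0, 20.0)
        assert fs.n_frames == (44100 - 1764) // 882 + 1 == 49

    def test_constant_signal_rms(self):
        fs = compute_frames(Recording(np.full(44100, 0.5), 44100))
        np.testing.assert_allclose(fs.frame_rms, 0.5)

    def test_sine_rms_near_one_over_sqrt2(self):
        # 1 kHz fits whole cycles into each 40 ms frame
        fs = compute_frames(sine(1000.0))
        np.testing.assert_allclose(fs.frame_rms, 1 / np.sqrt(2), rtol=1e-6)

    def test_too_short_recording(self):
        with pytest.raises(InputTooShortError):
            compute_frames(Recording(np.zeros(100), 44100))


class TestCva:
    def test_constant_tone_is_zero(self):
        assert cva(compute_frames(sine(1000.0))) == pytest.approx(0.0, abs=1e-9)

    def test_gain_invariance(self):
        rec = synth_call(f0=800, am_rate=2, am_depth=0.4, duration=4.0, seed=1)
        loud = Recording(rec.samples * 10, rec.sample_rate)
        assert cva(compute_frames(rec)) == pytest.approx(cva(compute_frames(loud)))

    def test_am_envelope_integration_oracle(self):
        # depth m with slow AM -> CVA = m/sqrt(2); >=50 cycles for 2% accuracy
        rec = synth_call(f0=1000, am_rate=2.0, am_depth=0.5, duration=25.0)
        got = cva(compute_frames(rec))
        assert abs(got - 0.5 / np.sqrt(2)) / (0.5 / np.sqrt(2)) < 0.02


class TestDominantFrequency:
    def test_pure_tone_within_one_bin(self):
        fs = compute_frames(sine(1000.0))
        bin_width = 44100 / 1764
        assert abs(dominant_frequency(fs) - 1000.0) <= bin_width

    def test_stronger_partial_wins(self):
        t = np.arange(44100) / 44100.0
        x = 1.0 * np.sin(2 * np.pi * 500 * t) + 0.5 * np.sin(2 * np.pi * 2000 * t)
        fs = compute_frames(Recording(x, 44100))
        assert abs(dominant_frequency(fs) - 500.0) <= 25.0 + 1e-9

    def test_harmonic_stack_with_rolloff_reports_f0(self):
        rec = synth_call(f0=800, n_harmonics=5, rolloff_db=6.0, duration=1.0)
        fs = compute_frames(rec)
        bin_width = rec.sample_rate / int(0.04 * rec.sample_rate)
        assert abs(dominant_frequency(fs) - 800.0) <= bin_width


class TestSpectralFlux:
    def test_stationary_tone_near_zero(self):
        fs = compute_frames(sine(1102.5))  # frame-aligned: 44.1 cycles per 40ms
        tone_norm = np.sqrt((fs.frame_spectra[0] ** 2).sum())
        assert spectral_flux(fs) < 0.01 * tone_norm

    def test_alternating_silence_tone_equals_spectrum_norm(self):
        # one tone frame and one silent frame: flux == ||tone spectrum||
        rate = 10000.0
        win = int(0.04 * rate)
        tone = np.sin(2 * np.pi * 500 * np.arange(2 * win) / rate)
        tone[win:] = 0.0
        fs = compute_frames(Recording(tone, rate), 40.0, 40.0)  # hop = window
        assert fs.n_frames == 2
        norm0 = np.sqrt((fs.frame_spectra[0] ** 2).sum())
        assert spectral_flux(fs) == pytest.approx(norm0)

    def test_am_flux_exceeds_stationary_flux(self):
        stat = synth_call(f0=1000, am_depth=0.0, duration=2.0)
        am = synth_call(f0=1000, am_rate=10.0, am_depth=0.8, duration=2.0)
        assert spectral_flux(compute_frames(am)) > spectral_flux(compute_frames(stat))

    def test_single_frame_insufficient(self):
        rec = Recording(np.ones(1764), 44100)
        with pytest.raises(InputTooShortError):
            spectral_flux(compute_frames(rec, 40.0, 40.0))


class TestSpectralIrregularity:
    def test_flat_comb_near_zero(self):
        # many equal-amplitude partials -> normalized SI ~ 1/N -> small
        t = np.arange(44100) / 44100.0
        x = sum(np.sin(2 * np.pi * f * t) for f in range(500, 8001, 500))
        si = spectral_irregularity(compute_frames(Recording(x, 44100)))
        assert si < 0.15

    def test_single_partial_scores_one(self):
        si = spectral_irregularity(compute_frames(sine(1000.0)))
        assert si == pytest.approx(1.0, abs=0.05)

    def test_alternating_amplitudes_exceed_flat_comb(self):
        t = np.arange(44100) / 44100.0
        freqs = list(range(500, 8001, 500))
        flat = sum(np.sin(2 * np.pi * f * t) for f in freqs)
        alt = sum(
            (1.0 if k % 2 == 0 else 0.2) * np.sin(2 * np.pi * f * t)
            for k, f in enumerate(freqs)
        )
        si_flat = spectral_irregularity(compute_frames(Recording(flat, 44100)))
        si_alt = spectral_irregularity(compute_frames(Recording(alt, 44100)))
        assert si_alt > si_flat

    def test_gain_invariance_of_normalized_si(self):
        rec = synth_call(f0=700, n_harmonics=4, duration=1.0)
        loud = Recording(rec.samples * 25, rec.sample_rate)
        assert spectral_irregularity(compute_frames(rec)) == pytest.approx(
            spectral_irregularity(compute_frames(loud))
        )


class TestTonality:
    def test_white_noise_near_one(self, rng):
        rec = Recording(rng.standard_normal(44100), 44100)
        assert tonality(compute_frames(rec)) > 0.5

    def test_pure_tone_near_zero(self):
        assert tonality(compute_frames(sine(1000.0))) < 0.05

    def test_monotone_in_noise_level(self):
        vals = [
            tonality(compute_frames(synth_call(f0=1000, noise_snr_db=snr, seed=3)))
            for snr in (30.0, 10.0, -10.0)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_bounded_in_unit_interval(self, rng):
        for seed in range(3):
            rec = synth_call(
                f0=500 + 300 * seed, n_harmonics=3, noise_snr_db=15.0, seed=seed
            )
            t = tonality(compute_frames(rec))
            assert 0.0 < t <= 1.0


class TestDeterminismAndAggregation:
    def test_identical_input_identical_features(self):
        rec = synth_call(f0=900, n_harmonics=3, noise_snr_db=20.0, seed=8)
        f1 = extract_features(rec)
        f2 = extract_features(Recording(rec.samples.copy(), rec.sample_rate))
        assert f1 == f2

    def _meta(self):
        return pd.DataFrame(
            {"species_id": ["sp1"], "clade": ["c1"], "svl_mm": [50.0]}
        )

    def test_single_recording_species_value(self):
        rec = synth_call(f0=1000, duration=1.0, species_id="sp1", seed=0)
        table = species_trait_table([rec], self._meta())
        feats = extract_features(rec)
        assert table.loc["sp1", "cva"] == pytest.approx(feats["cva"])
        assert table.loc["sp1", "logdf"] == pytest.approx(np.log10(feats["df"]))
        assert table.loc["sp1", "logsvl"] == pytest.approx(np.log10(50.0))

    def test_two_recordings_linear_mean_then_log(self):
        r1 = synth_call(f0=800, duration=1.0, species_id="sp1")
        r2 = synth_call(f0=1200, duration=1.0, species_id="sp1")
        table = species_trait_table([r1, r2], self._meta())
        # DF means 800 and 1200 Hz -> mean 1000 -> logDF = 3
        assert table.loc["sp1", "logdf"] == pytest.approx(np.log10(1000.0), abs=1e-3)

    def test_missing_svl_names_species(self):
        rec = synth_call(f0=1000, species_id="sp1")
        meta = pd.DataFrame(
            {"species_id": ["sp1"], "clade": ["c1"], "svl_mm": [np.nan]}
        )
        with pytest.raises(ValueError, match="sp1"):
            species_trait_table([rec], meta)

    def test_species_without_recordings_rejected(self):
        rec = synth_call(f0=1000, species_id="sp1")
        meta = pd.DataFrame(
            {"species_id": ["sp1", "sp2"], "clade": ["c1", "c1"], "svl_mm": [50.0, 60.0]}
        )
        with pytest.raises(ValueError, match="sp2"):
            species_trait_table([rec], meta)

    def test_extractor_is_sklearn_compatible(self):
        est = CallFeatureExtractor(window_ms=40.0)
        assert est.get_params()["window_ms"] == 40.0
        est.set_params(hop_ms=10.0)
        out = est.fit([]).transform([synth_call(f0=600, species_id="s")])
        assert list(out["species_id"]) == ["s"]
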