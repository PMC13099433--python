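import numpy as np
import pytest

import efpcouple as ec
from efpcouple.efp import (
    EEGRecording,
    EFPModel,
    TimeFrequencyGrid,
    band_centers,
    bin_time_frequency,
    compute_efp_timecourse,
    compute_efp_value,
    default_band_edges,
    demo_model,
    preprocess_eeg,
    stockwell_transform,
)


def _sine_recording(freq, fs=250.0, dur=12.0, channels=("Pz", "FCz")):
    t = np.arange(int(fs * dur)) / fs
    x = np.sin(2 * np.pi * freq * t)
    samples = np.vstack([x, np.zeros_like(x)])
    return EEGRecording(samples, fs, list(channels))


def stockwell_oracle(x, fs, freq):
    """Direct time-domain Gaussian-windowed DFT (O(N^2) per frequency).

    The window is the classic sigma = 1/f Gaussian (amplitude f/sqrt(2 pi)),
    periodized over the circular signal domain; phase referenced to t = 0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    k = int(round(freq * n / fs))
    f_cps = k / n  # cycles per sample
    d = np.arange(n)
    amp = f_cps / np.sqrt(2 * np.pi)
    out = np.zeros(n, dtype=complex)
    phase = np.exp(-2j * np.pi * k * d / n)
    for j in range(n):
        w = np.zeros(n)
        for p in (-2, -1, 0, 1, 2):
            w += amp * np.exp(-((j - d + p * n) ** 2) * f_cps**2 / 2)
        out[j] = np.sum(x * phase * w)
    return out


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_all_zero_recording_stays_zero(self):
        rec = EEGRecording(np.zeros((2, 2500)), 250.0, ["Pz", "FCz"])
        out = preprocess_eeg(rec)
        assert np.allclose(out.samples, 0.0)

    def test_notch_attenuates_33hz_sinusoid(self):
        rec = _sine_recording(33.0, dur=20.0)
        out = preprocess_eeg(rec, notches=((33.0, 4.0),))
        steady = slice(int(5 * 250), int(15 * 250))
        rms_in = np.sqrt(np.mean(rec.samples[0, steady] ** 2))
        rms_out = np.sqrt(np.mean(out.samples[0, steady] ** 2))
        assert rms_out < 0.05 * rms_in

    def test_passband_10hz_amplitude_preserved(self):
        rec = _sine_recording(10.0, dur=20.0)
        out = preprocess_eeg(rec)
        steady = slice(int(5 * 250), int(15 * 250))
        amp = np.max(np.abs(out.samples[0, steady]))
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_band_outside_nyquist_rejected(self):
        rec = _sine_recording(10.0)
        with pytest.raises(ValueError):
            preprocess_eeg(rec, band=(0.75, 200.0))


# ---------------------------------------------------------------------------
# Stockwell transform
# ---------------------------------------------------------------------------

class TestStockwell:
    def test_zero_signal_gives_zero_transform(self):
        S = stockwell_transform(np.zeros(64), 64.0, [5.0, 10.0])
        assert np.allclose(S, 0.0)

    def test_sinusoid_peaks_at_its_own_frequency(self):
        fs, dur = 250.0, 12.0
        t = np.arange(int(fs * dur)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        freqs = np.arange(1.0, 41.0)
        power = np.abs(stockwell_transform(x, fs, freqs)) ** 2
        assert freqs[np.argmax(power.mean(axis=0))] == 10.0

    def test_linearity_in_the_input(self, rng):
        x = rng.standard_normal(128)
        a = 3.7
        S1 = stockwell_transform(a * x, 128.0, [12.0])
        S2 = a * stockwell_transform(x, 128.0, [12.0])
        assert np.max(np.abs(S1 - S2)) <= 1e-9 * np.max(np.abs(S2))

    @pytest.mark.parametrize("n,fs", [(64, 64.0), (256, 128.0), (512, 250.0)])
    def test_matches_direct_gaussian_windowed_dft_oracle(self, n, fs, rng):
        x = rng.standard_normal(n)
        freqs = [fs / 16, fs / 8, fs / 3]
        S = stockwell_transform(x, fs, freqs)
        for j, f in enumerate(freqs):
            ref = stockwell_oracle(x, fs, f)
            rel = np.max(np.abs(S[:, j] - ref)) / np.max(np.abs(ref))
            assert rel < 1e-6

    def test_nonpositive_and_super_nyquist_frequencies_rejected(self):
        x = np.zeros(64)
        for f in (0.0, -3.0, 40.0):
            with pytest.raises(ValueError):
                stockwell_transform(x, 64.0, [f])

    def test_minimum_signal_length_enforced(self):
        with pytest.raises(ValueError):
            stockwell_transform(np.zeros(4), 8.0, [1.0])


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

class TestBinning:
    def test_constant_power_pools_to_constant(self):
        grid = bin_time_frequency(np.full((2000, 10), 3.25), 250.0, 1.0,
                                  default_band_edges(), freqs=band_centers(default_band_edges()))
        assert np.allclose(grid.power, 3.25)

    def test_toy_grid_matches_brute_force_rectangle_means(self):
        # 1 s at 8 Hz "sampling", 4 freq columns pooled into 2 bands
        p = np.arange(32, dtype=float).reshape(8, 4)
        freqs = [1.0, 2.0, 3.0, 4.0]
        bands = [[0.5, 2.5], [2.5, 4.5]]
        grid = bin_time_frequency(p, 8.0, 0.25, bands, freqs=freqs)
        expected = np.zeros((4, 2))
        for tb in range(4):
            for b, cols in enumerate(([0, 1], [2, 3])):
                acc = [p[r, c] for r in range(8) if r // 2 == tb for c in cols]
                expected[tb, b] = np.mean(acc)
        assert np.allclose(grid.power, expected)

    def test_twelve_second_segment_yields_48_by_10(self):
        p = np.abs(np.random.default_rng(0).standard_normal((3000, 10)))
        edges = default_band_edges()
        grid = bin_time_frequency(p, 250.0, 0.25, edges, freqs=band_centers(edges))
        assert grid.power.shape == (48, 10)

    def test_indivisible_duration_rejected(self):
        with pytest.raises(ValueError):
            bin_time_frequency(np.ones((1001, 10)), 250.0, 0.25, default_band_edges(),
                               freqs=band_centers(default_band_edges()))


# ---------------------------------------------------------------------------
# EFP evaluation
# ---------------------------------------------------------------------------

class TestEFPValue:
    def _grid(self, power):
        return TimeFrequencyGrid(power, 0.25, default_band_edges())

    def test_zero_grid_returns_intercept(self):
        model = demo_model()
        model.intercept = 0.3
        assert compute_efp_value(self._grid(np.zeros((48, 10))), model) == pytest.approx(0.3)

    def test_one_hot_weight_reads_single_bin(self):
        w = np.zeros((48, 10))
        w[5, 2] = 1.0
        model = EFPModel(weights=w, intercept=0.1)
        p = np.zeros((48, 10))
        p[5, 2] = 4.2
        assert compute_efp_value(self._grid(p), model) == pytest.approx(0.1 + 4.2)

    def test_matches_brute_force_nested_loop_sum(self, rng):
        p = np.abs(rng.standard_normal((48, 10)))
        w = rng.standard_normal((48, 10))
        model = EFPModel(weights=w, intercept=-0.7)
        expected = -0.7
        for i in range(48):
            for j in range(10):
                expected += p[i, j] * w[i, j]
        assert compute_efp_value(self._grid(p), model) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        model = demo_model()
        with pytest.raises(ValueError):
            compute_efp_value(self._grid(np.zeros((24, 10))), model)

    def test_efp_map_is_linear_in_the_power_grid(self, rng):
        model = EFPModel(weights=rng.standard_normal((48, 10)), intercept=0.0)
        p1 = np.abs(rng.standard_normal((48, 10)))
        p2 = np.abs(rng.standard_normal((48, 10)))
        v = compute_efp_value(self._grid(2 * p1 + 3 * p2), model)
        v12 = 2 * compute_efp_value(self._grid(p1), model) + 3 * compute_efp_value(
            self._grid(p2), model
        )
        assert v == pytest.approx(v12, abs=1e-10)


# ---------------------------------------------------------------------------
# time-course
# ---------------------------------------------------------------------------

class TestTimecourse:
    def test_sixty_second_recording_emits_33_values(self):
        rec = EEGRecording(
            np.random.default_rng(1).standard_normal((2, 15000)), 250.0, ["Pz", "FCz"]
        )
        tc = compute_efp_timecourse(rec, demo_model(), stride_s=1.5)
        assert len(tc.values) == 33
        assert tc.times[0] == pytest.approx(12.0)
        assert tc.times[-1] == pytest.approx(60.0)
        assert tc.warmup_steps == 7  # grid slots at 1.5 s steps before 12 s

    def test_zero_eeg_gives_zero_timecourse(self):
        rec = EEGRecording(np.zeros((2, 15000)), 250.0, ["Pz", "FCz"])
        tc = compute_efp_timecourse(rec, demo_model(), stride_s=1.5)
        assert np.allclose(tc.values, 0.0)

    def test_tracks_latent_on_synthetic_eeg(self, slow_latent, demo_efp):
        # the EFP at time t summarizes the trailing 12-s segment, so it is
        # compared against the latent at the segment centers
        centers = demo_efp.times - 6.0
        r = np.corrcoef(demo_efp.values, slow_latent.at(centers))[0, 1]
        assert r > 0.5

    def test_recording_shorter_than_segment_rejected(self):
        rec = EEGRecording(np.zeros((2, 1000)), 250.0, ["Pz", "FCz"])
        with pytest.raises(ValueError):
            compute_efp_timecourse(rec, demo_model())


def test_model_json_roundtrip(tmp_path, rng):
    model = EFPModel(weights=rng.standard_normal((48, 10)), intercept=0.42, name="m1")
    path = tmp_path / "model.json"
    model.save(path)
    back = EFPModel.load(path)
    assert np.array_equal(back.weights, model.weights)
    assert back.intercept == model.intercept
    assert back.band_edges.shape == (10, 2)
    assert back.derivation == ("Pz", "FCz")


def test_incompatible_model_format_rejected(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text('{"format": "something-else"}')
    with pytest.raises(ValueError):
        EFPModel.load(path)
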