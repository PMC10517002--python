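"""Wavelet-decomposition line-length comparator."""

import numpy as np
import pytest
import pywt

from ratseiz import (
    AnnotationTrack,
    EEGRecording,
    LineLengthConfig,
    ValidationError,
    detect_linelength,
    sliding_linelength,
    sweep_linelength_configs,
    wavelet_decompose,
)


def filter_bank_dwt(x, wavelet_name, level):
    """Independent oracle: symmetric extension + convolution + downsampling."""
    w = pywt.Wavelet(wavelet_name)
    f = len(w.dec_lo)
    approx = np.asarray(x, dtype=float)
    for _ in range(level):
        ext = np.concatenate([approx[: f - 1][::-1], approx, approx[-(f - 1):][::-1]])
        out_len = (len(approx) + f - 1) // 2
        detail = np.convolve(ext, w.dec_hi, mode="full")[f::2][:out_len]
        approx = np.convolve(ext, w.dec_lo, mode="full")[f::2][:out_len]
    return detail


class TestWaveletDecompose:
    @pytest.mark.parametrize("level", [2, 3, 4, 5])
    def test_matches_filter_bank_oracle(self, level):
        x = np.random.default_rng(level).standard_normal(1024)
        got = wavelet_decompose(x, level, "db4")
        np.testing.assert_allclose(got, filter_bank_dwt(x, "db4", level), atol=1e-10)

    def test_perfect_reconstruction(self):
        x = np.random.default_rng(9).standard_normal(512)
        coeffs = pywt.wavedec(x, "db4", level=4, mode="symmetric")
        back = pywt.waverec(coeffs, "db4", mode="symmetric")[: len(x)]
        assert np.max(np.abs(back - x)) / np.max(np.abs(x)) < 1e-8

    def test_constant_signal_has_vanishing_details(self):
        d = wavelet_decompose(np.full(256, 3.7), 3, "db4")
        assert np.max(np.abs(d)) < 1e-9

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValidationError):
            wavelet_decompose(np.ones(7), 3, "db4")


class TestSlidingLineLength:
    def test_hand_examples(self):
        assert np.all(sliding_linelength(np.ones(16), 125, 32.0) == 0.0)
        got = sliding_linelength(np.array([0.0, 1.0, 0.0, 1.0]), 125, 32.0)
        assert got.tolist() == [3.0]

    def test_matches_brute_force_loop(self):
        x = np.random.default_rng(4).standard_normal(100)
        got = sliding_linelength(x, 250, 32.0)  # 8 coeffs per window
        for w, val in enumerate(got):
            chunk = x[w * 8 : (w + 1) * 8]
            assert val == pytest.approx(
                sum(abs(chunk[i + 1] - chunk[i]) for i in range(7))
            )

    def test_window_too_short_rejected(self):
        with pytest.raises(ValidationError):
            sliding_linelength(np.ones(64), 125, 8.0)  # 1 coeff per window


def noise_recording(duration=120.0, rate=256.0, seed=0, n_ch=2):
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    return EEGRecording(
        channel_names=[f"c{i}" for i in range(n_ch)],
        sampling_rate=rate,
        samples=50.0 * rng.standard_normal((n_ch, n)),
    )


class TestDetect:
    def test_pure_noise_yields_no_events_at_high_threshold(self):
        rec = noise_recording(seed=21)
        cfg = LineLengthConfig(baseline_interval=(0.0, 30.0), threshold_multiplier=5.0)
        assert detect_linelength(rec, cfg) == []

    def test_planted_spike_train_is_detected(self):
        rec = noise_recording(seed=22)
        rate = rec.sampling_rate
        t = np.arange(int(10 * rate)) / rate
        spikes = np.zeros_like(t)
        for c in np.arange(0.0, 10.0, 1 / 7.0):  # 7 Hz spike train
            spikes += np.exp(-0.5 * ((t - c) / 0.005) ** 2)
        i0 = int(60 * rate)
        rec.samples[:, i0 : i0 + spikes.size] += 800.0 * spikes
        cfg = LineLengthConfig(baseline_interval=(0.0, 30.0))
        events = detect_linelength(rec, cfg)
        assert any(e.start < 70.0 and e.end > 60.0 for e in events)

    def test_detection_count_monotone_in_threshold(self):
        rec, track, _ = None, None, None
        from ratseiz import SynthConfig, generate_recording

        rec, track, _ = generate_recording(
            SynthConfig(duration=240.0, sampling_rate=256.0,
                        seizure_rate_per_hour=45.0,
                        seizure_duration_range=(4.0, 20.0), seed=5)
        )
        counts = []
        for k in (0.5, 1.0, 2.0, 4.0, 8.0):
            cfg = LineLengthConfig(
                baseline_interval=(0.0, 4.0), threshold_multiplier=k
            )
            base_free = AnnotationTrack()  # skip baseline/seizure validation
            counts.append(len(detect_linelength(rec, cfg, annotations=base_free)))
        assert counts == sorted(counts, reverse=True)

    def test_baseline_overlapping_annotations_rejected(self):
        rec = noise_recording(seed=23)
        cfg = LineLengthConfig(baseline_interval=(0.0, 30.0))
        track = AnnotationTrack(((10.0, 20.0),))
        with pytest.raises(ValidationError):
            detect_linelength(rec, cfg, annotations=track)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            LineLengthConfig(decomposition_level=1)
        with pytest.raises(ValidationError):
            LineLengthConfig(window_ms=100)


@pytest.fixture(scope="module")
def hires_recording():
    """Short recording at the full 1024 Hz rate, where every level/window combination is valid."""
    from ratseiz import SynthConfig, generate_recording

    cfg = SynthConfig(duration=240.0, seizure_rate_per_hour=45.0,
                      seizure_duration_range=(4.0, 20.0), seed=5)
    rec, track, _ = generate_recording(cfg)
    return rec, track


class TestSweep:
    def test_full_grid_and_argmax(self, hires_recording):
        rec, track = hires_recording
        # the first 5 s are event-free by construction (placement margin)
        cfg = LineLengthConfig(baseline_interval=(0.0, 4.0), threshold_multiplier=3.0)
        best, reports = sweep_linelength_configs(rec, track, base_config=cfg)
        assert set(reports) == {(l, w) for l in (2, 3, 4, 5) for w in (125, 250, 500)}
        best_report = reports[(best.decomposition_level, best.window_ms)]
        assert all(
            best_report.seizure_sensitivity >= r.seizure_sensitivity
            for r in reports.values()
        )

    def test_single_combination_is_best_trivially(self, hires_recording):
        rec, track = hires_recording
        cfg = LineLengthConfig(baseline_interval=(0.0, 4.0))
        best, reports = sweep_linelength_configs(
            rec, track, levels=(3,), windows_ms=(250,), base_config=cfg
        )
        assert (best.decomposition_level, best.window_ms) == (3, 250)
        assert len(reports) == 1
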