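import numpy as np
import pytest
from scipy.signal import get_window

from usvkit.config import DetectionParams, PipelineConfig, StftParams
from usvkit.detection import (compute_spectrogram, detect, estimate_noise_floor,
                              extract_contour, segment_calls)
from usvkit.io_formats import Recording
from usvkit.synthetic import make_contour, render_audio, CallParams

FS = 250_000.0


def _tone(freq, dur, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return (amp * np.sin(2 * np.pi * freq * t)).astype(np.float32)


def _flat_contour(freq=70_000.0, dur=0.05):
    p = CallParams(duration_s=dur, f_min=freq, f_max=freq, f_start=freq,
                   f_end=freq, mean_freq_target=freq)
    return make_contour(p)


class TestSpectrogram:
    def test_zero_signal_gives_zero_power(self):
        rec = Recording(samples=np.zeros(10_000, np.float32), sample_rate=FS)
        spec = compute_spectrogram(rec)
        assert np.all(spec.power == 0)
        dt = np.diff(spec.frame_times)
        assert np.allclose(dt, 128 / FS)
        assert spec.bin_freqs[0] == 0 and spec.bin_freqs[-1] == FS / 2

    def test_pure_tone_argmax_is_tone_bin(self):
        rec = Recording(samples=_tone(70_000, 0.1), sample_rate=FS)
        spec = compute_spectrogram(rec)
        peak = spec.bin_freqs[spec.power.argmax(axis=1)]
        assert np.all(np.abs(peak - 70_000) <= spec.bin_width_hz / 2 + 1e-9)

    def test_parseval_energy_conservation(self, rng):
        x = rng.standard_normal(50_000).astype(np.float32)
        rec = Recording(samples=x, sample_rate=FS)
        stft = StftParams()
        spec = compute_spectrogram(rec, stft)
        w = get_window(stft.window, stft.window_length, fftbins=True)
        # one-sided power: double all bins except DC and Nyquist
        total = spec.power.sum() + spec.power[:, 1:-1].sum()
        windowed = 0.0
        L, hop = stft.window_length, stft.hop
        for i in range(spec.power.shape[0]):
            seg = x[i * hop:i * hop + L] * w
            windowed += (seg ** 2).sum() * L
        assert total == pytest.approx(windowed, rel=0.01)

    def test_too_short_recording_raises(self):
        rec = Recording(samples=np.zeros(100, np.float32), sample_rate=FS)
        with pytest.raises(ValueError, match="shorter than one"):
            compute_spectrogram(rec)


class TestNoiseFloor:
    def test_white_noise_floor_is_flat(self, rng):
        rec = Recording(samples=rng.standard_normal(300_000).astype(np.float32),
                        sample_rate=FS)
        spec = compute_spectrogram(rec)
        floor = estimate_noise_floor(spec)
        inner = floor[2:-2]  # windowing attenuates the DC/Nyquist edges
        assert inner.max() / inner.min() < 1.25 / 0.75

    def test_floor_robust_to_one_sparse_call(self, rng):
        noise = 0.01 * rng.standard_normal(int(10 * FS)).astype(np.float32)
        quiet = Recording(samples=noise, sample_rate=FS)
        with_call = noise.copy()
        burst = _tone(70_000, 0.05)
        with_call[100_000:100_000 + burst.size] += burst
        loud = Recording(samples=with_call, sample_rate=FS)
        f0 = estimate_noise_floor(compute_spectrogram(quiet))
        f1 = estimate_noise_floor(compute_spectrogram(loud))
        np.testing.assert_allclose(f1, f0, rtol=0.05)

    def test_zero_input_gives_zero_floor(self):
        rec = Recording(samples=np.zeros(100_000, np.float32), sample_rate=FS)
        assert np.all(estimate_noise_floor(compute_spectrogram(rec)) == 0)

    def test_too_few_frames_raises(self):
        rec = Recording(samples=np.zeros(1_000, np.float32), sample_rate=FS)
        spec = compute_spectrogram(rec)
        with pytest.raises(ValueError, match="frames"):
            estimate_noise_floor(spec)


class TestSegmentation:
    def test_noise_only_yields_nothing(self, rng):
        rec = render_audio([], snr_db=-np.inf, rng=rng, tail_s=5.0)
        spec = compute_spectrogram(rec)
        segs = segment_calls(spec, estimate_noise_floor(spec))
        assert segs == []

    def test_single_call_found_with_tight_boundaries(self, rng):
        c = _flat_contour(dur=0.05).shifted(1.0)
        rec = render_audio([c], snr_db=20.0, rng=rng, tail_s=1.0)
        spec = compute_spectrogram(rec)
        segs = segment_calls(spec, estimate_noise_floor(spec))
        assert len(segs) == 1
        f0, f1 = segs[0]
        onset = spec.frame_times[f0] - spec.hop_s / 2
        offset = spec.frame_times[f1 - 1] + spec.hop_s / 2
        assert abs(onset - 1.0) < 0.001
        assert abs(offset - 1.05) < 0.001

    def test_close_calls_merge_within_gap(self, rng):
        a = _flat_contour(dur=0.02).shifted(1.0)
        b = _flat_contour(dur=0.02).shifted(1.022)  # 2 ms apart < 3 ms merge gap
        rec = render_audio([a, b], snr_db=25.0, rng=rng, tail_s=1.0)
        spec = compute_spectrogram(rec)
        segs = segment_calls(spec, estimate_noise_floor(spec))
        assert len(segs) == 1

    def test_raising_threshold_never_increases_call_count(self, rng):
        contours = [_flat_contour(dur=0.03).shifted(0.5 + 0.2 * i)
                    for i in range(8)]
        rec = render_audio(contours, snr_db=15.0, rng=rng, tail_s=0.5)
        spec = compute_spectrogram(rec)
        floor = estimate_noise_floor(spec)
        counts = []
        # thresholds within the operating regime (noise-voiced frames rare);
        # far below it, spurious voiced frames merge neighbouring calls and
        # the count is no longer monotone in the threshold
        for thr in (10.0, 12.0, 14.0, 20.0, 30.0, 45.0):
            det = DetectionParams(snr_threshold_db=thr)
            counts.append(len(segment_calls(spec, floor, det)))
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 8 and counts[-1] == 0


class TestContourExtraction:
    def test_tone_frequency_within_100_hz(self, rng):
        c = _flat_contour(70_000, 0.05).shifted(1.0)
        rec = render_audio([c], snr_db=35.0, rng=rng, tail_s=1.0)
        spec = compute_spectrogram(rec)
        segs = segment_calls(spec, estimate_noise_floor(spec))
        contour = extract_contour(spec, segs[0])
        assert abs(contour.freqs.mean() - 70_000) < 100

    def test_linear_chirp_monotone_after_smoothing(self, rng):
        p = CallParams(duration_s=0.06, f_min=60_000, f_max=70_000,
                       f_start=60_000, f_end=70_000, mean_freq_target=65_000)
        c = make_contour(p).shifted(1.0)
        rec = render_audio([c], snr_db=30.0, rng=rng, tail_s=1.0)
        spec = compute_spectrogram(rec)
        segs = segment_calls(spec, estimate_noise_floor(spec))
        contour = extract_contour(spec, segs[0])
        # assess inside the true call interval: boundary frames whose window
        # mostly covers silence carry no reliable frequency estimate
        inside = (contour.times >= c.onset_s) & (contour.times <= c.offset_s)
        freqs = contour.freqs[inside]
        sm = np.convolve(freqs, np.ones(3) / 3, mode="valid")
        assert np.all(np.diff(sm) > -300)

    def test_jump_call_shows_discontinuity(self, rng):
        p = CallParams(duration_s=0.05, f_min=55_000, f_max=75_000,
                       f_start=65_000, f_end=65_000, mean_freq_target=65_000,
                       jump_offsets=((0.4, 15_000.0),))
        c = make_contour(p).shifted(1.0)
        rec = render_audio([c], snr_db=30.0, rng=rng, tail_s=1.0)
        spec = compute_spectrogram(rec)
        segs = segment_calls(spec, estimate_noise_floor(spec))
        contour = extract_contour(spec, segs[0])
        assert np.max(np.abs(np.diff(contour.freqs))) > 10_000

    def test_short_segment_rejected(self, rng):
        rec = Recording(samples=rng.standard_normal(100_000).astype(np.float32),
                        sample_rate=FS)
        spec = compute_spectrogram(rec)
        with pytest.raises(ValueError, match="fewer than 2"):
            extract_contour(spec, (10, 11))


class TestDetect:
    def test_silence_gives_empty_table(self):
        rec = Recording(samples=np.zeros(int(FS), np.float32), sample_rate=FS,
                        animal_id="m1", group="control_male")
        records, contours = detect(rec)
        assert records == [] and contours == []

    def test_deterministic_given_fixed_input(self, rng):
        c = _flat_contour(dur=0.04).shifted(0.5)
        rec = render_audio([c], snr_db=20.0, rng=rng, tail_s=0.5)
        rec.animal_id, rec.group = "m1", "tp_male"
        r1, c1 = detect(rec)
        r2, c2 = detect(rec)
        assert [x.onset_s for x in r1] == [x.onset_s for x in r2]
        np.testing.assert_array_equal(c1[0].freqs, c2[0].freqs)

    def test_low_sample_rate_rejected(self):
        rec = Recording(samples=np.zeros(100_000, np.float32), sample_rate=96_000)
        with pytest.raises(ValueError, match="band"):
            detect(rec)
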