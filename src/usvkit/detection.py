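"""Deterministic spectral call detector.

Pipeline: magnitude-squared STFT -> per-bin median noise floor -> band-limited
SNR thresholding -> run merging and minimum-duration filtering -> per-call
frequency-contour extraction with parabolic sub-bin peak interpolation.

The voicing statistic (max over in-band bins of power over floor) is smoothed
with a short moving average before thresholding; a single STFT frame of white
noise has an exponential power distribution whose upper tail crosses a 10 dB
ratio over the median floor often enough to seed spurious runs, and averaging
a few frames suppresses this while leaving tonal calls untouched.  Run
boundaries are then refined on the unsmoothed statistic so onsets are not
blurred by the averaging window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .config import DetectionParams, PipelineConfig, StftParams
from .contour import Contour
from .io_formats import CallRecord, Recording

_CHUNK = 1 << 16  # frames per FFT chunk, bounds peak memory


@dataclass
class Spectrogram:
    """Linear-power STFT: frames x frequency bins."""

    power: np.ndarray       # float32, (n_frames, n_bins)
    frame_times: np.ndarray  # s, frame centers
    bin_freqs: np.ndarray    # Hz
    sample_rate: float
    stft: StftParams

    @property
    def hop_s(self) -> float:
        return self.stft.hop / self.sample_rate

    @property
    def bin_width_hz(self) -> float:
        return float(self.bin_freqs[1] - self.bin_freqs[0])


def compute_spectrogram(rec: Recording, stft: StftParams | None = None) -> Spectrogram:
    """Magnitude-squared STFT with the configured window; no edge padding."""
    stft = stft or StftParams()
    stft.validate()
    x = np.asarray(rec.samples, dtype=np.float32)
    if x.dtype == np.int16:
        x = x.astype(np.float32)
    L, hop = stft.window_length, stft.hop
    if x.size < L:
        raise ValueError(f"recording of {x.size} samples shorter than one "
                         f"window ({L} samples)")
    w = get_window(stft.window, L, fftbins=True).astype(np.float32)
    n_frames = 1 + (x.size - L) // hop
    n_bins = L // 2 + 1
    power = np.empty((n_frames, n_bins), dtype=np.float32)
    view = np.lib.stride_tricks.sliding_window_view(x, L)[::hop][:n_frames]
    for i0 in range(0, n_frames, _CHUNK):
        i1 = min(i0 + _CHUNK, n_frames)
        X = np.fft.rfft(view[i0:i1] * w, axis=1)
        power[i0:i1] = (X.real ** 2 + X.imag ** 2).astype(np.float32)
    frame_times = (np.arange(n_frames) * hop + L / 2) / rec.sample_rate
    bin_freqs = np.fft.rfftfreq(L, 1.0 / rec.sample_rate)
    return Spectrogram(power=power, frame_times=frame_times, bin_freqs=bin_freqs,
                       sample_rate=rec.sample_rate, stft=stft)


def estimate_noise_floor(spec: Spectrogram, min_frames: int = 50) -> np.ndarray:
    """Per-bin median power across frames (robust to sparse calls)."""
    if spec.power.shape[0] < min_frames:
        raise ValueError(f"need at least {min_frames} frames to estimate the "
                         f"noise floor, got {spec.power.shape[0]}")
    return np.median(spec.power, axis=0).astype(np.float64)


def _band_ratio(spec: Spectrogram, floor: np.ndarray,
                det: DetectionParams) -> np.ndarray:
    """Per-frame, in-band power over floor (float32, frames x band bins)."""
    band = (spec.bin_freqs >= det.band_low_hz) & (spec.bin_freqs <= det.band_high_hz)
    if not band.any():
        raise ValueError("analysis band contains no frequency bins")
    fb = floor[band]
    safe = np.where(fb > 0, fb, 1.0).astype(np.float32)
    ratio = spec.power[:, band] / safe
    if (fb <= 0).any():  # zero floor: any positive power counts as voiced
        zero = fb <= 0
        ratio[:, zero] = np.where(spec.power[:, band][:, zero] > 0, np.inf, 0.0)
    return ratio


def segment_calls(spec: Spectrogram, floor: np.ndarray,
                  det: DetectionParams | None = None) -> list[tuple[int, int]]:
    """Half-open voiced frame intervals after merging and duration filtering.

    The voicing test (max over in-band bins of power/floor above the SNR
    threshold) is applied to a ``smooth_frames``-wide temporal average of the
    per-bin ratio; run edges are then refined with the unsmoothed ratio in
    the few bins around the run's edge peak, so boundary placement is not
    blurred by the averaging.
    """
    det = det or DetectionParams()
    det.validate()
    from scipy.ndimage import uniform_filter1d

    ratio = _band_ratio(spec, floor, det)
    thr = 10 ** (det.snr_threshold_db / 10.0)
    k = max(1, det.smooth_frames)
    sm = uniform_filter1d(ratio, size=k, axis=0, mode="nearest") if k > 1 else ratio
    stat = sm.max(axis=1)
    if sm is not ratio:
        del sm
    n = stat.size
    runs = _runs(stat > thr)

    def _local(j: int, b: int) -> float:
        return float(ratio[j, max(0, b - 2):b + 3].max())

    refined = []
    for f0, f1 in runs:
        b_on = int(np.argmax(ratio[f0]))
        while f0 > 0 and _local(f0 - 1, b_on) > thr:
            f0 -= 1
        b_off = int(np.argmax(ratio[f1 - 1]))
        while f1 < n and _local(f1, b_off) > thr:
            f1 += 1
        refined.append((f0, f1))
    hop_s = spec.hop_s
    merged: list[tuple[int, int]] = []
    for f0, f1 in refined:
        if merged and (f0 - merged[-1][1]) * hop_s < det.merge_gap_s:
            merged[-1] = (merged[-1][0], max(merged[-1][1], f1))
        else:
            merged.append((f0, f1))
    return [(f0, f1) for f0, f1 in merged if (f1 - f0) * hop_s >= det.min_duration_s]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def extract_contour(spec: Spectrogram, segment: tuple[int, int],
                    det: DetectionParams | None = None) -> Contour:
    """Per-frame in-band peak frequency with 3-point parabolic refinement."""
    det = det or DetectionParams()
    f0, f1 = segment
    if f1 - f0 < 2:
        raise ValueError(f"segment {segment} has fewer than 2 frames")
    if not (0 <= f0 < f1 <= spec.power.shape[0]):
        raise ValueError(f"segment {segment} outside spectrogram")
    band = np.nonzero((spec.bin_freqs >= det.band_low_hz)
                      & (spec.bin_freqs <= det.band_high_hz))[0]
    sub = spec.power[f0:f1][:, band].astype(np.float64)
    if sub.shape[0] >= 3:  # light temporal smoothing halves peak jitter
        from scipy.ndimage import uniform_filter1d
        sub = uniform_filter1d(sub, size=3, axis=0, mode="nearest")
    k = np.argmax(sub, axis=1)
    # Edge frames carry little call energy (the window only grazes the call),
    # so their unconstrained argmax can land on a noise bin; constrain the
    # first/last few frames to a small neighborhood of the interior ridge.
    n_f = sub.shape[0]
    m = min(4, n_f // 3)
    if m > 0:
        for i in range(m):
            lo = max(0, int(k[m]) - 4)
            k[i] = lo + int(np.argmax(sub[i, lo:int(k[m]) + 5]))
        for i in range(n_f - m, n_f):
            lo = max(0, int(k[n_f - 1 - m]) - 4)
            k[i] = lo + int(np.argmax(sub[i, lo:int(k[n_f - 1 - m]) + 5]))
    rows = np.arange(sub.shape[0])
    amp = sub[rows, k]
    logp = np.log(np.maximum(sub, 1e-300))
    km = np.clip(k - 1, 0, band.size - 1)
    kp = np.clip(k + 1, 0, band.size - 1)
    a, b, c = logp[rows, km], logp[rows, k], logp[rows, kp]
    denom = a - 2 * b + c
    delta = np.where((k > 0) & (k < band.size - 1) & (np.abs(denom) > 1e-12),
                     0.5 * (a - c) / np.where(np.abs(denom) > 1e-12, denom, 1.0),
                     0.0)
    delta = np.clip(delta, -0.5, 0.5)
    freqs = spec.bin_freqs[band[k]] + delta * spec.bin_width_hz
    times = spec.frame_times[f0:f1]
    hop_s = spec.hop_s
    return Contour(times=times, freqs=freqs, amps=amp,
                   onset_s=float(times[0] - hop_s / 2),
                   offset_s=float(times[-1] + hop_s / 2))


def detect(rec: Recording, config: PipelineConfig | None = None,
           ) -> tuple[list[CallRecord], list[Contour]]:
    """Full detection: spectrogram, floor, segmentation, contours.

    Deterministic for fixed config.  Uses the recording's animal/group
    metadata for the emitted call records.
    """
    config = (config or PipelineConfig()).validate()
    if rec.sample_rate < 2 * config.detection.band_high_hz:
        raise ValueError(
            f"sample rate {rec.sample_rate} Hz below twice the analysis band "
            f"ceiling ({config.detection.band_high_hz} Hz)")
    spec = compute_spectrogram(rec, config.stft)
    floor = estimate_noise_floor(spec)
    segments = segment_calls(spec, floor, config.detection)
    animal = rec.animal_id or "anon"
    records, contours = [], []
    for i, seg in enumerate(segments):
        c = extract_contour(spec, seg, config.detection)
        contours.append(c)
        records.append(CallRecord(
            call_id=f"{animal}_{i:05d}", animal_id=animal, group=rec.group,
            onset_s=c.onset_s, offset_s=c.offset_s))
    return records, contours
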