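"""The frequency contour: per-frame dominant frequency of one call.

Every acoustic feature is computed from this object, whether it came from the
spectral detector or from the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Contour:
    """Per-frame frequency/amplitude trace of a single call.

    ``times`` are frame centers in seconds, strictly increasing and lying in
    ``[onset_s, offset_s)``; ``freqs`` in Hz; ``amps`` linear power.
    """

    times: np.ndarray
    freqs: np.ndarray
    amps: np.ndarray
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.amps = np.asarray(self.amps, dtype=float)
        if not (self.times.shape == self.freqs.shape == self.amps.shape):
            raise ValueError("times, freqs, amps must have matching shapes")
        if self.times.size < 2:
            raise ValueError("a contour needs at least 2 frames")
        if not self.offset_s > self.onset_s:
            raise ValueError("offset_s must exceed onset_s")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def shifted(self, dt: float) -> "Contour":
        """A copy displaced in time by ``dt`` seconds."""
        return Contour(self.times + dt, self.freqs.copy(), self.amps.copy(),
                       self.onset_s + dt, self.offset_s + dt)
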