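"""Synthetic USV sessions with known ground truth.

The generator emulates 5-minute recording sessions of the four experimental
groups (control/testosterone-propionate x female/male): per-call acoustic
parameters are drawn from truncated normals centred on the published group
means, call shapes follow nine qualitative archetypes (jump calls, short
high-frequency calls, flat segments, long modulated calls, ...), inter-call
intervals mix short within-bout gaps with long between-bout pauses straddling
the 2-s bout rule, and call-type sequences follow a per-group first-order
Markov chain.  Every emitted call carries its true parameters, so the
detector, the feature extractor, the call typer and the transition machinery
can all be scored against exact truth.

Contours are built from a piecewise-linear base through two interior knots
(placed at the contour minimum and maximum) whose times are solved so the
trace simultaneously hits the requested start, end, min, max and time-average
frequency; sinusoidal modulation cycles and in-band jump discontinuities are
then superimposed with a small iterative correction that restores the target
mean.  A fixed symmetric chirp cannot satisfy these mutually constrained
values (max - min must equal the frequency dynamic while the mean need not be
the band midpoint), which is why the knot times are free parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contour import Contour
from .io_formats import GROUPS, Recording

DEFAULT_FRAME_HOP_S = 128 / 250_000  # matches the default STFT hop at 250 kHz
DEFAULT_SAMPLE_RATE = 250_000.0

#: Archetype id 0 is a "noise blob": very short, nearly flat, used to plant a
#: removable noise cluster when exercising the call typer.
NOISE_ARCHETYPE = 0


class InfeasibleContourError(ValueError):
    """Requested contour constraints cannot be met simultaneously."""


@dataclass
class CallParams:
    """Ground-truth parameters of one synthetic call."""

    duration_s: float
    f_min: float
    f_max: float
    f_start: float
    f_end: float
    mean_freq_target: float
    n_modulation_cycles: int = 0
    modulation_amp_hz: float = 0.0
    jump_offsets: tuple[tuple[float, float], ...] = ()  # (time fraction, magnitude Hz)
    amplitude: float = 1.0
    archetype: int = 1

    def validate(self) -> "CallParams":
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        lo, hi = self.f_min, self.f_max
        for name in ("f_start", "f_end", "mean_freq_target"):
            v = getattr(self, name)
            if not lo - 1e-6 <= v <= hi + 1e-6:
                raise InfeasibleContourError(
                    f"{name}={v:.1f} Hz outside [f_min, f_max] = [{lo:.1f}, {hi:.1f}]")
        return self


# ---------------------------------------------------------------------------
# Archetype shape table.  Numeric centres are generator configuration, chosen
# so the nine shapes are separable in the 12-feature space; the qualitative
# descriptions follow the canonical call-type vocabulary (jump call, short
# high-frequency call, flat segment, ...).  dur/dyn are multiplicative
# factors on the group means, off is an additive frequency offset (Hz); all
# three are re-normalized per group so the mixture-weighted means reproduce
# the group-level parameter means exactly.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchetypeShape:
    name: str
    dur: float = 1.0
    dyn: float = 1.0
    off: float = 0.0
    delta: float = 1.0            # multiplier on the group delta (end - start)
    n_mod: int = 0
    mod_amp: float = 0.0          # fraction of half-dynamic
    jumps: tuple[tuple[float, float], ...] = ()  # (time fraction, fraction of dynamic)


ARCHETYPES: dict[int, ArchetypeShape] = {
    1: ArchetypeShape("jump", dur=1.0, dyn=1.8,
                      jumps=((0.35, 0.8), (0.65, 0.8))),
    2: ArchetypeShape("high-frequency short", dur=0.55, dyn=0.8, off=6_000.0),
    3: ArchetypeShape("short flat segment", dur=0.45, dyn=0.35, delta=0.2),
    4: ArchetypeShape("long, small slope", dur=1.6, dyn=0.55, delta=0.3),
    5: ArchetypeShape("slope, high frequency", dur=1.0, dyn=1.2, off=3_000.0,
                      delta=1.8),
    6: ArchetypeShape("high linearity / total variation", dur=1.0, dyn=1.0,
                      n_mod=4, mod_amp=0.9),
    7: ArchetypeShape("upward, modulated", dur=1.0, dyn=1.0, delta=1.4,
                      n_mod=2, mod_amp=0.6),
    8: ArchetypeShape("high-frequency short slope (low band)", dur=0.65, dyn=0.6,
                      off=-5_000.0, delta=0.8),
    9: ArchetypeShape("long, modulated", dur=1.7, dyn=1.1,
                      n_mod=2, mod_amp=0.5),
}

NOISE_SHAPE = ArchetypeShape("noise blob", dur=0.15, dyn=0.1, off=-12_000.0,
                             delta=0.1)


def _stationary_distribution(P: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _transition_matrix(boosts: dict[tuple[int, int], float]) -> np.ndarray:
    """Row-stochastic 9x9 matrix: uniform background plus boosted cells."""
    M = np.ones((9, 9))
    for (i, j), w in boosts.items():
        M[i - 1, j - 1] += 9.0 * w
    return M / M.sum(axis=1, keepdims=True)


# Qualitative per-group transition patterns: females favour 5 -> 2, males show
# a strong 2 -> 9 flow; self-transitions on types 2 and 5 are common.
_GROUP_BOOSTS: dict[str, dict[tuple[int, int], float]] = {
    "control_female": {(5, 2): 1.5, (2, 5): 0.8, (5, 5): 0.5, (2, 8): 0.5,
                       (8, 8): 0.5, (8, 2): 0.3},
    "control_male": {(2, 9): 1.2, (9, 2): 0.6, (2, 2): 0.5, (5, 2): 0.4,
                     (2, 8): 0.7, (8, 8): 0.5},
    "tp_female": {(5, 2): 1.2, (2, 2): 0.9, (2, 7): 0.8, (7, 2): 0.8,
                  (7, 7): 0.4, (2, 5): 0.4},
    "tp_male": {(2, 9): 1.2, (9, 2): 0.8, (2, 2): 0.9, (5, 2): 0.4, (2, 5): 0.3},
}


@dataclass
class GroupPreset:
    """Per-group generating distribution.

    ``duration_ms``/``f_min_hz``/``f_max_hz``/``mean_freq_hz``/``delta_freq_hz``
    are the group means of the corresponding per-call parameters; per-call
    draws are truncated normals with sd = cv * mean.  ``transition`` is the
    9x9 row-stochastic call-type chain whose stationary distribution doubles
    as the archetype mixture.
    """

    group: str
    duration_ms: float
    f_min_hz: float
    f_max_hz: float
    mean_freq_hz: float
    delta_freq_hz: float
    cv: float = 0.10
    n_animals: int = 7
    median_calls: int = 300
    transition: np.ndarray = field(default_factory=lambda: np.full((9, 9), 1 / 9))
    ici_within_frac: float = 0.8
    ici_within: tuple[float, float] = (0.05, 0.5)
    ici_between: tuple[float, float] = (2.5, 10.0)
    #: Within-archetype shrink of the band-center spread (archetype-scale
    #: mode only): part of the group-level frequency spread is carried by the
    #: archetype offsets, the remainder by this within-class draw.
    center_shrink: float = 0.4
    # normalized archetype effects, filled by __post_init__
    mixture_weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    _dur_mult: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _dyn_mult: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _freq_off: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (9, 9):
            raise ValueError("transition must be 9x9")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if self.mixture_weights is None:
            self.mixture_weights = _stationary_distribution(self.transition)
        self.mixture_weights = np.asarray(self.mixture_weights, dtype=float)
        if abs(self.mixture_weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        self._normalize_effects()

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.f_min_hz + self.f_max_hz)

    @property
    def freq_dynamic_hz(self) -> float:
        return self.f_max_hz - self.f_min_hz

    def _normalize_effects(self) -> None:
        w = self.mixture_weights
        ids = np.arange(1, 10)
        dur = np.array([ARCHETYPES[i].dur for i in ids])
        dyn = np.array([ARCHETYPES[i].dyn for i in ids])
        off = np.array([ARCHETYPES[i].off for i in ids])
        dlt = np.array([ARCHETYPES[i].delta for i in ids])
        self._dur_mult = dur / float(w @ dur)
        self._delta_mult = dlt / float(w @ dlt)
        # Every archetype's dynamic must be able to contain its own delta;
        # floor the multipliers per archetype, then rescale so the mixture
        # mean stays 1 (bisection on the common scale factor).
        floor = 1.5 * np.abs(self.delta_freq_hz) * self._delta_mult / self.freq_dynamic_hz
        if float(w @ floor) >= 1.0:
            raise ValueError(f"{self.group}: |delta| too large for the frequency dynamic")

        def mults_at(s: float) -> np.ndarray:
            return np.maximum(dyn * s, floor)

        lo_s, hi_s = 1e-6, 10.0
        for _ in range(80):  # bisection: the mixture mean is monotone in s
            mid = 0.5 * (lo_s + hi_s)
            if float(w @ mults_at(mid)) < 1.0:
                lo_s = mid
            else:
                hi_s = mid
        self._dyn_mult = mults_at(0.5 * (lo_s + hi_s))
        self._freq_off = off - float(w @ off)

    def archetype_effect(self, archetype: int,
                         ) -> tuple[float, float, float, float, ArchetypeShape]:
        """(dur mult, dynamic mult, freq offset, delta mult, shape)."""
        if archetype == NOISE_ARCHETYPE:
            s = NOISE_SHAPE
            return s.dur, s.dyn, s.off, s.delta, s
        s = ARCHETYPES[archetype]
        i = archetype - 1
        return (float(self._dur_mult[i]), float(self._dyn_mult[i]),
                float(self._freq_off[i]), float(self._delta_mult[i]), s)


def default_presets() -> dict[str, GroupPreset]:
    """The four calibrated group presets (published group means, cv = 0.10)."""
    table = {
        #                duration  f_min   f_max    mean    delta   n  median
        "control_female": (44.49, 50_420, 59_100, 54_941, 457.7, 7, 332),
        "control_male": (40.28, 49_854, 59_347, 54_431, 435.2, 15, 522),
        "tp_female": (47.76, 58_001, 72_386, 65_023, 5_279.5, 14, 614),
        "tp_male": (40.57, 58_552, 68_326, 63_430, 394.8, 7, 1_249),
    }
    presets = {}
    for group, (dur, fmin, fmax, mean, delta, n, med) in table.items():
        presets[group] = GroupPreset(
            group=group, duration_ms=dur, f_min_hz=fmin, f_max_hz=fmax,
            mean_freq_hz=mean, delta_freq_hz=delta, n_animals=n, median_calls=med,
            transition=_transition_matrix(_GROUP_BOOSTS[group]))
    return presets


# ---------------------------------------------------------------------------
# Contour construction
# ---------------------------------------------------------------------------

def _knot_mean(t1: float, t2: float, fs: float, a: float, b: float, fe: float) -> float:
    return 0.5 * ((fs + a) * t1 + (a + b) * (t2 - t1) + (b + fe) * (1.0 - t2))


def _corners(eps: float) -> list[tuple[float, float]]:
    return [(eps, 2 * eps), (eps, 1 - eps), (1 - 2 * eps, 1 - eps)]


def achievable_mean_range(fs: float, fe: float, fmin: float, fmax: float,
                          eps: float = 0.02) -> tuple[float, float]:
    """Range of time-average frequencies the two-knot family can realize."""
    vals = []
    for a, b in ((fmin, fmax), (fmax, fmin)):
        vals += [_knot_mean(t1, t2, fs, a, b, fe) for t1, t2 in _corners(eps)]
    return min(vals), max(vals)


def _solve_knots(fs: float, fe: float, fmin: float, fmax: float, target: float,
                 eps: float = 0.02) -> tuple[float, float, float, float]:
    """Knot times (t1, t2) and values (a, b) whose trace has the target mean."""
    orders = ((fmin, fmax), (fmax, fmin)) if fe >= fs else ((fmax, fmin), (fmin, fmax))
    for a, b in orders:
        cs = _corners(eps)
        vals = [_knot_mean(t1, t2, fs, a, b, fe) for t1, t2 in cs]
        for (i, j) in ((0, 1), (1, 2), (0, 2)):
            v1, v2 = vals[i], vals[j]
            if (v1 - target) * (v2 - target) <= 0:
                u = 0.5 if v1 == v2 else (target - v1) / (v2 - v1)
                t1 = cs[i][0] + u * (cs[j][0] - cs[i][0])
                t2 = cs[i][1] + u * (cs[j][1] - cs[i][1])
                return t1, t2, a, b
    lo, hi = achievable_mean_range(fs, fe, fmin, fmax, eps)
    raise InfeasibleContourError(
        f"mean_freq_target={target:.1f} Hz outside achievable [{lo:.1f}, {hi:.1f}] "
        f"for f_start={fs:.1f}, f_end={fe:.1f}, band [{fmin:.1f}, {fmax:.1f}]")


def _assemble(tau: np.ndarray, p: CallParams, target: float,
              jump_dirs: list[float] | None = None,
              ) -> tuple[np.ndarray, list[float]]:
    n = tau.size
    fmin, fmax = p.f_min, p.f_max
    if fmax - fmin < 1e-9:
        return np.full(n, fmin), []
    t1, t2, a, b = _solve_knots(p.f_start, p.f_end, fmin, fmax, target)
    f = np.interp(tau, [0.0, t1, t2, 1.0], [p.f_start, a, b, p.f_end])
    i1 = int(np.clip(np.argmin(np.abs(tau - t1)), 1, n - 2))
    i2 = int(np.clip(np.argmin(np.abs(tau - t2)), 1, n - 2))
    if i2 == i1:
        i2 = min(i1 + 1, n - 2)
    f[i1], f[i2] = a, b
    if p.n_modulation_cycles > 0 and p.modulation_amp_hz > 0:
        head = np.minimum(f - fmin, fmax - f)
        amp = np.minimum(p.modulation_amp_hz, 0.95 * np.maximum(head, 0.0))
        f = f + amp * np.sin(2 * np.pi * p.n_modulation_cycles * tau)
    dirs_out: list[float] = []
    for j, (frac, mag) in enumerate(p.jump_offsets):
        width = 0.08
        mask = (tau >= frac) & (tau < frac + width)
        if not mask.any() or mask.all():
            dirs_out.append(0.0)
            continue
        if jump_dirs is not None and jump_dirs[j] != 0.0:
            sign = jump_dirs[j]
        else:  # jump away from the nearer band edge; frozen across re-solves
            med = float(np.median(f[mask]))
            sign = -1.0 if (med - fmin) >= (fmax - med) else 1.0
        dirs_out.append(sign)
        f[mask] = np.clip(f[mask] + sign * mag, fmin, fmax)
    # re-assert the extreme and endpoint samples: jump clipping may have
    # displaced the sample that realizes the contour minimum or maximum
    f[i1], f[i2] = a, b
    f[0], f[-1] = p.f_start, p.f_end
    return f, dirs_out


def make_contour(p: CallParams, frame_hop_s: float = DEFAULT_FRAME_HOP_S) -> Contour:
    """Sample a frequency trace realizing ``p`` (start/end/min/max/mean).

    All five frequency constraints are met within 0.5% relative; jumps and
    modulation cycles are superimposed inside the band and the target mean is
    restored by re-solving the knot times.
    """
    if frame_hop_s <= 0:
        raise ValueError("frame_hop_s must be positive")
    p.validate()
    dur = p.duration_s
    n = max(2, int(round(dur / frame_hop_s)) + 1)
    tau = np.linspace(0.0, 1.0, n)
    if p.f_max - p.f_min < 1e-9:
        f = np.full(n, p.f_min)
    else:
        lo, hi = achievable_mean_range(p.f_start, p.f_end, p.f_min, p.f_max)
        margin = 0.02 * (hi - lo)
        target = float(np.clip(p.mean_freq_target, lo + margin, hi - margin))
        f, dirs = _assemble(tau, p, target)
        best, best_err = f, abs(p.mean_freq_target - float(f.mean()))
        for _ in range(8):
            err = p.mean_freq_target - float(f.mean())
            if abs(err) < 1e-7 * p.mean_freq_target:
                break
            target = float(np.clip(target + err, lo + margin, hi - margin))
            f, _ = _assemble(tau, p, target, jump_dirs=dirs)
            e = abs(p.mean_freq_target - float(f.mean()))
            if e < best_err:
                best, best_err = f, e
        f = best
    env = p.amplitude * np.sin(np.pi * (np.arange(n) + 0.5) / n) ** 2
    times = np.arange(n) * (dur / n)
    return Contour(times=times, freqs=f, amps=env, onset_s=0.0, offset_s=dur)


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float = -np.inf, hi: float = np.inf) -> float:
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(200):  # rejection; bounds are always generous here
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_call_params(preset: GroupPreset, archetype: int,
                       rng: np.random.Generator,
                       archetype_scale: bool = True) -> CallParams:
    """Draw one call's parameters from the preset for the given archetype.

    Truncation keeps every draw feasible: the dynamic always contains the
    delta, the band stays inside the analysis range, and the mean target stays
    strictly inside the knot-solvable region.

    With ``archetype_scale=False`` the archetype contributes shape only
    (modulation cycles, jumps) and every scale parameter is drawn from a
    truncated normal centred exactly on the group mean with sd = cv * mean —
    the calibration condition used to verify round-trip recovery of the group
    parameter table.
    """
    d_mult, g_mult, off, dl_mult, shape = preset.archetype_effect(archetype)
    if not archetype_scale and archetype != NOISE_ARCHETYPE:
        d_mult, g_mult, off, dl_mult = 1.0, 1.0, 0.0, 1.0
    cv = preset.cv
    delta_mean = preset.delta_freq_hz * dl_mult
    delta = (rng.normal(delta_mean, cv * abs(delta_mean)) if cv > 0 else delta_mean)
    dyn_mean = preset.freq_dynamic_hz * g_mult
    dyn = _trunc_normal(rng, dyn_mean, cv * dyn_mean,
                        lo=max(300.0, 1.2 * abs(delta)))
    c_mean = preset.center_hz + off
    c_sd = cv * preset.center_hz * (preset.center_shrink if archetype_scale else 1.0)
    c = _trunc_normal(rng, c_mean, c_sd,
                      lo=32_000.0 + dyn / 2, hi=105_000.0 - dyn / 2)
    f_min, f_max = c - dyn / 2, c + dyn / 2
    mean = c + (preset.mean_freq_hz - preset.center_hz)
    if cv > 0:
        mean += rng.normal(0.0, 0.02 * preset.mean_freq_hz)
    mod_amp = shape.mod_amp * dyn / 2
    jumps = tuple((frac, magfrac * dyn) for frac, magfrac in shape.jumps)
    # jump windows displace the time-average by up to ~width * magnitude;
    # reserve that budget so the mean-restoring knot solve stays feasible
    jump_budget = 1.3 * sum(0.08 * mag for _, mag in jumps)
    pad = 0.51 * abs(delta) + 0.03 * dyn
    mean = float(np.clip(mean, f_min + pad, f_max - pad))
    for _ in range(2):  # the achievable range moves with f_start/f_end
        fs, fe = mean - delta / 2, mean + delta / 2
        lo, hi = achievable_mean_range(fs, fe, f_min, f_max)
        margin = max(0.05 * (hi - lo), jump_budget)
        mean = float(np.clip(mean, lo + margin, hi - margin))
    fs, fe = mean - delta / 2, mean + delta / 2
    dur_mean = preset.duration_ms * d_mult / 1000.0
    dur = _trunc_normal(rng, dur_mean, cv * dur_mean, lo=0.003)
    return CallParams(
        duration_s=dur, f_min=f_min, f_max=f_max, f_start=fs, f_end=fe,
        mean_freq_target=mean, n_modulation_cycles=shape.n_mod,
        modulation_amp_hz=mod_amp, jump_offsets=jumps,
        amplitude=1.0, archetype=archetype).validate()


def sample_calls(preset: GroupPreset, n: int, rng: np.random.Generator,
                 frame_hop_s: float = DEFAULT_FRAME_HOP_S,
                 archetype_scale: bool = True,
                 ) -> tuple[list[CallParams], list[Contour]]:
    """n i.i.d. calls from the preset's archetype mixture, with contours."""
    archetypes = rng.choice(np.arange(1, 10), size=n, p=preset.mixture_weights)
    params = [sample_call_params(preset, int(a), rng, archetype_scale)
              for a in archetypes]
    contours = [make_contour(p, frame_hop_s) for p in params]
    return params, contours


# ---------------------------------------------------------------------------
# Session / cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact per-call truth for one simulated session."""

    animal_id: str
    group: str
    seed: int
    calls: pd.DataFrame  # one row per call


TRUTH_COLUMNS = ("call_id", "animal_id", "group", "onset_s", "offset_s",
                 "archetype", "duration_s", "f_min", "f_max", "f_start",
                 "f_end", "mean_freq_target", "n_modulation_cycles", "n_jumps")


def simulate_session(animal_id: str, preset: GroupPreset, n_calls: int,
                     rng: np.random.Generator,
                     frame_hop_s: float = DEFAULT_FRAME_HOP_S,
                     seed: int = 0) -> tuple[list[Contour], GroundTruth]:
    """One animal's session: Markov archetype sequence + bout-structured timing."""
    if n_calls < 0:
        raise ValueError("n_calls must be >= 0")
    rows, contours = [], []
    t = 0.5
    state = int(rng.choice(9, p=preset.mixture_weights)) + 1
    for k in range(n_calls):
        p = sample_call_params(preset, state, rng)
        c = make_contour(p, frame_hop_s).shifted(t)
        contours.append(c)
        rows.append({
            "call_id": f"{animal_id}_{k:05d}", "animal_id": animal_id,
            "group": preset.group, "onset_s": c.onset_s, "offset_s": c.offset_s,
            "archetype": state, "duration_s": p.duration_s, "f_min": p.f_min,
            "f_max": p.f_max, "f_start": p.f_start, "f_end": p.f_end,
            "mean_freq_target": p.mean_freq_target,
            "n_modulation_cycles": p.n_modulation_cycles,
            "n_jumps": len(p.jump_offsets),
        })
        if rng.random() < preset.ici_within_frac:
            ici = rng.uniform(*preset.ici_within)
        else:
            ici = rng.uniform(*preset.ici_between)
        t = c.offset_s + ici
        state = int(rng.choice(9, p=preset.transition[state - 1])) + 1
    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return contours, GroundTruth(animal_id=animal_id, group=preset.group,
                                 seed=seed, calls=truth)


def render_audio(contours: list[Contour], sample_rate: float = DEFAULT_SAMPLE_RATE,
                 snr_db: float = 20.0, rng: np.random.Generator | None = None,
                 ramp_s: float = 0.001, window_length: int = 512,
                 tail_s: float = 0.5) -> Recording:
    """Render contours as frequency-modulated tones in white Gaussian noise.

    ``snr_db`` is the per-bin SNR: the ratio, in the default analysis STFT, of
    a unit-amplitude tone's peak-bin power to the expected noise power per
    bin.  ``snr_db = -inf`` renders noise only.
    """
    rng = np.random.default_rng() if rng is None else rng
    max_f = max((float(c.freqs.max()) for c in contours), default=0.0)
    if contours and sample_rate < 2 * (max_f + 5_000.0):
        raise ValueError(f"sample rate {sample_rate} Hz below Nyquist requirement "
                         f"for max contour frequency {max_f:.0f} Hz (+5 kHz margin)")
    end = max((c.offset_s for c in contours), default=0.5) + tail_s
    n = int(round(end * sample_rate))
    w = np.hanning(window_length)
    coherent = w.sum() / 2.0               # tone peak-bin magnitude per unit amplitude
    noise_gain = np.sqrt(np.sum(w ** 2))   # per-bin noise magnitude per unit sigma
    if np.isneginf(snr_db):
        sigma = coherent / noise_gain      # reference noise level (0 dB)
        return Recording(samples=(sigma * rng.standard_normal(n)).astype(np.float32),
                         sample_rate=sample_rate)
    sigma = coherent / (10 ** (snr_db / 20.0) * noise_gain)
    out = (sigma * rng.standard_normal(n)).astype(np.float32) if sigma > 0 else np.zeros(n, np.float32)
    for c in contours:
        i0 = int(round(c.onset_s * sample_rate))
        i1 = min(int(round(c.offset_s * sample_rate)), n)
        if i1 - i0 < 2:
            continue
        t = np.arange(i0, i1) / sample_rate
        f_inst = np.interp(t, c.times, c.freqs)
        phase = 2 * np.pi * np.cumsum(f_inst) / sample_rate
        env = np.ones(i1 - i0)
        nr = min(int(ramp_s * sample_rate), (i1 - i0) // 2)
        if nr > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
            env[:nr] = ramp
            env[-nr:] = ramp[::-1]
        amp = float(np.sqrt(c.amps.max())) if c.amps.max() > 0 else 1.0
        out[i0:i1] += (amp * env * np.sin(phase)).astype(np.float32)
    return Recording(samples=out, sample_rate=sample_rate)


@dataclass
class CohortConfig:
    """Cohort layout; defaults mirror the published study design."""

    groups: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "control_female": (7, 332), "control_male": (15, 522),
        "tp_female": (14, 614), "tp_male": (7, 1_249)})
    master_seed: int = 0
    cv: float = 0.10
    audio: bool = False
    snr_db: float = 20.0
    sample_rate: float = DEFAULT_SAMPLE_RATE
    frame_hop_s: float = DEFAULT_FRAME_HOP_S
    #: lognormal spread of per-animal call counts (median-preserving); at the
    #: study's group sizes this keeps group sample medians within ~20% of the
    #: configured medians with high probability
    count_log_sd: float = 0.15

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "groups" in d:
            d["groups"] = {g: tuple(v) for g, v in d["groups"].items()}
        return cls(**d)


def simulate_cohort(config: CohortConfig, outdir: str | Path | None = None,
                    overwrite: bool = False,
                    ) -> tuple[list[tuple[list[Contour], GroundTruth]], pd.DataFrame]:
    """Simulate every session of a cohort; optionally write truth CSVs (+WAV).

    Per-animal call counts are the group median times a lognormal factor
    (median-preserving).  Fully regenerable from ``config.master_seed``.
    """
    presets = default_presets()
    root = None
    if outdir is not None:
        root = Path(outdir)
        if root.exists() and any(root.iterdir()) and not overwrite:
            raise FileExistsError(f"{root} exists and is non-empty; pass overwrite=True")
        root.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.master_seed)
    sessions, manifest_rows = [], []
    for group, (n_animals, median_calls) in config.groups.items():
        preset = presets[group]
        preset.cv = config.cv
        for j in range(n_animals):
            child = ss.spawn(1)[0]
            seed = int(child.generate_state(1)[0] % (2 ** 31))
            rng = np.random.default_rng(child)
            n_calls = max(1, int(round(median_calls * np.exp(
                rng.normal(0.0, config.count_log_sd)))))
            animal_id = f"{group}_{j:02d}"
            contours, truth = simulate_session(
                animal_id, preset, n_calls, rng, config.frame_hop_s, seed=seed)
            sessions.append((contours, truth))
            manifest_rows.append({"animal_id": animal_id, "group": group,
                                  "n_calls": n_calls, "seed": seed})
            if root is not None:
                truth.calls.to_csv(root / f"{animal_id}_truth_calls.csv",
                                   index=False, float_format="%.17g")
                if config.audio:
                    from .io_formats import write_wav
                    rec = render_audio(contours, config.sample_rate,
                                       config.snr_db, rng)
                    write_wav(root / f"{animal_id}.wav", rec)
    manifest = pd.DataFrame(manifest_rows)
    if root is not None:
        manifest.to_csv(root / "cohort_manifest.csv", index=False)
        digest = hashlib.sha256(
            manifest.to_csv(index=False).encode()).hexdigest()
        (root / "cohort.json").write_text(json.dumps(
            {"master_seed": config.master_seed, "n_sessions": len(sessions),
             "manifest_sha256": digest}, indent=2) + "\n")
    return sessions, manifest
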