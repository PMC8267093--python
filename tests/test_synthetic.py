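import numpy as np
import pandas as pd
import pytest

from usvkit.contour import Contour
from usvkit.synthetic import (NOISE_ARCHETYPE, CallParams, CohortConfig, GroupPreset,
                              InfeasibleContourError, default_presets, make_contour,
                              render_audio, sample_call_params, sample_calls,
                              simulate_cohort, simulate_session)


def _flat_params(f=70_000.0, dur=0.05):
    return CallParams(duration_s=dur, f_min=f, f_max=f, f_start=f, f_end=f,
                      mean_freq_target=f)


class TestMakeContour:
    def test_flat_call_is_constant(self):
        c = make_contour(_flat_params())
        assert np.all(c.freqs == 70_000.0)
        assert c.duration_s == pytest.approx(0.05)

    def test_linear_chirp_is_monotone_with_midpoint_mean(self):
        p = CallParams(duration_s=0.05, f_min=60_000, f_max=70_000,
                       f_start=60_000, f_end=70_000, mean_freq_target=65_000)
        c = make_contour(p)
        assert np.all(np.diff(c.freqs) >= -1e-9)
        assert c.freqs.mean() == pytest.approx(65_000, rel=0.005)

    def test_published_style_constrained_call(self):
        # min/max/delta/mean jointly constrained, mean off the band midpoint
        p = CallParams(duration_s=0.04776, f_min=58_001, f_max=72_386,
                       f_start=65_023 - 5_279.5 / 2, f_end=65_023 + 5_279.5 / 2,
                       mean_freq_target=65_023)
        c = make_contour(p)
        assert c.freqs[0] == pytest.approx(p.f_start, rel=0.005)
        assert c.freqs[-1] == pytest.approx(p.f_end, rel=0.005)
        assert c.freqs.min() == pytest.approx(58_001, rel=0.005)
        assert c.freqs.max() == pytest.approx(72_386, rel=0.005)
        assert c.freqs.mean() == pytest.approx(65_023, rel=0.005)

    def test_infeasible_mean_raises_naming_bound(self):
        p = CallParams(duration_s=0.05, f_min=60_000, f_max=70_000,
                       f_start=65_000, f_end=65_000, mean_freq_target=75_000)
        with pytest.raises(InfeasibleContourError, match="f_max|75000"):
            make_contour(p)

    def test_jump_call_has_large_interframe_step(self, presets):
        rng = np.random.default_rng(0)
        p = sample_call_params(presets["tp_female"], 1, rng)
        c = make_contour(p)
        assert np.max(np.abs(np.diff(c.freqs))) > 10_000

    @pytest.mark.parametrize("group", list(default_presets()))
    def test_closure_on_sampled_calls(self, presets, group):
        """Truth contours recover the drawn parameters within 0.5%."""
        rng = np.random.default_rng(99)
        params, contours = sample_calls(presets[group], 150, rng)
        for p, c in zip(params, contours):
            assert c.duration_s == pytest.approx(p.duration_s, rel=1e-9)
            assert c.freqs.min() == pytest.approx(p.f_min, rel=0.005)
            assert c.freqs.max() == pytest.approx(p.f_max, rel=0.005)
            assert c.freqs[0] == pytest.approx(p.f_start, rel=0.005)
            assert c.freqs[-1] == pytest.approx(p.f_end, rel=0.005)
            assert c.freqs.mean() == pytest.approx(p.mean_freq_target, rel=0.005)


class TestSampling:
    def test_cv_zero_draws_equal_preset_means(self, presets):
        preset = default_presets()["control_male"]
        preset.cv = 0.0
        rng = np.random.default_rng(1)
        draws = [sample_call_params(preset, 5, rng, archetype_scale=False)
                 for _ in range(5)]
        for p in draws:
            assert p.duration_s * 1000 == pytest.approx(preset.duration_ms)
            assert p.f_max - p.f_min == pytest.approx(preset.freq_dynamic_hz)
            assert p.mean_freq_target == pytest.approx(preset.mean_freq_hz, rel=1e-6)
            assert p.f_end - p.f_start == pytest.approx(preset.delta_freq_hz)

    def test_same_seed_gives_identical_draws(self, presets):
        a = sample_call_params(presets["tp_male"], 3, np.random.default_rng(7))
        b = sample_call_params(presets["tp_male"], 3, np.random.default_rng(7))
        assert a == b

    def test_calibration_mean_of_many_draws(self, presets):
        """Sample mean of duration over many draws matches the preset mean."""
        rng = np.random.default_rng(5)
        preset = presets["tp_female"]
        durs = [sample_call_params(preset, int(a), rng, archetype_scale=False).duration_s
                for a in rng.choice(np.arange(1, 10), 10_000, p=preset.mixture_weights)]
        assert np.mean(durs) * 1000 == pytest.approx(47.76, rel=0.01)

    def test_all_draws_satisfy_invariants(self, presets):
        rng = np.random.default_rng(17)
        for group, preset in presets.items():
            for _ in range(200):
                arch = int(rng.integers(1, 10))
                p = sample_call_params(preset, arch, rng)
                assert p.f_min <= min(p.f_start, p.f_end, p.mean_freq_target)
                assert p.f_max >= max(p.f_start, p.f_end, p.mean_freq_target)
                assert p.duration_s > 0


class TestSession:
    def test_empty_session(self, presets, rng):
        contours, truth = simulate_session("m0", presets["control_female"], 0, rng)
        assert contours == [] and len(truth.calls) == 0

    def test_degenerate_chain_alternates(self, presets, rng):
        import dataclasses
        P = np.full((9, 9), 1e-12)
        P[4, 1] = 1.0  # 5 -> 2
        P[1, 4] = 1.0  # 2 -> 5
        for i in (0, 2, 3, 5, 6, 7, 8):
            P[i, 4] = 1.0
        P = P / P.sum(axis=1, keepdims=True)
        pi = np.zeros(9)
        pi[4] = 1.0
        preset = dataclasses.replace(default_presets()["control_female"],
                                     transition=P, mixture_weights=pi)
        _, truth = simulate_session("m0", preset, 10, rng)
        seq = truth.calls["archetype"].tolist()
        assert seq == [5, 2] * 5

    def test_onsets_strictly_increasing_and_nonoverlapping(self, presets, rng):
        contours, truth = simulate_session("m0", presets["tp_male"], 50, rng)
        t = truth.calls
        assert (t["onset_s"].diff().dropna() > 0).all()
        assert (t["onset_s"].shift(-1).dropna().to_numpy()
                >= t["offset_s"].to_numpy()[:-1]).all()

    def test_bigram_frequencies_match_chain(self, presets):
        """Empirical conditional bigram frequencies converge to the chain."""
        rng = np.random.default_rng(11)
        preset = presets["tp_male"]
        n = 50_001
        states = np.empty(n, dtype=int)
        states[0] = rng.choice(9, p=preset.mixture_weights)
        for i in range(1, n):
            states[i] = rng.choice(9, p=preset.transition[states[i - 1]])
        counts = np.zeros((9, 9))
        np.add.at(counts, (states[:-1], states[1:]), 1)
        cond = counts / counts.sum(axis=1, keepdims=True)
        assert np.max(np.abs(cond - preset.transition)) < 0.02


class TestRenderAudio:
    def test_pure_tone_peaks_at_its_frequency(self):
        c = make_contour(_flat_params(70_000, 0.05))
        rec = render_audio([c.shifted(0.2)], snr_db=40.0,
                           rng=np.random.default_rng(0))
        from usvkit.detection import compute_spectrogram
        spec = compute_spectrogram(rec)
        frames = (spec.frame_times > 0.21) & (spec.frame_times < 0.24)
        peak_bins = spec.power[frames].argmax(axis=1)
        peak_freqs = spec.bin_freqs[peak_bins]
        assert np.all(np.abs(peak_freqs - 70_000) <= spec.bin_width_hz)

    def test_nyquist_violation_raises(self):
        c = make_contour(_flat_params(70_000, 0.05))
        with pytest.raises(ValueError, match="Nyquist"):
            render_audio([c.shifted(0.1)], sample_rate=120_000,
                         rng=np.random.default_rng(0))

    def test_noise_only_renders_pure_noise(self):
        rec = render_audio([], snr_db=-np.inf, rng=np.random.default_rng(0),
                           tail_s=1.0)
        assert rec.samples.size > 0
        assert np.std(rec.samples) > 0


class TestCohort:
    SMALL = {"control_female": (2, 30), "control_male": (2, 30),
             "tp_female": (2, 30), "tp_male": (2, 30)}

    def test_truth_csvs_are_reproducible_bytes(self, tmp_path):
        cfg = CohortConfig(groups=self.SMALL, master_seed=3)
        simulate_cohort(cfg, outdir=tmp_path / "a")
        simulate_cohort(cfg, outdir=tmp_path / "b")
        for pa in sorted((tmp_path / "a").glob("*_truth_calls.csv")):
            pb = tmp_path / "b" / pa.name
            assert pa.read_bytes() == pb.read_bytes()

    def test_refuses_existing_output_without_overwrite(self, tmp_path):
        cfg = CohortConfig(groups=self.SMALL, master_seed=3)
        simulate_cohort(cfg, outdir=tmp_path)
        with pytest.raises(FileExistsError):
            simulate_cohort(cfg, outdir=tmp_path)
        simulate_cohort(cfg, outdir=tmp_path, overwrite=True)

    def test_default_cohort_mirrors_study_design(self):
        """43 sessions; per-group call-count medians near the configured ones."""
        cfg = CohortConfig(master_seed=0)
        sessions, manifest = simulate_cohort(cfg)
        assert len(sessions) == 43
        expected = {"control_female": 332, "control_male": 522,
                    "tp_female": 614, "tp_male": 1_249}
        med = manifest.groupby("group")["n_calls"].median()
        for group, target in expected.items():
            assert med[group] == pytest.approx(target, rel=0.20)
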