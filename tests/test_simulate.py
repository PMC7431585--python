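"""Design generator, EEG simulator and behavioral simulator."""

import numpy as np
import pandas as pd
import pytest

from alphalat.config import RETROCUE_ONSET_MS
from alphalat.containers import condition_of
from alphalat.lateralization import ali_map, window_mean
from alphalat.simulate import (
    SimParams,
    alpha_band_calibration,
    generate_design,
    pink_noise,
    simulate_behavior,
    simulate_eeg,
    simulate_subject,
    _condition_amplitudes,
)
from alphalat.timefreq import build_wavelet_family, morlet_power


class TestDesign:
    def test_full_scale_proportions_exact(self, design800):
        d = design800
        counts = d["retrocue"].value_counts()
        # 25% per retro-cue token; "li"+"re" = 50% target lateral
        assert counts["target_lateral_left"] == 200
        assert counts["target_lateral_right"] == 200
        assert counts["distractor_lateral"] == 200
        assert counts["neutral"] == 200
        # probe composition: cued (YES) 50%, non-cued and new (NO) 25% each
        probes = d["probe"].value_counts()
        assert probes["cued"] == 400
        assert probes["noncued"] == 200
        assert probes["new"] == 200
        # blocks of 100
        assert (d["block"].value_counts() == 100).all()
        assert sorted(d["block"].unique()) == list(range(1, 9))

    def test_small_design_scales_proportionally(self):
        d = generate_design(16, seed=1)
        assert (d["retrocue"].value_counts() == 4).all()
        assert d["probe"].value_counts()["cued"] == 8

    def test_neutral_trials_never_noncued(self, design800):
        neutral = design800[design800["retrocue"] == "neutral"]
        assert set(neutral["probe"]) <= {"cued", "new"}

    def test_target_lateral_sides_match_cue(self, design800):
        li = design800[design800["retrocue"] == "target_lateral_left"]
        re = design800[design800["retrocue"] == "target_lateral_right"]
        assert (li["precue_side"] == "left").all()
        assert (re["precue_side"] == "right").all()

    def test_indivisible_count_rejected(self):
        with pytest.raises(ValueError, match="divisible by 16"):
            generate_design(100)

    def test_reproducible_from_seed(self):
        a, b = generate_design(64, seed=7), generate_design(64, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = generate_design(64, seed=8)
        assert not a["retrocue"].equals(c["retrocue"])


class TestPinkNoise:
    def test_rms_matches_target(self, rng):
        x, _ = pink_noise(rng, 4096, 500.0, 1.0, 10.0, 400)
        assert x.std() == pytest.approx(10.0, rel=0.02)

    def test_spectrum_slope_is_one_over_f(self, rng):
        x, _ = pink_noise(rng, 8192, 500.0, 1.0, 10.0, 200)
        f = np.fft.rfftfreq(8192, 1 / 500.0)
        psd = (np.abs(np.fft.rfft(x, axis=0)) ** 2).mean(axis=1)
        band = (f > 1) & (f < 100)
        slope = np.polyfit(np.log(f[band]), np.log(psd[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)


class TestEEGCalibration:
    def test_injected_ali_inverts_to_power_ratio(self):
        # contralateral/ipsilateral expected power ratio (1-L)/(1+L)
        params = SimParams(n_trials=16)
        k, nf = alpha_band_calibration(params)
        amps = _condition_amplitudes(params, {"target_lateral": 0.2})
        a_ipsi, a_contra = amps["target_lateral"]
        ratio = (nf + k * a_contra**2) / (nf + k * a_ipsi**2)
        assert ratio == pytest.approx((1 - 0.2) / (1 + 0.2), rel=1e-9)

    def test_zero_ali_gives_unit_ratio(self):
        params = SimParams(n_trials=16)
        amps = _condition_amplitudes(params, {"neutral": 0.0})
        a_ipsi, a_contra = amps["neutral"]
        assert a_ipsi == pytest.approx(a_contra)
        assert a_ipsi == pytest.approx(params.alpha_amp_uv)

    def test_infeasible_ali_raises(self):
        params = SimParams(n_trials=16, alpha_amp_uv=0.5)
        with pytest.raises(ValueError, match="infeasible"):
            _condition_amplitudes(params, {"target_lateral": 0.9})


class TestEEGSimulation:
    def test_deterministic_given_seed(self):
        params = SimParams(n_trials=16, seed=4)
        design = generate_design(16, seed=4)
        a = simulate_eeg(design, params, rng=np.random.default_rng(1))
        b = simulate_eeg(design, params, rng=np.random.default_rng(1))
        np.testing.assert_array_equal(a.data, b.data)

    def test_missing_cluster_channels_rejected(self):
        params = SimParams(n_trials=16, channels=("PO7", "PO8", "Cz"))
        with pytest.raises(ValueError, match="cluster channels"):
            simulate_eeg(generate_design(16), params)

    def test_estimated_ali_sign_tracks_injection(self, fast_config):
        """Recover the injected lateralization sign per condition from the
        full wavelet analysis of a single simulated subject."""
        params = SimParams(n_trials=96, ali_subject_sd=0.0, lapse_rate=0.0, seed=2)
        design = generate_design(96, seed=2)
        epochs = simulate_eeg(design, params, rng=np.random.default_rng(2))
        fam = build_wavelet_family(fast_config.f_min_hz, fast_config.f_max_hz,
                                   fast_config.n_freqs, srate=epochs.srate)
        tf = morlet_power(epochs, fam, channels=fast_config.cluster_channels,
                          time_grid=fast_config.time_grid)
        wm = {}
        for cond in ("target_lateral", "distractor_lateral", "neutral"):
            m = ali_map(tf, design, cond)
            wm[cond] = window_mean(m, tf.freqs, tf.times_ms,
                                   window_ms=fast_config.window_epoch_ms)
        assert wm["target_lateral"] > 0.03
        assert wm["distractor_lateral"] < -0.03
        assert abs(wm["neutral"]) < abs(wm["target_lateral"])

    def test_zero_injection_gives_near_zero_ali(self, fast_config):
        params = SimParams(n_trials=96, ali_target_lateral=0.0,
                           ali_distractor_lateral=0.0, ali_subject_sd=0.0,
                           lapse_rate=0.0, seed=6)
        design = generate_design(96, seed=6)
        epochs = simulate_eeg(design, params, rng=np.random.default_rng(6))
        fam = build_wavelet_family(fast_config.f_min_hz, fast_config.f_max_hz,
                                   fast_config.n_freqs, srate=epochs.srate)
        tf = morlet_power(epochs, fam, channels=fast_config.cluster_channels,
                          time_grid=fast_config.time_grid)
        m = ali_map(tf, design, "target_lateral")
        wm = window_mean(m, tf.freqs, tf.times_ms,
                         window_ms=fast_config.window_epoch_ms)
        assert abs(wm) < 0.05


class TestBehavior:
    def _big_null_params(self, **kw):
        defaults = dict(n_trials=1600, rt_benefit_ms=0.0, interference_ms=0.0,
                        rt_subject_sd_ms=0.0, rt_effect_sd_ms=0.0,
                        lapse_rate=0.0, seed=3)
        defaults.update(kw)
        return SimParams(**defaults)

    def test_null_effects_equal_condition_means(self):
        params = self._big_null_params()
        t = simulate_behavior(generate_design(1600, seed=3), params)
        sel = t[t["retrocue"] != "neutral"]["rt_ms"].mean()
        neu = t[t["retrocue"] == "neutral"]["rt_ms"].mean()
        assert sel == pytest.approx(neu, abs=25.0)

    def test_rt_benefit_converges_to_parameter(self):
        params = self._big_null_params(rt_benefit_ms=60.0)
        frames = [
            simulate_behavior(generate_design(1600, seed=3), params,
                              rng=np.random.default_rng(100 + i))
            for i in range(5)
        ]
        t = pd.concat(frames)
        diff = (t[t["retrocue"] != "neutral"]["rt_ms"].mean()
                - t[t["retrocue"] == "neutral"]["rt_ms"].mean())
        assert diff == pytest.approx(-60.0, abs=15.0)

    def test_interference_slows_and_impairs_noncued(self):
        params = self._big_null_params(interference_ms=80.0, noncued_error_factor=3.0)
        t = simulate_behavior(generate_design(1600, seed=3), params)
        noncued = t[t["probe"] == "noncued"]
        new = t[t["probe"] == "new"]
        assert noncued["rt_ms"].mean() > new["rt_ms"].mean() + 30
        assert noncued["correct"].mean() < new["correct"].mean()

    def test_perfect_accuracy_without_lapses(self):
        params = SimParams(n_trials=160, accuracy_base=1.0, lapse_rate=0.0, seed=1)
        t = simulate_behavior(generate_design(160, seed=1), params)
        assert t["correct"].all()

    def test_negative_shift_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimParams(rt_benefit_ms=-1.0)
        with pytest.raises(ValueError):
            SimParams(interference_ms=-5.0)


def test_subject_end_to_end_reproducible(fast_params):
    t1, e1 = simulate_subject(fast_params, seed=77)
    t2, e2 = simulate_subject(fast_params, seed=77)
    pd.testing.assert_frame_equal(t1, t2)
    np.testing.assert_array_equal(e1.data, e2.data)
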