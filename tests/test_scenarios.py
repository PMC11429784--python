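"""End-to-end synthetic experiments: sweep, vibration, physio, MIMO head."""

import numpy as np
import pytest
from scipy.signal import find_peaks

import bptsim as b
from bptsim.scenarios import (ScenarioConfig, count_peaks, estimate_heart_rate,
                              gen_mimo_head, gen_physio, gen_translation_sweep,
                              gen_vibration_event)


class TestScenarioConfig:
    def test_yaml_round_trip(self):
        cfg = ScenarioConfig(kind="physio", seed=5, noise_sigma=0.01,
                             params={"heart_rate_bpm": 70})
        back = ScenarioConfig.from_yaml(cfg.to_yaml())
        assert back == cfg
        assert back.config_hash() == cfg.config_hash()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            ScenarioConfig(kind="nope")

    def test_unknown_field_named_in_error(self):
        with pytest.raises(ValueError, match="frequenzies"):
            ScenarioConfig.from_yaml("kind: physio\nfrequenzies: [1]\n")

    def test_missing_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            ScenarioConfig.from_yaml("seed: 3\n")


class TestTranslationSweep:
    def test_modulation_and_peaks_increase_with_frequency(self, sweep_result):
        """Standing waves at 2.4 GHz: more peaks, deeper modulation than 127.8 MHz."""
        res = sweep_result
        n = res.unique_offsets.size
        pt = np.abs(res.envelopes["pt_127.8MHz"][:n])
        bpt = np.abs(res.envelopes["bpt_2463.9MHz"][:n])
        for ci in range(pt.shape[1]):
            assert count_peaks(bpt[:, ci]) >= count_peaks(pt[:, ci])
            pm_pt, _ = b.percent_modulation(pt[:, ci])
            pm_bpt, _ = b.percent_modulation(bpt[:, ci])
            assert np.ptp(pm_bpt) > np.ptp(pm_pt)

    def test_adjacent_coils_differ_more_at_high_frequency(self, sweep_result):
        """Local standing-wave sampling decorrelates adjacent coil envelopes."""
        res = sweep_result
        n = res.unique_offsets.size

        def nrms_diff(env):
            a = np.abs(env[:n, 0]) / np.abs(env[:n, 0]).mean()
            c = np.abs(env[:n, 1]) / np.abs(env[:n, 1]).mean()
            return np.sqrt(np.mean((a - c) ** 2))

        assert nrms_diff(res.envelopes["bpt_2463.9MHz"]) > nrms_diff(
            res.envelopes["pt_127.8MHz"])

    def test_round_trip_through_kspace(self, sweep_result):
        res = sweep_result
        off = res.raw.meta["tone_offsets"]["bpt_2463.9MHz"]
        series = b.extract_tone(res.raw, off)
        env = res.envelopes["bpt_2463.9MHz"]
        # noise-limited recovery of the embedded envelope
        err = np.abs(series.values - env) / np.abs(env).mean()
        assert np.median(err) < 0.01

    def test_zero_travel_gives_flat_envelopes(self):
        cfg = ScenarioConfig(kind="translation_sweep", seed=2,
                             frequencies_hz=(127.8e6,),
                             params={"travel_m": 0.0, "n_positions": 3,
                                     "n_repeats": 1})
        res = gen_translation_sweep(cfg)
        env = np.abs(res.envelopes["pt_127.8MHz"])
        pm, _ = b.percent_modulation(env[:, 0])
        np.testing.assert_allclose(pm, 0.0, atol=1e-6)

    def test_seed_determinism(self):
        cfg = ScenarioConfig(kind="translation_sweep", seed=3,
                             frequencies_hz=(127.8e6,),
                             params={"n_positions": 5, "n_repeats": 1})
        r1 = gen_translation_sweep(cfg)
        r2 = gen_translation_sweep(cfg)
        np.testing.assert_array_equal(r1.raw.data, r2.raw.data)
        assert r1.raw.meta["config_hash"] == r2.raw.meta["config_hash"]


@pytest.fixture(scope="module")
def vibration_result():
    return gen_vibration_event(ScenarioConfig(kind="vibration", seed=4,
                                              noise_sigma=1e-4))


@pytest.fixture(scope="module")
def physio_result():
    return gen_physio(ScenarioConfig(kind="physio", seed=6, noise_sigma=1e-3))


@pytest.fixture(scope="module")
def mimo_result():
    return gen_mimo_head(ScenarioConfig(kind="mimo_head", seed=8,
                                        noise_sigma=1e-3))


class TestVibration:

    def test_overdamped_limit_is_pure_step(self):
        cfg = ScenarioConfig(kind="vibration", seed=4, noise_sigma=0.0,
                             params={"zeta1": 50.0, "zeta2": 50.0})
        res = gen_vibration_event(cfg)
        d = res.displacement.values
        # monotone ramp segments, no oscillation beyond the two ramps
        assert count_peaks(d, prominence_frac=0.01) <= 1

    def test_ring_down_log_decrement_recovers_zeta(self, vibration_result):
        """Damping ratio from successive BPT ring-down peak amplitudes (<5%)."""
        raw = vibration_result.raw
        off = raw.meta["tone_offsets"]["bpt"]
        env = np.abs(b.extract_tone(raw, off).values[:, 0])
        fs = vibration_result.displacement.sample_rate
        t0 = vibration_result.events[0]["t_ring_s"]
        zeta_true = vibration_result.events[0]["zeta"]
        f0 = vibration_result.events[0]["f0_hz"]
        t = vibration_result.displacement.times
        window = (t > t0 + 0.02) & (t < t0 + 1.5)
        base = np.median(env[(t > t0 + 4.0) & (t < t0 + 5.0)])
        ring = env[window] - base
        peaks, _ = find_peaks(ring, distance=int(0.5 * fs / f0))
        good = ring[peaks] > 0.05 * ring[peaks].max()
        # log-decrement as the slope of log peak amplitude vs time
        slope = np.polyfit(t[window][peaks][good],
                           np.log(ring[peaks][good]), 1)[0]
        zeta_est = -slope / (2 * np.pi * f0)
        assert zeta_est == pytest.approx(zeta_true, rel=0.05)

    def test_second_event_more_damped(self, vibration_result):
        assert vibration_result.events[1]["zeta"] > vibration_result.events[0]["zeta"]

    def test_accelerometer_double_integration_matches_bpt(self, vibration_result):
        """Displacement from the accelerometer correlates with the BPT envelope."""
        raw = vibration_result.raw
        off = raw.meta["tone_offsets"]["bpt"]
        env = np.abs(b.extract_tone(raw, off).values[:, 0])
        fs = vibration_result.displacement.sample_rate
        d_acc = b.accel_to_displacement(vibration_result.accelerometer.values, fs, 2.5)
        env_hp = b.zero_phase_highpass(env, 2.5, fs)
        r = np.corrcoef(d_acc, env_hp)[0, 1]
        assert abs(r) > 0.95

    def test_invalid_damping_rejected(self):
        cfg = ScenarioConfig(kind="vibration", seed=1, params={"zeta1": -0.1})
        with pytest.raises(ValueError, match="damping"):
            gen_vibration_event(cfg)


class TestPhysio:

    def test_respiratory_rate_recovered_from_extraction(self, physio_result):
        raw = physio_result.raw
        off = raw.meta["tone_offsets"]["bpt"]
        env = np.abs(b.extract_tone(raw, off).values[:, 0])
        fs = physio_result.traces["respiration"].sample_rate
        spec = np.abs(np.fft.rfft(env - env.mean()))
        freqs = np.fft.rfftfreq(env.size, 1 / fs)
        band = (freqs > 0.05) & (freqs < 0.9)
        peak = freqs[band][np.argmax(spec[band])]
        assert peak == pytest.approx(physio_result.respiratory_rate_hz, rel=0.1)

    def test_heart_rate_recovered_from_dbcg_template(self, physio_result):
        """Beat spacing of the dBCG wave train gives the configured HR +-1 bpm."""
        card = physio_result.traces["cardiac_dbcg"].values
        fs = physio_result.traces["cardiac_dbcg"].sample_rate
        hr = estimate_heart_rate(card, fs)
        assert hr == pytest.approx(physio_result.heart_rate_bpm, abs=1.0)

    def test_zero_cardiac_amplitude_leaves_respiration_only(self):
        def cardiac_band_power(cardiac_amplitude):
            cfg = ScenarioConfig(kind="physio", seed=6, noise_sigma=0.0,
                                 params={"cardiac_amplitude": cardiac_amplitude,
                                         "bulk_amplitude": 0.0})
            res = gen_physio(cfg)
            off = res.raw.meta["tone_offsets"]["bpt"]
            env = np.abs(b.extract_tone(res.raw, off).values[:, 0])
            fs = res.traces["respiration"].sample_rate
            win = np.hanning(env.size)
            spec = np.abs(np.fft.rfft((env - env.mean()) * win)) ** 2
            freqs = np.fft.rfftfreq(env.size, 1 / fs)
            return spec[(freqs > 0.9) & (freqs < 10.0)].sum()

        # power above 0.9 Hz collapses to the (zero-)noise floor
        assert cardiac_band_power(0.0) < 1e-4 * cardiac_band_power(0.06)

    def test_zero_stiffness_reverts_to_single_peak_per_beat(self):
        cfg = ScenarioConfig(kind="physio", seed=6,
                             params={"stiffness": 0.0})
        res = gen_physio(cfg)
        card = res.traces["cardiac_dbcg"].values
        fs = res.traces["cardiac_dbcg"].sample_rate
        period = 60.0 / res.heart_rate_bpm
        one_beat = card[int(2 * period * fs):int(3 * period * fs)]
        peaks, _ = find_peaks(one_beat,
                              prominence=0.1 * np.ptp(one_beat))
        assert peaks.size == 1

    def test_stiff_array_shows_multi_peak_wave_train(self, physio_result):
        card = physio_result.traces["cardiac_dbcg"].values
        fs = physio_result.traces["cardiac_dbcg"].sample_rate
        period = 60.0 / physio_result.heart_rate_bpm
        one_beat = np.abs(card[int(2 * period * fs):int(3 * period * fs)])
        peaks, _ = find_peaks(one_beat, prominence=0.1 * np.ptp(one_beat))
        assert peaks.size >= 2

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            gen_physio(ScenarioConfig(kind="physio",
                                      params={"heart_rate_bpm": -10}))


class TestMimoHead:

    def test_shapes_match_protocol(self, mimo_result):
        assert mimo_result.calibration.matrix.shape == (115, 44)
        assert mimo_result.inference.matrix.shape == (50, 44)
        assert mimo_result.calibration_truth.shape == (115, 6)

    def test_zero_motion_gives_constant_frames(self):
        cfg = ScenarioConfig(kind="mimo_head", seed=8, noise_sigma=0.0,
                             params={"n_inference_frames": 10,
                                     "inference_motion_amplitude": 0.0})
        res = gen_mimo_head(cfg)
        assert np.ptp(res.inference.matrix, axis=0).max() < 1e-9

    def test_end_to_end_regression_recovers_motion(self, mimo_result):
        """pca_fit(calibration) -> project inference -> regress to reg-PCs."""
        model = b.pca_fit(mimo_result.calibration, 3)
        scores = b.pca_project(model, mimo_result.inference)
        reg = b.savgol_smooth(mimo_result.inference_truth, 11, 4)
        reg_model = b.pca_fit(reg, 3)
        reg_pcs = b.pca_project(reg_model, reg)
        for k in range(2):  # nod+shake only excite 2 directions
            fit = b.regress_multicoil(scores, reg_pcs[:, k])
            assert fit.pearson_r >= 0.95

    def test_both_antennas_at_least_as_good_as_single(self, mimo_result):
        reg = b.savgol_smooth(mimo_result.inference_truth, 11, 4)
        reg_model = b.pca_fit(reg, 2)
        reg_pcs = b.pca_project(reg_model, reg)
        for k in range(2):
            r_both = b.regress_multicoil(mimo_result.inference,
                                         reg_pcs[:, k]).pearson_r
            for a in (0, 1):
                r_single = b.regress_multicoil(
                    mimo_result.inference.select_antenna(a), reg_pcs[:, k]).pearson_r
                assert r_both >= r_single - 1e-9

    def test_inference_scores_form_crossing_paths(self, mimo_result):
        """Nod and shake trace two distinct 1-D trajectories in PC space."""
        model = b.pca_fit(mimo_result.calibration, 3)
        scores = b.pca_project(model, mimo_result.inference)
        labels = mimo_result.inference.labels
        paths = {}
        for lab in ("nod", "shake"):
            S = scores[labels == lab]
            S = S - S.mean(axis=0)
            _, _, vt = np.linalg.svd(S, full_matrices=False)
            resid = S - np.outer(S @ vt[0], vt[0])
            paths[lab] = (vt[0], np.sqrt(np.mean(resid**2)), S)
        # separation: each path's extent along its own line vs the other's
        for a, c in (("nod", "shake"), ("shake", "nod")):
            dir_a, spread_a, S_a = paths[a]
            other_resid = S_a - np.outer(S_a @ paths[c][0], paths[c][0])
            sep = np.sqrt(np.mean(other_resid**2))
            assert sep > 3 * spread_a

    def test_separability_of_nod_vs_shake_scores(self, mimo_result):
        model = b.pca_fit(mimo_result.calibration, 3)
        scores = b.pca_project(model, mimo_result.inference)
        res = b.separability_plane(scores, mimo_result.inference.labels)
        assert res.loo_accuracy > 0.8

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError, match="box"):
            gen_mimo_head(ScenarioConfig(kind="mimo_head",
                                         params={"box_rotation_deg": -1}))
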