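"""Generator properties: kinematic laws, phase reversal, reproducibility."""

import numpy as np
import pytest

import smd
from smd.synthetic import CouplingSpec, _coupling_z


class TestConfigValidation:
    def test_rejects_nonphysical_cycle_rate(self):
        with pytest.raises(ValueError, match="non-physical"):
            smd.SimulationConfig(cycle_rate_normal=15.0)

    def test_rejects_bad_erd_depth(self):
        with pytest.raises(ValueError, match="erd_depth"):
            smd.SimulationConfig(erd_depth=1.5)

    def test_negative_device_lag_allowed(self):
        cfg = smd.SimulationConfig(device_lag=-50)
        assert cfg.device_lag == -50


class TestArticulatorySession:
    def test_about_ten_productions_per_normal_trial_set(self):
        """~10 cycles fit a 12 s normal-rate trial set."""
        cfg = smd.SimulationConfig(n_trial_sets=2, seed=3)
        _, _, truth = smd.simulate_articulatory_session(cfg)
        counts = truth.cycles.groupby("trial_set").size()
        assert len(counts) == 2
        assert all(abs(c - 10) <= 1 for c in counts)

    def test_degenerate_jitter_gives_identical_cycles(self):
        cfg = smd.SimulationConfig(n_trial_sets=2, amplitude_sd=0.0,
                                   duration_jitter=0.0, seed=1)
        _, _, truth = smd.simulate_articulatory_session(cfg)
        assert truth.cycles.amplitude.nunique() == 1
        assert np.allclose(truth.cycles.d_open, truth.cycles.d_open.iloc[0])
        assert np.allclose(truth.cycles.stiffness_open,
                           truth.cycles.stiffness_open.iloc[0])

    def test_landmarks_strictly_increasing(self, articulatory_session):
        _, _, truth = articulatory_session
        lm = truth.cycles[["t1", "t2", "t3", "t4"]].to_numpy()
        assert (np.diff(lm, axis=1) > 0).all()

    def test_analytic_peak_velocity(self, articulatory_session):
        """Raised-cosine closed form: v_peak = A*pi/(2D)."""
        _, _, truth = articulatory_session
        expected = truth.cycles.amplitude * np.pi / (2 * truth.cycles.d_open)
        assert np.allclose(truth.cycles.peak_velocity_open, expected)

    def test_velocity_linear_in_amplitude(self, articulatory_session):
        _, _, truth = articulatory_session
        r = np.corrcoef(truth.cycles.amplitude,
                        truth.cycles.peak_velocity_open)[0, 1]
        assert r >= 0.9

    def test_stiffness_strictly_decreasing_in_duration(self, articulatory_session):
        _, _, truth = articulatory_session
        df = truth.cycles.sort_values("d_open")
        assert (np.diff(df.stiffness_open) < 0).all()

    @pytest.mark.parametrize("utterance,expected_sign", [("ipa", -1), ("api", 1)])
    def test_phase_reversal(self, utterance, expected_sign):
        """BC minima fall on the descending (ipa) / ascending (api) TB limb."""
        cfg = smd.SimulationConfig(n_trial_sets=2, trial_set_duration=8.0,
                                   utterance=utterance, seed=5)
        tracks, _, truth = smd.simulate_articulatory_session(cfg)
        tb = smd.compute_gesture(tracks["TB"], tracks["NAS"], "xy", "TB")
        slope = np.gradient(tb.magnitude, tb.time)
        # BC minima at interior cycle starts
        t_min = truth.cycles.groupby("trial_set").t_start.apply(
            lambda s: s.iloc[1:]).to_numpy()
        signs = np.sign(slope[np.searchsorted(tb.time, t_min)])
        assert (signs == expected_sign).all()

    def test_acoustic_bursts_at_closures(self, articulatory_session):
        _, acoustic, truth = articulatory_session
        at_closure = np.interp(truth.cycles.t4, acoustic.time, acoustic.data)
        assert (at_closure > 0.9).all()

    def test_bit_reproducible(self, small_config):
        t1, a1, g1 = smd.simulate_articulatory_session(small_config)
        t2, a2, g2 = smd.simulate_articulatory_session(small_config)
        assert np.array_equal(t1["UL"].position, t2["UL"].position)
        assert np.array_equal(a1.data, a2.data)
        assert g1.cycles.equals(g2.cycles)


class TestLeadfield:
    def test_shape_contract(self):
        lf = smd.make_leadfield(64, (5, 5, 5))
        assert lf.gain.shape == (64, 125, 3)

    def test_orientation_blocks_full_rank(self, leadfield):
        ranks = [np.linalg.matrix_rank(leadfield.gain[:, p, :])
                 for p in range(leadfield.n_points)]
        assert min(ranks) == 3

    def test_deterministic_under_seed(self):
        a = smd.make_leadfield(16, (3, 3, 3), seed=4)
        b = smd.make_leadfield(16, (3, 3, 3), seed=4)
        assert np.array_equal(a.gain, b.gain)

    def test_coincident_grid_points_flagged(self):
        lf = smd.make_leadfield(16, (3, 3, 3), grid_spacing=0.0)
        assert "degenerate_point_pairs" in lf.metadata


class TestMEGSession:
    def test_sensor_count_mismatch_rejected(self, small_config,
                                            articulatory_session):
        _, acoustic, truth = articulatory_session
        lf = smd.make_leadfield(8, (3, 3, 3))
        with pytest.raises(ValueError, match="sensors"):
            smd.simulate_meg_session(small_config, lf, truth, acoustic)

    def test_bit_reproducible(self, small_config, articulatory_session, leadfield):
        _, acoustic, truth = articulatory_session
        r1, _ = smd.simulate_meg_session(small_config, leadfield, truth, acoustic)
        r2, _ = smd.simulate_meg_session(small_config, leadfield, truth, acoustic)
        assert np.array_equal(r1.data, r2.data)

    def test_beta_erd_during_speech(self, small_config, articulatory_session,
                                    leadfield, meg_session):
        """Beta source power drops by ~(1-erd_depth)^2 during trial sets."""
        from scipy import signal as sg
        _, _, _ = articulatory_session
        rec, truth = meg_session
        cfg = small_config
        sos = sg.butter(4, cfg.beta_band, btype="band", fs=rec.sfreq, output="sos")
        g = leadfield.gain[:, truth.source_index, :] @ truth.source_orientation
        vs = (g / np.linalg.norm(g)) @ sg.sosfiltfilt(sos, rec.data, axis=-1)
        t = (np.arange(rec.n_samples) - truth.device_lag) / rec.sfreq
        in_speech = np.zeros_like(t, bool)
        for lo, hi in truth.trial_set_windows:
            in_speech |= (t >= lo + 0.5) & (t < hi - 0.5)
        in_rest = np.zeros_like(t, bool)
        for k in range(len(truth.trial_set_windows) - 1):
            in_rest |= ((t >= truth.trial_set_windows[k, 1] + 0.5)
                        & (t < truth.trial_set_windows[k + 1, 0] - 0.5))
        ratio = vs[in_speech].var() / vs[in_rest].var()
        expected = (1 - cfg.erd_depth) ** 2
        assert ratio < 0.6  # well below 1: desynchronisation
        assert abs(ratio - expected) < 0.2

    def test_single_source_noiseless_covariance_rank_one(self, small_config,
                                                         articulatory_session,
                                                         leadfield):
        """In the source band the noiseless sensor covariance is rank 1."""
        _, acoustic, truth = articulatory_session
        cfg = small_config.replace(noise_sd=0.0, artifact_gain=0.0)
        rec, _ = smd.simulate_meg_session(cfg, leadfield, truth, acoustic)
        C = np.cov(rec.data)
        ev = np.linalg.eigvalsh(C)
        assert ev[-1] / ev[-2] > 1e6

    def test_coupling_orders_premovement_beta_power(self, small_config,
                                                    articulatory_session,
                                                    leadfield):
        """gain > 0 makes pre-movement coupling-band power monotone in the
        kinematic parameter; gain = 0 shows no such ordering."""
        from scipy import signal as sg
        from scipy.stats import spearmanr
        _, acoustic, truth0 = articulatory_session
        rhos = {}
        for gain in (0.0, 1.0):
            cfg = small_config.replace(
                coupling=CouplingSpec(parameter="stiffness", gain=gain,
                                      onset_lead_ms=90.0, duration_ms=300.0,
                                      band=(18.0, 22.0)),
                noise_sd=0.1, artifact_gain=0.0)
            rec, truth = smd.simulate_meg_session(cfg, leadfield, truth0, acoustic)
            sos = sg.butter(4, (18, 22), btype="band", fs=rec.sfreq, output="sos")
            g = leadfield.gain[:, truth.source_index, :] @ truth.source_orientation
            vs = (g / np.linalg.norm(g)) @ sg.sosfiltfilt(sos, rec.data, axis=-1)
            power = []
            for t1 in truth.cycles.t1:
                i0 = int((t1 - 0.09) * rec.sfreq) + truth.device_lag
                power.append((vs[i0:i0 + int(0.3 * rec.sfreq)] ** 2).mean())
            rhos[gain] = spearmanr(truth.cycles.stiffness_open, power).statistic
        # single-trial narrowband power is a few-dof estimate, so the ordering
        # is strong but not perfect
        assert rhos[1.0] > 0.5
        assert abs(rhos[0.0]) < 0.35
        assert rhos[1.0] - rhos[0.0] > 0.3

    def test_coupling_z_monotone_in_parameter(self):
        vals = np.array([3.0, 1.0, 2.0, 5.0])
        z = _coupling_z(vals)
        assert np.array_equal(np.argsort(z), np.argsort(vals))
        assert z.min() == -1.0 and z.max() == 1.0


class TestTrialBandPower:
    def test_shapes_and_determinism(self):
        p1, prm1, t1 = smd.simulate_trial_band_power(n_trials=40, rng=5)
        p2, prm2, t2 = smd.simulate_trial_band_power(n_trials=40, rng=5)
        assert p1.shape == (40, 50, 3)
        assert np.array_equal(p1, p2) and prm1.equals(prm2)

    def test_coupling_restricted_to_band_and_window(self):
        base, prm, times = smd.simulate_trial_band_power(
            n_trials=60, coupling_gain=0.0, rng=11)
        coup, prm2, _ = smd.simulate_trial_band_power(
            n_trials=60, coupling_gain=0.8, rng=11)
        diff = coup != base
        assert not diff[:, :, [0, 2]].any()          # mu/gamma untouched
        changed_times = np.flatnonzero(diff[:, :, 1].any(axis=0))
        w = np.flatnonzero((times >= -0.09 - 1e-9) & (times < 0.21 - 1e-9))
        assert np.array_equal(changed_times, w)
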