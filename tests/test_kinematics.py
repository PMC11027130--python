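"""Gesture construction, movement segmentation and kinematic profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import smd
from smd.kinematics import (RAISED_COSINE_F10, RAISED_COSINE_F90,
                            records_to_frame)

from conftest import raised_cosine_signal


def _track(name, t, pos):
    return smd.ArticulatoryTrack(name, t, pos)


class TestOcclusalFrame:
    def _canonical_tracks(self, n=100):
        t = np.arange(n) / 100.0
        tracks = {
            "nose": _track("nose", t, np.tile([60.0, 0, 0], (n, 1))),
            "left_ear": _track("left_ear", t, np.tile([0.0, 40, 0], (n, 1))),
            "right_ear": _track("right_ear", t, np.tile([0.0, -40, 0], (n, 1))),
            "UL": _track("UL", t, np.column_stack(
                [np.full(n, 30.0), np.zeros(n), 5 + np.sin(t)])),
        }
        return tracks

    def test_identity_references_unchanged(self):
        tracks = self._canonical_tracks()
        out = smd.transform_to_occlusal_frame(tracks)
        for name in tracks:
            assert np.allclose(out[name].position, tracks[name].position,
                               atol=1e-9)

    def test_recovers_known_rigid_transform(self):
        tracks = self._canonical_tracks()
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 12.0])
        moved = {n: _track(n, tr.time, tr.position @ R.T + shift)
                 for n, tr in tracks.items()}
        out = smd.transform_to_occlusal_frame(moved)
        for name in tracks:
            assert np.abs(out[name].position - tracks[name].position).max() < 1e-6

    def test_collinear_references_rejected(self):
        tracks = self._canonical_tracks()
        n = len(tracks["nose"].time)
        tracks["nose"] = _track("nose", tracks["nose"].time,
                                np.tile([0.0, 10.0, 0.0], (n, 1)))
        with pytest.raises(ValueError, match="collinear"):
            smd.transform_to_occlusal_frame(tracks)

    def test_nan_reference_block_rejected(self):
        tracks = self._canonical_tracks(200)
        pos = tracks["nose"].position.copy()
        pos[120:140] = np.nan
        tracks["nose"] = _track("nose", tracks["nose"].time, pos)
        out = smd.transform_to_occlusal_frame(tracks, block_duration=0.5)
        assert np.isnan(out["UL"].position[120:140]).all()
        assert np.isfinite(out["UL"].position[:100]).all()


class TestComputeGesture:
    def test_coincident_tracks_zero(self):
        t = np.arange(50) / 100.0
        a = _track("UL", t, np.random.default_rng(0).normal(size=(50, 3)))
        b = _track("LL", t, a.position.copy())
        g = smd.compute_gesture(a, b)
        assert np.allclose(g.magnitude, 0.0)

    def test_three_four_five(self):
        t = np.arange(10) / 100.0
        a = _track("UL", t, np.tile([0.0, 3.0, 9.0], (10, 1)))
        b = _track("LL", t, np.tile([4.0, 0.0, -2.0], (10, 1)))
        g = smd.compute_gesture(a, b, plane="xy")
        assert np.allclose(g.magnitude, 5.0)

    def test_generator_round_trip(self, articulatory_session, small_config):
        """UL-LL distance reproduces the generator's stored BC waveform."""
        from smd.synthetic import _bc_waveform
        tracks, _, truth = articulatory_session
        g = smd.compute_gesture(tracks["UL"], tracks["LL"], "xy", "BC")
        t = tracks["UL"].time
        expected = _bc_waveform(t, truth.cycles, baseline=2.0)
        assert np.abs(g.magnitude - expected).max() < 1e-9

    def test_time_base_mismatch_rejected(self):
        a = _track("UL", np.arange(50) / 100.0, np.zeros((50, 3)))
        b = _track("LL", 10.0 + np.arange(50) / 100.0, np.zeros((50, 3)))
        with pytest.raises(ValueError, match="time base"):
            smd.compute_gesture(a, b)


class TestDetectMovements:
    def test_constant_signal_empty(self):
        sig = smd.GesturalSignal("BC", np.arange(100) / 100.0, np.full(100, 3.0))
        assert smd.detect_movements(sig) == []

    def test_noise_below_threshold_empty(self):
        rng = np.random.default_rng(0)
        sig = smd.GesturalSignal("BC", np.arange(500) / 100.0,
                                 5 + 0.05 * rng.standard_normal(500))
        assert smd.detect_movements(sig, min_amplitude=1.0) == []

    def test_nonuniform_sampling_rejected(self):
        t = np.r_[np.arange(50) / 100.0, 1.0 + np.arange(50) / 50.0]
        sig = smd.GesturalSignal("BC", t, np.sin(t))
        with pytest.raises(ValueError, match="uniform"):
            smd.detect_movements(sig)

    def test_raised_cosine_landmark_fractions(self):
        """10/90% crossings at acos(0.8)/pi and 1-acos(0.8)/pi of D (<0.1%)."""
        D = 0.2
        sig = raised_cosine_signal(amplitude=10.0, duration=D, sfreq=1000.0,
                                   n_cycles=1, pad=0.3)
        (cycle,) = smd.detect_movements(sig, min_amplitude=1.0,
                                        smooth_cutoff=None)
        assert abs((cycle.t1 - 0.3) / D - RAISED_COSINE_F10) < 1e-3 * RAISED_COSINE_F10
        assert abs((cycle.t2 - 0.3) / D - RAISED_COSINE_F90) < 1e-3 * RAISED_COSINE_F90

    def test_recovers_generator_cycle_count_and_landmarks(
            self, articulatory_session, small_config):
        tracks, _, truth = articulatory_session
        g = smd.compute_gesture(tracks["UL"], tracks["LL"], "xy", "BC")
        cycles = smd.detect_movements(g, min_amplitude=3.0)
        assert len(cycles) == len(truth.cycles)
        dt = 1.0 / small_config.sampling_rate_track
        det = np.array([[c.t1, c.t2, c.t3, c.t4] for c in cycles])
        true = truth.cycles[["t1", "t2", "t3", "t4"]].to_numpy()
        assert np.abs(det - true).max() < dt

    def test_landmark_ordering_invariant(self, articulatory_session):
        tracks, _, _ = articulatory_session
        g = smd.compute_gesture(tracks["UL"], tracks["LL"], "xy", "BC")
        for c in smd.detect_movements(g, min_amplitude=3.0):
            assert c.t1 < c.t2 <= c.t3 < c.t4


class TestComputeKinematics:
    def test_analytic_oracle(self):
        """A=10 mm, D=200 ms: amplitude 10, v_peak 78.54 mm/s, stiffness 7.854."""
        sig = raised_cosine_signal(amplitude=10.0, duration=0.2, sfreq=1000.0)
        (cycle,) = smd.detect_movements(sig, min_amplitude=1.0, smooth_cutoff=None)
        opening, closing = smd.compute_kinematics(sig, cycle, smooth_cutoff=None)
        v_expect = 10.0 * math.pi / (2 * 0.2)
        for rec in (opening, closing):
            assert abs(rec.amplitude - 10.0) < 1e-3 * 10.0
            assert abs(rec.peak_velocity - v_expect) < 1e-3 * v_expect
            assert abs(rec.stiffness - v_expect / 10.0) < 2e-3 * v_expect / 10.0

    def test_scale_equivariance(self):
        """Doubling A at fixed D doubles v_peak, leaves stiffness unchanged."""
        recs = {}
        for A in (5.0, 10.0):
            sig = raised_cosine_signal(amplitude=A, duration=0.15, sfreq=1000.0)
            (cyc,) = smd.detect_movements(sig, min_amplitude=0.5, smooth_cutoff=None)
            recs[A], _ = smd.compute_kinematics(sig, cyc, smooth_cutoff=None)
        assert recs[10.0].peak_velocity == pytest.approx(
            2 * recs[5.0].peak_velocity, rel=1e-3)
        assert recs[10.0].stiffness == pytest.approx(recs[5.0].stiffness, rel=1e-3)

    @given(st.floats(0.08, 0.4), st.floats(4.0, 16.0))
    @settings(max_examples=20, deadline=None)
    def test_stiffness_duration_product_is_half_pi(self, D, A):
        """stiffness * D = pi/2 across the noiseless raised-cosine family."""
        sig = raised_cosine_signal(amplitude=A, duration=D, sfreq=2000.0)
        cycles = smd.detect_movements(sig, min_amplitude=A / 4, smooth_cutoff=None)
        assert len(cycles) == 1
        opening, _ = smd.compute_kinematics(sig, cycles[0], smooth_cutoff=None)
        assert opening.stiffness * opening.duration == pytest.approx(
            math.pi / 2, rel=5e-3)


class TestOutlierExclusion:
    def test_excludes_aberrant_movements(self, articulatory_session):
        tracks, _, _ = articulatory_session
        g = smd.compute_gesture(tracks["UL"], tracks["LL"], "xy", "BC")
        cycles = smd.detect_movements(g, min_amplitude=3.0)
        records = [r for c in cycles for r in smd.compute_kinematics(g, c)]
        # inject one grossly aberrant "speech error"
        bad = smd.KinematicRecord("opening", 999, amplitude=80.0, duration=2.0,
                                  landmark_duration=1.5, peak_velocity=60.0,
                                  stiffness=0.75, onset_time=0.0)
        kept, n_excluded = smd.exclude_outliers(records + [bad])
        assert n_excluded >= 1
        assert all(r.cycle_index != 999 for r in kept)


class TestProfiles:
    def _family(self, rng=None, n=60, D=None):
        rng = np.random.default_rng(rng)
        recs = []
        for k in range(n):
            A = rng.uniform(5, 15)
            Dk = D if D is not None else rng.uniform(0.08, 0.4)
            v = A * math.pi / (2 * Dk)
            recs.append(smd.KinematicRecord(
                "opening", k, amplitude=A, duration=Dk, landmark_duration=Dk,
                peak_velocity=v, stiffness=v / A, onset_time=float(k)))
        return recs

    def test_noiseless_fixed_duration_family_r_is_one(self):
        va, _ = smd.build_profiles(self._family(0, D=0.2))
        assert va.fit["r"] == pytest.approx(1.0, abs=1e-12)

    def test_synthetic_session_r_at_least_09(self, articulatory_session):
        tracks, _, _ = articulatory_session
        g = smd.compute_gesture(tracks["UL"], tracks["LL"], "xy", "BC")
        cycles = smd.detect_movements(g, min_amplitude=3.0)
        records = [r for c in cycles for r in smd.compute_kinematics(g, c)]
        records, _ = smd.exclude_outliers(records)
        va, _ = smd.build_profiles(records)
        assert va.fit["r"] >= 0.9

    def test_shuffled_pairing_destroys_association(self):
        recs = self._family(1)
        rng = np.random.default_rng(2)
        vels = rng.permutation([r.peak_velocity for r in recs])
        shuffled = [smd.KinematicRecord(
            r.movement_type, r.cycle_index, r.amplitude, r.duration,
            r.landmark_duration, v, v / r.amplitude, r.onset_time)
            for r, v in zip(recs, vels)]
        va, _ = smd.build_profiles(shuffled)
        assert abs(va.fit["r"]) < 0.3

    def test_stiffness_duration_curvilinear_with_knee(self):
        """Durations 80-400 ms give a decreasing-then-flat stiffness profile."""
        rng = np.random.default_rng(3)
        recs = []
        for k in range(120):
            Dk = rng.uniform(0.08, 0.4)
            A = rng.uniform(8, 12)
            s = math.pi / (2 * min(Dk, 0.2))  # plateau beyond 200 ms
            v = s * A
            recs.append(smd.KinematicRecord(
                "opening", k, A, Dk, Dk, v, s, float(k)))
        _, sd = smd.build_profiles(recs)
        assert 0.15 < sd.fit["knee"] < 0.26
        assert sd.fit["exponent"] < -0.5
        # fitted curve decreasing below the knee, flat above
        from smd.kinematics import _powerlaw_plateau
        d = np.linspace(0.08, 0.4, 50)
        y = _powerlaw_plateau(d, sd.fit["a"], sd.fit["exponent"], sd.fit["knee"])
        below = d < sd.fit["knee"]
        assert (np.diff(y[below]) < 0).all()
        assert np.allclose(np.diff(y[~below]), 0.0)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match=">=10"):
            smd.build_profiles(self._family(0, n=5))

    def test_records_frame_round_trip_columns(self):
        df = records_to_frame(self._family(0, n=12))
        assert {"amplitude", "duration", "peak_velocity", "stiffness"} <= set(df)
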