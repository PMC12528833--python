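"""Onset detection, sectioning, deviation and session-summary tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kels import (
    ArmGeometry,
    GeneratorConfig,
    JointVelocitySeries,
    Trajectory,
    cluster_submovement_classes,
    detect_movement_onset,
    early_late_summary,
    fit_deviation_ellipse,
    generate_trial,
    ke_session_trend,
    kinetic_energy,
    observed_ke,
    section_submovements,
    simulate_path,
    spatial_variability,
    trajectory_deviation,
)
from kels.behavior_metrics import DegenerateChordError, OnsetNotFoundError


def bell_speed(t, onset, duration, peak):
    """Smooth bell speed profile, zero outside [onset, onset+duration]."""
    phase = np.clip((t - onset) / duration, 0.0, 1.0)
    return peak * np.sin(np.pi * phase) ** 2


class TestOnsetDetection:
    t = np.arange(0.0, 1.0, 1e-3)

    def test_onset_at_bell_foot_before_crossing(self):
        speed = bell_speed(self.t, 0.3, 0.5, 0.2)
        onset = detect_movement_onset(self.t, speed, threshold=0.05)
        crossing = self.t[np.argmax(speed > 0.05)]
        assert onset < crossing
        assert onset == pytest.approx(0.3, abs=2e-3)

    def test_short_blip_rejected(self):
        speed = bell_speed(self.t, 0.5, 0.4, 0.2)
        speed[100:130] = 0.08  # 30 ms supra-threshold noise blip
        onset = detect_movement_onset(self.t, speed, threshold=0.05)
        assert onset == pytest.approx(0.5, abs=2e-3)

    def test_no_crossing_raises(self):
        with pytest.raises(OnsetNotFoundError):
            detect_movement_onset(self.t, np.full_like(self.t, 0.01), threshold=0.05)

    def test_always_accelerating_falls_back_with_warning(self):
        speed = 0.3 * self.t  # positive acceleration from the first sample
        with pytest.warns(RuntimeWarning):
            onset = detect_movement_onset(self.t, speed, threshold=0.05)
        assert onset == self.t[0]


@pytest.fixture(scope="module")
def trial(layout_e, geom):
    cfg = GeneratorConfig(trial_dev_sd=0.0, speed_noise_sd=0.0, hold_noise_amp=0.0)
    return generate_trial(
        layout_e, geom, (1, 4, 2), np.array([0.1, -0.2, 0.0]), cfg,
        np.random.default_rng(0),
    )


class TestSectioning:
    def test_three_slices_with_pair_ids(self, trial):
        pieces = section_submovements(trial, speed_threshold=0.05)
        assert [p.submovement_id for p in pieces] == ["0-1", "1-4", "4-2"]
        for p in pieces:
            assert p.hand.space == "hand" and p.joint.space == "joint"
            assert len(p.hand) == len(p.joint)

    def test_slices_recover_drawn_deviations(self, trial):
        pieces = section_submovements(trial, speed_threshold=0.05)
        measured = [trajectory_deviation(p.hand) for p in pieces]
        np.testing.assert_allclose(measured, [0.1, -0.2, 0.0], atol=1e-3)

    def test_onset_close_to_construction(self, trial):
        pieces = section_submovements(trial, speed_threshold=0.05)
        # first leg starts after the 250 ms centre hold
        assert pieces[0].hand.t[0] == pytest.approx(0.25, abs=5e-3)

    def test_same_pair_same_id_across_sequences(self, layout_e, geom):
        cfg = GeneratorConfig(trial_dev_sd=0.0, speed_noise_sd=0.0, hold_noise_amp=0.0)
        rng = np.random.default_rng(1)
        ids = []
        for seq in ((3, 5, 2), (2, 5, 3)):
            trial = generate_trial(layout_e, geom, seq, np.zeros(3), cfg, rng)
            ids.append([p.submovement_id for p in section_submovements(trial, 0.05)])
        assert "2-5" in ids[1] and "5-2" in ids[0]  # directed pairs stay distinct
        t1 = generate_trial(layout_e, geom, (2, 5, 3), np.zeros(3), cfg, rng)
        assert section_submovements(t1, 0.05)[1].submovement_id == "2-5"

    def test_bad_event_ordering_rejected(self, trial):
        import copy

        broken = copy.copy(trial)
        broken.reach_times = np.array([0.0, 2.0, 1.0, 3.0])
        with pytest.raises(ValueError):
            section_submovements(broken, 0.05)


class TestTrajectoryDeviation:
    def test_semicircle_magnitude_half(self):
        theta = np.linspace(0.0, np.pi, 200)
        # arc over the chord from (1,0) to (-1,0): movement towards -x, arc on the right
        traj = Trajectory("hand", np.arange(200.0), np.cos(theta), np.sin(theta))
        assert trajectory_deviation(traj) == pytest.approx(0.5, abs=1e-4)

    def test_wedge_sign_and_magnitude(self):
        # apex at perpendicular offset h over chord of length l
        l, h = 0.04, 0.01
        x = np.array([0.0, l / 2, l])
        traj_left = Trajectory("hand", np.arange(3.0), x, np.array([0.0, h, 0.0]))
        traj_right = Trajectory("hand", np.arange(3.0), x, np.array([0.0, -h, 0.0]))
        assert trajectory_deviation(traj_left) == pytest.approx(-h / l)
        assert trajectory_deviation(traj_right) == pytest.approx(h / l)

    def test_degenerate_chord_rejected(self):
        t = np.arange(3.0)
        with pytest.raises(DegenerateChordError):
            trajectory_deviation(Trajectory("hand", t, [0.0, 1.0, 0.0], [0.0, 1.0, 0.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        dev=st.floats(-0.5, 0.5),
        angle=st.floats(0.0, 2 * np.pi),
        shift=st.floats(-1.0, 1.0),
    )
    def test_invariant_under_rigid_motion(self, dev, angle, shift):
        pts = simulate_path((0.0, 0.0), (0.05, 0.02), dev, 101)
        base = trajectory_deviation(Trajectory("hand", np.arange(101.0), pts[:, 0], pts[:, 1]))
        c, s = np.cos(angle), np.sin(angle)
        rot = pts @ np.array([[c, s], [-s, c]]) + shift
        moved = trajectory_deviation(Trajectory("hand", np.arange(101.0), rot[:, 0], rot[:, 1]))
        assert moved == pytest.approx(base, abs=1e-9)

    def test_reversal_flips_sign(self):
        pts = simulate_path((0.0, 0.0), (0.05, 0.02), 0.3, 101)
        fwd = trajectory_deviation(Trajectory("hand", np.arange(101.0), pts[:, 0], pts[:, 1]))
        rev = trajectory_deviation(
            Trajectory("hand", np.arange(101.0), pts[::-1, 0], pts[::-1, 1])
        )
        assert rev == pytest.approx(-fwd, abs=1e-12)


class TestSpatialVariability:
    def make(self, offset, duration=0.5):
        t = np.arange(0.0, duration + 1e-9, 1e-3)
        return Trajectory("hand", t, t * 0.1, np.full_like(t, offset))

    def test_identical_trajectories_zero_sd(self):
        out = spatial_variability([self.make(0.0), self.make(0.0)])
        assert np.all(out["sd"] == 0.0)

    def test_symmetric_offset_gives_c(self):
        out = spatial_variability([self.make(0.01), self.make(-0.01)])
        np.testing.assert_allclose(out["sd"], 0.01, atol=1e-12)

    def test_truncated_at_shortest(self):
        out = spatial_variability([self.make(0.0, 0.3), self.make(0.0, 0.5)])
        assert out["time_s"].iloc[-1] == pytest.approx(0.3)

    def test_requires_two(self):
        with pytest.raises(ValueError):
            spatial_variability([self.make(0.0)])


class TestObservedKE:
    def test_delegates_to_kinetic_energy(self, geom, rng):
        vel = JointVelocitySeries(np.arange(100.0), rng.normal(size=100), rng.normal(size=100))
        assert observed_ke(vel, geom) == kinetic_energy(vel, geom)

    def test_constant_shoulder_rotation(self, geom):
        vel = JointVelocitySeries(np.arange(100.0), np.ones(100), np.zeros(100))
        assert observed_ke(vel, geom) == pytest.approx(100 * 0.5 * geom.Is)


class TestEarlyLate:
    @staticmethod
    def records(n_sessions, drift_per_session=0.0, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_sessions):
            for trial in range(5):
                rows.append(
                    {
                        "session_id": s,
                        "submovement_id": "0-1",
                        "hand_dev": 0.1 + drift_per_session * s + rng.normal(0.0, sd),
                    }
                )
        return pd.DataFrame(rows)

    def test_stationary_difference_near_zero(self):
        out = early_late_summary(self.records(20, sd=0.02, seed=1), n_edge=10)
        se = 0.02 / np.sqrt(50)
        assert abs(out["difference"].iloc[0]) < 4 * se

    def test_planted_drift_recovered(self):
        # +0.2 a.u. total drift over 20 sessions => late-early = 0.1 per block maths
        out = early_late_summary(self.records(20, drift_per_session=0.2 / 19), n_edge=10)
        expected = (np.mean(np.arange(10, 20)) - np.mean(np.arange(10))) * 0.2 / 19
        assert out["difference"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_too_few_sessions(self):
        with pytest.raises(ValueError):
            early_late_summary(self.records(15), n_edge=10)


class TestKETrend:
    def test_decreasing_series_negative_r(self):
        slope, r = ke_session_trend(np.array([5.0, 4.5, 4.4, 4.0, 3.2]))
        assert slope < 0 and r < 0

    def test_exact_line_unit_r(self):
        slope, r = ke_session_trend(2.0 + 0.3 * np.arange(10))
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(0.3)

    def test_constant_series_warns(self):
        with pytest.warns(RuntimeWarning):
            slope, r = ke_session_trend(np.full(5, 2.0))
        assert (slope, r) == (0.0, 0.0)


class TestEllipse:
    def test_diagonal_line_gives_45_degrees(self):
        pts = np.column_stack([np.linspace(0, 1, 20)] * 2)
        with pytest.warns(RuntimeWarning):
            fit = fit_deviation_ellipse(pts)
        assert fit.major_axis_angle_deg == pytest.approx(45.0)

    def test_isotropic_cloud_axis_ratio_near_one(self, rng):
        pts = rng.normal(size=(10_000, 2))
        fit = fit_deviation_ellipse(pts)
        assert fit.semi_major / fit.semi_minor == pytest.approx(1.0, abs=0.05)

    def test_horizontal_line_degenerate(self):
        pts = np.column_stack([np.linspace(0, 1, 20), np.zeros(20)])
        with pytest.warns(RuntimeWarning):
            fit = fit_deviation_ellipse(pts)
        assert fit.major_axis_angle_deg == pytest.approx(0.0)
        assert fit.semi_minor == pytest.approx(0.0, abs=1e-12)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            fit_deviation_ellipse(np.ones((5, 2)))


class TestCosineKMeans:
    @staticmethod
    def bundles(rng, angles_deg=(20.0, 70.0), n=12, spread=3.0):
        pts, truth = [], []
        for label, ang in enumerate(angles_deg):
            a = np.deg2rad(ang + rng.normal(0, spread, n))
            r = rng.uniform(0.5, 2.0, n)
            pts.append(np.column_stack([r * np.cos(a), r * np.sin(a)]))
            truth += [label] * n
        return np.vstack(pts), np.array(truth)

    def test_planted_bundles_recovered(self, rng):
        X, truth = self.bundles(rng)
        labels = cluster_submovement_classes(X, k=2, rng=np.random.default_rng(0))
        # canonicalisation maps the lower-angle (lower joint-dev) bundle to 0?
        # direction at 20 deg has the larger first component -> class 1
        assert np.array_equal(labels, 1 - truth) or np.array_equal(labels, truth)
        assert len(set(map(tuple, zip(truth, labels)))) == 2  # perfect recovery

    def test_scale_invariance(self, rng):
        X, _ = self.bundles(rng)
        base = cluster_submovement_classes(X, k=2, rng=np.random.default_rng(0))
        X2 = X.copy()
        X2[3] *= 17.0
        scaled = cluster_submovement_classes(X2, k=2, rng=np.random.default_rng(0))
        assert np.array_equal(base, scaled)

    def test_zero_vector_rejected(self):
        X = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            cluster_submovement_classes(X)

    def test_single_direction_degenerate(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.warns(RuntimeWarning):
            labels = cluster_submovement_classes(X, k=2)
        assert np.all(labels == 0)
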