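"""Feature operators: geometry, events, temporal features, interpolation."""

import math

import numpy as np
import pandas as pd
import pytest

import cowgait as cg
from cowgait.gait_features import (
    FeatureExtractionError,
    GaitEventError,
    GaitFeatureError,
    MissingKeypointError,
    StanceInterval,
    _columns,
)


def make_trajectory(n_frames=10, fps=50.0, **overrides):
    """A minimal valid trajectory; override columns via keyword arrays."""
    t = np.arange(n_frames) / fps
    data = pd.DataFrame(index=pd.RangeIndex(n_frames), columns=_columns(), dtype=float)
    x = 200.0 * t
    for kp in cg.KEYPOINTS:
        data[f"{kp}_x"] = x
        data[f"{kp}_y"] = 100.0
    for hoof in cg.HOOVES:
        data[f"{hoof}_y"] = 0.0
    for col, vals in overrides.items():
        data[col] = vals
    return cg.Trajectory(cow_id="test", fps=fps, data=data)


def stance(hoof, land, lift, x=0.0):
    return StanceInterval(hoof=hoof, t_land_ms=land, t_lift_ms=lift, x_cm=x)


# ---------------------------------------------------------------------------
# back-arch curvature
# ---------------------------------------------------------------------------

class TestBackArchCurvature:
    def test_unit_circle(self):
        assert cg.back_arch_curvature((0, 1), (1, 0), (0, -1)) == pytest.approx(1.0)

    def test_collinear_is_flat(self):
        assert cg.back_arch_curvature((0, 0), (50, 0), (100, 0)) == 0.0

    def test_against_circumcenter_solve(self):
        """Oracle: solve the two perpendicular-bisector equations numerically."""
        pts = np.array([[0.0, 0.0], [50.0, 0.5], [100.0, 0.0]])
        # circumcenter c satisfies |c-p1|=|c-p2|=|c-p3| -> two linear equations
        a = 2 * (pts[1] - pts[0])
        b = 2 * (pts[2] - pts[0])
        rhs = np.array(
            [
                pts[1] @ pts[1] - pts[0] @ pts[0],
                pts[2] @ pts[2] - pts[0] @ pts[0],
            ]
        )
        center = np.linalg.solve(np.vstack([a, b]), rhs)
        radius = np.linalg.norm(pts[0] - center)
        assert cg.back_arch_curvature(*pts) == pytest.approx(1.0 / radius, rel=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(GaitFeatureError, match="distinct"):
            cg.back_arch_curvature((0, 0), (0, 0), (1, 1))

    @pytest.mark.parametrize("angle", [0.3, 1.1, 2.5])
    def test_rigid_motion_invariance_and_scaling(self, angle):
        pts = np.array([[0.0, 0.0], [50.0, 0.5], [100.0, 0.0]])
        k0 = cg.back_arch_curvature(*pts)
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        moved = pts @ rot.T + np.array([12.3, -4.5])
        assert cg.back_arch_curvature(*moved) == pytest.approx(k0, rel=1e-9)
        assert cg.back_arch_curvature(*(3.0 * pts)) == pytest.approx(k0 / 3.0, rel=1e-9)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

class TestInterpolateMissing:
    def test_linear_midpoint(self):
        traj = make_trajectory(3)
        traj.data.loc[1, "head_x"] = np.nan
        traj.data.loc[0, "head_x"] = 0.0
        traj.data.loc[2, "head_x"] = 2.0
        out = cg.interpolate_missing(traj)
        assert out.data.loc[1, "head_x"] == pytest.approx(1.0)

    def test_identity_when_complete(self):
        traj = make_trajectory(5)
        out = cg.interpolate_missing(traj)
        pd.testing.assert_frame_equal(out.data, traj.data)

    def test_run_of_three_equally_spaced(self):
        traj = make_trajectory(6)
        traj.data["head_y"] = [10.0, np.nan, np.nan, np.nan, 50.0, 50.0]
        out = cg.interpolate_missing(traj)
        assert out.data["head_y"].tolist() == pytest.approx([10, 20, 30, 40, 50, 50])

    def test_present_entries_unchanged(self):
        traj = make_trajectory(6)
        traj.data.loc[2, "withers_y"] = 123.0
        traj.data.loc[3, "withers_y"] = np.nan
        out = cg.interpolate_missing(traj)
        assert out.data.loc[2, "withers_y"] == 123.0

    def test_fully_missing_keypoint_rejected(self):
        traj = make_trajectory(5)
        traj.data[["head_x", "head_y"]] = np.nan
        with pytest.raises(MissingKeypointError, match="head"):
            cg.interpolate_missing(traj)


# ---------------------------------------------------------------------------
# head bob and speed
# ---------------------------------------------------------------------------

class TestHeadBobAmplitude:
    def test_max_over_swings(self):
        """Cycles with peak-to-trough 3, 5, 4 (and mirrored) cm -> amplitude 5 cm.

        The amplitude sequence is mirrored so the varying envelope does not
        tilt the linear detrend of the height series.
        """
        fps = 100.0
        cycle = 100  # frames per cycle
        segs = [
            (amp / 2) * np.sin(2 * np.pi * np.arange(cycle) / cycle)
            for amp in (3.0, 5.0, 4.0, 4.0, 5.0, 3.0)
        ]
        y = 100.0 + np.concatenate(segs + [np.zeros(2)])
        traj = make_trajectory(len(y), fps=fps, head_y=y)
        assert cg.head_bob_amplitude(traj) == pytest.approx(5.0, rel=0.02)

    def test_constant_head_height_is_zero(self):
        traj = make_trajectory(50)
        assert cg.head_bob_amplitude(traj) == 0.0

    def test_recovers_generator_amplitude(self, lame_walk):
        got = cg.head_bob_amplitude(lame_walk.trajectory)
        assert got == pytest.approx(15.8, rel=0.05)


class TestWalkingSpeed:
    def test_six_metres_in_three_seconds(self):
        fps = 50.0
        n = 151  # 3 s elapsed
        x = np.linspace(0, 600.0, n)
        traj = make_trajectory(n, fps=fps, withers_x=x)
        assert cg.walking_speed(traj) == pytest.approx(2.0)

    def test_stationary_cow(self):
        traj = make_trajectory(50, withers_x=np.full(50, 10.0))
        assert cg.walking_speed(traj) == 0.0

    def test_single_frame_rejected(self):
        with pytest.raises(GaitFeatureError):
            cg.walking_speed(make_trajectory(1))


# ---------------------------------------------------------------------------
# stance detection
# ---------------------------------------------------------------------------

class TestDetectStanceIntervals:
    def test_events_within_one_frame_of_ground_truth(self, lame_walk):
        det = cg.detect_stance_intervals(lame_walk.trajectory)
        dt = 1000.0 / lame_walk.trajectory.fps
        for hoof, true_events in lame_walk.events.items():
            for t_land, t_lift, _x in true_events:
                best = min(det[hoof], key=lambda s: abs(s.t_land_ms - t_land))
                assert abs(best.t_land_ms - t_land) <= dt + 1e-9
                assert abs(best.t_lift_ms - t_lift) <= dt + 1e-9

    def test_grounded_hoof_single_interval(self):
        traj = make_trajectory(100)
        for hoof in cg.HOOVES:
            traj.data[f"{hoof}_x"] = 5.0
            traj.data[f"{hoof}_y"] = 0.0
        det = cg.detect_stance_intervals(traj)
        for hoof in cg.HOOVES:
            assert len(det[hoof]) == 1
            only = det[hoof][0]
            assert only.t_land_ms == 0.0
            assert only.t_lift_ms == pytest.approx(100 * 20.0)
            assert only.left_censored and only.right_censored

    def test_degenerate_thresholds_stance_everywhere(self, lame_walk):
        config = cg.ExtractionConfig(height_thresh_cm=1e6, motion_thresh_cm=1e6)
        det = cg.detect_stance_intervals(lame_walk.trajectory, config)
        n = lame_walk.trajectory.n_frames
        for hoof in cg.HOOVES:
            assert len(det[hoof]) == 1
            assert det[hoof][0].t_land_ms == 0.0
            assert det[hoof][0].t_lift_ms == pytest.approx(n * 20.0)

    def test_missing_frames_rejected(self):
        traj = make_trajectory(50)
        traj.data.loc[3, "hoof_FL_y"] = np.nan
        with pytest.raises(MissingKeypointError):
            cg.detect_stance_intervals(traj)


# ---------------------------------------------------------------------------
# temporal features on enumerated stance sets
# ---------------------------------------------------------------------------

class TestStepOverlap:
    def test_single_cycle_direct_substitution(self):
        stances = {
            "hoof_FL": [stance("hoof_FL", 0, 400, x=100.0)],
            "hoof_HL": [stance("hoof_HL", 500, 900, x=90.0)],
            "hoof_FR": [stance("hoof_FR", 100, 500, x=100.0)],
            "hoof_HR": [stance("hoof_HR", 600, 1000, x=95.0)],
        }
        # delta_left = 100-90 = 10, delta_right = 100-95 = 5 -> max = 10
        assert cg.step_overlap(stances) == pytest.approx(10.0)

    def test_perfect_tracking_is_zero(self):
        stances = {
            "hoof_FL": [stance("hoof_FL", 0, 400, x=100.0)],
            "hoof_HL": [stance("hoof_HL", 500, 900, x=100.0)],
            "hoof_FR": [stance("hoof_FR", 100, 500, x=130.0)],
            "hoof_HR": [stance("hoof_HR", 600, 1000, x=130.0)],
        }
        assert cg.step_overlap(stances) == 0.0

    def test_no_pairing_rejected(self):
        stances = {h: [] for h in cg.HOOVES}
        stances["hoof_HL"] = [stance("hoof_HL", 0, 400)]
        with pytest.raises(GaitEventError):
            cg.step_overlap(stances)

    def test_recovers_generator_overlap(self, lame_walk):
        det = cg.detect_stance_intervals(lame_walk.trajectory)
        assert cg.step_overlap(det) == pytest.approx(17.3, abs=0.5)


class TestSupportingPhase:
    def test_hind_asymmetry(self):
        stances = {
            "hoof_FL": [stance("hoof_FL", 0, 620)],
            "hoof_FR": [stance("hoof_FR", 0, 620)],
            "hoof_HL": [stance("hoof_HL", 0, 700)],
            "hoof_HR": [stance("hoof_HR", 0, 382)],
        }
        assert cg.supporting_phase_feature(stances) == pytest.approx(318.0)

    def test_both_pairs_enumerated(self):
        stances = {
            "hoof_FL": [stance("hoof_FL", 0, 650)],
            "hoof_FR": [stance("hoof_FR", 0, 600)],
            "hoof_HL": [stance("hoof_HL", 0, 640)],
            "hoof_HR": [stance("hoof_HR", 0, 660)],
        }
        assert cg.supporting_phase_feature(stances) == pytest.approx(50.0)

    def test_symmetric_gait_is_zero(self):
        stances = {h: [stance(h, 0, 600)] for h in cg.HOOVES}
        assert cg.supporting_phase_feature(stances) == 0.0

    def test_missing_hoof_rejected(self):
        stances = {h: [stance(h, 0, 600)] for h in cg.HOOVES}
        stances["hoof_HR"] = []
        with pytest.raises(GaitEventError, match="hoof_HR"):
            cg.supporting_phase_feature(stances)


class TestHoofStepTime:
    def test_sum_of_two_strides(self):
        # one hoof with stride cycles 400 and 420 ms, others shorter
        stances = {
            "hoof_FL": [stance("hoof_FL", t, t + 100) for t in (0, 400, 820)],
            "hoof_FR": [stance("hoof_FR", t, t + 100) for t in (0, 300, 600)],
            "hoof_HL": [stance("hoof_HL", t, t + 100) for t in (0, 350, 700)],
            "hoof_HR": [stance("hoof_HR", t, t + 100) for t in (0, 380, 760)],
        }
        assert cg.hoof_step_time_feature(stances) == pytest.approx(820.0)

    def test_periodic_gait(self):
        stances = {
            h: [stance(h, i * 788.0, i * 788.0 + 100) for i in range(4)]
            for h in cg.HOOVES
        }
        assert cg.hoof_step_time_feature(stances) == pytest.approx(1576.0, abs=1.0)

    def test_too_few_touchdowns_rejected(self):
        stances = {h: [stance(h, 0, 100), stance(h, 700, 800)] for h in cg.HOOVES}
        with pytest.raises(GaitEventError):
            cg.hoof_step_time_feature(stances)


# ---------------------------------------------------------------------------
# composite extraction
# ---------------------------------------------------------------------------

class TestExtractFeatures:
    def test_flat_symmetric_walk(self, level_walk):
        feats = cg.extract_features(level_walk.trajectory)
        assert feats.back_arch == pytest.approx(0.0, abs=1e-9)
        assert feats.head_bob_cm == pytest.approx(0.0, abs=1e-6)
        assert feats.supporting_phase_ms == pytest.approx(0.0, abs=40.0)
        assert feats.speed_mps == pytest.approx(2.0, rel=1e-6)

    def test_zero_motion_clip_errors_with_feature_name(self):
        traj = make_trajectory(100)
        for kp in cg.KEYPOINTS:
            traj.data[f"{kp}_x"] = 5.0
        with pytest.raises(FeatureExtractionError) as exc:
            cg.extract_features(traj)
        assert exc.value.feature in ("step_overlap_cm", "hoof_step_time_ms")

    def test_interpolates_dropout_automatically(self, default_config):
        rng = np.random.default_rng(5)
        params = cg.sample_gait_parameters(2, default_config, rng=rng)
        clean = cg.synthesize_trajectory(params, duration_s=7.0, fps=50.0)
        noisy = cg.synthesize_trajectory(
            params, duration_s=7.0, fps=50.0, dropout_rate=0.02, rng=rng
        )
        assert noisy.trajectory.has_missing
        f_clean = cg.extract_features(clean.trajectory).as_array()
        f_noisy = cg.extract_features(noisy.trajectory).as_array()
        assert np.allclose(f_clean, f_noisy, rtol=0.12, atol=25.0)


def test_temporal_features_time_shift_invariant():
    base = {
        "hoof_FL": [stance("hoof_FL", 0, 620, x=10), stance("hoof_FL", 700, 1300, x=150)],
        "hoof_FR": [stance("hoof_FR", 350, 900, x=80), stance("hoof_FR", 1050, 1650, x=220)],
        "hoof_HL": [stance("hoof_HL", 100, 640, x=5), stance("hoof_HL", 800, 1340, x=145)],
        "hoof_HR": [stance("hoof_HR", 450, 950, x=75), stance("hoof_HR", 1150, 1700, x=215)],
    }
    shift = {
        h: [
            StanceInterval(h, s.t_land_ms + 5000, s.t_lift_ms + 5000, s.x_cm + 300)
            for s in ivals
        ]
        for h, ivals in base.items()
    }
    assert cg.supporting_phase_feature(base) == pytest.approx(
        cg.supporting_phase_feature(shift)
    )
    assert cg.step_overlap(base) == pytest.approx(cg.step_overlap(shift))
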