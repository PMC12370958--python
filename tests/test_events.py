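import numpy as np
import pandas as pd
import pytest

from pdpose.events import (GAIT_FEATURES, REARING_FEATURES, Stride,
                           axial_bending_angle, axial_bending_clips,
                           detect_strides, detect_turning,
                           feet_placement_stats, gait_feature_table,
                           gait_features, rearing_features)
from pdpose.pose import EventAnnotation, NodeId, PoseSequence
from pdpose.simulate import generate_session, preset

from conftest import make_pose


def rotating_pose(n_pad=15, n_turn=30, rate_deg=3.0, direction=1.0):
    """Body rotating about a fixed anus at rate_deg per frame after a pad."""
    n = n_pad + n_turn + n_pad
    heading = np.concatenate([
        np.zeros(n_pad),
        direction * rate_deg * np.arange(1, n_turn + 1),
        np.full(n_pad, direction * rate_deg * n_turn),
    ])
    rad = np.deg2rad(heading)
    chest = np.stack([np.cos(rad), np.sin(rad), np.full(n, 1.0)], axis=1)
    return make_pose(n, chest=chest, anus=(0.0, 0.0, 0.8)), heading


class TestTurning:
    def test_constant_heading_no_events(self):
        seq = make_pose(60, chest=(1.0, 0.0, 1.0), anus=(0.0, 0.0, 0.8))
        assert detect_turning(seq) == []

    def test_constant_rotation_integrates_to_90(self):
        seq, _ = rotating_pose(rate_deg=3.0, n_turn=30)
        events = detect_turning(seq)
        assert len(events) == 1
        ev = events[0]
        assert ev.direction == 1  # counterclockwise = left
        assert ev.turning_angle == pytest.approx(90.0, rel=0.1)
        assert ev.turning_velocity == pytest.approx(
            ev.turning_angle / ev.turning_duration)

    def test_right_turn_direction(self):
        seq, _ = rotating_pose(rate_deg=3.0, direction=-1.0)
        events = detect_turning(seq)
        assert len(events) == 1 and events[0].direction == -1

    def test_single_frame_flip_suppressed(self):
        n = 40
        heading = np.zeros(n)
        heading[20:] = 180.0  # one abrupt 180-degree flip
        rad = np.deg2rad(heading)
        chest = np.stack([np.cos(rad), np.sin(rad), np.ones(n)], axis=1)
        seq = make_pose(n, chest=chest, anus=(0.0, 0.0, 0.8))
        assert detect_turning(seq) == []

    def test_world_rotation_invariant_reflection_flips(self):
        seq, _ = rotating_pose()
        a = detect_turning(seq)[0]
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        b = detect_turning(seq.transformed(rotation=rot))[0]
        assert b.direction == a.direction
        assert b.turning_angle == pytest.approx(a.turning_angle, abs=1e-6)
        refl = np.diag([1.0, -1.0, 1.0])
        c = detect_turning(seq.transformed(rotation=refl))[0]
        assert c.direction == -a.direction


class TestRearing:
    def _ramp_pose(self):
        # linear ascent 0 -> 3 cm over frames 0..29, symmetric descent 29..58
        z = np.concatenate([np.linspace(0, 3, 30), np.linspace(3, 0, 30)[1:]])
        chest = np.zeros((59, 3))
        chest[:, 2] = z
        return make_pose(59, chest=chest)

    def test_feature_vector_length_11(self):
        seq = self._ramp_pose()
        ev = EventAnnotation("rearing", 0, 58, peak_frame=29)
        feats = rearing_features(seq, ev)
        assert list(feats.index) == REARING_FEATURES
        assert len(feats) == 11

    def test_linear_ramp_arithmetic(self):
        seq = self._ramp_pose()
        ev = EventAnnotation("rearing", 0, 58, peak_frame=29)
        f = rearing_features(seq, ev)
        assert f["up_displacement_cm"] == pytest.approx(3.0)
        assert f["down_displacement_cm"] == pytest.approx(3.0)
        assert f["up_duration_s"] == pytest.approx(29 / 30)
        # oracle: 29 finite-difference intervals spanning 3 cm
        assert f["up_vz_mean"] == pytest.approx(3.0 / (29 / 30), rel=1e-9)
        assert f["up_vz_std"] == pytest.approx(0.0, abs=1e-9)

    def test_flat_chest_all_zero(self):
        seq = make_pose(40, chest=(0.0, 0.0, 1.0))
        ev = EventAnnotation("rearing", 5, 35, peak_frame=20)
        f = rearing_features(seq, ev)
        assert np.allclose(f.to_numpy(), 0.0, atol=1e-12) or \
            (f[["up_displacement_cm", "down_displacement_cm", "up_vz_mean",
                "down_vz_mean"]].abs() < 1e-12).all()

    def test_event_outside_session_rejected(self):
        seq = make_pose(20)
        with pytest.raises(ValueError):
            rearing_features(seq, EventAnnotation("rearing", 5, 25,
                                                  peak_frame=10))


class TestStrides:
    def test_small_case_oracle(self):
        # swing flags F T T F F T T F -> swings [1,3) and [5,7)
        swings = [EventAnnotation("swing", 1, 3, foot=NodeId.r_foot),
                  EventAnnotation("swing", 5, 7, foot=NodeId.r_foot)]
        strides = detect_strides(swings)
        assert len(strides) == 1
        st = strides[0]
        assert (st.start_frame, st.end_frame) == (3, 7)
        assert (st.swing_start, st.swing_end) == (5, 7)
        assert st.stance == (3, 5)

    def test_single_swing_no_strides(self):
        swings = [EventAnnotation("swing", 1, 3, foot=NodeId.r_foot)]
        assert detect_strides(swings) == []

    def test_rearing_overlap_excluded(self):
        swings = [EventAnnotation("swing", 1, 3, foot=NodeId.r_foot),
                  EventAnnotation("swing", 5, 7, foot=NodeId.r_foot),
                  EventAnnotation("swing", 9, 11, foot=NodeId.r_foot)]
        rearing = [EventAnnotation("rearing", 4, 6, peak_frame=5)]
        strides = detect_strides(swings, rearing)
        assert [(s.start_frame, s.end_frame) for s in strides] == [(7, 11)]

    def test_ground_truth_boundaries_exact(self, control_session):
        """Strides from generator swing phases match the phase oracle."""
        seq, truth = control_session
        swings = [e for e in truth.events
                  if e.kind == "swing" and e.foot == NodeId.r_foot]
        strides = [s for s in detect_strides(truth.events)
                   if s.foot == NodeId.r_foot]
        oracle = [(a.end_frame, b.end_frame)
                  for a, b in zip(swings, swings[1:])]
        got = [(s.start_frame, s.end_frame) for s in strides]
        assert got == oracle


class TestGaitFeatures:
    def test_feature_vector_length_28(self, control_session):
        seq, truth = control_session
        table = gait_feature_table(seq, truth.events)
        assert len(GAIT_FEATURES) == 28
        assert list(table.columns[-28:]) == GAIT_FEATURES
        assert len(table) > 10
        assert np.all(np.isfinite(table[GAIT_FEATURES].to_numpy()))

    def test_duty_factor_bounded(self, control_session):
        seq, truth = control_session
        table = gait_feature_table(seq, truth.events)
        assert table["duty_factor"].between(0, 1).all()

    def test_stride_duration_matches_oscillator_period(self, control_session):
        seq, truth = control_session
        table = gait_feature_table(seq, truth.events)
        # stride frequency is clipped to [1.5, 3.5] Hz in the generator
        med = table["stride_duration_s"].median()
        assert 1 / 3.5 - 1 / 30 <= med <= 1 / 1.5 + 1 / 30


class TestAxialBending:
    def test_collinear_is_180(self):
        seq = make_pose(3, nose=(1, 0, 0), anus=(-1, 0, 0),
                        r_foot=(0.5, 0, 0), l_foot=(-0.5, 0, 0))
        np.testing.assert_allclose(axial_bending_angle(seq), 180.0, atol=1e-9)

    def test_right_angle_dot_product(self):
        seq = make_pose(3, nose=(1, 1, 0), anus=(-1, 1, 0),
                        r_foot=(0.5, -0.5, 0), l_foot=(-0.5, 0.5, 0))
        np.testing.assert_allclose(axial_bending_angle(seq), 90.0, atol=1e-9)

    def test_sustained_bend_yields_clips(self):
        # theta = 60 deg for 300 frames
        ang = np.deg2rad(60)
        seq = make_pose(300, nose=(np.cos(ang), np.sin(ang), 0),
                        anus=(1.0, 0.0, 0.0),
                        r_foot=(0.25, -0.25, 0), l_foot=(-0.25, 0.25, 0))
        np.testing.assert_allclose(axial_bending_angle(seq), 60.0, atol=1e-9)
        clips = axial_bending_clips(seq)
        assert len(clips) >= 1
        for c in clips:
            assert c.mean_angle == pytest.approx(60.0, abs=1e-6)
            assert c.end_frame - c.start_frame == 60

    def test_straight_posture_no_clips(self):
        seq = make_pose(300, nose=(1, 0, 0), anus=(-1, 0, 0),
                        r_foot=(0.5, -0.3, 0), l_foot=(-0.5, 0.3, 0))
        assert axial_bending_clips(seq) == []

    def test_threshold_monotonicity(self, pd_session):
        seq, _ = pd_session
        n60 = len(axial_bending_clips(seq, threshold=60.0))
        n75 = len(axial_bending_clips(seq, threshold=75.0))
        n90 = len(axial_bending_clips(seq, threshold=90.0))
        assert n60 <= n75 <= n90


class TestFeetPlacement:
    def test_feet_ahead_zero_percent(self):
        seq = make_pose(50, chest=(1, 0, 1), anus=(0, 0, 0.8),
                        r_foot=(0.5, -0.3, 0), l_foot=(0.5, 0.3, 0))
        _, _, _, pct = feet_placement_stats(seq)
        assert pct == 0.0

    def test_mirrored_feet_fifty_percent(self):
        seq = make_pose(50, chest=(1, 0, 1), anus=(0, 0, 0.8),
                        r_foot=(0.5, -0.3, 0), l_foot=(-0.5, 0.3, 0))
        _, _, _, pct = feet_placement_stats(seq)
        assert pct == pytest.approx(50.0)

    def test_pd_cohort_trails_more(self, control_session, pd_session):
        _, _, _, pct_ct = feet_placement_stats(control_session[0])
        _, _, _, pct_pd = feet_placement_stats(pd_session[0])
        assert pct_pd > pct_ct
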