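"""Trajectory I/O, Procrustes alignment, kinematics and zone annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from foragemod.geometry import (ArenaGeometry, CENTER, IN_TUNNEL, POT2,
                                TUNNEL_ENTRY, WALL, ZONE_NAMES)
from foragemod.tracking import (AlignmentError, KinematicsConfig,
                                Trajectory, TrackingFormatError,
                                TrackingValidationError, annotate_zones,
                                compute_kinematics, extract_bouts,
                                procrustes_align, procrustes_transform,
                                read_tracking_table, write_tracking_table,
                                SLOW, MEDIUM, FAST)


def make_traj(x, y, frame_rate=30.0, **kw):
    n = len(x)
    return Trajectory(mouse_id="m001", phase="Foraging",
                      t=np.arange(n) / frame_rate,
                      x=np.asarray(x, float), y=np.asarray(y, float),
                      frame_rate=frame_rate, **kw)


class TestReader:
    def test_well_formed_roundtrip(self, tmp_path):
        traj = make_traj([0.0, 1.0, 2.0], [0.0, 0.5, 1.0])
        path = tmp_path / "t.csv"
        write_tracking_table(traj, path)
        back = read_tracking_table(path)
        assert back.n_frames == 3
        np.testing.assert_allclose(back.x, traj.x, atol=1e-6)
        np.testing.assert_allclose(back.t, traj.t, atol=1e-6)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,t,x\n0,0.0,1.0\n")
        with pytest.raises(TrackingFormatError):
            read_tracking_table(path)

    def test_backwards_time_is_validation_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,t,x,y\n0,0.0,1,1\n1,0.5,1,1\n2,0.2,1,1\n")
        with pytest.raises(TrackingValidationError):
            read_tracking_table(path)

    def test_unparseable_coordinates_interpolated_short_gap(self, tmp_path):
        path = tmp_path / "gap.csv"
        rows = ["frame,t,x,y"] + [f"{i},{i/30:.4f},{float(i)},0.0" for i in range(10)]
        rows[3] = "2,0.0667,not_a_number,0.0"
        path.write_text("\n".join(rows) + "\n")
        traj = read_tracking_table(path)
        assert not traj.missing[2]  # interpolated
        assert abs(traj.x[2] - 2.0) < 1e-6


class TestProcrustes:
    def test_identity_when_already_aligned(self, geometry):
        lm = geometry.landmarks()
        s, R, b, rmsd = procrustes_transform(lm, lm)
        assert rmsd < 1e-10
        assert abs(s - 1) < 1e-10
        np.testing.assert_allclose(R, np.eye(2), atol=1e-10)

    def test_pure_translation_recovered(self, geometry):
        lm = geometry.landmarks()
        shifted = lm + np.array([3.0, -2.0])
        s, R, b, rmsd = procrustes_transform(shifted, lm)
        assert rmsd < 1e-10
        np.testing.assert_allclose(b, [-3.0, 2.0], atol=1e-9)
        traj = make_traj([3.0, 4.0], [-2.0, -1.0], landmarks=shifted)
        out = procrustes_align(traj, geometry)
        np.testing.assert_allclose(out.x, [0.0, 1.0], atol=1e-9)
        np.testing.assert_allclose(out.y, [0.0, 1.0], atol=1e-9)

    def test_rotation_scale_matches_svd_oracle(self, geometry):
        # independent closed-form oracle: orthogonal Procrustes on centered
        # landmarks with the optimal similarity scale
        rng = np.random.default_rng(3)
        lm = geometry.landmarks()
        theta = rng.uniform(0, 2 * np.pi)
        Rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        src = 1.1 * lm @ Rot.T + np.array([2.0, -5.0])
        s, R, b, rmsd = procrustes_transform(src, lm)
        assert rmsd < 1e-8
        mapped = s * src @ R.T + b
        np.testing.assert_allclose(mapped, lm, atol=1e-8)
        # oracle via scipy
        from scipy.linalg import orthogonal_procrustes
        A = src - src.mean(0)
        B = lm - lm.mean(0)
        Ro, scale = orthogonal_procrustes(A, B)
        np.testing.assert_allclose(s * A @ Ro, B, atol=1e-8)

    def test_collinear_landmarks_raise(self):
        bad = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(AlignmentError):
            procrustes_transform(bad, bad + 1.0)

    def test_alignment_idempotent(self, geometry):
        rng = np.random.default_rng(0)
        traj = make_traj(rng.uniform(-5, 5, 50), rng.uniform(5, 15, 50),
                         landmarks=geometry.landmarks())
        once = procrustes_align(traj, geometry)
        twice = procrustes_align(once, geometry)
        np.testing.assert_allclose(once.x, twice.x, atol=1e-9)
        np.testing.assert_allclose(once.y, twice.y, atol=1e-9)


class TestKinematics:
    def test_constant_position_single_slow_bout(self):
        traj = make_traj(np.ones(20), np.ones(20))
        out = compute_kinematics(traj, KinematicsConfig(smoothing_window=1))
        np.testing.assert_allclose(out.velocity, 0.0)
        assert len(out.bouts) == 1
        b = out.bouts[0]
        assert b.vclass == SLOW and b.n_frames == 20

    @pytest.mark.parametrize("speed,expected", [
        (5.0, SLOW), (15.0, MEDIUM), (15.01, FAST), (4.99, SLOW), (5.01, MEDIUM),
    ])
    def test_class_boundaries_closed_as_stated(self, speed, expected):
        # frame rate 10 keeps the boundary steps exactly representable
        # (0.5 and 1.5 cm), so v == 5.0 / 15.0 lands on the boundary
        step = speed / 10.0
        x = np.arange(30) * step
        traj = make_traj(x, np.zeros(30), frame_rate=10.0)
        out = compute_kinematics(traj, KinematicsConfig(smoothing_window=1))
        assert np.all(out.vclass == expected)

    def test_bout_rule_longer_than_three_frames(self):
        vclass = np.array([SLOW] * 4 + [MEDIUM] * 2 + [FAST] * 5, dtype=np.int8)
        bouts = extract_bouts(vclass, min_bout_frames=3)
        classes = [b.vclass for b in bouts]
        assert classes == [SLOW, FAST]  # run of 2 medium frames is no bout

    def test_single_frame_raises(self):
        with pytest.raises(Exception):
            compute_kinematics(make_traj([0.0], [0.0]))

    @given(v=st.floats(min_value=0.0, max_value=30.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_boundary_property(self, v):
        step = v / 10.0
        x = np.arange(10) * step
        traj = make_traj(x, np.zeros(10), frame_rate=10.0)
        out = compute_kinematics(traj, KinematicsConfig(smoothing_window=1))
        cls = out.vclass[0]
        if v <= 5.0 + 1e-9:
            assert cls == SLOW or abs(v - 5.0) < 1e-6
        elif v > 15.0 + 1e-9:
            assert cls == FAST
        # velocities are never negative
        assert np.all(out.velocity >= 0)


class TestZones:
    def test_pot2_center_is_pot2(self, geometry):
        px, py = geometry.pot_center(2)
        traj = make_traj([px, px], [py, py])
        out = annotate_zones(traj, geometry)
        assert np.all(out.zone == POT2)

    @pytest.mark.parametrize("factor,is_pot", [(1.6, True), (1.8, False)])
    def test_pot_zone_radius_factor(self, geometry, factor, is_pot):
        px, py = geometry.pot_center(2)
        cx, cy = geometry.arena_center
        # step radially toward the arena center, away from other features
        v = np.array([cx - px, cy - py])
        v = v / np.linalg.norm(v)
        p = np.array([px, py]) + factor * geometry.pot_radius * v
        out = annotate_zones(make_traj([p[0]] * 2, [p[1]] * 2), geometry)
        assert (out.zone[0] == POT2) == is_pot

    def test_arena_center_is_center_zone(self, geometry):
        cx, cy = geometry.arena_center
        out = annotate_zones(make_traj([cx] * 2, [cy] * 2), geometry)
        assert np.all(out.zone == CENTER)

    def test_zone_partition_counts_sum_to_frames(self, geometry):
        rng = np.random.default_rng(1)
        cx, cy = geometry.arena_center
        r = np.sqrt(rng.uniform(0, 1, 500)) * geometry.arena_radius
        th = rng.uniform(0, 2 * np.pi, 500)
        traj = make_traj(cx + r * np.cos(th), cy + r * np.sin(th))
        out = annotate_zones(traj, geometry)
        counts = np.bincount(out.zone, minlength=11)
        assert counts.sum() == traj.n_frames

    def test_in_tunnel_precedence(self, geometry):
        ix, iy = geometry.in_tunnel_point
        out = annotate_zones(make_traj([ix] * 2, [iy] * 2), geometry)
        assert np.all(out.zone == IN_TUNNEL)
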