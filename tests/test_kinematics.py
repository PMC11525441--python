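import math

import numpy as np
import pytest
from scipy.integrate import quad

from kinemotion import kinematics
from kinemotion.kinematics import (
    ALL_KEYPOINTS,
    STATISTIC_INVENTORY,
    FeatureSeries,
    acceleration,
    aggregate,
    angular_acceleration,
    angular_speed,
    com_distance,
    convex_hull_2d,
    convex_hull_3d,
    dimensionless_jerk,
    extract_all,
    finite_difference,
    head_angle_back,
    head_angle_vertical,
    limb_contraction,
    speed,
)
from kinemotion.motion_io import CamPosSeries
from kinemotion.skeleton import KEYPOINT_LABELS

from .conftest import series_from_positions


def brute_force_hull_area(points: np.ndarray) -> float:
    """O(n^3) 2D convex hull by pairwise edge test + shoelace area."""
    points = np.unique(np.asarray(points, dtype=float), axis=0)
    n = len(points)
    if n < 3:
        return 0.0
    hull_edges = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = points[i], points[j]
            cross = [
                (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
                for k, p in enumerate(points)
                if k not in (i, j)
            ]
            if all(c <= 1e-12 for c in cross):
                hull_edges.append((i, j))
    if not hull_edges:
        return 0.0
    succ = dict(hull_edges)
    start = hull_edges[0][0]
    order = [start]
    while True:
        nxt = succ[order[-1]]
        if nxt == start:
            break
        order.append(nxt)
    poly = points[order]
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestFiniteDifference:
    def test_constant_is_zero(self):
        out = finite_difference(np.ones((10, 3)), 1, 240.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linear_motion(self):
        t = np.arange(240) / 240.0
        channel = np.stack([t, np.zeros_like(t), np.zeros_like(t)], axis=1)
        out = finite_difference(channel, 1, 240.0)
        np.testing.assert_allclose(out[1:-1], np.tile([1.0, 0.0, 0.0], (238, 1)), atol=1e-9)

    def test_sinusoid_analytic_bound(self):
        framerate, f, A = 240.0, 2.0, 0.3
        t = np.arange(481) / framerate
        channel = (A * np.sin(2 * math.pi * f * t)).reshape(-1, 1)
        out = finite_difference(channel, 1, framerate)
        expected = A * 2 * math.pi * f * np.cos(2 * math.pi * f * t)
        max_err = np.abs(out[1:-1, 0] - expected[1:-1]).max()
        assert max_err < (2 * math.pi * f / framerate) ** 2 * A * 2 * math.pi * f

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match="at least 4"):
            finite_difference(np.zeros((3, 3)), 3, 60.0)


class TestSpeed:
    def test_stationary_zero(self, make_series):
        series = make_series(np.ones((20, 1, 3)))
        np.testing.assert_allclose(speed(series, "Pelvis").values, 0.0, atol=1e-12)

    def test_uniform_circle(self, make_series):
        t = np.arange(241) / 240.0
        positions = np.stack(
            [np.cos(2 * np.pi * t), np.sin(2 * np.pi * t), np.zeros_like(t)], axis=1
        ).reshape(-1, 1, 3)
        v = speed(make_series(positions), "Pelvis")
        np.testing.assert_allclose(v.values[1:-1], 2 * np.pi, atol=1e-3)

    def test_helix_analytic(self, make_series):
        t = np.arange(481) / 240.0
        r, pitch, omega = 0.7, 0.4, 3.0
        positions = np.stack(
            [r * np.cos(omega * t), r * np.sin(omega * t), pitch * t], axis=1
        ).reshape(-1, 1, 3)
        v = speed(make_series(positions), "Pelvis")
        expected = math.hypot(r * omega, pitch)
        np.testing.assert_allclose(v.values[1:-1], expected, atol=1e-3)

    def test_unknown_keypoint_lists_labels(self, make_series):
        series = make_series(np.zeros((5, 2, 3)))
        with pytest.raises(KeyError, match="Pelvis"):
            speed(series, "Nose")

    def test_file_velocity_channel_preferred(self, make_series):
        series = make_series(np.zeros((5, 1, 3)))
        series.aux["velocity"] = np.full((5, 1, 3), [3.0, 4.0, 0.0])
        np.testing.assert_allclose(speed(series, "Pelvis").values, 5.0)
        np.testing.assert_allclose(
            speed(series, "Pelvis", use_file_channels=False).values, 0.0, atol=1e-12
        )


class TestAcceleration:
    def test_constant_velocity_zero(self, make_series):
        t = np.arange(100) / 240.0
        positions = np.stack([t, 2 * t, -t], axis=1).reshape(-1, 1, 3)
        a = acceleration(make_series(positions), "Pelvis")
        np.testing.assert_allclose(a.values[2:-2], 0.0, atol=1e-9)

    def test_centripetal_magnitude(self, make_series):
        t = np.arange(241) / 240.0
        r, omega = 0.5, 4.0
        positions = np.stack(
            [r * np.cos(omega * t), r * np.sin(omega * t), np.zeros_like(t)], axis=1
        ).reshape(-1, 1, 3)
        a = acceleration(make_series(positions), "Pelvis")
        np.testing.assert_allclose(a.values[2:-2], r * omega**2, rtol=1e-3)

    def test_stationary_zero(self, make_series):
        a = acceleration(make_series(np.ones((10, 1, 3))), "Pelvis")
        np.testing.assert_allclose(a.values, 0.0, atol=1e-12)


class TestAngular:
    def test_fixed_orientation_zero(self, make_series):
        series = make_series(np.zeros((10, 1, 3)), orientations=np.ones((10, 1, 3)))
        np.testing.assert_allclose(angular_speed(series, "Pelvis").values, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            angular_acceleration(series, "Pelvis").values, 0.0, atol=1e-10
        )

    def test_full_revolution_per_second(self, make_series):
        # wrapped angles force the unwrapping path
        t = np.arange(481) / 240.0
        angle = np.mod(2 * np.pi * t + np.pi, 2 * np.pi) - np.pi
        orientations = np.zeros((481, 1, 3))
        orientations[:, 0, 2] = angle
        w = angular_speed(make_series(np.zeros((481, 1, 3)), orientations=orientations), "Pelvis")
        np.testing.assert_allclose(w.values[1:-1], 2 * np.pi, atol=1e-6)

    def test_90_degrees_per_second(self, make_series):
        t = np.arange(241) / 240.0
        orientations = np.zeros((241, 1, 3))
        orientations[:, 0, 2] = math.pi / 2 * t
        w = angular_speed(make_series(np.zeros((241, 1, 3)), orientations=orientations), "Pelvis")
        np.testing.assert_allclose(w.values, math.pi / 2, atol=1e-9)

    def test_quadratic_angle_constant_acceleration(self, make_series):
        alpha = 3.0
        t = np.arange(241) / 240.0
        orientations = np.zeros((241, 1, 3))
        orientations[:, 0, 0] = 0.5 * alpha * t**2
        w = angular_acceleration(
            make_series(np.zeros((241, 1, 3)), orientations=orientations), "Pelvis"
        )
        np.testing.assert_allclose(w.values[2:-2], alpha, rtol=1e-6)


class TestLimbContraction:
    def _full_series(self, head, extremities):
        positions = np.zeros((1, 23, 3))
        positions[0, KEYPOINT_LABELS.index("Head")] = head
        for label, p in zip(("Right hand", "Left hand", "Right toe", "Left toe"), extremities):
            positions[0, KEYPOINT_LABELS.index(label)] = p
        return series_from_positions(positions)

    def test_coincident_zero(self):
        series = self._full_series([0, 0, 0], [[0, 0, 0]] * 4)
        np.testing.assert_allclose(limb_contraction(series).values, 0.0, atol=1e-12)

    def test_hand_computed_mean(self):
        # distances 1, 2, 3, 4 -> mean 2.5
        series = self._full_series(
            [0, 0, 0], [[1, 0, 0], [0, 2, 0], [0, 0, 3], [4, 0, 0]]
        )
        np.testing.assert_allclose(limb_contraction(series).values, 2.5, atol=1e-12)

    def test_translation_invariant(self, full_body_series):
        shifted = series_from_positions(
            full_body_series.positions + [5.0, -3.0, 2.0],
            framerate=full_body_series.framerate,
        )
        np.testing.assert_allclose(
            limb_contraction(shifted).values,
            limb_contraction(full_body_series).values,
            atol=1e-9,
        )


class TestComDistance:
    def test_at_com_zero(self, make_series):
        positions = np.ones((5, 1, 3))
        series = make_series(positions, com=positions[:, 0])
        np.testing.assert_allclose(com_distance(series, "Pelvis").values, 0.0, atol=1e-12)

    def test_3_4_5(self, make_series):
        com = np.zeros((5, 3))
        positions = np.tile([3.0, 4.0, 0.0], (5, 1, 1))
        series = make_series(positions, com=com)
        np.testing.assert_allclose(com_distance(series, "Pelvis").values, 5.0, atol=1e-12)

    def test_translation_invariant(self, full_body_series):
        shift = np.array([1.0, 2.0, 3.0])
        shifted = series_from_positions(
            full_body_series.positions + shift,
            framerate=full_body_series.framerate,
            com=full_body_series.com + shift,
        )
        for label in ("Pelvis", "Right hand"):
            np.testing.assert_allclose(
                com_distance(shifted, label).values,
                com_distance(full_body_series, label).values,
                atol=1e-9,
            )


class TestDimensionlessJerk:
    def test_constant_velocity_zero(self, make_series):
        t = np.arange(100) / 60.0
        positions = np.stack([t, np.zeros_like(t), np.zeros_like(t)], axis=1).reshape(-1, 1, 3)
        series = make_series(positions, framerate=60.0, com=positions[:, 0])
        assert dimensionless_jerk(series, "com") == pytest.approx(0.0, abs=1e-9)

    def test_minimum_jerk_polynomial_oracle(self, make_series):
        # classical minimum-jerk point-to-point move; oracle = analytic jerk
        # integrated independently with adaptive quadrature
        T, D, fs = 1.0, 0.5, 20000.0
        n = int(T * fs) + 1
        tau = np.arange(n) / fs / T
        x = D * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
        positions = np.zeros((n, 1, 3))
        positions[:, 0, 0] = x
        series = make_series(positions, framerate=fs, com=positions[:, 0])
        value = dimensionless_jerk(series, "com")

        jerk = lambda u: D / T**3 * (60 - 360 * u / T + 360 * (u / T) ** 2)  # noqa: E731
        oracle = T**5 / D**2 * quad(lambda u: jerk(u) ** 2, 0, T)[0]
        assert value == pytest.approx(oracle, rel=1e-3)

    def test_scale_invariance(self, full_body_series):
        scaled = series_from_positions(
            full_body_series.positions * 2.0,
            framerate=full_body_series.framerate,
            com=full_body_series.com * 2.0,
        )
        a = dimensionless_jerk(full_body_series, "com")
        b = dimensionless_jerk(scaled, "com")
        assert b == pytest.approx(a, rel=1e-9)

    def test_zero_extent_zero_jerk_is_zero(self, make_series):
        positions = np.zeros((50, 1, 3))
        series = make_series(positions, framerate=60.0, com=np.ones((50, 3)))
        assert dimensionless_jerk(series, "com") == 0.0

    def test_resampling_stability(self, make_series):
        # the same smooth trajectory sampled at fs and 2 fs drifts < 1%
        def build(fs):
            t = np.arange(int(4 * fs) + 1) / fs
            x = 0.4 * np.sin(2 * np.pi * 0.5 * t) + 0.1 * np.sin(2 * np.pi * 1.3 * t)
            positions = np.zeros((t.size, 1, 3))
            positions[:, 0, 0] = x
            return make_series(positions, framerate=fs, com=positions[:, 0])

        a = dimensionless_jerk(build(2000.0), "com")
        b = dimensionless_jerk(build(4000.0), "com")
        assert abs(b - a) / a < 0.01


class TestHeadAngles:
    def _series(self, t8, neck, head):
        positions = np.zeros((1, 23, 3))
        positions[0, KEYPOINT_LABELS.index("T8")] = t8
        positions[0, KEYPOINT_LABELS.index("Neck")] = neck
        positions[0, KEYPOINT_LABELS.index("Head")] = head
        return series_from_positions(positions)

    def test_collinear_zero(self):
        s = self._series([0, 0, 0], [0, 0, 1], [0, 0, 2])
        np.testing.assert_allclose(head_angle_back(s).values, 0.0, atol=1e-9)

    def test_perpendicular(self):
        s = self._series([0, 0, 0], [0, 0, 1], [1, 0, 1])
        np.testing.assert_allclose(head_angle_back(s).values, math.pi / 2, atol=1e-12)

    def test_rotation_invariant(self, full_body_series):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [0.3, -0.2, 1.1]).as_matrix()
        rotated = series_from_positions(
            full_body_series.positions @ R.T, framerate=full_body_series.framerate
        )
        np.testing.assert_allclose(
            head_angle_back(rotated).values, head_angle_back(full_body_series).values, atol=1e-9
        )

    def test_vertical_upright_zero(self):
        s = self._series([0, 0, 0], [0, 0, 1], [0, 0, 2])
        np.testing.assert_allclose(head_angle_vertical(s).values, 0.0, atol=1e-9)

    def test_vertical_horizontal_head(self):
        s = self._series([0, 0, 0], [0, 0, 1], [1, 0, 1])
        np.testing.assert_allclose(head_angle_vertical(s).values, math.pi / 2, atol=1e-12)

    def test_vertical_45_degrees(self):
        s = self._series([0, 0, 0], [0, 0, 1], [0, 1 / math.sqrt(2), 1 + 1 / math.sqrt(2)])
        np.testing.assert_allclose(head_angle_vertical(s).values, math.pi / 4, atol=1e-9)

    def test_coincident_keypoints_error(self):
        s = self._series([0, 0, 0], [0, 0, 0], [0, 0, 1])
        with pytest.raises(ValueError, match="zero-length"):
            head_angle_back(s)


class TestConvexHull3D:
    def test_unit_cube(self, make_series):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        interior = np.full((15, 3), 0.5)
        points = np.vstack([corners, interior]).reshape(1, 23, 3)
        fs = convex_hull_3d(make_series(points), "per-frame")
        np.testing.assert_allclose(fs.values, 1.0, atol=1e-12)

    def test_regular_tetrahedron(self, make_series):
        a = 1.3
        verts = a / (2 * math.sqrt(2)) * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        # edge length check: |v0 - v1| should be a
        assert np.linalg.norm(verts[0] - verts[1]) == pytest.approx(a)
        fs = convex_hull_3d(make_series(verts.reshape(1, 4, 3)), "per-frame")
        np.testing.assert_allclose(fs.values, a**3 / (6 * math.sqrt(2)), atol=1e-9)

    def test_static_pose_per_frame_equals_global_and_union(self, make_series):
        rng = np.random.default_rng(6)
        frame = rng.normal(size=(23, 3))
        series = make_series(np.tile(frame, (5, 1, 1)))
        per_frame = convex_hull_3d(series, "per-frame")
        global_vol = convex_hull_3d(series, "global")
        union_vol = convex_hull_3d(series, "union", voxel=0.02)
        np.testing.assert_allclose(per_frame.values, global_vol, atol=1e-9)
        assert union_vol == pytest.approx(global_vol, rel=0.1)
        assert union_vol <= global_vol + 1e-12

    def test_degenerate_frame_zero_with_warning(self, make_series):
        series = make_series(np.zeros((2, 5, 3)))
        with pytest.warns(UserWarning, match="degenerate"):
            fs = convex_hull_3d(series, "per-frame")
        np.testing.assert_allclose(fs.values, 0.0)

    def test_translating_cube_union_analytic(self, make_series):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        n_frames = 11
        frames = np.stack(
            [corners + [0.05 * k, 0, 0] for k in range(n_frames)]
        )  # sweeps x over [0, 1.5]
        series = make_series(frames)
        union = convex_hull_3d(series, "union", voxel=0.025)
        assert union == pytest.approx(1.5, rel=0.02)

    def test_union_voxel_convergence(self, make_series):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        frames = np.stack([corners + [0.1 * k, 0.05 * k, 0] for k in range(6)])
        series = make_series(frames)
        coarse = convex_hull_3d(series, "union", voxel=0.04)
        fine = convex_hull_3d(series, "union", voxel=0.02)
        assert abs(fine - coarse) / fine < 0.02


class TestConvexHull2D:
    def _campos(self, frames):
        frames = np.asarray(frames, dtype=float)
        xyd = np.concatenate([frames, np.ones(frames.shape[:2] + (1,))], axis=2)
        names = [f"p{i}" for i in range(frames.shape[1])]
        return CamPosSeries(names, xyd, 60.0)

    def test_full_screen(self):
        campos = self._campos([[[0, 0], [1, 0], [1, 1], [0, 1]]])
        fs = convex_hull_2d(campos, "per-frame")
        np.testing.assert_allclose(fs.values, 1.0, atol=1e-12)

    def test_triangle_area(self):
        campos = self._campos([[[0, 0], [0.5, 0], [0, 0.5]]])
        fs = convex_hull_2d(campos, "per-frame")
        np.testing.assert_allclose(fs.values, 0.125, atol=1e-12)

    def test_union_le_global(self):
        rng = np.random.default_rng(7)
        campos = self._campos(rng.uniform(0, 1, size=(6, 8, 2)))
        assert convex_hull_2d(campos, "union") <= convex_hull_2d(campos, "global") + 1e-12

    @pytest.mark.parametrize("n_points", [3, 4, 5, 6, 7, 8])
    def test_matches_brute_force_oracle(self, n_points):
        rng = np.random.default_rng(n_points)
        points = rng.uniform(0, 1, size=(n_points, 2))
        campos = self._campos(points.reshape(1, n_points, 2))
        fs = convex_hull_2d(campos, "per-frame")
        assert fs.values[0] == pytest.approx(brute_force_hull_area(points), rel=1e-12)


class TestAggregate:
    def _fs(self, values, framerate=1.0):
        return FeatureSeries("test", ALL_KEYPOINTS, np.asarray(values, float), "m", framerate)

    def test_constant(self):
        fs = self._fs([2.0] * 5)
        assert aggregate(fs, "average") == 2.0
        assert aggregate(fs, "mad") == 0.0
        assert aggregate(fs, "max") == 2.0

    def test_mad_hand_computed(self):
        # median 3; |3 - x| = [2, 1, 0, 1, 2]; median of that = 1
        assert aggregate(self._fs([1, 2, 3, 4, 5]), "mad") == 1.0

    def test_integral_trapezoid(self):
        fs = self._fs([0, 1, 2, 3], framerate=2.0)
        assert aggregate(fs, "integral") == pytest.approx(np.trapezoid([0, 1, 2, 3], dx=0.5))

    def test_max_ge_average(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 10, size=50)
        fs = self._fs(values)
        assert aggregate(fs, "max") >= aggregate(fs, "average")

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate(self._fs([]), "average")

    def test_nan_excluded(self):
        fs = self._fs([1.0, np.nan, 3.0])
        assert aggregate(fs, "average") == 2.0


@pytest.fixture(scope="module")
def inputs():
    from kinemotion.motion_io import project_campos
    from kinemotion.synthetic import (
        DEFAULT_PROFILES,
        default_camera,
        generate_choreography,
        render_silhouette,
    )

    series = generate_choreography(
        2, DEFAULT_PROFILES["joy"], duration=1.0, framerate=60.0, seed=11
    )
    camera = default_camera()
    campos = project_campos(series, camera, 30.0)
    clip = render_silhouette(series, camera, fps=12.5, size=(72, 128))
    return series, campos, clip


class TestExtractAll:

    def test_full_inventory_32(self, inputs):
        series, campos, clip = inputs
        table = extract_all(series, campos, clip, voxel=0.05)
        kinds = set(zip(table["feature"], table["statistic"]))
        assert kinds == set(STATISTIC_INVENTORY)
        assert len(kinds) == 32
        assert table["feature"].nunique() == 12

    def test_without_silhouette_29_kinds(self, inputs, caplog):
        series, campos, _ = inputs
        import logging

        with caplog.at_level(logging.WARNING):
            table = extract_all(series, campos, None, voxel=0.05)
        kinds = set(zip(table["feature"], table["statistic"]))
        assert len(kinds) == 29
        assert not any(f == "qom" for f, _ in kinds)
        assert any("silhouette" in r.message for r in caplog.records)

    def test_deterministic(self, inputs):
        series, campos, clip = inputs
        a = extract_all(series, campos, clip, voxel=0.05)
        b = extract_all(series, campos, clip, voxel=0.05)
        assert a.equals(b)

    def test_per_joint_rows_expanded(self, inputs):
        series, campos, clip = inputs
        table = extract_all(series, campos, clip, voxel=0.05)
        sub = table[(table["feature"] == "speed") & (table["statistic"] == "average")]
        assert len(sub) == 24  # 23 keypoints + ALL mean row
        all_row = sub[sub["keypoint"] == ALL_KEYPOINTS]["value"].iloc[0]
        per_joint = sub[sub["keypoint"] != ALL_KEYPOINTS]["value"]
        assert all_row == pytest.approx(per_joint.mean())

    def test_nonnegative(self, inputs):
        series, campos, clip = inputs
        table = extract_all(series, campos, clip, voxel=0.05)
        assert (table["value"] >= -1e-12).all()
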