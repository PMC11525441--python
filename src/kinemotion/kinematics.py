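"""Kinematic features and summary statistics.

Twelve features are computed from keypoint pose series, camera-relative
landmark series and silhouette clips, and aggregated into 32 summary
statistics: per-frame speed / acceleration / angular speed / angular
acceleration (average, MAD, max each), limb contraction, distance to
center of mass, head tilt w.r.t. back and w.r.t. vertical (average, MAD
each), quantity of motion (average, MAD, integral), dimensionless jerk
(one scalar), and 3D / 2D convex hull (average, MAD, global, union each).

Every feature is a nonnegative scalar per frame (a norm, distance, angle
in [0, pi], ratio, area, or volume).  Derivatives use central finite
differences with one-sided boundaries; Euler angle channels are unwrapped
per axis before differentiation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPoint
from shapely.ops import unary_union

from . import skeleton
from .motion_io import CamPosSeries, KeypointFrameSeries

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSeries",
    "finite_difference",
    "speed",
    "acceleration",
    "angular_speed",
    "angular_acceleration",
    "limb_contraction",
    "com_distance",
    "dimensionless_jerk",
    "head_angle_back",
    "head_angle_vertical",
    "convex_hull_3d",
    "convex_hull_2d",
    "aggregate",
    "extract_all",
    "ALL_KEYPOINTS",
    "STATISTIC_INVENTORY",
    "SUMMARY_COLUMNS",
]

#: Sentinel keypoint label for full-body features and cross-joint means.
ALL_KEYPOINTS = "ALL"

#: The 32 (feature, statistic) kinds of a full extraction.
STATISTIC_INVENTORY: tuple[tuple[str, str], ...] = tuple(
    (feature, statistic)
    for feature, statistics in [
        ("speed", ("average", "mad", "max")),
        ("acceleration", ("average", "mad", "max")),
        ("angular_speed", ("average", "mad", "max")),
        ("angular_acceleration", ("average", "mad", "max")),
        ("limb_contraction", ("average", "mad")),
        ("com_distance", ("average", "mad")),
        ("qom", ("average", "mad", "integral")),
        ("dimensionless_jerk", ("integral",)),
        ("head_angle_back", ("average", "mad")),
        ("head_angle_vertical", ("average", "mad")),
        ("convex_hull_3d", ("average", "mad", "global", "union")),
        ("convex_hull_2d", ("average", "mad", "global", "union")),
    ]
    for statistic in statistics
)

SUMMARY_COLUMNS = ("sequence", "emotion", "feature", "statistic", "keypoint", "value", "units")


@dataclass
class FeatureSeries:
    """One nonnegative scalar per frame for a named kinematic feature.

    ``n_edge`` marks how many frames at each end are boundary-estimated
    (one-sided differences); aggregations include them by default.
    Undefined frames are NaN and are excluded from aggregation.
    """

    name: str
    keypoint: str
    values: np.ndarray
    units: str
    framerate: float
    n_edge: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError(f"feature values must be 1-D, got shape {self.values.shape}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < -1e-12:
            raise ValueError(
                f"feature {self.name!r} has negative value {finite.min()!r}"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.framerate


# ---------------------------------------------------------------------------
# Differentiation
# ---------------------------------------------------------------------------


def finite_difference(channel: np.ndarray, order: int, framerate: float) -> np.ndarray:
    """Time derivative of a per-frame channel by repeated central differences.

    Interior frames use second-order central differences; the first/last
    frame of each pass uses a one-sided difference.  Output length equals
    input length; units are divided by s**order.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    channel = np.asarray(channel, dtype=float)
    if channel.shape[0] < order + 1:
        raise ValueError(
            f"order-{order} differentiation needs at least {order + 1} frames, "
            f"got {channel.shape[0]}"
        )
    out = channel
    dt = 1.0 / framerate
    # second-order one-sided edges: first-order edges leave an O(dt)
    # boundary error that repeated differentiation amplifies to O(1/dt)
    edge_order = 2 if channel.shape[0] >= 3 else 1
    for _ in range(order):
        out = np.gradient(out, dt, axis=0, edge_order=edge_order)
    return out


def _position_derivative(
    series: KeypointFrameSeries, j: int, order: int, use_file_channels: bool
) -> np.ndarray:
    channel_name = {1: "velocity", 2: "acceleration"}.get(order)
    if use_file_channels and channel_name in series.aux:
        return series.aux[channel_name][:, j]
    return finite_difference(series.positions[:, j], order, series.framerate)


def _orientation_derivative(
    series: KeypointFrameSeries, j: int, order: int, use_file_channels: bool
) -> np.ndarray:
    channel_name = {1: "angular_velocity", 2: "angular_acceleration"}.get(order)
    if use_file_channels and channel_name in series.aux:
        return series.aux[channel_name][:, j]
    unwrapped = np.unwrap(series.orientations[:, j], axis=0)
    return finite_difference(unwrapped, order, series.framerate)


# ---------------------------------------------------------------------------
# Per-keypoint features
# ---------------------------------------------------------------------------


def speed(
    series: KeypointFrameSeries, keypoint: str, use_file_channels: bool = True
) -> FeatureSeries:
    """Euclidean norm of the keypoint velocity, in m/s."""
    j = series.index_of(keypoint)
    v = _position_derivative(series, j, 1, use_file_channels)
    return FeatureSeries(
        "speed", keypoint, np.linalg.norm(v, axis=1), "m/s", series.framerate, n_edge=1
    )


def acceleration(
    series: KeypointFrameSeries, keypoint: str, use_file_channels: bool = True
) -> FeatureSeries:
    """Euclidean norm of the keypoint acceleration, in m/s^2."""
    j = series.index_of(keypoint)
    a = _position_derivative(series, j, 2, use_file_channels)
    return FeatureSeries(
        "acceleration", keypoint, np.linalg.norm(a, axis=1), "m/s^2", series.framerate, n_edge=2
    )


def angular_speed(
    series: KeypointFrameSeries, keypoint: str, use_file_channels: bool = True
) -> FeatureSeries:
    """Euclidean norm of the Euler-angle rate, in rad/s."""
    j = series.index_of(keypoint)
    w = _orientation_derivative(series, j, 1, use_file_channels)
    return FeatureSeries(
        "angular_speed", keypoint, np.linalg.norm(w, axis=1), "rad/s", series.framerate, n_edge=1
    )


def angular_acceleration(
    series: KeypointFrameSeries, keypoint: str, use_file_channels: bool = True
) -> FeatureSeries:
    """Euclidean norm of the second Euler-angle derivative, in rad/s^2."""
    j = series.index_of(keypoint)
    w = _orientation_derivative(series, j, 2, use_file_channels)
    return FeatureSeries(
        "angular_acceleration",
        keypoint,
        np.linalg.norm(w, axis=1),
        "rad/s^2",
        series.framerate,
        n_edge=2,
    )


def com_distance(series: KeypointFrameSeries, keypoint: str) -> FeatureSeries:
    """Distance between a keypoint and the center of mass, in m."""
    j = series.index_of(keypoint)
    d = np.linalg.norm(series.positions[:, j] - series.com, axis=1)
    return FeatureSeries("com_distance", keypoint, d, "m", series.framerate)


# ---------------------------------------------------------------------------
# Full-body features
# ---------------------------------------------------------------------------


def limb_contraction(series: KeypointFrameSeries) -> FeatureSeries:
    """Mean distance between the head and the four extremity endpoints, in m."""
    head = series.positions[:, series.index_of("Head")]
    dists = [
        np.linalg.norm(head - series.positions[:, series.index_of(label)], axis=1)
        for label in skeleton.EXTREMITY_LABELS
    ]
    values = np.mean(dists, axis=0)
    return FeatureSeries("limb_contraction", ALL_KEYPOINTS, values, "m", series.framerate)


def _unit(vectors: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError(f"zero-length {what} segment (coincident keypoints)")
    return vectors / norms


def head_angle_back(series: KeypointFrameSeries) -> FeatureSeries:
    """Angle between the lower-back->neck and neck->head directions, in rad."""
    a, b, c = (series.positions[:, series.index_of(l)] for l in skeleton.HEAD_CHAIN_LABELS)
    u_ab = _unit(b - a, "back")
    u_bc = _unit(c - b, "neck-head")
    cosine = np.clip(np.sum(u_ab * u_bc, axis=1), -1.0, 1.0)
    return FeatureSeries(
        "head_angle_back", ALL_KEYPOINTS, np.arccos(cosine), "rad", series.framerate
    )


def head_angle_vertical(series: KeypointFrameSeries) -> FeatureSeries:
    """Angle between the neck->head direction and global vertical, in rad."""
    _, b, c = (series.positions[:, series.index_of(l)] for l in skeleton.HEAD_CHAIN_LABELS)
    u_bc = _unit(c - b, "neck-head")
    cosine = np.clip(u_bc[:, 2], -1.0, 1.0)
    return FeatureSeries(
        "head_angle_vertical", ALL_KEYPOINTS, np.arccos(cosine), "rad", series.framerate
    )


def _trajectory_diameter(points: np.ndarray) -> float:
    """Exact Euclidean diameter of a point set (max pairwise distance).

    The diameter is attained at convex hull vertices, so the hull is used
    to prune when possible; degenerate sets fall back to a brute-force
    pairwise scan (bounding-box diagonal beyond 10^4 points).
    """
    points = np.unique(points, axis=0)
    if points.shape[0] < 2:
        return 0.0
    candidates = points
    if points.shape[0] > 4:
        try:
            candidates = points[ConvexHull(points).vertices]
        except QhullError:
            if points.shape[0] > 10_000:
                span = points.max(axis=0) - points.min(axis=0)
                return float(np.linalg.norm(span))
    diffs = candidates[:, None, :] - candidates[None, :, :]
    return float(np.sqrt((diffs**2).sum(axis=2)).max())


def dimensionless_jerk(
    series: KeypointFrameSeries, trajectory: str = "com"
) -> float:
    """Duration- and amplitude-normalized integral of squared jerk.

    Computes ``(duration^5 / extent^2) * integral(|d^3 p/dt^3|^2 dt)`` over
    the whole sequence, with jerk from third-order finite differences, the
    integral by the trapezoidal rule on the frame grid in seconds, and the
    movement extent the Euclidean diameter of the trajectory point set.
    ``trajectory`` is ``"com"`` (default full-body choice) or a keypoint
    label.
    """
    if trajectory == "com":
        traj = series.com
    else:
        traj = series.positions[:, series.index_of(trajectory)]
    if series.frame_count < 4:
        raise ValueError("dimensionless jerk needs at least 4 frames")
    jerk = finite_difference(traj, 3, series.framerate)
    squared = (jerk**2).sum(axis=1)
    integral = float(np.trapezoid(squared, dx=1.0 / series.framerate))
    extent = _trajectory_diameter(traj)
    duration = (series.frame_count - 1) / series.framerate
    if extent == 0.0:
        if integral < 1e-30:
            return 0.0
        raise ValueError("zero movement extent with nonzero jerk: normalization undefined")
    return duration**5 / extent**2 * integral


# ---------------------------------------------------------------------------
# Convex hulls
# ---------------------------------------------------------------------------


def _hull_volume_3d(points: np.ndarray) -> float:
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        warnings.warn("degenerate (coplanar) frame: convex hull volume set to 0")
        return 0.0


def convex_hull_3d(
    series: KeypointFrameSeries, mode: str = "per-frame", voxel: float = 0.01
):
    """Convex-hull volume of the keypoint cloud, in m^3.

    ``mode="per-frame"`` returns a :class:`FeatureSeries` of per-frame hull
    volumes; ``"global"`` the volume of the hull of all keypoints over all
    frames; ``"union"`` the volume of the union of per-frame hulls,
    approximated on a voxel grid of edge ``voxel`` meters and clipped to
    the global volume (the union is a subset of the global hull).
    """
    if mode == "per-frame":
        values = np.array([_hull_volume_3d(p) for p in series.positions])
        return FeatureSeries("convex_hull_3d", ALL_KEYPOINTS, values, "m^3", series.framerate)
    all_points = series.positions.reshape(-1, 3)
    global_volume = _hull_volume_3d(all_points)
    if mode == "global":
        return global_volume
    if mode != "union":
        raise ValueError(f"unknown mode {mode!r}; expected per-frame, global or union")

    lo = all_points.min(axis=0)
    hi = all_points.max(axis=0)
    counts = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    centers = [lo[d] + (np.arange(counts[d]) + 0.5) * voxel for d in range(3)]
    occupied = np.zeros(tuple(counts), dtype=bool)
    for frame in series.positions:
        try:
            hull = ConvexHull(frame)
        except QhullError:
            continue  # degenerate frame contributes zero volume
        eqs = hull.equations  # (n_faces, 4): normal . x + offset <= 0 inside
        f_lo = frame.min(axis=0)
        f_hi = frame.max(axis=0)
        idx = []
        for d in range(3):
            i0 = int(np.searchsorted(centers[d], f_lo[d] - voxel))
            i1 = int(np.searchsorted(centers[d], f_hi[d] + voxel))
            idx.append((i0, i1))
        (x0, x1), (y0, y1), (z0, z1) = idx
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        sub = occupied[x0:x1, y0:y1, z0:z1]
        todo = ~sub
        if not todo.any():
            continue
        gx, gy, gz = np.meshgrid(
            centers[0][x0:x1], centers[1][y0:y1], centers[2][z0:z1], indexing="ij"
        )
        pts = np.stack([gx[todo], gy[todo], gz[todo]], axis=1)
        inside = (pts @ eqs[:, :3].T + eqs[:, 3] <= 1e-9).all(axis=1)
        sub[todo] = inside
        occupied[x0:x1, y0:y1, z0:z1] = sub
    union_volume = float(occupied.sum()) * voxel**3
    return min(union_volume, global_volume)


def _hull_area_2d(points: np.ndarray) -> float:
    return float(MultiPoint(points).convex_hull.area)


def convex_hull_2d(campos: CamPosSeries, mode: str = "per-frame"):
    """Convex-hull area of the landmark screen positions (ratio of screen).

    ``mode="per-frame"`` returns a :class:`FeatureSeries`; ``"global"`` the
    hull area over all frames; ``"union"`` the exact area of the union of
    per-frame hull polygons (always <= global).
    """
    if mode == "per-frame":
        values = np.array([_hull_area_2d(f) for f in campos.xy])
        return FeatureSeries(
            "convex_hull_2d", ALL_KEYPOINTS, values, "screen-ratio^2", campos.framerate
        )
    global_area = _hull_area_2d(campos.xy.reshape(-1, 2))
    if mode == "global":
        return global_area
    if mode != "union":
        raise ValueError(f"unknown mode {mode!r}; expected per-frame, global or union")
    hulls = [MultiPoint(f).convex_hull for f in campos.xy]
    union_area = float(unary_union(hulls).area)
    return min(union_area, global_area)


# ---------------------------------------------------------------------------
# Aggregation and the full summary
# ---------------------------------------------------------------------------


def aggregate(
    feature: FeatureSeries, statistic: str, exclude_edges: bool = False
) -> float:
    """Reduce a feature series to one scalar.

    ``statistic`` is ``average`` (mean over frames), ``mad`` (median of
    absolute deviations from the series median, no consistency constant),
    ``max``, or ``integral`` (trapezoidal sum over time in seconds).
    NaN frames (undefined values) are excluded.  With ``exclude_edges``
    the boundary-estimated frames marked by the feature are dropped first.
    """
    values = feature.values
    times = feature.times
    if exclude_edges and feature.n_edge:
        k = feature.n_edge
        values = values[k:-k]
        times = times[k:-k]
    mask = np.isfinite(values)
    values = values[mask]
    times = times[mask]
    if values.size == 0:
        raise ValueError(f"cannot aggregate empty feature series {feature.name!r}")
    if statistic == "average":
        return float(values.mean())
    if statistic == "mad":
        return float(np.median(np.abs(np.median(values) - values)))
    if statistic == "max":
        return float(values.max())
    if statistic == "integral":
        return float(np.trapezoid(values, x=times))
    raise ValueError(f"unknown statistic {statistic!r}")


_PER_JOINT = {
    "speed": (speed, ("average", "mad", "max")),
    "acceleration": (acceleration, ("average", "mad", "max")),
    "angular_speed": (angular_speed, ("average", "mad", "max")),
    "angular_acceleration": (angular_acceleration, ("average", "mad", "max")),
    "com_distance": (com_distance, ("average", "mad")),
}

_FULL_BODY = {
    "limb_contraction": (limb_contraction, ("average", "mad")),
    "head_angle_back": (head_angle_back, ("average", "mad")),
    "head_angle_vertical": (head_angle_vertical, ("average", "mad")),
}


def extract_all(
    series: KeypointFrameSeries,
    campos: CamPosSeries | None = None,
    silhouette_clip=None,
    *,
    sequence: str = "",
    emotion: str = "",
    delta: int = 5,
    voxel: float = 0.01,
    jerk_trajectory: str = "com",
    use_file_channels: bool = True,
    exclude_edges: bool = False,
) -> pd.DataFrame:
    """Compute the full 32-statistic summary table for one sequence.

    Returns a long-format DataFrame with columns ``sequence, emotion,
    feature, statistic, keypoint, value, units``.  Per-joint features add
    one row per keypoint plus an ALL row holding the cross-joint mean of
    the statistic.  If ``campos`` or ``silhouette_clip`` is missing, the
    dependent features (2D hull; QoM) are omitted with a logged warning.
    """
    from .silhouette import qom as silhouette_qom

    rows: list[tuple] = []

    def add(feature: str, statistic: str, keypoint: str, value: float, units: str) -> None:
        rows.append((sequence, emotion, feature, statistic, keypoint, float(value), units))

    for name, (func, statistics) in _PER_JOINT.items():
        per_joint: dict[str, FeatureSeries] = {}
        for label in series.keypoint_labels:
            if name == "com_distance":
                per_joint[label] = func(series, label)
            else:
                per_joint[label] = func(series, label, use_file_channels)
        units = next(iter(per_joint.values())).units
        for statistic in statistics:
            per_joint_values = {
                label: aggregate(fs, statistic, exclude_edges)
                for label, fs in per_joint.items()
            }
            for label, value in per_joint_values.items():
                add(name, statistic, label, value, units)
            add(name, statistic, ALL_KEYPOINTS, np.mean(list(per_joint_values.values())), units)

    for name, (func, statistics) in _FULL_BODY.items():
        fs = func(series)
        for statistic in statistics:
            add(name, statistic, ALL_KEYPOINTS, aggregate(fs, statistic, exclude_edges), fs.units)

    if silhouette_clip is not None:
        q = silhouette_qom(silhouette_clip, delta)
        for statistic in ("average", "mad", "integral"):
            add("qom", statistic, ALL_KEYPOINTS, aggregate(q, statistic), "dimensionless")
    else:
        logger.warning("no silhouette clip: QoM statistics omitted")

    add(
        "dimensionless_jerk",
        "integral",
        ALL_KEYPOINTS,
        dimensionless_jerk(series, jerk_trajectory),
        "dimensionless",
    )

    hull3 = convex_hull_3d(series, "per-frame")
    for statistic in ("average", "mad"):
        add("convex_hull_3d", statistic, ALL_KEYPOINTS, aggregate(hull3, statistic), "m^3")
    add("convex_hull_3d", "global", ALL_KEYPOINTS, convex_hull_3d(series, "global"), "m^3")
    add(
        "convex_hull_3d",
        "union",
        ALL_KEYPOINTS,
        convex_hull_3d(series, "union", voxel=voxel),
        "m^3",
    )

    if campos is not None:
        hull2 = convex_hull_2d(campos, "per-frame")
        for statistic in ("average", "mad"):
            add(
                "convex_hull_2d",
                statistic,
                ALL_KEYPOINTS,
                aggregate(hull2, statistic),
                "screen-ratio^2",
            )
        add("convex_hull_2d", "global", ALL_KEYPOINTS, convex_hull_2d(campos, "global"), "screen-ratio^2")
        add("convex_hull_2d", "union", ALL_KEYPOINTS, convex_hull_2d(campos, "union"), "screen-ratio^2")
    else:
        logger.warning("no CamPos series: 2D convex hull statistics omitted")

    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
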