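"""Readers/writers for the package's data modalities and framerate resampling.

Three modalities are supported:

* a documented minimal dialect of the MVNX-style XML export of inertial
  motion-capture suits (segments + per-frame position / orientation /
  centerOfMass records, optional derivative and foot-contact channels),
* per-quantity tabular CSV files,
* camera-relative "CamPos" JSON (screen-ratio x, y plus metric depth).

Internally everything is meters and radians; frames are 0-based with
``t = frame / framerate``.
"""

from __future__ import annotations

import json
import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "KeypointFrameSeries",
    "CameraModel",
    "CamPosSeries",
    "MvnxParseError",
    "ValidationError",
    "parse_mvnx",
    "write_csv",
    "read_csv",
    "project_campos",
    "resample",
    "write_campos_json",
    "read_campos_json",
    "CSV_QUANTITIES",
]


class MvnxParseError(ValueError):
    """Malformed MVNX-style document."""


class ValidationError(ValueError):
    """Inconsistent channel shapes or invalid metadata."""


#: Optional per-keypoint derivative channels an MVNX-style file may carry.
AUX_CHANNELS = ("velocity", "acceleration", "angular_velocity", "angular_acceleration")

#: CSV quantity -> filename stem, in the canonical export order.
CSV_QUANTITIES = (
    "position",
    "orientation",
    "velocity",
    "angular_velocity",
    "acceleration",
    "angular_acceleration",
    "center_of_mass",
    "foot_contacts",
)


@dataclass
class KeypointFrameSeries:
    """Per-keypoint 3D pose time series.

    Attributes
    ----------
    keypoint_labels : list of str
        Segment names in file order; a full-body series carries the 23
        canonical labels.
    positions : ndarray, shape (T, J, 3)
        Keypoint positions in meters, world frame (x north, y west, z up).
    orientations : ndarray, shape (T, J, 3)
        Euler angle vectors in radians (Z-flexion / X-abduction /
        Y-internal convention).
    com : ndarray, shape (T, 3)
        Center of mass in meters.
    foot_contacts : ndarray of bool, shape (T, 2)
        Left/right foot contact flags.
    framerate : float
        Sampling rate in Hz, > 0.
    aux : dict
        Optional derivative channels (velocity, acceleration,
        angular_velocity, angular_acceleration), each (T, J, 3).
    """

    keypoint_labels: list[str]
    positions: np.ndarray
    orientations: np.ndarray
    com: np.ndarray
    foot_contacts: np.ndarray
    framerate: float
    aux: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.com = np.asarray(self.com, dtype=float)
        self.foot_contacts = np.asarray(self.foot_contacts, dtype=bool)
        self.validate()

    @property
    def frame_count(self) -> int:
        return self.positions.shape[0]

    @property
    def n_keypoints(self) -> int:
        return len(self.keypoint_labels)

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (0-based frames)."""
        return np.arange(self.frame_count) / self.framerate

    def validate(self) -> None:
        if self.framerate <= 0:
            raise ValidationError(f"framerate must be > 0, got {self.framerate}")
        T, J = self.positions.shape[:2]
        if J != len(self.keypoint_labels):
            raise ValidationError(
                f"positions carry {J} keypoints but {len(self.keypoint_labels)} labels given"
            )
        for name, arr, shape in [
            ("positions", self.positions, (T, J, 3)),
            ("orientations", self.orientations, (T, J, 3)),
            ("com", self.com, (T, 3)),
            ("foot_contacts", self.foot_contacts, (T, 2)),
        ]:
            if arr.shape != shape:
                raise ValidationError(
                    f"channel {name!r} has shape {arr.shape}, expected {shape}"
                )
        for name, arr in self.aux.items():
            if name not in AUX_CHANNELS:
                raise ValidationError(f"unknown auxiliary channel {name!r}")
            if arr.shape != (T, J, 3):
                raise ValidationError(
                    f"auxiliary channel {name!r} has shape {arr.shape}, expected {(T, J, 3)}"
                )

    def index_of(self, label: str) -> int:
        try:
            return self.keypoint_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown keypoint {label!r}; valid labels: "
                + ", ".join(self.keypoint_labels)
            ) from None


@dataclass
class CameraModel:
    """Pinhole camera: pose + horizontal field of view + aspect ratio.

    ``rotation`` maps world vectors to camera coordinates; its rows are the
    camera right / up / forward axes expressed in world coordinates.
    """

    position: np.ndarray
    rotation: np.ndarray
    fov: float = math.radians(60.0)
    aspect: float = 16.0 / 9.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not (0.0 < self.fov < math.pi):
            raise ValidationError(f"field of view must be in (0, pi), got {self.fov}")
        if self.aspect <= 0:
            raise ValidationError(f"aspect ratio must be > 0, got {self.aspect}")

    @classmethod
    def look_at(
        cls,
        position,
        target,
        up=(0.0, 0.0, 1.0),
        fov: float = math.radians(60.0),
        aspect: float = 16.0 / 9.0,
    ) -> "CameraModel":
        position = np.asarray(position, dtype=float)
        forward = np.asarray(target, dtype=float) - position
        forward = forward / np.linalg.norm(forward)
        right = np.cross(forward, np.asarray(up, dtype=float))
        right = right / np.linalg.norm(right)
        cam_up = np.cross(right, forward)
        return cls(position, np.stack([right, cam_up, forward]), fov, aspect)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project world points (..., 3) to (x, y, depth) screen triplets.

        x, y are screen ratios in [0, 1] for visible points (x: 0 left ->
        1 right, y: 0 bottom -> 1 top); depth is the signed distance along
        the optical axis in meters.  Points behind the camera keep a
        non-positive depth and are not dropped.
        """
        d = np.asarray(points, dtype=float) - self.position
        cam = d @ self.rotation.T  # (..., 3): right, up, forward components
        depth = cam[..., 2]
        tan_h = math.tan(self.fov / 2.0)
        tan_v = tan_h / self.aspect
        with np.errstate(divide="ignore", invalid="ignore"):
            x = 0.5 + cam[..., 0] / (2.0 * tan_h * depth)
            y = 0.5 + cam[..., 1] / (2.0 * tan_v * depth)
        return np.stack([x, y, depth], axis=-1)


@dataclass
class CamPosSeries:
    """Camera-relative landmark coordinates: (x, y, depth) per landmark/frame."""

    landmark_names: list[str]
    frames: np.ndarray  # (T, J, 3)
    framerate: float = 60.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.framerate <= 0:
            raise ValidationError(f"framerate must be > 0, got {self.framerate}")
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError(
                f"frames must have shape (T, J, 3), got {self.frames.shape}"
            )
        if self.frames.shape[1] != len(self.landmark_names):
            raise ValidationError(
                f"frames carry {self.frames.shape[1]} landmarks but "
                f"{len(self.landmark_names)} names given"
            )
        if not np.all(np.isfinite(self.frames[..., :2])):
            raise ValidationError("x/y screen ratios must be finite")

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    @property
    def xy(self) -> np.ndarray:
        return self.frames[..., :2]


# ---------------------------------------------------------------------------
# MVNX-style XML
# ---------------------------------------------------------------------------

_FRAME_CHANNEL_TAGS = {
    "position": "position",
    "orientation": "orientation",
    "centerOfMass": "center_of_mass",
    "velocity": "velocity",
    "acceleration": "acceleration",
    "angularVelocity": "angular_velocity",
    "angularAcceleration": "angular_acceleration",
    "footContacts": "foot_contacts",
}


def _floats(element: ET.Element, tag: str) -> np.ndarray:
    text = element.text or ""
    try:
        return np.array(text.split(), dtype=float)
    except ValueError as exc:
        raise MvnxParseError(f"cannot parse numbers in <{tag}>: {exc}") from exc


def parse_mvnx(document: str | Path) -> KeypointFrameSeries:
    """Parse an MVNX-style XML document into a :class:`KeypointFrameSeries`.

    ``document`` is XML text, or a path to a file containing it.  Unknown
    elements are ignored with a logged warning.  Velocity/acceleration
    channels present in the file are retained in ``series.aux``.

    Raises
    ------
    MvnxParseError
        On malformed XML or a missing required element.
    ValidationError
        On inconsistent channel frame counts.
    """
    if isinstance(document, Path):
        document = document.read_text()
    elif isinstance(document, str) and "<" not in document:
        document = Path(document).read_text()
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise MvnxParseError(f"malformed XML near root element: {exc}") from exc

    subject = root.find("subject")
    if subject is None:
        raise MvnxParseError("missing required element <subject>")
    try:
        framerate = float(subject.get("frameRate", "0"))
    except ValueError as exc:
        raise MvnxParseError(f"invalid frameRate attribute on <subject>: {exc}") from exc

    segments_el = subject.find("segments")
    if segments_el is None:
        raise MvnxParseError("missing required element <segments>")
    labels = []
    for seg in segments_el.iter("segment"):
        label = seg.get("label")
        if label is None:
            raise MvnxParseError("<segment> without label attribute")
        labels.append(label)
    if not labels:
        raise MvnxParseError("<segments> contains no <segment> elements")

    frames_el = subject.find("frames")
    if frames_el is None:
        raise MvnxParseError("missing required element <frames>")

    channels: dict[str, list[np.ndarray]] = {name: [] for name in _FRAME_CHANNEL_TAGS.values()}
    for frame in frames_el.iter("frame"):
        for child in frame:
            name = _FRAME_CHANNEL_TAGS.get(child.tag)
            if name is None:
                logger.warning("ignoring unknown frame element <%s>", child.tag)
                continue
            channels[name].append(_floats(child, child.tag))

    counts = {name: len(vals) for name, vals in channels.items() if vals}
    for required in ("position", "orientation", "center_of_mass"):
        if required not in counts:
            raise MvnxParseError(f"document carries no {required} frames")
    n_frames = counts["position"]
    mismatched = {k: v for k, v in counts.items() if v != n_frames}
    if mismatched:
        raise ValidationError(
            f"frame-count mismatch: position has {n_frames} frames but "
            + ", ".join(f"{k} has {v}" for k, v in mismatched.items())
        )

    J = len(labels)
    positions = np.stack(channels["position"]).reshape(n_frames, J, 3)
    orientations = np.stack(channels["orientation"]).reshape(n_frames, J, 3)
    com = np.stack(channels["center_of_mass"]).reshape(n_frames, 3)
    if channels["foot_contacts"]:
        foot = np.stack(channels["foot_contacts"]).reshape(n_frames, 2) > 0.5
    else:
        foot = np.zeros((n_frames, 2), dtype=bool)
    aux = {
        name: np.stack(channels[name]).reshape(n_frames, J, 3)
        for name in AUX_CHANNELS
        if channels[name]
    }
    return KeypointFrameSeries(
        keypoint_labels=labels,
        positions=positions,
        orientations=orientations,
        com=com,
        foot_contacts=foot,
        framerate=framerate,
        aux=aux,
    )


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def _per_keypoint_columns(labels: list[str]) -> list[str]:
    return [f"{label}_{axis}" for label in labels for axis in "xyz"]


def write_csv(series: KeypointFrameSeries, out: str | Path) -> list[Path]:
    """Write one CSV per quantity into directory ``out``.

    Emits the eight canonical files: position, orientation, velocity,
    angular_velocity, acceleration, angular_acceleration, center_of_mass,
    foot_contacts.  Derivative channels missing from ``series.aux`` are
    computed with central finite differences.

    Returns the written file paths in canonical order.
    """
    from .kinematics import finite_difference

    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    T = series.frame_count
    flat = lambda a: a.reshape(T, -1)  # noqa: E731

    derived = dict(series.aux)
    if "velocity" not in derived:
        derived["velocity"] = finite_difference(series.positions, 1, series.framerate)
    if "acceleration" not in derived:
        derived["acceleration"] = finite_difference(series.positions, 2, series.framerate)
    unwrapped = np.unwrap(series.orientations, axis=0)
    if "angular_velocity" not in derived:
        derived["angular_velocity"] = finite_difference(unwrapped, 1, series.framerate)
    if "angular_acceleration" not in derived:
        derived["angular_acceleration"] = finite_difference(unwrapped, 2, series.framerate)

    tables = {
        "position": (flat(series.positions), _per_keypoint_columns(series.keypoint_labels)),
        "orientation": (flat(series.orientations), _per_keypoint_columns(series.keypoint_labels)),
        "velocity": (flat(derived["velocity"]), _per_keypoint_columns(series.keypoint_labels)),
        "angular_velocity": (
            flat(derived["angular_velocity"]),
            _per_keypoint_columns(series.keypoint_labels),
        ),
        "acceleration": (
            flat(derived["acceleration"]),
            _per_keypoint_columns(series.keypoint_labels),
        ),
        "angular_acceleration": (
            flat(derived["angular_acceleration"]),
            _per_keypoint_columns(series.keypoint_labels),
        ),
        "center_of_mass": (series.com, ["com_x", "com_y", "com_z"]),
        "foot_contacts": (
            series.foot_contacts.astype(int),
            ["left_foot", "right_foot"],
        ),
    }
    written = []
    for quantity in CSV_QUANTITIES:
        data, columns = tables[quantity]
        df = pd.DataFrame(data, columns=columns)
        df.insert(0, "frame", np.arange(T))
        path = out / f"{quantity}.csv"
        df.to_csv(path, index=False, float_format="%.12g")
        written.append(path)
    meta = {"framerate": series.framerate, "keypoint_labels": series.keypoint_labels}
    (out / "series.json").write_text(json.dumps(meta, indent=1))
    return written


def read_csv(directory: str | Path) -> KeypointFrameSeries:
    """Read a CSV set written by :func:`write_csv` back into a series."""
    directory = Path(directory)
    meta = json.loads((directory / "series.json").read_text())
    labels = meta["keypoint_labels"]
    J = len(labels)

    def load(quantity: str) -> np.ndarray:
        return pd.read_csv(directory / f"{quantity}.csv").drop(columns="frame").to_numpy()

    T = load("position").shape[0]
    aux = {}
    for quantity in ("velocity", "acceleration", "angular_velocity", "angular_acceleration"):
        path = directory / f"{quantity}.csv"
        if path.exists():
            aux[quantity] = load(quantity).reshape(T, J, 3)
    return KeypointFrameSeries(
        keypoint_labels=labels,
        positions=load("position").reshape(T, J, 3),
        orientations=load("orientation").reshape(T, J, 3),
        com=load("center_of_mass"),
        foot_contacts=load("foot_contacts") > 0.5,
        framerate=meta["framerate"],
        aux=aux,
    )


# ---------------------------------------------------------------------------
# CamPos
# ---------------------------------------------------------------------------


def project_campos(
    series: KeypointFrameSeries, camera: CameraModel, out_hz: float = 60.0
) -> CamPosSeries:
    """Project keypoints through ``camera`` into a CamPos series at ``out_hz``.

    Temporal resampling is nearest-frame selection, preserving exact
    captured poses (the timing error is bounded by half a source frame).
    """
    if out_hz <= 0:
        raise ValidationError(f"output rate must be > 0, got {out_hz}")
    if out_hz > series.framerate:
        raise ValidationError(
            f"output rate {out_hz} Hz exceeds source framerate {series.framerate} Hz"
        )
    duration = (series.frame_count - 1) / series.framerate
    n_out = int(math.floor(duration * out_hz)) + 1
    t_out = np.arange(n_out) / out_hz
    src_idx = np.clip(
        np.rint(t_out * series.framerate).astype(int), 0, series.frame_count - 1
    )
    projected = camera.project(series.positions[src_idx])
    return CamPosSeries(
        landmark_names=list(series.keypoint_labels), frames=projected, framerate=out_hz
    )


def write_campos_json(campos: CamPosSeries, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "framerate": campos.framerate,
        "landmark_names": campos.landmark_names,
        "frames": [[list(map(float, lm)) for lm in frame] for frame in campos.frames],
    }
    path.write_text(json.dumps(payload))
    return path


def read_campos_json(path: str | Path) -> CamPosSeries:
    payload = json.loads(Path(path).read_text())
    return CamPosSeries(
        landmark_names=payload["landmark_names"],
        frames=np.asarray(payload["frames"], dtype=float),
        framerate=payload["framerate"],
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample(
    series: KeypointFrameSeries, target_hz: float, force: bool = False
) -> KeypointFrameSeries:
    """Resample a series to ``target_hz`` by linear interpolation.

    Positions and CoM are interpolated linearly; orientations are unwrapped
    per Euler axis before interpolation; foot contacts use nearest-frame.
    First and last frames are preserved exactly.  Upsampling above the
    source framerate is refused unless ``force`` is true.
    """
    if target_hz <= 0:
        raise ValidationError(f"target framerate must be > 0, got {target_hz}")
    if target_hz > series.framerate and not force:
        raise ValidationError(
            f"refusing to upsample from {series.framerate} Hz to {target_hz} Hz "
            "(pass force=True to override)"
        )
    t_src = series.times
    duration = t_src[-1]
    n_out = max(2, int(round(duration * target_hz)) + 1) if series.frame_count > 1 else 1
    t_out = np.linspace(0.0, duration, n_out) if n_out > 1 else np.array([0.0])

    def interp(arr: np.ndarray) -> np.ndarray:
        shape = arr.shape
        flat = arr.reshape(shape[0], -1)
        out = np.empty((n_out, flat.shape[1]))
        for k in range(flat.shape[1]):
            out[:, k] = np.interp(t_out, t_src, flat[:, k])
        return out.reshape((n_out,) + shape[1:])

    nearest = np.clip(np.rint(t_out * series.framerate).astype(int), 0, series.frame_count - 1)
    aux = {name: interp(arr) for name, arr in series.aux.items()}
    return KeypointFrameSeries(
        keypoint_labels=list(series.keypoint_labels),
        positions=interp(series.positions),
        orientations=interp(np.unwrap(series.orientations, axis=0)),
        com=interp(series.com),
        foot_contacts=series.foot_contacts[nearest],
        framerate=target_hz,
        aux=aux,
    )
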