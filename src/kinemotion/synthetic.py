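"""Synthetic emotion-modulated choreography, silhouette rendering, and
dataset building.

Sequences are arm-dominant keyframe motions on a fixed 23-keypoint
skeleton with constant bone lengths, modulated per emotion by speed
(time warp), expansion (pose amplitude), smoothness (low-frequency
jitter), head-tilt bias, and a pause fraction.  Everything is
deterministic given the integer seed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import skeleton
from .motion_io import CameraModel, KeypointFrameSeries, project_campos, write_campos_json, write_csv
from .silhouette import SilhouetteClip, save_mask_frames

__all__ = [
    "EmotionProfile",
    "DEFAULT_PROFILES",
    "EMOTIONS",
    "TAKE_ORDER",
    "DatasetManifest",
    "generate_choreography",
    "render_silhouette",
    "write_mvnx",
    "build_dataset",
    "uniform_rotation_series",
    "default_camera",
]

#: The six emotion categories.
EMOTIONS = ("anger", "contentment", "fear", "joy", "neutrality", "sadness")

#: Fixed take order within a sequence (emotions first, explanation last).
TAKE_ORDER = ("neutrality", "joy", "contentment", "sadness", "fear", "anger", "explanation")


@dataclass(frozen=True)
class EmotionProfile:
    """Modulation parameters for one emotional intention."""

    emotion: str
    speed_scale: float = 1.0  # time-warp multiplier
    expansion_scale: float = 1.0  # pose amplitude multiplier
    jitter: float = 0.0  # smoothness perturbation amplitude, m
    head_tilt: float = 0.0  # rad, + = head pitched down/forward
    pause_fraction: float = 0.0  # fraction of the take spent frozen

    def __post_init__(self) -> None:
        if self.speed_scale < 0 or self.expansion_scale <= 0:
            raise ValueError("speed and expansion scales must be positive")
        if self.jitter < 0:
            raise ValueError("jitter amplitude must be >= 0")
        if not (0.0 <= self.pause_fraction <= 1.0):
            raise ValueError("pause fraction must be in [0, 1]")


#: Default profiles: fast/expanded anger and joy, slow/contracted sadness
#: and fear, head-down sadness, slow-positive contentment.  Qualitative
#: directions only; every number is configurable.
DEFAULT_PROFILES: dict[str, EmotionProfile] = {
    "anger": EmotionProfile("anger", 1.8, 1.25, 0.010, 0.0, 0.0),
    "joy": EmotionProfile("joy", 1.6, 1.30, 0.006, -0.10, 0.0),
    "neutrality": EmotionProfile("neutrality", 1.0, 1.00, 0.0, 0.0, 0.0),
    "contentment": EmotionProfile("contentment", 0.8, 1.05, 0.0, -0.05, 0.05),
    "fear": EmotionProfile("fear", 0.6, 0.60, 0.012, 0.10, 0.20),
    "sadness": EmotionProfile("sadness", 0.5, 0.70, 0.004, 0.40, 0.30),
}


# ---------------------------------------------------------------------------
# Skeleton rest pose
# ---------------------------------------------------------------------------

_SHOULDER_W = 0.05  # T8 -> clavicle origin, m
_GH_OFFSET = 0.15  # clavicle -> glenohumeral joint, m
_L_UPPER_ARM = 0.28
_L_FOREARM = 0.26
_L_HAND = 0.18
_L_HEAD = 0.13

# label -> rest position (x forward/north, y left/west, z up); arm chain and
# head are overwritten by the animation.
_REST: dict[str, tuple[float, float, float]] = {
    "Pelvis": (0.0, 0.0, 1.00),
    "L5": (0.0, 0.0, 1.08),
    "L3": (0.0, 0.0, 1.18),
    "T12": (0.0, 0.0, 1.28),
    "T8": (0.0, 0.0, 1.38),
    "Neck": (0.0, 0.0, 1.53),
    "Head": (0.0, 0.0, 1.66),
    "Right shoulder": (0.0, -_SHOULDER_W, 1.50),
    "Left shoulder": (0.0, _SHOULDER_W, 1.50),
    "Right upper leg": (0.0, -0.09, 0.95),
    "Right lower leg": (0.0, -0.09, 0.50),
    "Right foot": (0.0, -0.09, 0.08),
    "Right toe": (0.12, -0.09, 0.02),
    "Left upper leg": (0.0, 0.09, 0.95),
    "Left lower leg": (0.0, 0.09, 0.50),
    "Left foot": (0.0, 0.09, 0.08),
    "Left toe": (0.12, 0.09, 0.02),
}

#: CoM weights per canonical keypoint (roughly trunk-heavy), normalized at use.
_COM_WEIGHTS = {
    "Pelvis": 0.16, "L5": 0.08, "L3": 0.08, "T12": 0.08, "T8": 0.08,
    "Neck": 0.03, "Head": 0.07,
    "Right shoulder": 0.02, "Right upper arm": 0.03, "Right forearm": 0.02,
    "Right hand": 0.01,
    "Left shoulder": 0.02, "Left upper arm": 0.03, "Left forearm": 0.02,
    "Left hand": 0.01,
    "Right upper leg": 0.07, "Right lower leg": 0.04, "Right foot": 0.01,
    "Right toe": 0.005,
    "Left upper leg": 0.07, "Left lower leg": 0.04, "Left foot": 0.01,
    "Left toe": 0.005,
}


def _arm_direction(abduction: np.ndarray, flexion: np.ndarray, side: float) -> np.ndarray:
    """Unit direction of an arm bone from straight-down rest.

    ``abduction`` lifts the arm laterally (toward -y for the right arm,
    side=-1; +y for the left, side=+1); ``flexion`` lifts it forward (+x).
    Returns (T, 3) unit vectors.
    """
    ca, sa = np.cos(abduction), np.sin(abduction)
    cf, sf = np.cos(flexion), np.sin(flexion)
    # start at (0,0,-1); rotate about x by side*abduction, then about y by -flexion
    d = np.stack([sf * ca, side * sa * cf, -ca * cf], axis=1)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def _warped_time(times: np.ndarray, profile: EmotionProfile) -> np.ndarray:
    """Motion phase tau(t): advances at speed_scale, frozen in the pause window."""
    if times.size == 0:
        return times
    duration = times[-1] if times[-1] > 0 else 1.0
    rate = np.full_like(times, profile.speed_scale)
    if profile.pause_fraction > 0:
        start = 0.4 * duration
        stop = start + profile.pause_fraction * duration
        rate[(times >= start) & (times < stop)] = 0.0
    dt = np.diff(times, prepend=0.0)
    return np.cumsum(rate * dt)


def generate_choreography(
    sequence_id: int,
    profile: EmotionProfile,
    duration: float = 6.0,
    framerate: float = 240.0,
    seed: int = 0,
) -> KeypointFrameSeries:
    """Generate one emotion-modulated 23-keypoint sequence.

    The base keyframe curves (arm angle sinusoids) depend only on
    ``(seed, sequence_id)`` so the six emotional takes of a sequence share
    the same choreography; jitter additionally depends on the emotion.
    Bone lengths are constant by construction (forward kinematics on unit
    directions).
    """
    if not isinstance(sequence_id, (int, np.integer)) or sequence_id < 1:
        raise ValueError(f"unknown sequence id {sequence_id!r}: expected integer >= 1")
    if duration <= 0 or framerate <= 0:
        raise ValueError("duration and framerate must be > 0")

    curve_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=[int(seed), int(sequence_id), 0])
    )
    jitter_rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=[int(seed), int(sequence_id), 1, TAKE_ORDER.index(profile.emotion)
                     if profile.emotion in TAKE_ORDER else 99]
        )
    )

    T = int(round(duration * framerate)) + 1
    times = np.arange(T) / framerate
    tau = _warped_time(times, profile)

    # base curves: integer cycle counts over the take so integer speed
    # scales keep the phase window commensurate
    def curve(amplitude: float) -> np.ndarray:
        k = int(curve_rng.integers(2, 6))
        phase = float(curve_rng.uniform(0, 2 * math.pi))
        return amplitude * 0.5 * (1.0 - np.cos(2 * math.pi * k / duration * tau + phase))

    expansion = profile.expansion_scale
    arm_angles = {}
    for side_name in ("Right", "Left"):
        abd_u = curve(1.1 * expansion)
        flex_u = curve(0.8 * expansion)
        abd_e = curve(0.4 * expansion)
        flex_e = curve(0.7 * expansion)
        if profile.jitter > 0:
            # low-frequency jitter on the angles: amplitude scaled so the
            # hand displacement is on the order of the jitter in meters
            sigma = profile.jitter / (_L_UPPER_ARM + _L_FOREARM)
            for arr in (abd_u, flex_u, abd_e, flex_e):
                k = float(jitter_rng.uniform(1.0, 3.0))
                phase = float(jitter_rng.uniform(0, 2 * math.pi))
                arr += sigma * np.sin(2 * math.pi * k * times + phase)
        arm_angles[side_name] = (abd_u, flex_u, abd_e, flex_e)

    labels = list(skeleton.KEYPOINT_LABELS)
    positions = np.zeros((T, len(labels), 3))
    orientations = np.zeros((T, len(labels), 3))
    for label, rest in _REST.items():
        positions[:, labels.index(label)] = rest

    # head: pitch forward by the head-tilt bias
    neck = np.asarray(_REST["Neck"])
    tilt = profile.head_tilt
    head_dir = np.array([math.sin(tilt), 0.0, math.cos(tilt)])
    positions[:, labels.index("Head")] = neck + _L_HEAD * head_dir
    orientations[:, labels.index("Head"), 2] = tilt

    for side_name, side in (("Right", -1.0), ("Left", 1.0)):
        abd_u, flex_u, abd_e, flex_e = arm_angles[side_name]
        clavicle = np.asarray(_REST[f"{side_name} shoulder"])
        gh = clavicle + np.array([0.0, side * _GH_OFFSET, 0.0])
        d_upper = _arm_direction(abd_u, flex_u, side)
        d_fore = _arm_direction(abd_u + abd_e, flex_u + flex_e, side)
        elbow = gh + _L_UPPER_ARM * d_upper
        wrist = elbow + _L_FOREARM * d_fore
        hand = wrist + _L_HAND * d_fore  # end segment beyond the wrist
        positions[:, labels.index(f"{side_name} upper arm")] = gh
        positions[:, labels.index(f"{side_name} forearm")] = elbow
        positions[:, labels.index(f"{side_name} hand")] = hand
        # orientations: x = abduction, z = flexion (Z-flexion/X-abduction/Y-internal)
        for seg, (a, f) in {
            f"{side_name} upper arm": (abd_u, flex_u),
            f"{side_name} forearm": (abd_u + abd_e, flex_u + flex_e),
            f"{side_name} hand": (abd_u + abd_e, flex_u + flex_e),
        }.items():
            orientations[:, labels.index(seg), 0] = side * a
            orientations[:, labels.index(seg), 2] = f

    weights = np.array([_COM_WEIGHTS[label] for label in labels])
    weights = weights / weights.sum()
    com = np.einsum("tjc,j->tc", positions, weights)
    foot_contacts = np.ones((T, 2), dtype=bool)

    return KeypointFrameSeries(
        keypoint_labels=labels,
        positions=positions,
        orientations=orientations,
        com=com,
        foot_contacts=foot_contacts,
        framerate=framerate,
    )


def uniform_rotation_series(
    revolutions_per_s: float = 1.0,
    duration: float = 2.0,
    framerate: float = 240.0,
    axis: str = "z",
) -> KeypointFrameSeries:
    """Fixed-pose series whose segments rotate uniformly about one Euler axis.

    Orientation angles are wrapped into [-pi, pi) so downstream angular
    differentiation must unwrap; the exact angular rate is
    ``2*pi*revolutions_per_s`` rad/s.
    """
    T = int(round(duration * framerate)) + 1
    times = np.arange(T) / framerate
    angle = 2 * math.pi * revolutions_per_s * times
    wrapped = np.mod(angle + math.pi, 2 * math.pi) - math.pi
    labels = list(skeleton.KEYPOINT_LABELS)
    positions = np.zeros((T, len(labels), 3))
    for label, rest in _REST.items():
        positions[:, labels.index(label)] = rest
    positions[:, labels.index("Head")] = np.asarray(_REST["Neck"]) + [0, 0, _L_HEAD]
    for side_name, side in (("Right", -1.0), ("Left", 1.0)):
        gh = np.asarray(_REST[f"{side_name} shoulder"]) + [0.0, side * _GH_OFFSET, 0.0]
        positions[:, labels.index(f"{side_name} upper arm")] = gh
        positions[:, labels.index(f"{side_name} forearm")] = gh + [0, 0, -_L_UPPER_ARM]
        positions[:, labels.index(f"{side_name} hand")] = gh + [0, 0, -_L_UPPER_ARM - _L_FOREARM - _L_HAND]
    orientations = np.zeros((T, len(labels), 3))
    orientations[:, :, "xyz".index(axis)] = wrapped[:, None]
    weights = np.array([_COM_WEIGHTS[label] for label in labels])
    com = np.einsum("tjc,j->tc", positions, weights / weights.sum())
    return KeypointFrameSeries(
        keypoint_labels=labels,
        positions=positions,
        orientations=orientations,
        com=com,
        foot_contacts=np.ones((T, 2), dtype=bool),
        framerate=framerate,
    )


# ---------------------------------------------------------------------------
# Silhouette rendering
# ---------------------------------------------------------------------------

#: capsule radius (m) per bone, keyed by child label; default for the rest
_BONE_RADII = {
    "L5": 0.12, "L3": 0.12, "T12": 0.13, "T8": 0.13, "Neck": 0.06, "Head": 0.10,
    "Right upper arm": 0.05, "Left upper arm": 0.05,
    "Right forearm": 0.045, "Left forearm": 0.045,
    "Right hand": 0.04, "Left hand": 0.04,
    "Right upper leg": 0.08, "Left upper leg": 0.08,
    "Right lower leg": 0.06, "Left lower leg": 0.06,
}
_DEFAULT_RADIUS = 0.05


def default_camera(aspect: float = 16.0 / 9.0) -> CameraModel:
    """Camera 4 m in front of the figure, level with its chest."""
    return CameraModel.look_at(
        position=(4.0, 0.0, 1.2), target=(0.0, 0.0, 1.2), aspect=aspect
    )


def render_silhouette(
    series: KeypointFrameSeries,
    camera: CameraModel | None = None,
    fps: float = 25.0,
    size: tuple[int, int] = (1080, 1920),
) -> SilhouetteClip:
    """Rasterize the figure as boolean masks: one capsule per bone.

    ``size`` is (height, width) in pixels.  Keypoints are projected through
    the pinhole camera; each bone becomes a thickened segment whose pixel
    radius follows its metric radius and depth.  Deterministic.
    """
    if camera is None:
        camera = default_camera(aspect=size[1] / size[0])
    H, W = size
    n_out = max(1, int(math.floor((series.frame_count - 1) / series.framerate * fps)) + 1)
    t_out = np.arange(n_out) / fps
    src_idx = np.clip(np.rint(t_out * series.framerate).astype(int), 0, series.frame_count - 1)

    frames = np.zeros((n_out, H, W), dtype=bool)
    tan_h = math.tan(camera.fov / 2.0)
    cols = np.arange(W) + 0.5
    rows = np.arange(H) + 0.5
    for out_t, t in enumerate(src_idx):
        projected = camera.project(series.positions[t])  # (J, 3)
        px = projected[:, 0] * W
        py = (1.0 - projected[:, 1]) * H  # image row 0 is the top
        depth = projected[:, 2]
        frame = frames[out_t]
        for parent, child in skeleton.BONE_EDGES:
            if depth[parent] <= 0 or depth[child] <= 0:
                continue
            radius_m = _BONE_RADII.get(series.keypoint_labels[child], _DEFAULT_RADIUS)
            mean_depth = 0.5 * (depth[parent] + depth[child])
            r_px = radius_m / (2.0 * tan_h * mean_depth) * W
            a = np.array([px[parent], py[parent]])
            b = np.array([px[child], py[child]])
            x0 = int(np.clip(math.floor(min(a[0], b[0]) - r_px - 1), 0, W))
            x1 = int(np.clip(math.ceil(max(a[0], b[0]) + r_px + 1), 0, W))
            y0 = int(np.clip(math.floor(min(a[1], b[1]) - r_px - 1), 0, H))
            y1 = int(np.clip(math.ceil(max(a[1], b[1]) + r_px + 1), 0, H))
            if x0 >= x1 or y0 >= y1:
                continue
            gx, gy = np.meshgrid(cols[x0:x1], rows[y0:y1])
            ab = b - a
            denom = float(ab @ ab)
            if denom < 1e-12:
                dist2 = (gx - a[0]) ** 2 + (gy - a[1]) ** 2
            else:
                s = np.clip(((gx - a[0]) * ab[0] + (gy - a[1]) * ab[1]) / denom, 0.0, 1.0)
                dist2 = (gx - (a[0] + s * ab[0])) ** 2 + (gy - (a[1] + s * ab[1])) ** 2
            frame[y0:y1, x0:x1] |= dist2 <= r_px**2
    if not frames.any():
        warnings.warn("rendered figure is fully outside the frame")
    return SilhouetteClip(frames, fps)


# ---------------------------------------------------------------------------
# MVNX writer
# ---------------------------------------------------------------------------


def write_mvnx(series: KeypointFrameSeries) -> str:
    """Serialize a series as MVNX-style XML text (lossless round trip)."""
    fmt = lambda arr: " ".join(f"{v:.17g}" for v in np.asarray(arr).ravel())  # noqa: E731
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<mvnx version="4">',
        f'  <subject label="synthetic" frameRate="{series.framerate:.17g}">',
        "    <segments>",
    ]
    for i, label in enumerate(series.keypoint_labels, start=1):
        lines.append(f'      <segment id="{i}" label="{label}"/>')
    lines.append("    </segments>")
    lines.append(f'    <frames count="{series.frame_count}">')
    aux_tags = {
        "velocity": "velocity",
        "acceleration": "acceleration",
        "angular_velocity": "angularVelocity",
        "angular_acceleration": "angularAcceleration",
    }
    for t in range(series.frame_count):
        lines.append(f'      <frame index="{t}" time="{t / series.framerate:.17g}">')
        lines.append(f"        <position>{fmt(series.positions[t])}</position>")
        lines.append(f"        <orientation>{fmt(series.orientations[t])}</orientation>")
        lines.append(f"        <centerOfMass>{fmt(series.com[t])}</centerOfMass>")
        for name, tag in aux_tags.items():
            if name in series.aux:
                lines.append(f"        <{tag}>{fmt(series.aux[name][t])}</{tag}>")
        contacts = " ".join(str(int(v)) for v in series.foot_contacts[t])
        lines.append(f"        <footContacts>{contacts}</footContacts>")
        lines.append("      </frame>")
    lines.append("    </frames>")
    lines.append("  </subject>")
    lines.append("</mvnx>")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Dataset builder
# ---------------------------------------------------------------------------


@dataclass
class DatasetManifest:
    """Index of a built synthetic dataset."""

    root: str
    seed: int
    entries: list[dict]

    @property
    def emotional_entries(self) -> list[dict]:
        return [e for e in self.entries if e["take"] in EMOTIONS]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        return cls(**json.loads(text))


def build_dataset(
    out: str | Path,
    seed: int = 0,
    n_sequences: int = 9,
    duration: float = 6.0,
    framerate: float = 240.0,
    campos_hz: float = 60.0,
    silhouette_fps: float = 25.0,
    silhouette_size: tuple[int, int] = (1080, 1920),
    profiles: dict[str, EmotionProfile] | None = None,
    include_explanation: bool = True,
    force: bool = False,
) -> DatasetManifest:
    """Build the full synthetic dataset: per take MVNX, CSV, CamPos, masks.

    The default design is ``n_sequences`` sequences x 6 emotion takes plus
    one explanation take per sequence (9 x 7 = 63 entries).  Take order
    within a sequence is the fixed recording order.  Refuses to write into
    a non-empty directory unless ``force`` is set.
    """
    out = Path(out)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (pass force=True)")
    out.mkdir(parents=True, exist_ok=True)
    profiles = dict(DEFAULT_PROFILES if profiles is None else profiles)
    camera = default_camera(aspect=silhouette_size[1] / silhouette_size[0])

    takes = [t for t in TAKE_ORDER if include_explanation or t != "explanation"]
    entries = []
    for sequence_id in range(1, n_sequences + 1):
        for take in takes:
            profile = profiles[take if take != "explanation" else "neutrality"]
            if take == "explanation":
                # the explanation run-through is a calmer rendition
                profile = EmotionProfile("neutrality", speed_scale=0.7 * profile.speed_scale)
            series = generate_choreography(sequence_id, profile, duration, framerate, seed)
            entry_dir = out / f"seq{sequence_id:02d}_{take}"
            entry_dir.mkdir(parents=True, exist_ok=True)
            (entry_dir / "recording.mvnx").write_text(write_mvnx(series))
            write_csv(series, entry_dir / "csv")
            campos = project_campos(series, camera, min(campos_hz, framerate))
            write_campos_json(campos, entry_dir / "campos.json")
            clip = render_silhouette(series, camera, silhouette_fps, silhouette_size)
            save_mask_frames(clip, entry_dir / "silhouette")
            entries.append(
                {
                    "sequence": sequence_id,
                    "take": take,
                    "seed": seed,
                    "mvnx": str(entry_dir / "recording.mvnx"),
                    "csv": str(entry_dir / "csv"),
                    "campos": str(entry_dir / "campos.json"),
                    "silhouette": str(entry_dir / "silhouette"),
                }
            )
    manifest = DatasetManifest(root=str(out), seed=seed, entries=entries)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
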