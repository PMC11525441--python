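"""Boolean-mask video computations: motion mask, quantity of motion,
foreground statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .kinematics import ALL_KEYPOINTS, FeatureSeries

__all__ = [
    "SilhouetteClip",
    "ForegroundStats",
    "motion_mask",
    "qom",
    "foreground_stats",
    "load_mask_frames",
    "save_mask_frames",
    "binarize",
]


@dataclass
class SilhouetteClip:
    """Stack of boolean foreground masks (1 = figure) at a fixed fps."""

    frames: np.ndarray  # (T, H, W) bool
    fps: float = 25.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=bool)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must have shape (T, H, W), got {self.frames.shape}")
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ForegroundStats:
    """Per-frame foreground occupancy of a clip.

    ``ratio`` is active pixels / total pixels per frame.  Extents are the
    active bounding box as screen ratios: horizontal 0 (left) -> 1 (right),
    vertical 0 (bottom) -> 1 (top).  Frames with no active pixel have NaN
    extents and are flagged in ``empty``.
    """

    ratio: np.ndarray
    horizontal_min: np.ndarray
    horizontal_max: np.ndarray
    vertical_min: np.ndarray
    vertical_max: np.ndarray
    empty: np.ndarray

    @property
    def mean_ratio(self) -> float:
        return float(self.ratio.mean())

    def global_extents(self) -> dict[str, float]:
        """Per-clip min/max extents over the non-empty frames."""
        ok = ~self.empty
        return {
            "horizontal_min": float(np.min(self.horizontal_min[ok])),
            "horizontal_max": float(np.max(self.horizontal_max[ok])),
            "vertical_min": float(np.min(self.vertical_min[ok])),
            "vertical_max": float(np.max(self.vertical_max[ok])),
        }


def motion_mask(clip: SilhouetteClip, delta: int) -> np.ndarray:
    """Silhouette motion mask per frame.

    Frame ``t`` is active where any of the previous ``delta`` frames was
    active and the current frame is not.  Frames with fewer than ``delta``
    predecessors use the available history (frame 0 is all-inactive).
    """
    if delta < 1:
        raise ValueError(f"delta must be >= 1, got {delta}")
    if delta >= len(clip):
        raise ValueError(f"delta={delta} must be smaller than clip length {len(clip)}")
    frames = clip.frames
    masks = np.zeros_like(frames)
    for t in range(1, len(clip)):
        lo = max(0, t - delta)
        history = frames[lo:t].any(axis=0)
        masks[t] = history & ~frames[t]
    return masks


def qom(clip: SilhouetteClip, delta: int = 5) -> FeatureSeries:
    """Quantity of motion: recently vacated pixels over currently active ones.

    ``q(t) = |mask(t)| / |frame(t)|``, dimensionless and >= 0.  Frames with
    an empty current silhouette get NaN (undefined ratio), are excluded
    from aggregation, and trigger a warning.
    """
    masks = motion_mask(clip, delta)
    active = clip.frames.reshape(len(clip), -1).sum(axis=1).astype(float)
    moved = masks.reshape(len(clip), -1).sum(axis=1).astype(float)
    empty = active == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} frame(s) have an empty silhouette: QoM undefined there"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(empty, np.nan, moved / np.where(empty, 1.0, active))
    return FeatureSeries("qom", ALL_KEYPOINTS, values, "dimensionless", clip.fps)


def foreground_stats(clip: SilhouetteClip) -> ForegroundStats:
    """Per-frame foreground ratio and normalized bounding extents."""
    T = len(clip)
    H, W = clip.shape
    flat = clip.frames.reshape(T, -1)
    ratio = flat.sum(axis=1) / (H * W)
    empty = ~flat.any(axis=1)

    h_min = np.full(T, np.nan)
    h_max = np.full(T, np.nan)
    v_min = np.full(T, np.nan)
    v_max = np.full(T, np.nan)
    for t in range(T):
        if empty[t]:
            continue
        rows, cols = np.nonzero(clip.frames[t])
        h_min[t] = cols.min() / W
        h_max[t] = (cols.max() + 1) / W
        # image row 0 is the top; report bottom-origin screen ratios
        v_min[t] = 1.0 - (rows.max() + 1) / H
        v_max[t] = 1.0 - rows.min() / H
    return ForegroundStats(ratio, h_min, h_max, v_min, v_max, empty)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def binarize(image: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Boolean mask from a grayscale/color frame: luminance > threshold.

    Intended for white-on-black silhouette footage.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = image[..., :3].mean(axis=-1)
    return image > threshold


def save_mask_frames(clip: SilhouetteClip, out: str | Path, prefix: str = "frame") -> list[Path]:
    """Write the clip as a numbered PNG mask sequence."""
    import imageio.v3 as iio

    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, frame in enumerate(clip.frames):
        path = out / f"{prefix}_{t:05d}.png"
        iio.imwrite(path, (frame.astype(np.uint8)) * 255)
        paths.append(path)
    return paths


def load_mask_frames(directory: str | Path, fps: float = 25.0) -> SilhouetteClip:
    """Read a PNG mask sequence (sorted by filename) into a clip."""
    import imageio.v3 as iio

    paths = sorted(Path(directory).glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG frames found in {directory}")
    frames = np.stack([binarize(iio.imread(p), threshold=127) for p in paths])
    return SilhouetteClip(frames, fps)
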