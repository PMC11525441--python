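"""Canonical full-body keypoint model shared across the package.

The 23-segment labelling follows the standard inertial-suit biomechanical
model: a pelvis-to-head spinal chain, two 4-segment arms and two 4-segment
legs.  World frame is x -> (magnetic) north, y -> west, z -> up.
"""

from __future__ import annotations

#: Canonical segment labels in fixed order (Pelvis first, Left toe last).
KEYPOINT_LABELS: tuple[str, ...] = (
    "Pelvis",
    "L5",
    "L3",
    "T12",
    "T8",
    "Neck",
    "Head",
    "Right shoulder",
    "Right upper arm",
    "Right forearm",
    "Right hand",
    "Left shoulder",
    "Left upper arm",
    "Left forearm",
    "Left hand",
    "Right upper leg",
    "Right lower leg",
    "Right foot",
    "Right toe",
    "Left upper leg",
    "Left lower leg",
    "Left foot",
    "Left toe",
)

N_KEYPOINTS = len(KEYPOINT_LABELS)

#: Extremity endpoints used by the limb-contraction feature.
EXTREMITY_LABELS: tuple[str, ...] = ("Right hand", "Left hand", "Right toe", "Left toe")

#: Back/head chain used by the head-tilt features.
HEAD_CHAIN_LABELS: tuple[str, ...] = ("T8", "Neck", "Head")

#: Parent of each segment (by label) for rendering limbs; Pelvis is the root.
PARENTS: dict[str, str | None] = {
    "Pelvis": None,
    "L5": "Pelvis",
    "L3": "L5",
    "T12": "L3",
    "T8": "T12",
    "Neck": "T8",
    "Head": "Neck",
    "Right shoulder": "T8",
    "Right upper arm": "Right shoulder",
    "Right forearm": "Right upper arm",
    "Right hand": "Right forearm",
    "Left shoulder": "T8",
    "Left upper arm": "Left shoulder",
    "Left forearm": "Left upper arm",
    "Left hand": "Left forearm",
    "Right upper leg": "Pelvis",
    "Right lower leg": "Right upper leg",
    "Right foot": "Right lower leg",
    "Right toe": "Right foot",
    "Left upper leg": "Pelvis",
    "Left lower leg": "Left upper leg",
    "Left foot": "Left lower leg",
    "Left toe": "Left foot",
}

#: Bone edges as (parent_index, child_index) pairs in canonical label order.
BONE_EDGES: tuple[tuple[int, int], ...] = tuple(
    (KEYPOINT_LABELS.index(parent), KEYPOINT_LABELS.index(child))
    for child, parent in PARENTS.items()
    if parent is not None
)


def keypoint_index(label: str) -> int:
    """Index of ``label`` in the canonical ordering.

    Raises
    ------
    KeyError
        If the label is unknown; the message lists the valid labels.
    """
    try:
        return KEYPOINT_LABELS.index(label)
    except ValueError:
        raise KeyError(
            f"unknown keypoint {label!r}; valid labels: {', '.join(KEYPOINT_LABELS)}"
        ) from None
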