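import numpy as np
import pytest

from kinemotion.motion_io import KeypointFrameSeries
from kinemotion.skeleton import KEYPOINT_LABELS


def series_from_positions(
    positions, framerate=240.0, labels=None, orientations=None, com=None
) -> KeypointFrameSeries:
    """Build a series from a (T, J, 3) position array with sane defaults."""
    positions = np.asarray(positions, dtype=float)
    T, J = positions.shape[:2]
    if labels is None:
        labels = list(KEYPOINT_LABELS[:J])
    if orientations is None:
        orientations = np.zeros((T, J, 3))
    if com is None:
        com = positions.mean(axis=1)
    return KeypointFrameSeries(
        keypoint_labels=list(labels),
        positions=positions,
        orientations=orientations,
        com=np.asarray(com, dtype=float),
        foot_contacts=np.zeros((T, 2), dtype=bool),
        framerate=framerate,
    )


@pytest.fixture
def make_series():
    return series_from_positions


@pytest.fixture
def full_body_series():
    """A short deterministic full-body synthetic sequence."""
    from kinemotion.synthetic import DEFAULT_PROFILES, generate_choreography

    return generate_choreography(
        1, DEFAULT_PROFILES["neutrality"], duration=1.0, framerate=60.0, seed=42
    )
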