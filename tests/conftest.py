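import numpy as np
import pytest

from cylgrip import synthetic_hand as sh


@pytest.fixture(scope="session")
def hand():
    return sh.default_hand()


@pytest.fixture(scope="session")
def study_diameters():
    return (10.0, 60.0, 120.0)


@pytest.fixture(scope="session")
def grip_poses(hand, study_diameters):
    """Solved grip poses for the three study diameters."""
    return {d: sh.solve_grip_pose(hand, sh.GripScenario(d))
            for d in study_diameters}


@pytest.fixture(scope="session")
def posed_hands(hand, grip_poses):
    """Posed bone placements per diameter and finger (session-cached:
    mesh construction dominates test runtime)."""
    out = {}
    for d, pose in grip_poses.items():
        out[d] = {f: sh.pose_finger_chain(hand[f], pose, resolution=32)
                  for f in sh.FINGERS}
    return out


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random rotation matrix from a QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
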