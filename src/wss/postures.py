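"""Sleeping-posture taxonomy and canonical sensor orientations.

Eight *minor* postures collapse pairwise onto four *major* postures
(trunk orientation classes)::

    1, 2 -> right lateral decubitus
    3, 4 -> supine
    5, 6 -> left lateral decubitus
    7, 8 -> prone

The two minor postures within a major pair share the trunk orientation and
differ only in forearm placement: the second member has one or both forearms
rotated by a fixed offset (90 degrees by default) about the forearm long
axis, mirroring the real-world distinction of a 90-degree shoulder rotation
in one arm.

Conventions
-----------
World frame: Z up, Y toward the head of the bed, X across the bed.  In the
reference pose (supine, arms parallel to the body) every sensor frame is
aligned with the world frame, so supine is the identity orientation and
gravity reads (0, 0, -1) g on every sensor.  All rotations returned here map
world-frame vectors into the sensor frame.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

#: Sensor locations, in canonical order (also the feature-vector order).
LOCATIONS = ("trunk", "left_forearm", "right_forearm")

MINOR_POSTURES = tuple(range(1, 9))

#: Major postures in matrix/collapse order.
MAJORS = ("right", "supine", "left", "prone")

MINOR_DESCRIPTIONS = {
    1: "right lateral decubitus, both hands under cheek, arms parallel",
    2: "right lateral decubitus, bottom forearm under head, top arm in front of face",
    3: "supine, arms parallel to body",
    4: "supine, hands behind head",
    5: "left lateral decubitus, both hands under cheek, arms parallel",
    6: "left lateral decubitus, bottom forearm under head, top arm in front of face",
    7: "prone, hands in front of forehead",
    8: "prone, arms parallel to body",
}

# Trunk roll about the body long axis (world Y), degrees.
_TRUNK_ROLL_DEG = {"right": -90.0, "supine": 0.0, "left": 90.0, "prone": 180.0}

# minor -> (left forearm offset applied, right forearm offset applied)
_PAIR_OFFSET = {
    1: (False, False),
    2: (False, True),
    3: (False, False),
    4: (True, True),
    5: (False, False),
    6: (True, False),
    7: (True, True),
    8: (False, False),
}


def _check_minor(minor: int) -> int:
    if minor not in MINOR_POSTURES:
        raise ValueError(f"unknown posture label {minor!r}: expected an integer in 1..8")
    return int(minor)


def major_index(minor: int) -> int:
    """0-based index of the major posture for a minor label (1..8)."""
    return (_check_minor(minor) - 1) // 2


def major_of(minor: int) -> str:
    """Major posture name ('right', 'supine', 'left', 'prone') for a minor label."""
    return MAJORS[major_index(minor)]


def posture_orientation(minor: int, pair_offset_deg: float = 90.0) -> dict[str, Rotation]:
    """Canonical world->sensor rotations for one minor posture.

    Parameters
    ----------
    minor
        Minor posture label in 1..8.
    pair_offset_deg
        Rotation (degrees, about the forearm long axis) distinguishing the
        second member of each major pair.  The default of 90 degrees mirrors
        the shoulder rotation separating postures 1 and 2 (and 5 and 6).

    Returns
    -------
    dict mapping each sensor location to a :class:`Rotation` taking
    world-frame vectors into that sensor's frame.
    """
    minor = _check_minor(minor)
    roll = _TRUNK_ROLL_DEG[major_of(minor)]
    trunk = Rotation.from_euler("y", -roll, degrees=True)
    offset = Rotation.from_euler("y", pair_offset_deg, degrees=True)
    lf_off, rf_off = _PAIR_OFFSET[minor]
    left = offset * trunk if lf_off else trunk
    right = offset * trunk if rf_off else trunk
    return {"trunk": trunk, "left_forearm": left, "right_forearm": right}


def orientation_table(pair_offset_deg: float = 90.0) -> dict[int, dict[str, Rotation]]:
    """Orientation dictionaries for all eight minor postures."""
    return {m: posture_orientation(m, pair_offset_deg) for m in MINOR_POSTURES}


def gravity_template(minor: int, pair_offset_deg: float = 90.0) -> np.ndarray:
    """(3, 3) array of noise-free gravity directions (trunk, left, right forearm)."""
    rots = posture_orientation(minor, pair_offset_deg)
    g = np.array([0.0, 0.0, -1.0])
    return np.stack([rots[loc].apply(g) for loc in LOCATIONS])
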