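"""Landmark-based joint angle measurement.

The measurement convention mirrors CT-based bone morphometry of the gripping
hand: for each phalanx or metacarpal, a ring of surface points is picked
around the outer circumference of each bone end, the end *center* is
estimated from the ring, the bone's longitudinal axis is the direction from
the proximal-base center to the distal-head center, and the flexion angle of
a joint is the unsigned angle between the axes of its two articulating
bones.  All distances are millimetres, all angles degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    DegenerateRingError,
    FrameConstructionError,
    NormalizationError,
    ZeroLengthAxisError,
)

FINGERS = ("index", "middle", "ring", "small")
BONES = ("metacarpal", "proximal", "middle", "distal")
JOINTS = ("DIP", "PIP", "MP")

#: Joint -> (proximal bone, distal bone) whose axes subtend the flexion angle.
JOINT_BONES = {
    "MP": ("metacarpal", "proximal"),
    "PIP": ("proximal", "middle"),
    "DIP": ("middle", "distal"),
}


@dataclass(frozen=True)
class LandmarkRing:
    """Ordered surface points around one bone-end circumference."""

    bone_id: tuple  # (finger, bone)
    end: str  # "head" or "base"
    points: np.ndarray  # (n, 3) mm

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise DegenerateRingError("ring points must be an (n, 3) array")
        if pts.shape[0] < 3:
            raise DegenerateRingError(
                f"ring needs >= 3 points, got {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise DegenerateRingError("ring contains non-finite coordinates")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class BoneAxis:
    """Longitudinal bone axis from base center to head center."""

    bone_id: tuple
    base_center: np.ndarray
    head_center: np.ndarray
    direction: np.ndarray  # unit, base -> head

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(self.head_center - self.base_center))


@dataclass(frozen=True)
class CoordinateFrame:
    """Right-handed hand frame anchored at the capitate dorsal concavity.

    y points proximally along the third metacarpal, x palmarly, z radially.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def rotation(self) -> np.ndarray:
        """World->frame rotation matrix with axes as rows."""
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) @ self.rotation().T


def _unit(v: np.ndarray, err: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ZeroLengthAxisError(err)
    return v / n


def estimate_center(ring: LandmarkRing | np.ndarray, method: str = "centroid") -> np.ndarray:
    """Estimate the bone-end center from a landmark ring.

    ``method="centroid"`` is the default reading of "determined on the basis
    of the coordinates of these eight points": the arithmetic mean, exact for
    evenly spaced ring points and equivariant under rigid motion.
    ``method="circle_fit"`` instead fits a 3D circle by least squares
    (plane by SVD, then Gauss-Newton on center and radius in-plane).
    """
    pts = ring.points if isinstance(ring, LandmarkRing) else np.asarray(ring, float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise DegenerateRingError("center estimation needs >= 3 points")
    if method == "centroid":
        return pts.mean(axis=0)
    if method == "circle_fit":
        return fit_circle_center(pts)
    raise ValueError(f"unknown center estimator {method!r}")


def fit_circle_center(points: np.ndarray) -> np.ndarray:
    """Least-squares 3D circle fit; returns the fitted circle center.

    The points are projected onto their best-fit plane (total least squares
    via SVD); in-plane, a Kasa algebraic fit seeds a Gauss-Newton refinement
    of the geometric distance residuals.
    """
    pts = np.asarray(points, dtype=float)
    c0 = pts.mean(axis=0)
    q = pts - c0
    # plane normal = singular vector of least variance
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise DegenerateRingError("points are collinear; no circle fit")
    e1, e2 = vt[0], vt[1]
    u = q @ e1
    v = q @ e2
    # Kasa: minimize ||u^2+v^2 - 2a u - 2b v - c||
    A = np.column_stack([2 * u, 2 * v, np.ones_like(u)])
    b = u**2 + v**2
    (a0, b0, c0k), *_ = np.linalg.lstsq(A, b, rcond=None)
    r0 = np.sqrt(max(c0k + a0**2 + b0**2, 1e-12))

    def resid(p):
        a, b_, r = p
        return np.hypot(u - a, v - b_) - r

    sol = least_squares(resid, x0=[a0, b0, r0], method="lm")
    a, b_, _ = sol.x
    return c0 + a * e1 + b_ * e2


def bone_axis(base_ring: LandmarkRing, head_ring: LandmarkRing,
              method: str = "centroid") -> BoneAxis:
    """Axis from the proximal-base center to the distal-head center."""
    base_c = estimate_center(base_ring, method)
    head_c = estimate_center(head_ring, method)
    d = head_c - base_c
    direction = _unit(d, "base and head centers coincide")
    bone_id = base_ring.bone_id if isinstance(base_ring, LandmarkRing) else None
    return BoneAxis(bone_id=bone_id, base_center=base_c,
                    head_center=head_c, direction=direction)


def flexion_angle(proximal, distal) -> float:
    """Unsigned angle in degrees between two bone axes, in [0, 180].

    Accepts ``BoneAxis`` objects or bare unit vectors.  The dot product is
    clipped to [-1, 1] before the arccos to absorb floating-point drift.
    """
    u = proximal.direction if isinstance(proximal, BoneAxis) else np.asarray(proximal, float)
    v = distal.direction if isinstance(distal, BoneAxis) else np.asarray(distal, float)
    for w in (u, v):
        if abs(np.linalg.norm(w) - 1.0) > 1e-6:
            raise NormalizationError(
                f"axis direction has norm {np.linalg.norm(w):.8f}; expected unit"
            )
    dot = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return float(np.degrees(np.arccos(dot)))


def build_hand_frame(capitate_point, mc3_base_center, mc3_head_center,
                     palmar_reference) -> CoordinateFrame:
    """Construct the hand coordinate frame.

    Origin at the capitate dorsal concavity; y along the third metacarpal
    long axis with the proximal direction positive (base is the proximal
    end); x toward the palm, orthogonalized against y; z completes a
    right-handed frame (radial positive for a right hand).
    """
    origin = np.asarray(capitate_point, dtype=float)
    base = np.asarray(mc3_base_center, dtype=float)
    head = np.asarray(mc3_head_center, dtype=float)
    try:
        y = _unit(base - head, "third metacarpal base and head coincide")
    except ZeroLengthAxisError as e:
        raise FrameConstructionError(str(e)) from e
    p = np.asarray(palmar_reference, dtype=float) - origin
    x_raw = p - np.dot(p, y) * y
    if np.linalg.norm(x_raw) < 1e-9:
        raise FrameConstructionError(
            "palmar reference lies on the y-axis line; x-axis undefined"
        )
    x = x_raw / np.linalg.norm(x_raw)
    z = np.cross(x, y)
    return CoordinateFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


RingKey = tuple  # (finger, bone, end)


def measure_hand(rings: Mapping[RingKey, LandmarkRing | np.ndarray],
                 method: str = "centroid") -> pd.DataFrame:
    """Measure all 12 joint flexion angles of one hand in one grip.

    Parameters
    ----------
    rings
        Mapping from ``(finger, bone, end)`` to a landmark ring, for the
        four fingers, bones metacarpal/proximal/middle/distal and ends
        "base"/"head".
    method
        Center estimator passed to :func:`estimate_center`.

    Returns
    -------
    DataFrame with one row per (finger, joint) — always 12 rows — with
    columns ``finger, joint, angle_deg, status``.  Joints whose bone rings
    are missing get ``status="missing"`` and NaN angle instead of being
    silently dropped.
    """
    records = []
    for finger in FINGERS:
        axes: dict[str, BoneAxis | None] = {}
        for bone in BONES:
            rb = rings.get((finger, bone, "base"))
            rh = rings.get((finger, bone, "head"))
            if rb is None or rh is None:
                axes[bone] = None
                continue
            if not isinstance(rb, LandmarkRing):
                rb = LandmarkRing((finger, bone), "base", rb)
            if not isinstance(rh, LandmarkRing):
                rh = LandmarkRing((finger, bone), "head", rh)
            axes[bone] = bone_axis(rb, rh, method)
        for joint in ("DIP", "PIP", "MP"):
            prox_bone, dist_bone = JOINT_BONES[joint]
            a, b = axes[prox_bone], axes[dist_bone]
            if a is None or b is None:
                records.append(dict(finger=finger, joint=joint,
                                    angle_deg=np.nan, status="missing"))
            else:
                records.append(dict(finger=finger, joint=joint,
                                    angle_deg=flexion_angle(a, b), status="ok"))
    return pd.DataFrame.from_records(records)
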