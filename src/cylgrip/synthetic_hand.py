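"""Synthetic posed hand geometry and simulated angle cohorts.

Real inputs for this measurement method are CT-segmented bone meshes of a
hand gripping a cylinder, which cannot be redistributed.  This module
replaces them with a controllable stand-in:

* capsule-like phalanx/metacarpal meshes (cylindrical shaft with spherical
  end caps) posed by planar forward kinematics with known ground-truth
  joint angles;
* a deterministic grip solver that wraps a four-bone finger chain around a
  cylinder of given diameter (a circumscribed-polygon tangency model);
* a landmark-ring sampler emulating the manual picking of eight surface
  points around a bone-end circumference;
* a cohort simulator producing per-subject joint-angle tables with
  prescribed cell means/SDs and a subject-level random intercept.

Every downstream stage (center estimation, axis angles, coupling ratios,
repeated-measures ANOVA) is therefore testable against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import trimesh
from scipy.optimize import brentq

from . import reference_data
from .errors import (
    DegenerateRingError,
    IncompletePoseError,
    IncompleteSpecError,
    InfeasibleGripError,
    InvalidGeometryError,
)
from .landmark_geometry import BONES, FINGERS, JOINTS, CoordinateFrame, LandmarkRing

#: Flexion range-of-motion ceilings (degrees) used by the grip solver;
#: literature values for healthy adult fingers, rounded.
DEFAULT_ROM_DEG = {"MP": 90.0, "PIP": 105.0, "DIP": 70.0}


@dataclass(frozen=True)
class FingerChainSpec:
    """Dimensions of one finger's four-bone chain (mm).

    ``shaft_radius`` is the outer radius of the capsule proxy, i.e. the
    fleshy finger segment surface that actually contacts a gripped object,
    not the bare bone cortex.
    """

    finger_id: str
    segment_lengths: dict  # bone -> mm
    shaft_radius: float
    end_radii: dict  # bone -> (base cap radius, head cap radius) mm
    z_offset_mm: float = 0.0  # radioulnar placement of the finger plane

    def __post_init__(self):
        if self.finger_id not in FINGERS:
            raise InvalidGeometryError(f"unknown finger {self.finger_id!r}")
        for bone in BONES:
            if bone not in self.segment_lengths:
                raise InvalidGeometryError(f"missing segment length for {bone}")
            if self.segment_lengths[bone] <= 0:
                raise InvalidGeometryError(f"non-positive length for {bone}")
            rb, rh = self.end_radii[bone]
            if rb <= 0 or rh <= 0:
                raise InvalidGeometryError(f"non-positive end radius for {bone}")
        if self.shaft_radius <= 0:
            raise InvalidGeometryError("non-positive shaft radius")
        L = self.segment_lengths
        if not (L["distal"] < L["proximal"] < L["metacarpal"]):
            raise InvalidGeometryError(
                "expected distal < proximal < metacarpal segment lengths"
            )


@dataclass(frozen=True)
class PoseSpec:
    """Ground-truth flexion angle (deg) per (finger, joint)."""

    angles_deg: dict  # (finger, joint) -> degrees

    def __post_init__(self):
        for key, a in self.angles_deg.items():
            if not (0.0 <= a < 180.0):
                raise InvalidGeometryError(
                    f"angle {a} for {key} outside [0, 180)"
                )

    def angle(self, finger: str, joint: str) -> float:
        try:
            return self.angles_deg[(finger, joint)]
        except KeyError:
            raise IncompletePoseError(f"pose missing {joint} for {finger}")

    def fingers(self):
        return sorted({f for f, _ in self.angles_deg})

    @classmethod
    def uniform(cls, angle_deg: float, fingers=FINGERS) -> "PoseSpec":
        return cls({(f, j): float(angle_deg) for f in fingers for j in JOINTS})


@dataclass(frozen=True)
class GripScenario:
    """A cylinder-gripping condition."""

    diameter_mm: float
    contact_tolerance_mm: float = 0.5

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise InvalidGeometryError("cylinder diameter must be positive")
        if self.contact_tolerance_mm <= 0:
            raise InvalidGeometryError("contact tolerance must be positive")


@dataclass(frozen=True)
class BonePlacement:
    """A posed bone mesh with ground-truth end centers (hand coordinates)."""

    bone_id: tuple  # (finger, bone)
    mesh: trimesh.Trimesh
    true_base_center: np.ndarray
    true_head_center: np.ndarray
    base_radius: float
    head_radius: float
    shaft_radius: float

    @property
    def true_axis(self) -> np.ndarray:
        d = self.true_head_center - self.true_base_center
        return d / np.linalg.norm(d)

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(self.true_head_center - self.true_base_center))


# ---------------------------------------------------------------------------
# mesh construction

def _capsule_profile(length, shaft_radius, base_radius, head_radius, resolution):
    """2D profile (radius, height) of the coaxial cylinder+sphere union."""
    n = max(int(resolution) // 2, 8)
    segs = []
    if base_radius > shaft_radius:
        yb = math.sqrt(base_radius**2 - shaft_radius**2)
        th = np.linspace(-np.pi / 2, math.asin(yb / base_radius), n)
    else:
        yb = 0.0
        th = np.linspace(-np.pi / 2, 0.0, n)
    segs.append(np.c_[base_radius * np.cos(th), base_radius * np.sin(th)])
    segs.append([[shaft_radius, yb]])
    if head_radius > shaft_radius:
        yh = math.sqrt(head_radius**2 - shaft_radius**2)
        segs.append([[shaft_radius, length - yh]])
        th = np.linspace(math.asin(-yh / head_radius), np.pi / 2, n)
    else:
        yh = 0.0
        segs.append([[shaft_radius, length]])
        th = np.linspace(0.0, np.pi / 2, n)
    segs.append(np.c_[head_radius * np.cos(th), length + head_radius * np.sin(th)])
    prof = np.vstack(segs)
    keep = np.r_[True, np.linalg.norm(np.diff(prof, axis=0), axis=1) > 1e-12]
    return prof[keep]


#: rotate revolve's +z axis onto the canonical bone axis +y
_Z_TO_Y = trimesh.transformations.rotation_matrix(-np.pi / 2, [1, 0, 0])


def make_phalanx_mesh(length: float, shaft_radius: float, base_radius: float,
                      head_radius: float, resolution: int = 64,
                      bone_id: tuple = ("", "")) -> BonePlacement:
    """Build a capsule-proxy bone in canonical pose.

    Base center at the origin, head center at ``(0, length, 0)``; the solid
    is the union of a cylinder of ``shaft_radius`` along the axis and
    spheres of ``base_radius``/``head_radius`` about the end centers,
    generated as a watertight surface of revolution.
    """
    for name, v in [("length", length), ("shaft_radius", shaft_radius),
                    ("base_radius", base_radius), ("head_radius", head_radius)]:
        if v <= 0:
            raise InvalidGeometryError(f"non-positive {name}: {v}")
    if length <= base_radius + head_radius:
        raise InvalidGeometryError(
            f"length {length} must exceed base+head cap radii "
            f"{base_radius + head_radius}"
        )
    prof = _capsule_profile(length, shaft_radius, base_radius, head_radius,
                            resolution)
    mesh = trimesh.creation.revolve(prof, sections=max(int(resolution), 16),
                                    transform=_Z_TO_Y)
    return BonePlacement(
        bone_id=bone_id, mesh=mesh,
        true_base_center=np.zeros(3),
        true_head_center=np.array([0.0, float(length), 0.0]),
        base_radius=float(base_radius), head_radius=float(head_radius),
        shaft_radius=float(shaft_radius),
    )


def transform_placement(placement: BonePlacement, matrix: np.ndarray) -> BonePlacement:
    """Apply a 4x4 rigid transform to mesh and ground-truth centers."""
    mesh = placement.mesh.copy()
    mesh.apply_transform(matrix)
    h = lambda p: (matrix @ np.append(p, 1.0))[:3]
    return replace(placement, mesh=mesh,
                   true_base_center=h(placement.true_base_center),
                   true_head_center=h(placement.true_head_center))


# ---------------------------------------------------------------------------
# anthropometric defaults

_BASE_HAND_LENGTH = reference_data.MEAN_HAND_LENGTH_MM

#: segment lengths (mm) at the reference hand length, per finger
_BASE_SEGMENTS = {
    "index": {"metacarpal": 68.0, "proximal": 42.0, "middle": 25.0, "distal": 18.0},
    "middle": {"metacarpal": 65.0, "proximal": 45.0, "middle": 28.0, "distal": 19.0},
    "ring": {"metacarpal": 58.0, "proximal": 42.0, "middle": 27.0, "distal": 18.0},
    "small": {"metacarpal": 54.0, "proximal": 33.0, "middle": 20.0, "distal": 16.0},
}
_BASE_END_RADII = {
    "metacarpal": (7.0, 6.5), "proximal": (6.5, 6.0),
    "middle": (6.0, 5.5), "distal": (5.0, 4.5),
}
_BASE_SHAFT_RADIUS = 8.5
_Z_OFFSETS = {"index": 27.0, "middle": 9.0, "ring": -9.0, "small": -27.0}


def default_hand(hand_length_mm: float = _BASE_HAND_LENGTH) -> dict:
    """Four-finger chain specs scaled from the reference hand length."""
    s = hand_length_mm / _BASE_HAND_LENGTH
    hand = {}
    for f in FINGERS:
        hand[f] = FingerChainSpec(
            finger_id=f,
            segment_lengths={b: L * s for b, L in _BASE_SEGMENTS[f].items()},
            shaft_radius=_BASE_SHAFT_RADIUS * s,
            end_radii={b: (rb * s, rh * s) for b, (rb, rh) in _BASE_END_RADII.items()},
            z_offset_mm=_Z_OFFSETS[f] * s,
        )
    return hand


# ---------------------------------------------------------------------------
# forward kinematics

def pose_finger_chain(spec: FingerChainSpec, pose: PoseSpec,
                      frame: CoordinateFrame | None = None,
                      resolution: int = 48) -> list[BonePlacement]:
    """Pose one finger chain by planar forward kinematics.

    The metacarpal runs distally (local -y) from the frame origin region;
    each joint flexes about a z-parallel axis, positive toward the palm
    (+x).  Returns the four bones in metacarpal->distal order with
    ground-truth end centers in frame/world coordinates.
    """
    angles = {j: pose.angle(spec.finger_id, j) for j in ("MP", "PIP", "DIP")}
    chain = [("metacarpal", 0.0), ("proximal", angles["MP"]),
             ("middle", angles["PIP"]), ("distal", angles["DIP"])]

    if frame is not None:
        R = frame.rotation().T  # frame-local -> world
        o = frame.origin
    else:
        R, o = np.eye(3), np.zeros(3)

    placements = []
    p = np.array([0.0, 0.0, spec.z_offset_mm])
    phi = 0.0
    for bone, theta in chain:
        phi += math.radians(theta)
        d = np.array([math.sin(phi), -math.cos(phi), 0.0])
        L = spec.segment_lengths[bone]
        rb, rh = spec.end_radii[bone]
        canonical = make_phalanx_mesh(L, spec.shaft_radius, rb, rh,
                                      resolution, bone_id=(spec.finger_id, bone))
        # canonical +y axis -> d, then local -> world
        alpha = math.atan2(-math.sin(phi), -math.cos(phi))
        M = trimesh.transformations.rotation_matrix(alpha, [0, 0, 1])
        M[:3, 3] = p
        W = np.eye(4)
        W[:3, :3] = R
        W[:3, 3] = o
        placements.append(transform_placement(canonical, W @ M))
        p = p + L * d
    return placements


def recover_joint_angles(placements: list[BonePlacement]) -> dict:
    """Per-joint angles between consecutive true bone axes (degrees)."""
    out = {}
    joints = ("MP", "PIP", "DIP")
    for j, (a, b) in zip(joints, zip(placements, placements[1:])):
        dot = float(np.clip(np.dot(a.true_axis, b.true_axis), -1, 1))
        out[j] = math.degrees(math.acos(dot))
    return out


# ---------------------------------------------------------------------------
# grip solver

def _tangent_lengths(spec: FingerChainSpec):
    """Tangent-length propagation of the circumscribed wrap model."""
    L = spec.segment_lengths
    t0 = L["metacarpal"] / 2.0  # palm contact at mid-metacarpal
    t1 = L["proximal"] - t0
    t2 = L["middle"] - t1
    if t1 <= 0 or t2 <= 0 or t2 >= L["distal"]:
        raise InvalidGeometryError(
            f"finger {spec.finger_id}: segment lengths incompatible with "
            "the wrap model (tangent point falls outside a bone)"
        )
    return t0, t1, t2


def _raw_wrap_angles(spec: FingerChainSpec, rho: float) -> dict:
    t0, t1, t2 = _tangent_lengths(spec)
    return {
        "MP": math.degrees(2 * math.atan(t0 / rho)),
        "PIP": math.degrees(2 * math.atan(t1 / rho)),
        "DIP": math.degrees(2 * math.atan(t2 / rho)),
    }


def min_feasible_diameter(spec: FingerChainSpec) -> float:
    """Smallest cylinder diameter the chain can wrap without spiralling."""
    ts = _tangent_lengths(spec)

    def wrap_minus_full_turn(rho):
        return sum(2 * math.atan(t / rho) for t in ts) - 2 * math.pi

    if wrap_minus_full_turn(1e-9) <= 0:
        return 0.0
    rho_star = brentq(wrap_minus_full_turn, 1e-9, 1e6)
    return max(2 * (rho_star - spec.shaft_radius), 0.0)


def solve_grip_pose(spec, scenario: GripScenario,
                    rom_limits: dict | None = None) -> PoseSpec:
    """Deterministic grip pose for a cylinder of the given diameter.

    Wrap model: every bone axis is a tangent line to the *offset circle* of
    radius ``cylinder_radius + shaft_radius`` (the finger surface then
    touches the cylinder surface exactly).  The metacarpal contacts at its
    midpoint and tangent lengths propagate distally, giving joint angle
    ``2*atan(t/rho)`` at each joint.  Angles saturate at per-joint ROM
    ceilings, which releases distal contact — the joint limit acts as the
    adjacent constraint.  Accepts one :class:`FingerChainSpec` or a mapping
    ``finger -> FingerChainSpec``.
    """
    rom = dict(DEFAULT_ROM_DEG, **(rom_limits or {}))
    specs = {spec.finger_id: spec} if isinstance(spec, FingerChainSpec) else dict(spec)
    angles = {}
    infeasible = []
    for f, fs in specs.items():
        rho = scenario.diameter_mm / 2.0 + fs.shaft_radius
        raw = _raw_wrap_angles(fs, rho)
        if sum(raw.values()) > 360.0:
            infeasible.append((f, min_feasible_diameter(fs)))
            continue
        for j, a in raw.items():
            angles[(f, j)] = min(a, rom[j])
    if infeasible:
        dmin = max(d for _, d in infeasible)
        raise InfeasibleGripError(
            f"diameter {scenario.diameter_mm} mm too small for "
            f"{[f for f, _ in infeasible]}; minimum feasible diameter "
            f"{dmin:.2f} mm", dmin,
        )
    return PoseSpec(angles)


def cylinder_center_local(spec: FingerChainSpec, scenario: GripScenario) -> np.ndarray:
    """Cylinder axis point in the finger's local kinematic coordinates.

    In the convention of :func:`pose_finger_chain` (metacarpal base at the
    local origin, metacarpal along -y, palm toward +x), the gripped
    cylinder's axis runs parallel to z through this point.
    """
    rho = scenario.diameter_mm / 2.0 + spec.shaft_radius
    return np.array([rho, -spec.segment_lengths["metacarpal"] / 2.0,
                     spec.z_offset_mm])


# ---------------------------------------------------------------------------
# landmark sampling

def _ring_basis(axis: np.ndarray):
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    u = np.cross(ref, axis)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    return u, w


def sample_landmark_ring(placement: BonePlacement, end: str, n_points: int = 8,
                         angular_jitter_deg: float = 10.0,
                         radial_noise_mm: float = 0.2,
                         seed=None, rng=None) -> LandmarkRing:
    """Pick ``n_points`` surface points around one bone-end circumference.

    Emulates manual landmark picking: nominal spacing ``360/n_points``
    degrees around the cap-sphere equator (the plane through the true end
    center, perpendicular to the bone axis), perturbed by i.i.d. uniform
    in-plane angular jitter of ``+-angular_jitter_deg`` and isotropic
    Gaussian positional noise of SD ``radial_noise_mm``.  Reproducible for
    a fixed seed.
    """
    if n_points < 3:
        raise DegenerateRingError(f"ring needs >= 3 points, got {n_points}")
    if end not in ("head", "base"):
        raise ValueError("end must be 'head' or 'base'")
    if rng is None:
        rng = np.random.default_rng(seed)
    center = placement.true_head_center if end == "head" else placement.true_base_center
    radius = placement.head_radius if end == "head" else placement.base_radius
    axis = placement.true_axis
    u, w = _ring_basis(axis)
    nominal = 2 * np.pi * np.arange(n_points) / n_points
    jitter = rng.uniform(-1, 1, n_points) * math.radians(angular_jitter_deg)
    ang = nominal + jitter
    pts = (center[None, :]
           + radius * np.cos(ang)[:, None] * u[None, :]
           + radius * np.sin(ang)[:, None] * w[None, :])
    pts = pts + rng.normal(0.0, radial_noise_mm, size=pts.shape)
    return LandmarkRing(bone_id=placement.bone_id, end=end, points=pts)


def sample_hand_rings(placements_by_finger: dict, n_points: int = 8,
                      angular_jitter_deg: float = 10.0,
                      radial_noise_mm: float = 0.2, seed=None) -> dict:
    """Sample base+head rings for every bone of a posed four-finger hand.

    Returns the ``(finger, bone, end) -> LandmarkRing`` mapping that
    :func:`cylgrip.landmark_geometry.measure_hand` consumes.
    """
    rng = np.random.default_rng(seed)
    rings = {}
    for finger, placements in placements_by_finger.items():
        for pl in placements:
            _, bone = pl.bone_id
            for end in ("base", "head"):
                rings[(finger, bone, end)] = sample_landmark_ring(
                    pl, end, n_points=n_points,
                    angular_jitter_deg=angular_jitter_deg,
                    radial_noise_mm=radial_noise_mm, rng=rng,
                )
    return rings


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative parameters for a balanced per-subject angle cohort.

    Each record is ``cell_mean + f*cell_sd*z_subject +
    sqrt(1-f^2)*cell_sd*eps`` with ``f = subject_sd_fraction``, one
    standard-normal intercept ``z_subject`` per subject shared across all
    cells, and independent residuals; the total SD of every cell equals the
    prescribed ``cell_sds_deg`` exactly.
    """

    cell_means_deg: dict  # (diameter, finger, joint) -> deg
    cell_sds_deg: dict  # (diameter, finger, joint) -> deg
    n_subjects: int = 10
    subject_sd_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise IncompleteSpecError("need at least 2 subjects")
        if not (0.0 <= self.subject_sd_fraction <= 1.0):
            raise IncompleteSpecError("subject_sd_fraction must be in [0, 1]")
        if any(s < 0 for s in self.cell_sds_deg.values()):
            raise IncompleteSpecError("cell SDs must be >= 0")

    def grid(self):
        """Full (diameters, fingers, joints) cross implied by the cells."""
        keys = set(self.cell_means_deg)
        diameters = sorted({k[0] for k in keys})
        fingers = [f for f in FINGERS if f in {k[1] for k in keys}]
        joints = [j for j in ("DIP", "PIP", "MP") if j in {k[2] for k in keys}]
        for d in diameters:
            for f in fingers:
                for j in joints:
                    if (d, f, j) not in self.cell_means_deg:
                        raise IncompleteSpecError(f"missing cell mean for {(d, f, j)}")
                    if (d, f, j) not in self.cell_sds_deg:
                        raise IncompleteSpecError(f"missing cell SD for {(d, f, j)}")
        return diameters, fingers, joints


def default_cohort_spec(n_subjects: int = 10, subject_sd_fraction: float = 0.5,
                        seed: int = 0) -> SyntheticCohortSpec:
    """Cohort spec parameterized by the reference cell statistics."""
    means = {k: v[0] for k, v in reference_data.CELL_ANGLE_STATS.items()}
    sds = {k: v[1] for k, v in reference_data.CELL_ANGLE_STATS.items()}
    return SyntheticCohortSpec(cell_means_deg=means, cell_sds_deg=sds,
                               n_subjects=n_subjects,
                               subject_sd_fraction=subject_sd_fraction,
                               seed=seed)


def simulate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Simulate a balanced long-format joint-angle cohort.

    Returns a DataFrame with columns
    ``subject, diameter_mm, finger, joint, angle_deg`` and
    ``n_subjects * n_diameters * n_fingers * n_joints`` rows; angles are
    clipped to [0, 180).
    """
    diameters, fingers, joints = spec.grid()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    f = spec.subject_sd_fraction
    z = rng.standard_normal(n)
    rows = []
    for d in diameters:
        for fg in fingers:
            for j in joints:
                mu = spec.cell_means_deg[(d, fg, j)]
                sd = spec.cell_sds_deg[(d, fg, j)]
                eps = rng.standard_normal(n)
                ang = mu + f * sd * z + math.sqrt(1.0 - f * f) * sd * eps
                ang = np.clip(ang, 0.0, np.nextafter(180.0, 0.0))
                for s in range(n):
                    rows.append((s + 1, d, fg, j, ang[s]))
    return pd.DataFrame(rows, columns=["subject", "diameter_mm", "finger",
                                       "joint", "angle_deg"])
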