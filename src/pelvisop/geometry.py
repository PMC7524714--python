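"""Rigid-body primitives and the pelvic orientation decomposition.

The pelvis lives in a right-handed world frame with X mediolateral
(left positive), Y antero-posterior (anterior positive) and Z vertical
(cranial positive), all lengths in millimetres. A pelvic pose (rotation +
translation) is decomposed into three clinical angles:

* SOP -- sagittal orientation of the pelvis (rotation about X),
* FOP -- frontal orientation (rotation about Y),
* TOP -- transverse orientation (rotation about Z),

using the fixed intrinsic Euler sequence Z(TOP) -> X(SOP) -> Y(FOP), i.e.

    R = Rz(TOP) @ Rx(SOP) @ Ry(FOP).

This sequence leaves the SOP unchanged when the subject turns about the
vertical axis (an extra world-frame Z rotation only shifts the TOP), which
is the property one wants of a sagittal tilt measure read off a standing
radiograph. Anterior pelvic tilt is positive SOP by convention. All angles
are stored in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "EULER_SEQ",
    "Pose",
    "OrientationTriple",
    "Plane",
    "decompose_orientation",
    "recompose_orientation",
    "plane_orientation",
    "rotation_x",
    "rotation_y",
    "rotation_z",
    "angle_between",
]

#: Intrinsic Euler sequence: scipy's 'ZXY' returns angles (TOP, SOP, FOP).
EULER_SEQ = "ZXY"

_ORTHO_TOL = 1e-9
_GIMBAL_TOL_DEG = 1e-6


def rotation_x(deg: float) -> np.ndarray:
    """Rotation matrix about the mediolateral (X) axis, angle in degrees."""
    return Rotation.from_euler("x", deg, degrees=True).as_matrix()


def rotation_y(deg: float) -> np.ndarray:
    """Rotation matrix about the antero-posterior (Y) axis."""
    return Rotation.from_euler("y", deg, degrees=True).as_matrix()


def rotation_z(deg: float) -> np.ndarray:
    """Rotation matrix about the vertical (Z) axis."""
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two 3-vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle_between requires non-zero vectors")
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def _wrap_deg(a: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = (float(a) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class Pose:
    """A rigid transform: proper-orthogonal rotation plus translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply the transform to an (n, 3) array (or a single 3-vector)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "Pose") -> "Pose":
        """self after other: (self o other)(x) = self(other(x))."""
        return Pose(self.rotation @ other.rotation,
                    self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Pose":
        return Pose(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class OrientationTriple:
    """SOP/FOP/TOP in degrees; ``degenerate`` flags a gimbal configuration."""

    sop: float
    fop: float
    top: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        for name in ("sop", "fop", "top"):
            object.__setattr__(self, name, _wrap_deg(getattr(self, name)))

    def as_array(self) -> np.ndarray:
        return np.array([self.sop, self.fop, self.top])


def decompose_orientation(pose: Pose | np.ndarray) -> OrientationTriple:
    """Decompose a rotation into (SOP, FOP, TOP).

    Inverse of :func:`recompose_orientation`. At the gimbal configuration of
    the Z-X-Y sequence (middle angle SOP at +/-90 deg) the split between TOP
    and FOP is not unique; the result is then flagged ``degenerate`` (TOP
    absorbs the free angle).
    """
    R = pose.rotation if isinstance(pose, Pose) else np.asarray(pose, float)
    with warnings.catch_warnings():
        # scipy warns at gimbal lock; the triple is flagged instead
        warnings.simplefilter("ignore", UserWarning)
        top, sop, fop = Rotation.from_matrix(R).as_euler(EULER_SEQ,
                                                         degrees=True)
    degenerate = bool(abs(abs(sop) - 90.0) < _GIMBAL_TOL_DEG)
    return OrientationTriple(sop=float(sop), fop=float(fop), top=float(top),
                             degenerate=degenerate)


def recompose_orientation(triple: OrientationTriple) -> np.ndarray:
    """Rotation matrix Rz(TOP) @ Rx(SOP) @ Ry(FOP) from a triple."""
    return Rotation.from_euler(
        EULER_SEQ, [triple.top, triple.sop, triple.fop], degrees=True
    ).as_matrix()


@dataclass(frozen=True)
class Plane:
    """An oriented anatomical reference plane.

    ``frame`` is the plane's canonical orientation frame (a rotation matrix
    whose columns are the plane's mediolateral, anterior and superior axes in
    model coordinates). ``normal`` and ``anterior_axis`` describe the plane
    itself; for near-frontal planes (APP-like) the anterior direction is the
    normal and ``anterior_axis`` holds the in-plane superior axis.
    """

    origin: np.ndarray
    normal: np.ndarray
    anterior_axis: np.ndarray
    frame: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        a = np.asarray(self.anterior_axis, dtype=float).reshape(3)
        F = np.asarray(self.frame, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > _ORTHO_TOL:
            raise ValueError("plane normal must be a unit vector")
        if abs(np.linalg.norm(a) - 1.0) > _ORTHO_TOL:
            raise ValueError("anterior_axis must be a unit vector")
        if abs(float(np.dot(n, a))) > 1e-9:
            raise ValueError("anterior_axis must lie in the plane")
        if not np.allclose(F.T @ F, np.eye(3), atol=1e-8) or \
                abs(np.linalg.det(F) - 1.0) > 1e-8:
            raise ValueError("frame must be a proper rotation matrix")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "anterior_axis", a)
        object.__setattr__(self, "frame", F)

    def canonical_angles(self) -> OrientationTriple:
        """Euler angles of the plane frame itself (pose = identity)."""
        return decompose_orientation(self.frame)


def plane_orientation(plane: Plane, pose: Pose) -> OrientationTriple:
    """Orientation angles of a reference plane under a pelvic pose.

    The pose rotation is decomposed into (SOP, FOP, TOP) and the plane's
    canonical angles are added component-wise. The sagittal angle is thereby
    adjusted for the transverse and frontal orientation of the pelvis: every
    reference plane reports exactly the same SOP *change* between two poses,
    and a patient turning about the vertical axis does not alter the SOP.
    """
    p = decompose_orientation(pose)
    c = plane.canonical_angles()
    return OrientationTriple(
        sop=p.sop + c.sop,
        fop=p.fop + c.fop,
        top=p.top + c.top,
        degenerate=p.degenerate or c.degenerate,
    )
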