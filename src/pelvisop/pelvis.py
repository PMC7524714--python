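"""Pelvic landmark parametrization.

Builds the five pelvic reference planes used to define the sagittal
orientation of the pelvis (SOP), the 18 pose-invariant morphological
parameters (13 landmark distances, 5 landmark angles) and the lumbar
lordosis angle (LLA).

All sign/orientation choices are made from *intrinsic* references derived
from the landmarks themselves (the ASIS axis for mediolateral, the
ASIS-mid minus PSIS-mid direction for anterior, the hip-center midpoint to
iliac midline direction for cranial), never from world axes, so every
morphological parameter is exactly invariant under rigid transforms of the
landmark set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .geometry import Plane, Pose, angle_between

__all__ = [
    "LandmarkSet",
    "MorphoParams",
    "LumbarMeasures",
    "MissingLandmarkError",
    "DegeneratePlaneError",
    "PLANE_IDS",
    "construct_reference_plane",
    "register_reference_plane",
    "morphological_parameters",
    "lumbar_lordosis_angle",
    "REQUIRED_LANDMARKS",
    "MORPHO_DISTANCE_DEFS",
    "MORPHO_ANGLE_NAMES",
]


class MissingLandmarkError(KeyError):
    """A computation requires a landmark that is not in the set."""


class DegeneratePlaneError(ValueError):
    """The defining points of a reference plane are (near-)collinear."""


#: Names every full pelvic landmark set carries.
REQUIRED_LANDMARKS = (
    "ASIS_L", "ASIS_R", "PSIS_L", "PSIS_R",
    "pubic_symphysis", "pubic_tubercle_L", "pubic_tubercle_R",
    "sacral_promontory",
    "S1_endplate_anterior", "S1_endplate_posterior", "S1_endplate_center",
    "hip_center_L", "hip_center_R",
    "ischial_tuberosity_L", "ischial_tuberosity_R",
    "iliac_crest_L", "iliac_crest_R",
)

#: Optional lumbar superior-endplate point pairs (anterior/posterior).
LUMBAR_LANDMARKS = ("L1sup_a", "L1sup_p", "L5sup_a", "L5sup_p")


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3D anatomical points of one pelvis (coordinates in mm)."""

    points: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        pts = {}
        for name, p in dict(self.points).items():
            arr = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"landmark {name!r} has non-finite coordinates")
            pts[name] = arr
        object.__setattr__(self, "points", pts)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self) -> tuple[str, ...]:
        return tuple(self.points)

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise MissingLandmarkError(", ".join(missing))

    # -- derived helper points ------------------------------------------
    def midpoint(self, a: str, b: str) -> np.ndarray:
        return 0.5 * (self[a] + self[b])

    @property
    def hjc_midpoint(self) -> np.ndarray:
        return self.midpoint("hip_center_L", "hip_center_R")

    @property
    def asis_midpoint(self) -> np.ndarray:
        return self.midpoint("ASIS_L", "ASIS_R")

    @property
    def psis_midpoint(self) -> np.ndarray:
        return self.midpoint("PSIS_L", "PSIS_R")

    # -- intrinsic reference directions ---------------------------------
    def mediolateral_axis(self) -> np.ndarray:
        """Unit vector along the ASIS axis, pointing to the left."""
        v = self["ASIS_L"] - self["ASIS_R"]
        return v / np.linalg.norm(v)

    def anterior_reference(self) -> np.ndarray:
        """Unit vector from the PSIS midpoint toward the ASIS midpoint."""
        v = self.asis_midpoint - self.psis_midpoint
        return v / np.linalg.norm(v)

    def cranial_reference(self) -> np.ndarray:
        """Unit vector from the hip-center midpoint toward the iliac midline."""
        v = 0.5 * (self.asis_midpoint + self.psis_midpoint) - self.hjc_midpoint
        return v / np.linalg.norm(v)

    # -- transforms ------------------------------------------------------
    def transformed(self, pose: Pose) -> "LandmarkSet":
        return LandmarkSet({n: pose.apply(p) for n, p in self.points.items()})

    def scaled(self, factor: float) -> "LandmarkSet":
        return LandmarkSet({n: factor * p for n, p in self.points.items()})

    def array(self, names: Sequence[str]) -> np.ndarray:
        return np.stack([self[n] for n in names])

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        """Load a landmark file: JSON mapping name -> [x, y, z] in mm."""
        with open(path) as fh:
            raw = json.load(fh)
        if not isinstance(raw, dict):
            raise ValueError("landmark JSON must map names to [x, y, z]")
        for name, p in raw.items():
            if not (isinstance(p, (list, tuple)) and len(p) == 3):
                raise ValueError(f"landmark {name!r} is not an [x, y, z] triple")
        return cls(raw)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({n: list(map(float, p)) for n, p in self.points.items()},
                      fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Reference planes
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegeneratePlaneError("zero-length direction")
    return v / n


def _orient(v: np.ndarray, reference: np.ndarray) -> np.ndarray:
    return v if float(np.dot(v, reference)) >= 0.0 else -v


def _plane_from_endplate(lm: LandmarkSet) -> Plane:
    """SSP: plane of the S1 superior endplate (sacral slope plane)."""
    lm.require(("S1_endplate_anterior", "S1_endplate_posterior",
                "S1_endplate_center"))
    a = _unit(lm["S1_endplate_anterior"] - lm["S1_endplate_posterior"])
    ml = lm.mediolateral_axis()
    n = np.cross(ml, a)
    if np.linalg.norm(n) < 1e-6:
        raise DegeneratePlaneError("S1 endplate direction parallel to ML axis")
    n = _orient(_unit(n), lm.cranial_reference())
    a = _unit(a - np.dot(a, n) * n)
    a = _orient(a, lm.anterior_reference())
    x = np.cross(a, n)
    frame = np.column_stack([x, a, n])
    return Plane(origin=lm["S1_endplate_center"], normal=n,
                 anterior_axis=a, frame=frame)


def _frontal_like_plane(lm: LandmarkSet, normal: np.ndarray,
                        origin: np.ndarray) -> Plane:
    """Assemble a near-frontal plane (normal points anteriorly).

    The frame's anterior axis is the normal; the in-plane superior axis is
    stored in ``anterior_axis`` (there is no in-plane anterior direction).
    """
    n = _orient(_unit(normal), lm.anterior_reference())
    ml = lm.mediolateral_axis()
    up = np.cross(n, ml)
    if np.linalg.norm(up) < 1e-6:
        raise DegeneratePlaneError("plane normal parallel to ML axis")
    up = _orient(_unit(up), lm.cranial_reference())
    x = np.cross(n, up)
    frame = np.column_stack([x, n, up])
    return Plane(origin=origin, normal=n, anterior_axis=up, frame=frame)


def _plane_through_points(lm: LandmarkSet, names: tuple[str, str, str]) -> Plane:
    lm.require(names)
    p1, p2, p3 = (lm[n] for n in names)
    n = np.cross(p1 - p3, p2 - p3)
    if np.linalg.norm(n) < 1e-6 * max(np.linalg.norm(p1 - p3), 1.0):
        raise DegeneratePlaneError(f"collinear points {names}")
    return _frontal_like_plane(lm, n, (p1 + p2 + p3) / 3.0)


def _plane_app(lm: LandmarkSet) -> Plane:
    """APP: anterior pelvic plane through both ASIS and the symphysis."""
    return _plane_through_points(lm, ("ASIS_L", "ASIS_R", "pubic_symphysis"))


def _plane_ptp(lm: LandmarkSet) -> Plane:
    """PTP: pelvic-tilt plane through the hip-center axis and the pubic
    symphysis (the tilt of the hip-axis-to-symphysis line is a classical
    sagittal tilt measure)."""
    lm.require(("hip_center_L", "hip_center_R", "pubic_symphysis"))
    ml = lm["hip_center_L"] - lm["hip_center_R"]
    d = lm["pubic_symphysis"] - lm.hjc_midpoint
    n = np.cross(ml, d)
    if np.linalg.norm(n) < 1e-6 * max(np.linalg.norm(d), 1.0):
        raise DegeneratePlaneError("symphysis lies on the hip-center axis")
    return _frontal_like_plane(lm, n, lm["pubic_symphysis"])


def _plane_x1(lm: LandmarkSet) -> Plane:
    """X1 (default): plane through both PSIS and the pubic symphysis."""
    return _plane_through_points(lm, ("PSIS_L", "PSIS_R", "pubic_symphysis"))


def _plane_x2(lm: LandmarkSet) -> Plane:
    """X2 (default): plane through the iliac-crest highest points and the
    midpoint of the ischial tuberosities."""
    lm.require(("iliac_crest_L", "iliac_crest_R",
                "ischial_tuberosity_L", "ischial_tuberosity_R"))
    p1 = lm["iliac_crest_L"]
    p2 = lm["iliac_crest_R"]
    p3 = lm.midpoint("ischial_tuberosity_L", "ischial_tuberosity_R")
    n = np.cross(p1 - p3, p2 - p3)
    if np.linalg.norm(n) < 1e-6 * max(np.linalg.norm(p1 - p3), 1.0):
        raise DegeneratePlaneError("collinear iliac crest / tuberosity points")
    return _frontal_like_plane(lm, n, (p1 + p2) / 2.0)


_PLANE_BUILDERS: dict[str, Callable[[LandmarkSet], Plane]] = {
    "SSP": _plane_from_endplate,
    "APP": _plane_app,
    "PTP": _plane_ptp,
    "X1": _plane_x1,
    "X2": _plane_x2,
}

#: The five registered reference-plane identifiers.
PLANE_IDS = tuple(_PLANE_BUILDERS)


def register_reference_plane(plane_id: str,
                             builder: Callable[[LandmarkSet], Plane]) -> None:
    """Override one of the configurable slots (X1 or X2).

    SSP, PTP and APP are fixed; the registry always holds exactly five
    constructors.
    """
    if plane_id not in ("X1", "X2"):
        raise ValueError("only the X1/X2 slots are configurable")
    _PLANE_BUILDERS[plane_id] = builder


def construct_reference_plane(landmarks: LandmarkSet, plane_id: str) -> Plane:
    """Build one of the five pelvic reference planes from landmarks."""
    try:
        builder = _PLANE_BUILDERS[plane_id]
    except KeyError:
        raise ValueError(
            f"unknown plane id {plane_id!r}; expected one of {PLANE_IDS}"
        ) from None
    return builder(landmarks)


# ---------------------------------------------------------------------------
# Morphological parameters
# ---------------------------------------------------------------------------

def _named_point(lm: LandmarkSet, key: str) -> np.ndarray:
    if key == "hjc_midpoint":
        return lm.hjc_midpoint
    if key == "asis_midpoint":
        return lm.asis_midpoint
    if key == "psis_midpoint":
        return lm.psis_midpoint
    return lm[key]


#: Default 13 landmark distances (name, endpoint A, endpoint B).
MORPHO_DISTANCE_DEFS: tuple[tuple[str, str, str], ...] = (
    ("pubic_symphysis_to_hjc_midpoint", "pubic_symphysis", "hjc_midpoint"),
    ("sacral_center_to_hjc_midpoint", "S1_endplate_center", "hjc_midpoint"),
    ("symphysis_to_promontory", "pubic_symphysis", "sacral_promontory"),
    ("symphysis_to_sacral_center", "pubic_symphysis", "S1_endplate_center"),
    ("symphysis_to_asis_midpoint", "pubic_symphysis", "asis_midpoint"),
    ("symphysis_to_psis_midpoint", "pubic_symphysis", "psis_midpoint"),
    ("promontory_to_hjc_midpoint", "sacral_promontory", "hjc_midpoint"),
    ("promontory_to_asis_midpoint", "sacral_promontory", "asis_midpoint"),
    ("promontory_to_psis_midpoint", "sacral_promontory", "psis_midpoint"),
    ("sacral_center_to_asis_midpoint", "S1_endplate_center", "asis_midpoint"),
    ("sacral_center_to_psis_midpoint", "S1_endplate_center", "psis_midpoint"),
    ("inter_asis", "ASIS_L", "ASIS_R"),
    ("inter_hip_center", "hip_center_L", "hip_center_R"),
)

MORPHO_ANGLE_NAMES: tuple[str, ...] = (
    "pelvic_incidence",
    "sacral_pubic_angle",
    "asis_symphysis_promontory_angle",
    "promontory_hjcmid_symphysis_angle",
    "s1_endplate_to_app_angle",
)

N_MORPHO_DISTANCES = 13
N_MORPHO_ANGLES = 5


def _sagittal_project(v: np.ndarray, ml: np.ndarray) -> np.ndarray:
    """Remove the mediolateral component (intrinsic sagittal projection)."""
    return v - np.dot(v, ml) * ml


def pelvic_incidence(lm: LandmarkSet) -> float:
    """Angle between the caudal S1-endplate perpendicular at the endplate
    center and the line to the hip-center midpoint (degrees)."""
    ssp = _plane_from_endplate(lm)
    perp = -ssp.normal  # caudal perpendicular
    d = lm.hjc_midpoint - lm["S1_endplate_center"]
    return angle_between(perp, d)


def sacral_pubic_angle(lm: LandmarkSet) -> float:
    """Sagittal-plane angle between the S1 superior-endplate tangent and
    the line from the S1 endplate center to the pubic symphysis."""
    ml = lm.mediolateral_axis()
    u = _sagittal_project(lm["S1_endplate_anterior"]
                          - lm["S1_endplate_posterior"], ml)
    v = _sagittal_project(lm["pubic_symphysis"] - lm["S1_endplate_center"], ml)
    return angle_between(u, v)


def _angle_at(lm: LandmarkSet, vertex: str, a: str, b: str) -> float:
    p0 = _named_point(lm, vertex)
    return angle_between(_named_point(lm, a) - p0, _named_point(lm, b) - p0)


def _s1_to_app_angle(lm: LandmarkSet) -> float:
    ssp = _plane_from_endplate(lm)
    app = _plane_app(lm)
    return angle_between(ssp.normal, app.normal)


_MORPHO_ANGLE_FUNCS: dict[str, Callable[[LandmarkSet], float]] = {
    "pelvic_incidence": pelvic_incidence,
    "sacral_pubic_angle": sacral_pubic_angle,
    "asis_symphysis_promontory_angle":
        lambda lm: _angle_at(lm, "pubic_symphysis", "asis_midpoint",
                             "sacral_promontory"),
    "promontory_hjcmid_symphysis_angle":
        lambda lm: _angle_at(lm, "hjc_midpoint", "sacral_promontory",
                             "pubic_symphysis"),
    "s1_endplate_to_app_angle": _s1_to_app_angle,
}


@dataclass(frozen=True)
class MorphoParams:
    """18 pose-invariant morphological scalars: 13 distances (mm), 5 angles
    (degrees)."""

    distances: Mapping[str, float]
    angles: Mapping[str, float]

    def __post_init__(self) -> None:
        d = dict(self.distances)
        a = dict(self.angles)
        if len(d) != N_MORPHO_DISTANCES:
            raise ValueError(f"expected {N_MORPHO_DISTANCES} distances, got {len(d)}")
        if len(a) != N_MORPHO_ANGLES:
            raise ValueError(f"expected {N_MORPHO_ANGLES} angles, got {len(a)}")
        if any(v < 0 for v in d.values()):
            raise ValueError("distances must be non-negative")
        if any(not (0.0 <= v < 180.0) for v in a.values()):
            raise ValueError("angles must lie in [0, 180)")
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "angles", a)

    def as_dict(self) -> dict[str, float]:
        out = dict(self.distances)
        out.update(self.angles)
        return out

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.distances) + tuple(self.angles)


def morphological_parameters(
    landmarks: LandmarkSet,
    distance_defs: Sequence[tuple[str, str, str]] = MORPHO_DISTANCE_DEFS,
    angle_funcs: Mapping[str, Callable[[LandmarkSet], float]] | None = None,
) -> MorphoParams:
    """Compute the 18 morphological parameters of a pelvis.

    The registries are override-able but the counts (13 distances, 5 angles)
    are enforced, so downstream predictor tables always carry 18
    morphological columns.
    """
    if angle_funcs is None:
        angle_funcs = _MORPHO_ANGLE_FUNCS
    if len(distance_defs) != N_MORPHO_DISTANCES:
        raise ValueError(f"distance registry must define {N_MORPHO_DISTANCES} entries")
    if len(angle_funcs) != N_MORPHO_ANGLES:
        raise ValueError(f"angle registry must define {N_MORPHO_ANGLES} entries")
    landmarks.require(REQUIRED_LANDMARKS)
    distances = {
        name: float(np.linalg.norm(_named_point(landmarks, a)
                                   - _named_point(landmarks, b)))
        for name, a, b in distance_defs
    }
    angles = {name: float(fn(landmarks)) for name, fn in angle_funcs.items()}
    return MorphoParams(distances=distances, angles=angles)


# ---------------------------------------------------------------------------
# Lumbar lordosis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LumbarMeasures:
    lla: float
    l5s1_fused: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.lla < 120.0):
            raise ValueError("LLA out of plausible range (0, 120) degrees")


def _line_angle_sagittal(v: np.ndarray, ml: np.ndarray,
                         anterior: np.ndarray, cranial: np.ndarray) -> float:
    """Signed inclination of a line in the sagittal plane, degrees in
    (-90, 90]; positive = anterior end higher."""
    w = _sagittal_project(v, ml)
    y = float(np.dot(w, anterior))
    z = float(np.dot(w, cranial))
    if y < 0:  # lines are undirected
        y, z = -y, -z
    if y == 0.0 and z == 0.0:
        raise ValueError("endplate tangent has no sagittal component")
    return float(np.degrees(np.arctan2(z, y)))


def lumbar_lordosis_angle(landmarks: LandmarkSet, l5s1_fused: bool = False) -> float:
    """Lumbar lordosis angle: angle between the superior-endplate tangents
    of L1 and S1 (L1 and L5 when the L5-S1 segment is fused), measured in
    the sagittal projection, in degrees.

    The tangents are taken from 3D anterior/posterior endplate point pairs
    projected into the sagittal plane -- the orthographic equivalent of a
    standing lateral radiograph.
    """
    lower = ("L5sup_a", "L5sup_p") if l5s1_fused else \
        ("S1_endplate_anterior", "S1_endplate_posterior")
    landmarks.require(("L1sup_a", "L1sup_p") + lower)
    ml = landmarks.mediolateral_axis()
    anterior = landmarks.anterior_reference()
    anterior = anterior - np.dot(anterior, ml) * ml
    anterior /= np.linalg.norm(anterior)
    cranial = np.cross(ml, anterior)
    cranial = _orient(cranial, landmarks.cranial_reference())
    a1 = _line_angle_sagittal(landmarks["L1sup_a"] - landmarks["L1sup_p"],
                              ml, anterior, cranial)
    a2 = _line_angle_sagittal(landmarks[lower[0]] - landmarks[lower[1]],
                              ml, anterior, cranial)
    return abs(a1 - a2)
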