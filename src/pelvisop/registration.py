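"""Rigid 3D/2.5D registration of a pelvis model to biplanar projections.

The imaging model is a pair of orthogonal orthographic projections sharing
the vertical (Z) axis: the AP view drops the antero-posterior coordinate
(returns (x, z)) and the lateral view drops the mediolateral coordinate
(returns (y, z)). Real biplanar slot scanners have no vertical distortion
and only a mild horizontal fan; the fully orthographic model is a declared
simplification.

Registration runs in two stages, mirroring the clinical workflow:

1. :func:`preregister` -- closed-form + least-squares fit of the 6-DOF pose
   to a handful of manually picked landmarks (hip centers, symphysis,
   promontory by default) seen in one or both views.
2. :func:`refine` -- derivative-free local optimization (Nelder--Mead) of
   the mean squared distance between the projected model silhouette samples
   and the picked image contours, replacing the manual fine-tuning step.

:func:`icp_rigid` provides the rigid iterative-closest-point fit used to
transfer a postoperative cup reconstruction onto the preoperative bone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import OrientationTriple, Pose, plane_orientation
from .pelvis import LandmarkSet, construct_reference_plane

__all__ = [
    "BiplanarViews",
    "RegistrationResult",
    "UnderConstrainedError",
    "ContourError",
    "DEFAULT_PICK_NAMES",
    "project",
    "preregister",
    "refine",
    "measure_pose",
    "measure_sop",
    "icp_rigid",
]


class UnderConstrainedError(ValueError):
    """Fewer than three picked landmarks: the 6-DOF pose is not determined."""


class ContourError(ValueError):
    """Contour-based refinement was requested without contour samples."""


#: Landmarks picked on the images for pre-registration.
DEFAULT_PICK_NAMES = ("hip_center_L", "hip_center_R",
                      "pubic_symphysis", "sacral_promontory")


@dataclass(frozen=True)
class BiplanarViews:
    """Two orthogonal projections with picked 2D landmarks.

    ``ap_picks`` maps landmark name -> (x, z) in mm, ``lat_picks`` maps
    name -> (y, z). Optional ``ap_contour``/``lat_contour`` are (n, 2)
    arrays of projected silhouette samples.
    """

    ap_picks: Mapping[str, np.ndarray]
    lat_picks: Mapping[str, np.ndarray]
    ap_contour: np.ndarray | None = None
    lat_contour: np.ndarray | None = None

    def __post_init__(self) -> None:
        for attr in ("ap_picks", "lat_picks"):
            picks = {n: np.asarray(p, dtype=float).reshape(2)
                     for n, p in dict(getattr(self, attr)).items()}
            object.__setattr__(self, attr, picks)
        for attr in ("ap_contour", "lat_contour"):
            c = getattr(self, attr)
            if c is not None:
                c = np.asarray(c, dtype=float).reshape(-1, 2)
                object.__setattr__(self, attr, c)

    @property
    def has_contours(self) -> bool:
        return (self.ap_contour is not None and len(self.ap_contour) > 0
                and self.lat_contour is not None and len(self.lat_contour) > 0)

    def pick_names(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.ap_picks) | set(self.lat_picks)))

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "ap_picks": {n: list(map(float, p)) for n, p in self.ap_picks.items()},
            "lat_picks": {n: list(map(float, p)) for n, p in self.lat_picks.items()},
        }
        if self.ap_contour is not None:
            payload["ap_contour"] = self.ap_contour.tolist()
        if self.lat_contour is not None:
            payload["lat_contour"] = self.lat_contour.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "BiplanarViews":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            ap_picks=raw["ap_picks"],
            lat_picks=raw["lat_picks"],
            ap_contour=raw.get("ap_contour"),
            lat_contour=raw.get("lat_contour"),
        )


@dataclass(frozen=True)
class RegistrationResult:
    pose: Pose
    rms_residual: float
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")


def project(points: np.ndarray, pose: Pose) -> tuple[np.ndarray, np.ndarray]:
    """Orthographic biplanar projection of 3D points under a pose.

    Returns (ap, lat) where ap[:, i] = (x, z) and lat[:, i] = (y, z) of the
    transformed points.
    """
    p = pose.apply(np.atleast_2d(np.asarray(points, dtype=float)))
    ap = p[:, [0, 2]]
    lat = p[:, [1, 2]]
    return ap, lat


def _kabsch(src: np.ndarray, dst: np.ndarray) -> Pose:
    """Least-squares rigid transform mapping src onto dst (both (n, 3))."""
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return Pose(R, dc - R @ sc)


def _pose_from_params(x: np.ndarray) -> Pose:
    return Pose(Rotation.from_rotvec(x[:3]).as_matrix(), x[3:6])


def _params_from_pose(pose: Pose) -> np.ndarray:
    return np.concatenate([Rotation.from_matrix(pose.rotation).as_rotvec(),
                           pose.translation])


def preregister(landmarks: LandmarkSet, views: BiplanarViews,
                pick_names: Sequence[str] | None = None) -> Pose:
    """Fit the rigid pose to picked landmarks by 2D least squares.

    Every 3D pick contributes up to four scalar constraints (two per view it
    was picked in). The solution minimizes the sum of squared projected
    residuals over the 6-DOF pose; a closed-form point fit (from picks
    visible in both views, whose 3D position the two projections determine
    completely) provides the starting value.
    """
    names = views.pick_names() if pick_names is None else tuple(pick_names)
    names = tuple(n for n in names if n in landmarks
                  and (n in views.ap_picks or n in views.lat_picks))
    if len(names) < 3:
        raise UnderConstrainedError(
            f"need at least 3 picked landmarks, got {len(names)}")

    model = landmarks.array(names)

    # closed-form initialization from both-view picks
    both = [n for n in names if n in views.ap_picks and n in views.lat_picks]
    if len(both) >= 3:
        target = np.array([
            [views.ap_picks[n][0], views.lat_picks[n][0],
             0.5 * (views.ap_picks[n][1] + views.lat_picks[n][1])]
            for n in both])
        x0 = _params_from_pose(_kabsch(landmarks.array(both), target))
    else:
        x0 = np.zeros(6)

    ap_idx = [i for i, n in enumerate(names) if n in views.ap_picks]
    lat_idx = [i for i, n in enumerate(names) if n in views.lat_picks]
    ap_target = np.array([views.ap_picks[names[i]] for i in ap_idx]) \
        if ap_idx else np.zeros((0, 2))
    lat_target = np.array([views.lat_picks[names[i]] for i in lat_idx]) \
        if lat_idx else np.zeros((0, 2))

    def residuals(x: np.ndarray) -> np.ndarray:
        ap, lat = project(model, _pose_from_params(x))
        return np.concatenate([(ap[ap_idx] - ap_target).ravel(),
                               (lat[lat_idx] - lat_target).ravel()])

    sol = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12)
    return _pose_from_params(sol.x)


def refine(pose0: Pose, model_contour3d: np.ndarray,
           views: BiplanarViews, max_iter: int = 500,
           step_tol: float = 1e-4) -> RegistrationResult:
    """Contour-based local refinement of a pre-registered pose.

    Minimizes the mean squared distance from the projected model silhouette
    samples to the nearest target-contour point, summed over both views,
    with a Nelder--Mead search over a 6-vector of pose offsets (rotation in
    degrees, translation in mm). The returned pose never has a larger
    objective than ``pose0``.
    """
    if not views.has_contours:
        raise ContourError("views carry no contour samples")
    model = np.asarray(model_contour3d, dtype=float).reshape(-1, 3)
    if len(model) == 0:
        raise ContourError("empty model contour")
    trees = (cKDTree(views.ap_contour), cKDTree(views.lat_contour))

    R0, t0 = pose0.rotation, pose0.translation

    def pose_at(x: np.ndarray) -> Pose:
        dR = Rotation.from_rotvec(np.radians(x[:3])).as_matrix()
        return Pose(dR @ R0, dR @ t0 + x[3:6])

    trace: list[float] = []

    def objective(x: np.ndarray) -> float:
        ap, lat = project(model, pose_at(x))
        d_ap, _ = trees[0].query(ap)
        d_lat, _ = trees[1].query(lat)
        val = float(np.mean(d_ap**2) + np.mean(d_lat**2))
        trace.append(val)
        return val

    f0 = objective(np.zeros(6))
    res = minimize(objective, np.zeros(6), method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": step_tol,
                            "fatol": 1e-10})
    if res.fun <= f0:
        pose, fbest = pose_at(res.x), float(res.fun)
    else:  # local search never worsens the starting point
        pose, fbest = pose0, f0
    return RegistrationResult(pose=pose, rms_residual=float(np.sqrt(fbest / 2.0)),
                              n_iterations=int(res.nit),
                              converged=bool(res.success))


def measure_pose(landmarks: LandmarkSet, views: BiplanarViews,
                 model_contour3d: np.ndarray | None = None,
                 pick_names: Sequence[str] | None = None) -> Pose:
    """Full registration: landmark pre-registration, then contour refinement
    whenever both the views and the model provide contour samples."""
    pose = preregister(landmarks, views, pick_names=pick_names)
    if views.has_contours and model_contour3d is not None:
        pose = refine(pose, model_contour3d, views).pose
    return pose


def measure_sop(landmarks: LandmarkSet, views: BiplanarViews,
                plane: str = "SSP",
                model_contour3d: np.ndarray | None = None,
                pick_names: Sequence[str] | None = None) -> OrientationTriple:
    """Measure the orientation (SOP/FOP/TOP) of a reference plane from
    biplanar views of the pelvis."""
    pose = measure_pose(landmarks, views, model_contour3d=model_contour3d,
                        pick_names=pick_names)
    ref = construct_reference_plane(landmarks, plane)
    return plane_orientation(ref, pose)


def icp_rigid(source: np.ndarray, target: np.ndarray,
              init: Pose | None = None, max_iter: int = 200,
              tol: float = 1e-6) -> RegistrationResult:
    """Rigid iterative-closest-point registration of two point clouds.

    Alternates nearest-neighbour correspondence with the closed-form rigid
    least-squares fit until the RMS correspondence distance changes by less
    than ``tol`` mm. The RMS is non-increasing across iterations.
    """
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    dst = np.asarray(target, dtype=float).reshape(-1, 3)
    if len(src) < 3 or len(dst) < 3:
        raise ValueError("ICP needs at least 3 points in each cloud")
    for cloud, label in ((src, "source"), (dst, "target")):
        s = np.linalg.svd(cloud - cloud.mean(axis=0), compute_uv=False)
        if s[1] < 1e-9 * max(s[0], 1.0):
            raise ValueError(f"degenerate (collinear) {label} geometry")

    pose = init if init is not None else Pose.identity()
    tree = cKDTree(dst)
    rms_prev = np.inf
    rms = np.inf
    n_it = 0
    for n_it in range(1, max_iter + 1):
        moved = pose.apply(src)
        dists, idx = tree.query(moved)
        rms = float(np.sqrt(np.mean(dists**2)))
        if abs(rms_prev - rms) < tol:
            break
        rms_prev = rms
        pose = _kabsch(src, dst[idx])
    return RegistrationResult(pose=pose, rms_residual=rms,
                              n_iterations=n_it,
                              converged=abs(rms_prev - rms) < tol)
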