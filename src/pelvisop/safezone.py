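"""Range-of-motion-based cup safe zones and their shrinkage under sagittal
pelvic tilt uncertainty.

The model is a generic cone-impingement construction: the cup/liner permits
the prosthetic neck to deviate from the cup axis by up to half the
oscillation angle

    OA = 180 deg - 2 * arcsin(neck_diameter / head_diameter)

before neck-liner impingement. A cup orientation (radiographic inclination
and anteversion, Murray convention, in the anterior-pelvic-plane frame) is
*safe* when the neck axis stays inside that free cone throughout every
required hip motion arc. Stem geometry (CCD angle, stem anteversion) fixes
the neutral neck axis; motions rotate it about the hip center.

Sagittal tilt uncertainty is handled by intersecting the zones obtained
with the pelvis (and hence the cup, which is fixed to the bone) tilted by
each offset in a given set; the reported reduction is the area lost
relative to the nominal zone. The construction is deliberately generic --
the required-motion set is configurable -- so published percentages tied to
a specific proprietary zone definition are a qualitative, not quantitative,
reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .geometry import rotation_x

__all__ = [
    "ProsthesisSpec",
    "SafeZoneGrid",
    "DEFAULT_ROM",
    "oscillation_angle",
    "rom_safe_zone",
    "shrink_for_uncertainty",
]


@dataclass(frozen=True)
class ProsthesisSpec:
    """Implant geometry: head/neck diameters (mm), CCD angle and stem
    anteversion (degrees)."""

    head_diameter: float = 32.0
    neck_diameter: float = 11.5
    ccd_angle: float = 130.0
    stem_anteversion: float = 15.0

    def __post_init__(self) -> None:
        if not 0 < self.neck_diameter < self.head_diameter:
            raise ValueError("need 0 < neck_diameter < head_diameter")


#: Default required range of motion (degrees of arc amplitude).
DEFAULT_ROM: Mapping[str, float] = {
    "flexion": 130.0,
    "extension": 40.0,
    "internal_rotation_90flex": 40.0,
    "external_rotation": 40.0,
}


def oscillation_angle(spec: ProsthesisSpec) -> float:
    """Total cone angle of free neck motion, degrees."""
    ratio = spec.neck_diameter / spec.head_diameter
    if ratio >= 1.0:
        raise ValueError("neck/head ratio must be < 1")
    return 180.0 - 2.0 * np.degrees(np.arcsin(ratio))


def _neutral_neck_axis(spec: ProsthesisSpec) -> np.ndarray:
    """Unit vector from neck base toward the head center, right hip, APP
    frame (X medial, Y anterior, Z cranial)."""
    elev = np.radians(spec.ccd_angle - 90.0)
    azim = np.radians(spec.stem_anteversion)
    return np.array([np.cos(elev) * np.cos(azim),
                     np.cos(elev) * np.sin(azim),
                     np.sin(elev)])


def _axis_rotation(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


_SHAFT = np.array([0.0, 0.0, -1.0])  # femoral shaft, neutral stance


def _motion_rotation(name: str, angle: float) -> np.ndarray:
    """Femur rotation at a given angle along one named motion arc."""
    if name == "flexion":
        return rotation_x(angle)
    if name == "extension":
        return rotation_x(-angle)
    if name == "internal_rotation_90flex":
        return rotation_x(90.0) @ _axis_rotation(_SHAFT, angle)
    if name == "external_rotation":
        return _axis_rotation(_SHAFT, -angle)
    raise ValueError(f"unknown motion {name!r}")


def motion_neck_directions(spec: ProsthesisSpec,
                           required_rom: Mapping[str, float],
                           arc_step: float = 2.0) -> np.ndarray:
    """Neck shaft directions (head -> neck base, unit rows) swept along all
    required motion arcs, sampled every ``arc_step`` degrees."""
    n0 = _neutral_neck_axis(spec)
    dirs = [-n0]  # neutral stance is always required
    for name, amplitude in required_rom.items():
        if amplitude < 0:
            raise ValueError("ROM amplitudes must be non-negative")
        if amplitude == 0:  # motion not required: no arc, no base posture
            continue
        n_steps = max(int(np.ceil(amplitude / arc_step)), 1)
        for a in np.linspace(0.0, amplitude, n_steps + 1):
            dirs.append(-(_motion_rotation(name, a) @ n0))
    return np.asarray(dirs)


def _cup_axes(inclination: np.ndarray, anteversion: np.ndarray) -> np.ndarray:
    """Cup opening axes for a right hip from radiographic angles.

    Returns an array of shape (len(inclination), len(anteversion), 3). The
    axis points out of the cup opening: lateral (-X), anterior with
    anteversion, inferior with small inclination.
    """
    ri = np.radians(inclination)[:, None]
    av = np.radians(anteversion)[None, :]
    ax = -np.sin(ri) * np.cos(av)
    ay = np.broadcast_to(np.sin(av), ax.shape)
    az = -np.cos(ri) * np.cos(av)
    return np.stack(np.broadcast_arrays(ax, ay, az), axis=-1)


@dataclass(frozen=True)
class SafeZoneGrid:
    """Boolean impingement-free mask over a radiographic cup-angle grid
    (APP reference frame)."""

    inclination: np.ndarray   # degrees, strictly increasing
    anteversion: np.ndarray   # degrees, strictly increasing
    mask: np.ndarray          # shape (len(inclination), len(anteversion))

    def __post_init__(self) -> None:
        inc = np.asarray(self.inclination, float)
        av = np.asarray(self.anteversion, float)
        if np.any(np.diff(inc) <= 0) or np.any(np.diff(av) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        mask = np.asarray(self.mask, bool)
        if mask.shape != (len(inc), len(av)):
            raise ValueError("mask shape does not match the axes")
        object.__setattr__(self, "inclination", inc)
        object.__setattr__(self, "anteversion", av)
        object.__setattr__(self, "mask", mask)

    @property
    def grid_step(self) -> tuple[float, float]:
        return (float(self.inclination[1] - self.inclination[0]),
                float(self.anteversion[1] - self.anteversion[0]))

    def area(self) -> float:
        """Zone area in deg^2 (cell count times cell area)."""
        si, sa = self.grid_step
        return float(self.mask.sum()) * si * sa

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame(self.mask.astype(int), index=self.inclination,
                     columns=self.anteversion).to_csv(path)


def _safe_mask(spec: ProsthesisSpec, required_rom: Mapping[str, float],
               inclination: np.ndarray, anteversion: np.ndarray,
               pelvis_tilt: float = 0.0, arc_step: float = 2.0) -> np.ndarray:
    dirs = motion_neck_directions(spec, required_rom, arc_step=arc_step)
    axes = _cup_axes(inclination, anteversion)
    if pelvis_tilt != 0.0:
        axes = axes @ rotation_x(pelvis_tilt).T
    cos_lim = np.cos(np.radians(oscillation_angle(spec) / 2.0))
    dots = axes @ dirs.T                      # (ni, na, n_dirs)
    return dots.min(axis=-1) >= cos_lim


def rom_safe_zone(spec: ProsthesisSpec,
                  required_rom: Mapping[str, float] | None = None,
                  grid_step: float = 2.0,
                  inclination_range: tuple[float, float] = (0.0, 90.0),
                  anteversion_range: tuple[float, float] = (-30.0, 60.0),
                  arc_step: float = 2.0) -> SafeZoneGrid:
    """Compute the impingement-free cup orientation zone.

    A grid cell is safe iff, for every required motion, the neck axis stays
    within the free cone of half-angle OA/2 about the cup axis along the
    whole arc.
    """
    if required_rom is None:
        required_rom = DEFAULT_ROM
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    inc = np.arange(inclination_range[0], inclination_range[1] + 0.5 * grid_step,
                    grid_step)
    av = np.arange(anteversion_range[0], anteversion_range[1] + 0.5 * grid_step,
                   grid_step)
    if len(inc) < 2 or len(av) < 2:
        raise ValueError("empty safe-zone grid")
    mask = _safe_mask(spec, required_rom, inc, av, arc_step=arc_step)
    return SafeZoneGrid(inclination=inc, anteversion=av, mask=mask)


def shrink_for_uncertainty(zone: SafeZoneGrid, spec: ProsthesisSpec,
                           required_rom: Mapping[str, float] | None = None,
                           tilt_offsets: Sequence[float] = (0.0,),
                           arc_step: float = 2.0
                           ) -> tuple[SafeZoneGrid, float]:
    """Shrink a safe zone to cover sagittal tilt uncertainty.

    The zone is recomputed with the pelvis tilted sagittally by each offset
    (degrees; e.g. mean +/- k*SD of the expected postoperative change) and
    the masks intersected. Returns the shrunk zone and the reduction in
    percent of the nominal zone's area. Adding offsets can only shrink the
    result further.
    """
    if required_rom is None:
        required_rom = DEFAULT_ROM
    inter = zone.mask.copy()
    for off in tilt_offsets:
        inter &= _safe_mask(spec, required_rom, zone.inclination,
                            zone.anteversion, pelvis_tilt=float(off),
                            arc_step=arc_step)
    base = zone.mask.sum()
    reduction = 0.0 if base == 0 else 100.0 * (1.0 - inter.sum() / base)
    return (SafeZoneGrid(zone.inclination, zone.anteversion, inter),
            float(reduction))


def plot_zone(zone: SafeZoneGrid, ax=None, **imshow_kw):
    """Quick-look plot of a safe-zone mask (matplotlib, lazy import)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(zone.mask.T[::-1], extent=(zone.inclination[0], zone.inclination[-1],
                                         zone.anteversion[0], zone.anteversion[-1]),
              aspect="auto", **imshow_kw)
    ax.set_xlabel("radiographic inclination (deg)")
    ax.set_ylabel("radiographic anteversion (deg)")
    return ax
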