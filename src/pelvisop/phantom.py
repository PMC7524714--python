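"""Phantom accuracy protocol for the biplanar SOP measurement.

A synthetic trunk phantom (the template pelvis) is positioned at 19
controlled orientations -- a grid over dSOP/dTOP with two frontal poses and
two pure +/-30 deg sagittal poses -- and the SOP is measured from generated
biplanar views a fixed number of times per orientation. Since a physical
reference measurement is impossible without damaging a real phantom, the
mean of the measurements at the neutral orientation serves as the reference:
the neutral mean and the applied dSOP are subtracted from every measurement,
so the corrected values estimate the measurement error directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import plane_orientation
from .pelvis import LandmarkSet, construct_reference_plane
from .registration import preregister
from .synthetic_data import generate_phantom_views

__all__ = [
    "PhantomPose",
    "PhantomReport",
    "MissingNeutralError",
    "TABLE_GRID_POSES",
    "run_phantom_protocol",
]


class MissingNeutralError(ValueError):
    """The pose list lacks the neutral pose; the reference is undefined."""


@dataclass(frozen=True)
class PhantomPose:
    """Controlled orientation offsets applied to the phantom (degrees)."""

    d_sop: float
    d_fop: float
    d_top: float

    @property
    def is_neutral(self) -> bool:
        return self.d_sop == self.d_fop == self.d_top == 0.0

    def label(self) -> str:
        return f"({self.d_sop:g}, {self.d_fop:g}, {self.d_top:g})"


#: The 19-orientation protocol grid: dSOP in {-15, 0, 15} crossed with
#: dTOP in {-30, -15, 0, 15, 30}, two frontal poses (dSOP=15, dFOP=+/-15)
#: and the two pure sagittal extremes dSOP = +/-30.
TABLE_GRID_POSES: tuple[PhantomPose, ...] = tuple(
    PhantomPose(s, f, t) for s, f, t in [
        (0, 0, -30), (0, 0, -15), (0, 0, 0), (0, 0, 15), (0, 0, 30),
        (15, 0, -30), (15, 0, -15), (15, 0, 0), (15, 0, 15), (15, 0, 30),
        (-15, 0, -30), (-15, 0, -15), (-15, 0, 0), (-15, 0, 15), (-15, 0, 30),
        (15, 15, 0), (15, -15, 0),
        (30, 0, 0), (-30, 0, 0),
    ]
)


@dataclass(frozen=True)
class PhantomReport:
    """Per-pose and pooled summary of corrected SOP errors per plane."""

    table: pd.DataFrame       # one row per pose + pooled rows, stats per plane
    corrected: pd.DataFrame   # long form: pose, repeat, plane, corrected error
    planes: tuple[str, ...]
    repeats: int
    pick_noise_sd: float

    def pooled_mean_abs(self, plane: str = "SSP") -> float:
        """Pooled mean of absolute corrected SOP errors for one plane."""
        vals = self.corrected.loc[self.corrected["plane"] == plane, "error"]
        return float(np.abs(vals).mean())

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _summarize(values: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def run_phantom_protocol(
    landmarks: LandmarkSet,
    poses: Sequence[PhantomPose] | None = None,
    repeats: int = 5,
    pick_noise_sd: float = 0.5,
    seed: int = 0,
    planes: Sequence[str] = ("SSP", "PTP", "APP"),
) -> PhantomReport:
    """Run the full phantom protocol and tabulate corrected SOP errors.

    For every pose and repeat, biplanar views are generated with seeded pick
    noise, the pose is re-estimated by landmark pre-registration, and the
    SOP of each requested reference plane is read off. The mean SOP at the
    neutral pose (per plane) and the applied dSOP are subtracted; the
    corrected values are summarized as mean (SD, min to max) per pose plus
    pooled "all values" and "all absolute values" rows.
    """
    if poses is None:
        poses = TABLE_GRID_POSES
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not any(p.is_neutral for p in poses):
        raise MissingNeutralError(
            "pose list must include the neutral pose (0, 0, 0)")

    ref_planes = {p: construct_reference_plane(landmarks, p) for p in planes}
    seeds = np.random.SeedSequence(seed).spawn(len(poses) * repeats)

    records: list[dict] = []
    k = 0
    for pose in poses:
        for rep in range(repeats):
            views = generate_phantom_views(
                landmarks, pose, pick_noise_sd=pick_noise_sd,
                seed=seeds[k])
            k += 1
            solved = preregister(landmarks, views)
            for plane_id, plane in ref_planes.items():
                sop = plane_orientation(plane, solved).sop
                records.append({"pose": pose.label(), "d_sop": pose.d_sop,
                                "repeat": rep, "plane": plane_id, "sop": sop})
    raw = pd.DataFrame.from_records(records)

    neutral_label = next(p for p in poses if p.is_neutral).label()
    neutral_mean = (raw[raw["pose"] == neutral_label]
                    .groupby("plane")["sop"].mean())
    raw["error"] = raw["sop"] - raw["plane"].map(neutral_mean) - raw["d_sop"]

    rows = []
    for pose in poses:
        row: dict[str, object] = {"pose": pose.label(), "d_sop": pose.d_sop,
                                  "d_fop": pose.d_fop, "d_top": pose.d_top}
        for plane_id in planes:
            vals = raw.loc[(raw["pose"] == pose.label())
                           & (raw["plane"] == plane_id), "error"].to_numpy()
            for stat, v in _summarize(vals).items():
                row[f"{plane_id}_{stat}"] = v
        rows.append(row)
    for label, transform in (("all values", lambda v: v),
                             ("all absolute values", np.abs)):
        row = {"pose": label, "d_sop": np.nan, "d_fop": np.nan,
               "d_top": np.nan}
        for plane_id in planes:
            vals = transform(raw.loc[raw["plane"] == plane_id,
                                     "error"].to_numpy())
            for stat, v in _summarize(vals).items():
                row[f"{plane_id}_{stat}"] = v
        rows.append(row)

    table = pd.DataFrame(rows)
    corrected = raw[["pose", "d_sop", "repeat", "plane", "error"]].copy()
    return PhantomReport(table=table, corrected=corrected,
                         planes=tuple(planes), repeats=repeats,
                         pick_noise_sd=pick_noise_sd)
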