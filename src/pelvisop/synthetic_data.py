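"""Synthetic inputs for the whole pipeline.

Three generators:

* :func:`template_pelvis` -- a canonical, bilaterally symmetric landmark set
  with a designed sacral slope of 38.5 deg (the supine cohort mean, so the
  fixture doubles as a realistic measurement target) and a pelvic incidence
  near 56 deg; scale and per-coordinate Gaussian jitter produce families of
  plausible pelves.
* :func:`generate_phantom_views` -- biplanar projections of the template at
  a controlled (dSOP, dFOP, dTOP) orientation with seeded pick noise,
  emulating a trunk phantom positioned with gauge blocks in a biplanar
  scanner.
* :func:`generate_cohort` -- patient tables whose predictor marginals follow
  the published cohort descriptives and whose postoperative standing SOP
  follows the published linear generating models with Gaussian noise.

Cohort generating models (response = postoperative standing SOP, degrees):

* scenario A: 7.53 - 0.19*age + 1.01*supine_sop + eps, eps ~ N(0, 4.8^2)
* scenario B: -4.59 + 0.09*lla + 0.31*supine_sop + 0.61*standing_sop + eps,
  eps ~ N(0, 3.6^2)

The standing SOP is the supine SOP plus an independent N(-0.8, 5.2^2)
offset, so that the standing SD is sqrt(8.3^2 + 5.2^2) ~ 9.8 as published.
The LLA mean of 48.4 deg is calibrated so that the scenario-B model's
implied postoperative mean equals 34.7 deg, which also fixes the implied
mean standing-to-postoperative change at -3.0 deg.

Truncated marginals use mean-calibrated truncated normals: the parent
location is solved so the *truncated* mean equals the configured mean,
keeping the generator's marginal means exact in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .geometry import OrientationTriple, Pose, recompose_orientation
from .pelvis import (
    MORPHO_ANGLE_NAMES,
    MORPHO_DISTANCE_DEFS,
    LandmarkSet,
    morphological_parameters,
)
from .registration import DEFAULT_PICK_NAMES, BiplanarViews, project

__all__ = [
    "TEMPLATE_GROUND_TRUTH",
    "template_pelvis",
    "template_contour3d",
    "generate_phantom_views",
    "GeneratorConfig",
    "generate_cohort",
    "predictor_names",
    "predictor_matrix",
    "BIOMETRIC_PREDICTORS",
    "MORPHOLOGICAL_PREDICTORS",
    "FUNCTIONAL_PREDICTORS",
    "RESPONSE",
    "SCENARIO_COEFFS",
    "SCENARIO_NOISE_SD",
]

# ---------------------------------------------------------------------------
# Template pelvis
# ---------------------------------------------------------------------------

_SLOPE = 38.5          # designed sacral slope, deg
_LLA = 48.4            # designed lumbar lordosis angle, deg
_S1C = np.array([0.0, 25.0, 80.0])
_EP_HALF = 17.0        # S1 endplate half-length, mm


def _endplate_pair(center: np.ndarray, tilt_deg: float,
                   half: float) -> tuple[np.ndarray, np.ndarray]:
    d = half * np.array([0.0, np.cos(np.radians(tilt_deg)),
                         np.sin(np.radians(tilt_deg))])
    return center + d, center - d


_S1_A, _S1_P = _endplate_pair(_S1C, _SLOPE, _EP_HALF)
_L1_A, _L1_P = _endplate_pair(np.array([0.0, 35.0, 240.0]), _SLOPE - _LLA, 15.0)
_L5_A, _L5_P = _endplate_pair(np.array([0.0, 32.0, 110.0]), 25.0, 15.0)

_TEMPLATE_POINTS: dict[str, np.ndarray] = {
    "hip_center_L": np.array([85.0, 0.0, 0.0]),
    "hip_center_R": np.array([-85.0, 0.0, 0.0]),
    "ASIS_L": np.array([115.0, 70.0, 90.0]),
    "ASIS_R": np.array([-115.0, 70.0, 90.0]),
    "PSIS_L": np.array([42.0, -90.0, 95.0]),
    "PSIS_R": np.array([-42.0, -90.0, 95.0]),
    "pubic_symphysis": np.array([0.0, 66.0, -25.0]),
    "pubic_tubercle_L": np.array([16.0, 68.0, -15.0]),
    "pubic_tubercle_R": np.array([-16.0, 68.0, -15.0]),
    "sacral_promontory": _S1_A + np.array([0.0, 3.0, 1.0]),
    "S1_endplate_anterior": _S1_A,
    "S1_endplate_posterior": _S1_P,
    "S1_endplate_center": _S1C,
    "ischial_tuberosity_L": np.array([55.0, -20.0, -95.0]),
    "ischial_tuberosity_R": np.array([-55.0, -20.0, -95.0]),
    "iliac_crest_L": np.array([65.0, -10.0, 140.0]),
    "iliac_crest_R": np.array([-65.0, -10.0, 140.0]),
    "L1sup_a": _L1_A, "L1sup_p": _L1_P,
    "L5sup_a": _L5_A, "L5sup_p": _L5_P,
}

#: Designed (generator-input) values the template is built to reproduce.
TEMPLATE_GROUND_TRUTH: Mapping[str, float] = {
    "sacral_slope": _SLOPE,
    "lla": _LLA,
}


def template_pelvis(seed: int = 0, scale: float = 1.0,
                    jitter_sd: float = 0.0) -> LandmarkSet:
    """The canonical template landmark set, optionally scaled and jittered.

    ``jitter_sd`` adds independent N(0, jitter_sd^2) mm noise to every
    coordinate (breaking the exact bilateral symmetry of the unjittered
    template). Angles are scale-invariant; distances scale linearly.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    pts = {}
    for name, p in _TEMPLATE_POINTS.items():
        q = scale * p
        if jitter_sd > 0:
            q = q + rng.normal(0.0, jitter_sd, size=3)
        pts[name] = q
    return LandmarkSet(pts)


def _arc(p: np.ndarray, q: np.ndarray, bulge: np.ndarray,
         n: int) -> np.ndarray:
    """Quadratic Bezier arc from p to q bulging toward ``bulge``."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    c = 0.5 * (p + q) + bulge
    return (1 - t) ** 2 * p + 2 * t * (1 - t) * c + t**2 * q


def template_contour3d(landmarks: LandmarkSet, n_per_arc: int = 25) -> np.ndarray:
    """A deterministic silhouette stand-in: arcs along the iliac wings,
    pelvic brim and obturator region, sampled from the landmark geometry."""
    lm = landmarks
    arcs = [
        _arc(lm["ASIS_L"], lm["iliac_crest_L"], np.array([25.0, 0, 25.0]), n_per_arc),
        _arc(lm["ASIS_R"], lm["iliac_crest_R"], np.array([-25.0, 0, 25.0]), n_per_arc),
        _arc(lm["iliac_crest_L"], lm["PSIS_L"], np.array([10.0, -25.0, 10.0]), n_per_arc),
        _arc(lm["iliac_crest_R"], lm["PSIS_R"], np.array([-10.0, -25.0, 10.0]), n_per_arc),
        _arc(lm["ASIS_L"], lm["pubic_symphysis"], np.array([20.0, 25.0, -20.0]), n_per_arc),
        _arc(lm["ASIS_R"], lm["pubic_symphysis"], np.array([-20.0, 25.0, -20.0]), n_per_arc),
        _arc(lm["pubic_symphysis"], lm["ischial_tuberosity_L"],
             np.array([15.0, 10.0, -15.0]), n_per_arc),
        _arc(lm["pubic_symphysis"], lm["ischial_tuberosity_R"],
             np.array([-15.0, 10.0, -15.0]), n_per_arc),
        _arc(lm["sacral_promontory"], lm["PSIS_L"], np.array([15.0, 0, 10.0]), n_per_arc),
        _arc(lm["sacral_promontory"], lm["PSIS_R"], np.array([-15.0, 0, 10.0]), n_per_arc),
        _arc(lm["hip_center_L"], lm["ischial_tuberosity_L"],
             np.array([20.0, -10.0, 0.0]), n_per_arc),
        _arc(lm["hip_center_R"], lm["ischial_tuberosity_R"],
             np.array([-20.0, -10.0, 0.0]), n_per_arc),
    ]
    return np.vstack(arcs)


def generate_phantom_views(landmarks: LandmarkSet, pose,
                           pick_noise_sd: float = 0.0, seed: int = 0,
                           pick_names=DEFAULT_PICK_NAMES,
                           include_contours: bool = False) -> BiplanarViews:
    """Biplanar views of the model at a controlled phantom orientation.

    ``pose`` is anything with ``d_sop``/``d_fop``/``d_top`` attributes or a
    (dSOP, dFOP, dTOP) triple in degrees; the rotation is composed in the
    package's fixed Z(TOP)-X(SOP)-Y(FOP) sequence. Seeded isotropic Gaussian
    pick noise (mm) emulates manual landmark selection on the images.
    """
    if hasattr(pose, "d_sop"):
        d_sop, d_fop, d_top = pose.d_sop, pose.d_fop, pose.d_top
    else:
        d_sop, d_fop, d_top = pose
    rot = recompose_orientation(OrientationTriple(sop=d_sop, fop=d_fop, top=d_top))
    world_pose = Pose(rot, np.zeros(3))
    rng = np.random.default_rng(seed)

    names = tuple(n for n in pick_names if n in landmarks)
    ap, lat = project(landmarks.array(names), world_pose)
    if pick_noise_sd > 0:
        ap = ap + rng.normal(0.0, pick_noise_sd, ap.shape)
        lat = lat + rng.normal(0.0, pick_noise_sd, lat.shape)
    ap_picks = dict(zip(names, ap))
    lat_picks = dict(zip(names, lat))

    ap_contour = lat_contour = None
    if include_contours:
        contour = template_contour3d(landmarks)
        ap_contour, lat_contour = project(contour, world_pose)
        if pick_noise_sd > 0:
            ap_contour = ap_contour + rng.normal(0.0, pick_noise_sd, ap_contour.shape)
            lat_contour = lat_contour + rng.normal(0.0, pick_noise_sd, lat_contour.shape)
    return BiplanarViews(ap_picks=ap_picks, lat_picks=lat_picks,
                         ap_contour=ap_contour, lat_contour=lat_contour)


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

BIOMETRIC_PREDICTORS = ("sex", "age", "height", "weight", "bmi")
MORPHOLOGICAL_PREDICTORS = tuple(d[0] for d in MORPHO_DISTANCE_DEFS) + \
    MORPHO_ANGLE_NAMES
FUNCTIONAL_PREDICTORS = (
    "supine_sop", "standing_sop", "lla", "l5s1_fused",
    "rom_flexion", "rom_extension", "rom_abduction", "rom_adduction",
    "rom_internal_rotation", "rom_external_rotation",
)
RESPONSE = "postop_standing_sop"

#: Functional predictors only available with standing imaging (scenario B).
_STANDING_ONLY = ("standing_sop", "lla")

SCENARIO_COEFFS: Mapping[str, Mapping[str, float]] = {
    "A": {"intercept": 7.53, "age": -0.19, "supine_sop": 1.01},
    "B": {"intercept": -4.59, "lla": 0.09, "supine_sop": 0.31,
          "standing_sop": 0.61},
}
SCENARIO_NOISE_SD: Mapping[str, float] = {"A": 4.8, "B": 3.6}

#: (mean, sd, min, max) of truncated-normal marginals; cohort descriptives
#: where published, declared assumptions otherwise (ROM, LLA bounds).
DEFAULT_MARGINALS: Mapping[str, tuple[float, float, float, float]] = {
    "age": (62.7, 10.7, 34.0, 91.0),
    "height_male": (166.2, 7.6, 151.1, 181.8),
    "height_female": (154.4, 6.4, 140.0, 169.5),
    "weight_male": (69.3, 12.0, 51.7, 103.8),
    "weight_female": (55.0, 7.9, 35.9, 82.5),
    "supine_sop": (38.5, 8.3, 15.0, 57.3),
    "lla": (48.4, 10.0, 18.4, 78.4),
    "rom_flexion": (95.0, 15.0, 30.0, 135.0),
    "rom_extension": (5.0, 5.0, 0.0, 20.0),
    "rom_abduction": (20.0, 8.0, 0.0, 45.0),
    "rom_adduction": (15.0, 6.0, 0.0, 35.0),
    "rom_internal_rotation": (10.0, 8.0, 0.0, 40.0),
    "rom_external_rotation": (20.0, 8.0, 0.0, 45.0),
}

#: Standing SOP = supine SOP + N(mean, sd); keeps the published standing SD.
STANDING_DELTA = (-0.8, 5.2)
MALE_FRACTION = 29.0 / 196.0
FUSION_RATE = 0.08
MORPHO_CV = 0.05  # relative SD of the nuisance morphological marginals


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic cohort draw."""

    n: int
    seed: int = 0
    scenario: str = "B"
    noise_sd: float | None = None
    coefficients: Mapping[str, float] | None = None
    marginals: Mapping[str, tuple[float, float, float, float]] = \
        field(default_factory=lambda: dict(DEFAULT_MARGINALS))

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B"):
            raise ValueError(f"scenario must be 'A' or 'B', got {self.scenario!r}")
        if self.n < 10:
            raise ValueError("n must be at least 10")
        sd = self.resolved_noise_sd
        if not sd > 0:
            raise ValueError("noise_sd must be positive")

    @property
    def resolved_noise_sd(self) -> float:
        return SCENARIO_NOISE_SD[self.scenario] if self.noise_sd is None \
            else self.noise_sd

    @property
    def resolved_coefficients(self) -> Mapping[str, float]:
        return SCENARIO_COEFFS[self.scenario] if self.coefficients is None \
            else self.coefficients


def predictor_names(scenario: str) -> tuple[str, ...]:
    """The predictor columns of a scenario: 31 for A, 33 for B."""
    if scenario not in ("A", "B"):
        raise ValueError(f"scenario must be 'A' or 'B', got {scenario!r}")
    functional = FUNCTIONAL_PREDICTORS if scenario == "B" else \
        tuple(f for f in FUNCTIONAL_PREDICTORS if f not in _STANDING_ONLY)
    return BIOMETRIC_PREDICTORS + MORPHOLOGICAL_PREDICTORS + functional


def predictor_matrix(cohort: pd.DataFrame, scenario: str) -> pd.DataFrame:
    """The predictor block of a cohort table, in registry order."""
    return cohort.loc[:, list(predictor_names(scenario))]


def _calibrated_truncnorm(rng: np.random.Generator, mean: float, sd: float,
                          lo: float, hi: float, size: int) -> np.ndarray:
    """Truncated normal on [lo, hi] whose *truncated* mean equals ``mean``.

    Solves for the parent location; the configured sd is the parent scale.
    """
    if not lo < mean < hi:
        raise ValueError("mean must lie strictly inside the truncation bounds")

    def truncated_mean_minus_target(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    span = 10.0 * sd
    loc = brentq(truncated_mean_minus_target, mean - span, mean + span,
                 xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _template_morpho_means() -> dict[str, float]:
    return morphological_parameters(template_pelvis()).as_dict()


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Columns are the scenario's predictors (31 for A, 33 for B) followed by
    the response ``postop_standing_sop``. Identical configurations produce
    identical tables. Morphological and range-of-motion columns are nuisance
    predictors, drawn independently of the response.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    m = config.marginals

    sex = (rng.random(n) < MALE_FRACTION).astype(int)  # 1 = male
    age = _calibrated_truncnorm(rng, *m["age"], size=n)

    height = np.empty(n)
    weight = np.empty(n)
    n_male = int(sex.sum())
    height[sex == 1] = _calibrated_truncnorm(rng, *m["height_male"], size=n_male)
    height[sex == 0] = _calibrated_truncnorm(rng, *m["height_female"], size=n - n_male)
    weight[sex == 1] = _calibrated_truncnorm(rng, *m["weight_male"], size=n_male)
    weight[sex == 0] = _calibrated_truncnorm(rng, *m["weight_female"], size=n - n_male)
    bmi = weight / (height / 100.0) ** 2

    supine = _calibrated_truncnorm(rng, *m["supine_sop"], size=n)
    standing = supine + rng.normal(STANDING_DELTA[0], STANDING_DELTA[1], n)
    lla = _calibrated_truncnorm(rng, *m["lla"], size=n)
    fused = (rng.random(n) < FUSION_RATE).astype(int)

    cols: dict[str, np.ndarray] = {
        "sex": sex, "age": age, "height": height, "weight": weight, "bmi": bmi,
    }
    for name, mean in _template_morpho_means().items():
        cols[name] = rng.normal(mean, MORPHO_CV * abs(mean), n)
    cols["supine_sop"] = supine
    cols["standing_sop"] = standing
    cols["lla"] = lla
    cols["l5s1_fused"] = fused
    for rom in ("rom_flexion", "rom_extension", "rom_abduction",
                "rom_adduction", "rom_internal_rotation",
                "rom_external_rotation"):
        cols[rom] = _calibrated_truncnorm(rng, *m[rom], size=n)

    beta = config.resolved_coefficients
    linear = np.full(n, beta["intercept"], dtype=float)
    for name, b in beta.items():
        if name != "intercept":
            linear = linear + b * cols[name]
    response = linear + rng.normal(0.0, config.resolved_noise_sd, n)

    names = predictor_names(config.scenario)
    data = {name: cols[name] for name in names}
    data[RESPONSE] = response
    return pd.DataFrame(data)
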