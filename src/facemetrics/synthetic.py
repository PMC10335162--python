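"""Synthetic subject generator with known millimeter ground truth.

Builds landmark sets whose generating geometry (facial height, widths,
thirds, canthal tilt, brow shape, ...) is sampled from configurable
Gaussian marginals, then applies a random in-plane rotation and pixel scale.
The pre-rotation, pre-scale values are recorded as ground truth, so every
downstream stage can be validated without any real photographs.  Rasterized
eye crops with known iris center/diameter exercise the segmentation path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dataclass_fields, replace

import numpy as np
import pandas as pd

from .calibration import CalibrationContext, make_calibration
from .errors import GeometryError, ParameterError
from .landmarks import LandmarkSet, Point2D
from .measures import MEASUREMENT_COLUMNS

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "EyeImage",
    "female_spec",
    "male_spec",
    "sample_cohort",
    "render_eye",
    "ground_truth_table",
    "exact_calibration",
]

Param = tuple[float, float]  # (mean, sd)


@dataclass
class CohortSpec:
    """Generating distributions for one cohort, as (mean, sd) marginals.

    Lengths are cm, angles degrees, proportions unitless.  ``scale_range``
    (px/mm) and ``rotation_range`` (degrees, positive clockwise) are uniform
    ranges.  When ``bigonial_from_ratio`` is set the bigonial width is
    derived from the sampled facial height and ``ratio_fh_bigonial`` instead
    of its own marginal, pinning the per-subject ratio distribution.
    """

    group: str = "F"
    facial_height_cm: Param = (17.94, 1.14)
    bizygomatic_width_cm: Param = (13.05, 0.75)
    bigonial_width_cm: Param = (11.13, 0.70)
    nose_height_cm: Param = (3.82, 0.34)
    alar_width_cm: Param = (3.21, 0.37)
    interpupillary_distance_cm: Param = (6.17, 0.38)
    canthal_tilt_deg: Param = (8.50, 2.10)
    medial_brow_length_cm: Param = (3.04, 0.27)
    lateral_brow_length_cm: Param = (1.62, 0.30)
    brow_angle_1_deg: Param = (12.43, 8.68)
    brow_angle_3_deg: Param = (32.45, 19.78)
    upper_third_prop: Param = (0.324, 0.023)
    middle_third_prop: Param = (0.344, 0.020)
    lower_third_prop: Param = (0.332, 0.017)
    left_vertical_third_prop: Param = (0.311, 0.012)
    middle_vertical_third_prop: Param = (0.374, 0.017)
    right_vertical_third_prop: Param = (0.315, 0.010)
    ratio_fh_bigonial: Param = (1.613, 0.063)
    wtw_mm: Param = (11.71, 0.42)
    scale_range: tuple[float, float] = (5.0, 15.0)
    rotation_range: tuple[float, float] = (-10.0, 10.0)
    bigonial_from_ratio: bool = False
    landmark_noise_px: float = 0.0
    scleral_show_mm: float = -0.5  # lid margin 0.5 mm superior to the iris border
    brow_height_mm: float = 15.0  # apex elevation above the exocanthion line

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple) and len(v) == 2 and f.name.endswith(("_cm", "_deg", "_prop", "_mm", "ratio_fh_bigonial")):
                if v[1] < 0:
                    raise ParameterError(f"{f.name}: SD must be >= 0, got {v[1]}")
        if self.scale_range[0] <= 0 or self.scale_range[1] <= 0:
            raise ParameterError(f"scale_range must be positive, got {self.scale_range}")
        h_sum = (
            self.upper_third_prop[0]
            + self.middle_third_prop[0]
            + self.lower_third_prop[0]
        )
        if abs(h_sum - 1.0) > 0.01:
            raise ParameterError(
                f"horizontal third proportion means must sum to 1 +/- 0.01, got {h_sum}"
            )
        if self.landmark_noise_px < 0:
            raise ParameterError("landmark_noise_px must be >= 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSpec":
        kwargs = {}
        valid = {f.name for f in dataclass_fields(cls)}
        for k, v in data.items():
            if k not in valid:
                raise ParameterError(f"unknown cohort spec key {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def female_spec(**overrides) -> CohortSpec:
    """Cohort spec parameterized with the female group summary statistics."""
    return replace(CohortSpec(group="F"), **overrides) if overrides else CohortSpec(group="F")


def male_spec(**overrides) -> CohortSpec:
    """Cohort spec parameterized with the male group summary statistics."""
    spec = CohortSpec(
        group="M",
        facial_height_cm=(19.29, 1.24),
        bizygomatic_width_cm=(13.90, 0.80),
        bigonial_width_cm=(12.34, 0.77),
        nose_height_cm=(4.17, 0.38),
        alar_width_cm=(3.60, 0.37),
        interpupillary_distance_cm=(6.38, 0.33),
        canthal_tilt_deg=(6.51, 2.67),
        medial_brow_length_cm=(3.39, 0.43),
        lateral_brow_length_cm=(1.71, 0.29),
        brow_angle_1_deg=(9.90, 5.42),
        brow_angle_3_deg=(38.67, 10.08),
        upper_third_prop=(0.308, 0.023),
        middle_third_prop=(0.329, 0.017),
        lower_third_prop=(0.363, 0.022),
        left_vertical_third_prop=(0.314, 0.013),
        middle_vertical_third_prop=(0.371, 0.020),
        right_vertical_third_prop=(0.315, 0.013),
        ratio_fh_bigonial=(1.566, 0.085),
    )
    return replace(spec, **overrides) if overrides else spec


@dataclass
class EyeImage:
    """Grayscale eye crop with ground-truth iris geometry."""

    image: np.ndarray
    center: Point2D
    diameter_px: float
    noise_sd: float = 0.0
    endocanthion: Point2D | None = None
    exocanthion: Point2D | None = None


@dataclass
class SyntheticSubject:
    subject_id: str
    landmarks: LandmarkSet
    truth: dict[str, float]
    scale_px_per_mm: float
    rotation_deg: float
    wtw_mm: float
    group: str = ""
    eye_left: EyeImage | None = None
    eye_right: EyeImage | None = None

    @property
    def wtw_px(self) -> float:
        return self.wtw_mm * self.scale_px_per_mm


def exact_calibration(subject: SyntheticSubject) -> CalibrationContext:
    """Calibration using the subject's own true WTW geometry (zero scale error)."""
    return make_calibration(subject.wtw_px, wtw_reference_mm=subject.wtw_mm)


def _gauss(rng: np.random.Generator, param: Param, positive: bool = True) -> float:
    v = param[0] + param[1] * rng.standard_normal()
    if positive and param[0] > 0:
        v = max(v, 0.05 * param[0])
    return float(v)


def _composition(rng: np.random.Generator, params: tuple[Param, Param, Param]) -> np.ndarray:
    # Logistic-normal: perturb log-means with delta-method scaled noise and
    # renormalize through a softmax so the triplet sums to 1 exactly.
    means = np.array([p[0] for p in params], dtype=float)
    sds = np.array([p[1] for p in params], dtype=float)
    if np.any(means <= 0):
        raise ParameterError("composition means must be positive")
    z = np.log(means) + (sds / means) * rng.standard_normal(3)
    e = np.exp(z - z.max())
    return e / e.sum()


def render_eye(
    center: Point2D,
    diameter_px: float,
    image_size: tuple[int, int],
    noise_sd: float = 0.0,
    seed: int | None = None,
    iris_level: float = 0.15,
    sclera_level: float = 0.85,
) -> EyeImage:
    """Render a dark iris disc on a bright scleral background.

    The disc edge is anti-aliased via linear coverage; additive Gaussian
    noise of ``noise_sd`` (same units as the intensity levels) is applied
    when requested.  Deterministic for a fixed seed.
    """
    if diameter_px < 8:
        raise ParameterError(f"iris diameter must be >= 8 px, got {diameter_px}")
    h, w = int(image_size[0]), int(image_size[1])
    r = diameter_px / 2.0
    if (center.x - r < 0 or center.x + r > w - 1 or center.y - r < 0 or center.y + r > h - 1):
        raise GeometryError(
            f"iris (center {center}, diameter {diameter_px}) exceeds frame {(h, w)}"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - center.x, yy - center.y)
    coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)
    img = sclera_level - (sclera_level - iris_level) * coverage
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + noise_sd * rng.standard_normal(img.shape)
    return EyeImage(
        image=img, center=center, diameter_px=float(diameter_px), noise_sd=noise_sd
    )


def _render_subject_eye(
    wtw_px: float, noise_sd: float, seed: int
) -> EyeImage:
    frame = int(math.ceil(2.2 * wtw_px))
    c = Point2D(frame / 2.0, frame / 2.0)
    eye = render_eye(c, wtw_px, (frame, frame), noise_sd=noise_sd, seed=seed)
    # Pilot points for the canthus-seeded segmentation: one iris diameter
    # lateral of center, giving an initial radius of half the true radius.
    eye.endocanthion = Point2D(c.x - wtw_px, c.y)
    eye.exocanthion = Point2D(c.x + wtw_px, c.y)
    return eye


def _build_subject(
    spec: CohortSpec, rng: np.random.Generator, subject_id: str, render_eyes: bool,
    eye_noise_sd: float,
) -> SyntheticSubject:
    fh_cm = _gauss(rng, spec.facial_height_cm)
    bizyg_cm = _gauss(rng, spec.bizygomatic_width_cm)
    ratio_sample = _gauss(rng, spec.ratio_fh_bigonial)
    if spec.bigonial_from_ratio:
        bigon_cm = fh_cm / ratio_sample
    else:
        bigon_cm = _gauss(rng, spec.bigonial_width_cm)
    nose_cm = _gauss(rng, spec.nose_height_cm)
    alar_cm = _gauss(rng, spec.alar_width_cm)
    ipd_cm = _gauss(rng, spec.interpupillary_distance_cm)
    tilt = _gauss(rng, spec.canthal_tilt_deg, positive=False)
    med_brow_cm = _gauss(rng, spec.medial_brow_length_cm)
    lat_brow_cm = _gauss(rng, spec.lateral_brow_length_cm)
    a1 = float(np.clip(_gauss(rng, spec.brow_angle_1_deg, positive=False), -80.0, 80.0))
    a3 = float(np.clip(_gauss(rng, spec.brow_angle_3_deg, positive=False), -80.0, 80.0))
    h_props = _composition(
        rng, (spec.upper_third_prop, spec.middle_third_prop, spec.lower_third_prop)
    )
    v_props = _composition(
        rng,
        (
            spec.left_vertical_third_prop,
            spec.middle_vertical_third_prop,
            spec.right_vertical_third_prop,
        ),
    )
    wtw_mm = _gauss(rng, spec.wtw_mm)
    scale = float(rng.uniform(*spec.scale_range))
    theta = float(rng.uniform(*spec.rotation_range))

    # --- millimeter geometry, midline at x = 0, y increasing downward -----
    fh = fh_cm * 10.0
    up, mid = float(h_props[0]), float(h_props[1])
    lv, mv = float(v_props[0]), float(v_props[1])
    rv = float(v_props[2])
    pts: dict[str, tuple[float, float]] = {}
    y_gla = up * fh
    y_sub = (up + mid) * fh
    pts["trichion"] = (0.0, 0.0)
    pts["glabella"] = (0.0, y_gla)
    pts["subnasale"] = (0.0, y_sub)
    pts["menton"] = (0.0, fh)
    y_nas = y_gla + 0.15 * (y_sub - y_gla)
    pts["nasion"] = (0.0, y_nas)
    pts["pronasale"] = (0.0, y_nas + nose_cm * 10.0)

    # canthi: exocanthions share a row so the vertical thirds project onto x
    span = (ipd_cm * 10.0) / (1.0 - 0.5 * (lv + rv))
    y_exo = y_gla + 0.40 * (y_sub - y_gla)
    tan_t = math.tan(math.radians(tilt))
    x_exo_r = -span / 2.0
    pts["exocanthion_R"] = (x_exo_r, y_exo)
    pts["endocanthion_R"] = (x_exo_r + lv * span, y_exo + tan_t * lv * span)
    pts["exocanthion_L"] = (span / 2.0, y_exo)
    pts["endocanthion_L"] = (span / 2.0 - rv * span, y_exo + tan_t * rv * span)

    ipd = ipd_cm * 10.0
    y_pupil = y_exo + 0.5 * tan_t * 0.5 * (lv + rv) * span
    pts["pupil_R"] = (-ipd / 2.0, y_pupil)
    pts["pupil_L"] = (ipd / 2.0, y_pupil)

    # inferior iris border and lower lid margin (no scleral show by default)
    y_iris_inf = y_pupil + wtw_mm / 2.0
    for side, xp in (("R", -ipd / 2.0), ("L", ipd / 2.0)):
        pts[f"iris_inferior_{side}"] = (xp, y_iris_inf)
        pts[f"lowerlid_margin_{side}"] = (xp, y_iris_inf + spec.scleral_show_mm)

    # brows: apex above each pupil, limbs descending medially/laterally
    y_brow = y_exo - spec.brow_height_mm
    med, lat = med_brow_cm * 10.0, lat_brow_cm * 10.0
    r1, r3 = math.radians(a1), math.radians(a3)
    pts["brow_apex_L"] = (ipd / 2.0, y_brow)
    pts["brow_medial_L"] = (ipd / 2.0 - med * math.cos(r1), y_brow + med * math.sin(r1))
    pts["brow_lateral_L"] = (ipd / 2.0 + lat * math.cos(r3), y_brow + lat * math.sin(r3))
    pts["brow_apex_R"] = (-ipd / 2.0, y_brow)
    pts["brow_medial_R"] = (-ipd / 2.0 + med * math.cos(r1), y_brow + med * math.sin(r1))
    pts["brow_lateral_R"] = (-ipd / 2.0 - lat * math.cos(r3), y_brow + lat * math.sin(r3))

    pts["zygion_R"] = (-bizyg_cm * 5.0, 0.5 * (y_exo + y_sub))
    pts["zygion_L"] = (bizyg_cm * 5.0, 0.5 * (y_exo + y_sub))
    y_gon = y_sub + 0.75 * (fh - y_sub)
    pts["gonion_R"] = (-bigon_cm * 5.0, y_gon)
    pts["gonion_L"] = (bigon_cm * 5.0, y_gon)
    pts["alare_R"] = (-alar_cm * 5.0, y_sub)
    pts["alare_L"] = (alar_cm * 5.0, y_sub)

    # --- ground truth from the sampled parameters -------------------------
    def _d(a: str, b: str) -> float:  # analytic mm distance in construction frame
        return math.hypot(pts[a][0] - pts[b][0], pts[a][1] - pts[b][1])

    cos_t = math.cos(math.radians(tilt))
    truth: dict[str, float] = {
        "facial_height_cm": fh_cm,
        "bizygomatic_width_cm": bizyg_cm,
        "bigonial_width_cm": bigon_cm,
        "nose_height_cm": nose_cm,
        "alar_width_cm": alar_cm,
        "interpupillary_distance_cm": ipd_cm,
        "palpebral_fissure_length_cm": (span * 0.5 * (lv + rv) / cos_t) / 10.0,
        "canthal_tilt_deg": tilt,
        "facial_rotation_deg": theta,
        "upper_third_cm": up * fh_cm,
        "middle_third_cm": mid * fh_cm,
        "lower_third_cm": (1.0 - up - mid) * fh_cm,
        "upper_third_prop": up,
        "middle_third_prop": mid,
        "lower_third_prop": 1.0 - up - mid,
        "left_vertical_third_prop": lv,
        "middle_vertical_third_prop": mv,
        "right_vertical_third_prop": 1.0 - lv - mv,
        "brow_angle_1_deg": abs(a1),
        "brow_angle_2_deg": 180.0 - abs(a1 + a3),
        "brow_angle_3_deg": abs(a3),
        "medial_brow_length_cm": med_brow_cm,
        "lateral_brow_length_cm": lat_brow_cm,
        "total_brow_length_cm": med_brow_cm + lat_brow_cm,
        "medial_canthus_to_medial_brow_cm": 0.5
        * (_d("endocanthion_L", "brow_medial_L") + _d("endocanthion_R", "brow_medial_R"))
        / 10.0,
        "lateral_canthus_to_lateral_brow_cm": 0.5
        * (_d("exocanthion_L", "brow_lateral_L") + _d("exocanthion_R", "brow_lateral_R"))
        / 10.0,
        "scleral_show_flag": float(spec.scleral_show_mm > 0),
        "scleral_show_signed_mm": spec.scleral_show_mm,
        "ratio_fh_bigonial": fh_cm / bigon_cm,
        "ratio_fh_bizygomatic": fh_cm / bizyg_cm,
        "ratio_bizygomatic_bigonial": bizyg_cm / bigon_cm,
    }

    # --- rotate (clockwise-positive), scale, translate into pixel space ---
    c, s = math.cos(math.radians(theta)), math.sin(math.radians(theta))
    xy = np.array(list(pts.values()), dtype=float)
    rotated = np.column_stack([xy[:, 0] * c + xy[:, 1] * s, -xy[:, 0] * s + xy[:, 1] * c])
    px = rotated * scale
    px -= px.min(axis=0) - 10.0  # keep coordinates positive with a margin
    if spec.landmark_noise_px > 0:
        px = px + spec.landmark_noise_px * rng.standard_normal(px.shape)

    ls = LandmarkSet(subject_id=subject_id)
    for name, (x, y) in zip(pts.keys(), px):
        ls.add(name, float(x), float(y))

    subject = SyntheticSubject(
        subject_id=subject_id,
        landmarks=ls,
        truth=truth,
        scale_px_per_mm=scale,
        rotation_deg=theta,
        wtw_mm=wtw_mm,
        group=spec.group,
    )
    if render_eyes:
        wtw_px = wtw_mm * scale
        seeds = rng.integers(0, 2**31 - 1, size=2)
        subject.eye_left = _render_subject_eye(wtw_px, eye_noise_sd, int(seeds[0]))
        subject.eye_right = _render_subject_eye(wtw_px, eye_noise_sd, int(seeds[1]))
    return subject


def sample_cohort(
    spec: CohortSpec,
    n: int,
    seed: int,
    render_eyes: bool = True,
    eye_noise_sd: float = 0.0,
    id_prefix: str | None = None,
) -> list[SyntheticSubject]:
    """Draw ``n`` synthetic subjects; deterministic for a fixed seed."""
    if n < 1:
        raise ParameterError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else spec.group
    return [
        _build_subject(spec, rng, f"{prefix}{i + 1:03d}", render_eyes, eye_noise_sd)
        for i in range(n)
    ]


def ground_truth_table(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    """One row per subject with every ground-truth measurement column."""
    if not subjects:
        raise ParameterError("ground_truth_table needs at least one subject")
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id}
        row.update(s.truth)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[[c for c in MEASUREMENT_COLUMNS if c in df.columns]]
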