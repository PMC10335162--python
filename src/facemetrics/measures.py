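"""Per-subject facial measurement battery on calibrated landmark sets.

All angles follow the image convention (y increasing downward).  Facial
rotation is positive for a visually clockwise in-plane rotation (chin
deviating toward the viewer's right); canthal tilt is positive when the
exocanthion sits superior to the endocanthion.  Bilateral quantities are
reported as the mean of the subject's left and right sides.  Vertical-third
proportions are labeled in the viewer's frame (the "left" third spans the
subject's right eye), matching conventional frontal-photograph reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dataclass_fields

import numpy as np

from .calibration import CalibrationContext
from .errors import GeometryError, ParameterError, SchemaError
from .landmarks import LandmarkSet, Point2D, validate_core

__all__ = [
    "MeasurementRecord",
    "MEASUREMENT_COLUMNS",
    "facial_rotation",
    "canthal_tilt",
    "midline_distance",
    "bilateral_distance",
    "horizontal_thirds",
    "vertical_thirds",
    "brow_metrics",
    "scleral_show",
    "facial_ratios",
    "measure_subject",
]


@dataclass
class MeasurementRecord:
    """Full per-subject battery: lengths (cm), angles (deg), proportions, ratios."""

    subject_id: str = ""
    facial_height_cm: float = math.nan
    bizygomatic_width_cm: float = math.nan
    bigonial_width_cm: float = math.nan
    nose_height_cm: float = math.nan
    alar_width_cm: float = math.nan
    interpupillary_distance_cm: float = math.nan
    palpebral_fissure_length_cm: float = math.nan
    canthal_tilt_deg: float = math.nan
    facial_rotation_deg: float = math.nan
    upper_third_cm: float = math.nan
    middle_third_cm: float = math.nan
    lower_third_cm: float = math.nan
    upper_third_prop: float = math.nan
    middle_third_prop: float = math.nan
    lower_third_prop: float = math.nan
    left_vertical_third_prop: float = math.nan
    middle_vertical_third_prop: float = math.nan
    right_vertical_third_prop: float = math.nan
    brow_angle_1_deg: float = math.nan
    brow_angle_2_deg: float = math.nan
    brow_angle_3_deg: float = math.nan
    medial_brow_length_cm: float = math.nan
    lateral_brow_length_cm: float = math.nan
    total_brow_length_cm: float = math.nan
    medial_canthus_to_medial_brow_cm: float = math.nan
    lateral_canthus_to_lateral_brow_cm: float = math.nan
    scleral_show_flag: bool = False
    scleral_show_signed_mm: float = math.nan
    ratio_fh_bigonial: float = math.nan
    ratio_fh_bizygomatic: float = math.nan
    ratio_bizygomatic_bigonial: float = math.nan
    #: per-side values kept for debugging; not part of the tabular schema
    per_side: dict = field(default_factory=dict, repr=False, compare=False)

    def to_dict(self) -> dict:
        out = {}
        for f in dataclass_fields(self):
            if f.name == "per_side":
                continue
            v = getattr(self, f.name)
            out[f.name] = int(v) if f.name == "scleral_show_flag" else v
        return out


MEASUREMENT_COLUMNS: tuple[str, ...] = tuple(
    f.name for f in dataclass_fields(MeasurementRecord) if f.name != "per_side"
)


def _vec(a: Point2D, b: Point2D) -> np.ndarray:
    return np.array([b.x - a.x, b.y - a.y], dtype=float)


def facial_rotation(ls: LandmarkSet) -> float:
    """Signed in-plane head rotation (degrees) from the glabella-menton axis.

    Zero for a vertical median line; positive (clockwise) when the chin
    deviates toward the viewer's right.  Wrapped into (-90, 90].
    """
    g, m = ls["glabella"], ls["menton"]
    v = _vec(g, m)
    if np.hypot(*v) == 0:
        raise GeometryError("glabella and menton coincide; no median axis")
    ang = math.degrees(math.atan2(v[0], v[1]))
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return ang


def _raw_tilt(endo: Point2D, exo: Point2D, side: str) -> float:
    # Angle above horizontal of the lateral-pointing (endo -> exo) vector.
    v = _vec(endo, exo)
    if np.hypot(*v) == 0:
        raise GeometryError(f"coincident canthi on side {side}")
    if side == "R":  # lateral is the viewer-left direction on the subject's right
        return math.degrees(math.atan2(-v[1], -v[0]))
    return math.degrees(math.atan2(-v[1], v[0]))


def canthal_tilt(ls: LandmarkSet, rotation: float = 0.0) -> float:
    """Rotation-corrected canthal tilt (degrees), averaged over both eyes.

    A clockwise face rotation adds to the subject's-left raw tilt and
    subtracts from the subject's-right raw tilt, so the correction is applied
    with opposite signs per side; the L/R mean is then invariant under rigid
    rotation of the whole face.
    """
    raw_l = _raw_tilt(ls["endocanthion_L"], ls["exocanthion_L"], "L")
    raw_r = _raw_tilt(ls["endocanthion_R"], ls["exocanthion_R"], "R")
    corr_l = raw_l - rotation
    corr_r = raw_r + rotation
    return 0.5 * (corr_l + corr_r)


def midline_distance(
    ls: LandmarkSet, name_a: str, name_b: str, calib: CalibrationContext
) -> float:
    """Calibrated Euclidean distance between two named landmarks, in cm."""
    return calib.px_to_cm(ls[name_a].distance(ls[name_b]))


def bilateral_distance(
    ls: LandmarkSet, name_pair: tuple[str, str], calib: CalibrationContext
) -> float:
    """L/R mean of the calibrated distance between a pair of landmark stems.

    ``name_pair`` holds base names; ``_L``/``_R`` suffixes are appended per
    side, e.g. ``("endocanthion", "exocanthion")`` yields the mean palpebral
    fissure length.
    """
    a, b = name_pair
    d_l = midline_distance(ls, f"{a}_L", f"{b}_L", calib)
    d_r = midline_distance(ls, f"{a}_R", f"{b}_R", calib)
    return 0.5 * (d_l + d_r)


def _projected(ls: LandmarkSet, names: list[str], axis_a: str, axis_b: str) -> np.ndarray:
    u = _vec(ls[axis_a], ls[axis_b])
    norm = np.hypot(*u)
    if norm == 0:
        raise GeometryError(f"axis landmarks {axis_a}/{axis_b} coincide")
    u /= norm
    origin = ls[axis_a]
    return np.array([float(np.dot(_vec(origin, ls[n]), u)) for n in names])


def horizontal_thirds(
    ls: LandmarkSet, calib: CalibrationContext
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Upper/middle/lower facial thirds: lengths (cm) and proportions.

    The four midline landmarks are projected onto the median (glabella to
    menton) axis; segment lengths are successive projected distances and
    proportions are normalized by their sum, so the three proportions sum to
    1 exactly.
    """
    t = _projected(ls, ["trichion", "glabella", "subnasale", "menton"], "glabella", "menton")
    if not (t[0] < t[1] < t[2] < t[3]):
        raise GeometryError(
            "midline landmarks out of order along the median axis "
            f"(projections {t.round(3).tolist()})"
        )
    segs = np.diff(t)
    total = segs.sum()
    p_up = segs[0] / total
    p_mid = segs[1] / total
    # 1 - (p_up + p_mid) is exact for sums in [0.5, 2] (Sterbenz), so the
    # three proportions re-add to exactly 1.0
    p_low = 1.0 - (p_up + p_mid)
    cm = tuple(calib.px_to_cm(s) for s in segs)
    return cm, (float(p_up), float(p_mid), float(p_low))


def vertical_thirds(ls: LandmarkSet) -> tuple[float, float, float]:
    """Viewer-frame left/middle/right thirds of the exocanthion-to-exocanthion span.

    The four canthi are projected onto the line through the two exocanthions;
    proportions are successive projected segments over the total and sum to 1
    exactly.  The first ("left") third runs from the subject's-right
    exocanthion to the subject's-right endocanthion.
    """
    names = ["exocanthion_R", "endocanthion_R", "endocanthion_L", "exocanthion_L"]
    t = _projected(ls, names, "exocanthion_R", "exocanthion_L")
    if not (t[0] < t[1] < t[2] < t[3]):
        raise GeometryError(
            f"crossed canthi ordering (projections {t.round(3).tolist()})"
        )
    segs = np.diff(t)
    total = segs.sum()
    left = segs[0] / total
    middle = segs[1] / total
    right = 1.0 - (left + middle)
    return (float(left), float(middle), float(right))


def _angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.hypot(*v1), np.hypot(*v2)
    if n1 == 0 or n2 == 0:
        raise GeometryError("zero-length vector in angle computation")
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(c))


def brow_metrics(
    ls: LandmarkSet,
    calib: CalibrationContext,
    rotation: float = 0.0,
    canthus_brow_mode: str = "euclidean",
) -> dict:
    """Brow angles (vs. the interpupillary line), brow lengths, canthus gaps.

    Angle 1 sits at the apex between the ray to the medial brow point and the
    medially-directed ray parallel to the interpupillary (IP) line; angle 2
    is the included medial-apex-lateral angle; angle 3 mirrors angle 1 on the
    lateral side.  Measuring against the IP line makes the angles invariant
    to head rotation, so ``rotation`` is accepted only for interface symmetry.
    ``canthus_brow_mode`` selects Euclidean or rotation-corrected vertical
    canthus-to-brow distances.
    """
    if canthus_brow_mode not in ("euclidean", "vertical"):
        raise ParameterError(f"unknown canthus_brow_mode {canthus_brow_mode!r}")
    ip = _vec(ls["pupil_R"], ls["pupil_L"])  # points toward the subject's left
    if np.hypot(*ip) == 0:
        raise GeometryError("coincident pupils; no interpupillary line")
    ip = ip / np.hypot(*ip)

    angles = {1: [], 2: [], 3: []}
    med_len, lat_len = [], []
    canthus_med, canthus_lat = [], []
    theta = math.radians(rotation)
    for side in ("L", "R"):
        md, ap, lt = (ls[f"brow_{k}_{side}"] for k in ("medial", "apex", "lateral"))
        v_med, v_lat = _vec(ap, md), _vec(ap, lt)
        if np.hypot(*v_med) == 0 or np.hypot(*v_lat) == 0:
            raise GeometryError(f"coincident brow points on side {side}")
        medial_dir = -ip if side == "L" else ip
        angles[1].append(_angle_between(v_med, medial_dir))
        angles[2].append(_angle_between(v_med, v_lat))
        angles[3].append(_angle_between(v_lat, -medial_dir))
        med_len.append(midline_distance(ls, f"brow_medial_{side}", f"brow_apex_{side}", calib))
        lat_len.append(midline_distance(ls, f"brow_apex_{side}", f"brow_lateral_{side}", calib))
        if canthus_brow_mode == "euclidean":
            canthus_med.append(
                midline_distance(ls, f"endocanthion_{side}", f"brow_medial_{side}", calib)
            )
            canthus_lat.append(
                midline_distance(ls, f"exocanthion_{side}", f"brow_lateral_{side}", calib)
            )
        else:
            for (a, b), sink in (
                ((f"endocanthion_{side}", f"brow_medial_{side}"), canthus_med),
                ((f"exocanthion_{side}", f"brow_lateral_{side}"), canthus_lat),
            ):
                g = _vec(ls[b], ls[a])
                # undo the clockwise face rotation, keep the vertical component
                gy = g[0] * math.sin(theta) + g[1] * math.cos(theta)
                sink.append(calib.px_to_cm(abs(gy)))

    med = float(np.mean(med_len))
    lat = float(np.mean(lat_len))
    return {
        "brow_angle_1_deg": float(np.mean(angles[1])),
        "brow_angle_2_deg": float(np.mean(angles[2])),
        "brow_angle_3_deg": float(np.mean(angles[3])),
        "medial_brow_length_cm": med,
        "lateral_brow_length_cm": lat,
        "total_brow_length_cm": med + lat,
        "medial_canthus_to_medial_brow_cm": float(np.mean(canthus_med)),
        "lateral_canthus_to_lateral_brow_cm": float(np.mean(canthus_lat)),
    }


def scleral_show(
    ls: LandmarkSet, calib: CalibrationContext, rotation: float = 0.0
) -> tuple[bool, float, dict[str, float]]:
    """Signed inferior-iris-to-lower-lid gap per eye (mm) and combined flag.

    Positive gap means the inferior iris border sits superior to the lower
    lid margin (visible sclera).  The gap is evaluated along the
    rotation-corrected vertical.  Returns ``(flag, combined_mm, per_eye)``
    where the flag is true if either eye shows a positive gap and
    ``combined_mm`` is the mean signed gap.
    """
    theta = math.radians(rotation)
    per_eye: dict[str, float] = {}
    for side in ("L", "R"):
        iris = ls[f"iris_inferior_{side}"]
        lid = ls[f"lowerlid_margin_{side}"]
        g = _vec(iris, lid)
        gy = g[0] * math.sin(theta) + g[1] * math.cos(theta)  # unrotated Δy
        per_eye[side] = calib.px_to_mm(gy)
    combined = 0.5 * (per_eye["L"] + per_eye["R"])
    flag = any(v > 0 for v in per_eye.values())
    return flag, combined, per_eye


def facial_ratios(rec: MeasurementRecord) -> tuple[float, float, float]:
    """(facial height / bigonial, facial height / bizygomatic, bizygomatic / bigonial)."""
    fh = rec.facial_height_cm
    bg = rec.bigonial_width_cm
    bz = rec.bizygomatic_width_cm
    if bg <= 0 or bz <= 0:
        raise ParameterError(f"ratio denominators must be > 0 (bigonial {bg}, bizygomatic {bz})")
    return (fh / bg, fh / bz, bz / bg)


def measure_subject(
    ls: LandmarkSet,
    calib: CalibrationContext,
    canthus_brow_mode: str = "euclidean",
) -> MeasurementRecord:
    """Compute the full measurement battery for one calibrated landmark set."""
    missing = validate_core(ls)
    if missing:
        raise SchemaError(f"subject {ls.subject_id!r}: missing core landmarks {missing}")

    try:
        rot = facial_rotation(ls)
        rec = MeasurementRecord(subject_id=ls.subject_id, facial_rotation_deg=rot)
        rec.facial_height_cm = midline_distance(ls, "trichion", "menton", calib)
        rec.bizygomatic_width_cm = midline_distance(ls, "zygion_L", "zygion_R", calib)
        rec.bigonial_width_cm = midline_distance(ls, "gonion_L", "gonion_R", calib)
        rec.nose_height_cm = midline_distance(ls, "nasion", "pronasale", calib)
        rec.alar_width_cm = midline_distance(ls, "alare_L", "alare_R", calib)
        rec.interpupillary_distance_cm = midline_distance(ls, "pupil_L", "pupil_R", calib)
        rec.palpebral_fissure_length_cm = bilateral_distance(
            ls, ("endocanthion", "exocanthion"), calib
        )
        rec.canthal_tilt_deg = canthal_tilt(ls, rot)

        cm, props = horizontal_thirds(ls, calib)
        rec.upper_third_cm, rec.middle_third_cm, rec.lower_third_cm = cm
        rec.upper_third_prop, rec.middle_third_prop, rec.lower_third_prop = props
        (
            rec.left_vertical_third_prop,
            rec.middle_vertical_third_prop,
            rec.right_vertical_third_prop,
        ) = vertical_thirds(ls)

        for k, v in brow_metrics(ls, calib, rot, canthus_brow_mode).items():
            setattr(rec, k, v)

        flag, combined, per_eye = scleral_show(ls, calib, rot)
        rec.scleral_show_flag = flag
        rec.scleral_show_signed_mm = combined
        rec.per_side["scleral_show_mm"] = per_eye

        (
            rec.ratio_fh_bigonial,
            rec.ratio_fh_bizygomatic,
            rec.ratio_bizygomatic_bigonial,
        ) = facial_ratios(rec)
    except (GeometryError, ParameterError) as exc:
        raise type(exc)(f"subject {ls.subject_id!r}: {exc}") from exc
    return rec
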