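import math

import numpy as np
import pytest

from conftest import rotate_landmarks, simple_eyes, zero_sd
from facemetrics import (
    LandmarkSet,
    canthal_tilt,
    facial_rotation,
    horizontal_thirds,
    make_calibration,
    measure_subject,
    vertical_thirds,
)
from facemetrics.errors import GeometryError, ParameterError, SchemaError
from facemetrics.measures import (
    MeasurementRecord,
    bilateral_distance,
    brow_metrics,
    facial_ratios,
    midline_distance,
    scleral_show,
)
from facemetrics.synthetic import exact_calibration, female_spec, sample_cohort


class TestFacialRotation:
    def test_vertical_median_line(self):
        ls = LandmarkSet()
        ls.add("glabella", 100, 50)
        ls.add("menton", 100, 250)
        assert facial_rotation(ls) == 0.0

    def test_clockwise_positive(self):
        ls = LandmarkSet()
        ls.add("glabella", 100, 50)
        ls.add("menton", 120, 250)  # chin toward viewer's right
        assert facial_rotation(ls) == pytest.approx(math.degrees(math.atan2(20, 200)), abs=1e-9)
        assert facial_rotation(ls) == pytest.approx(5.71, abs=0.005)

    @pytest.mark.parametrize("theta", [-30.0, -5.0, 3.0, 12.5, 45.0])
    def test_rotation_equivariance(self, theta):
        ls = LandmarkSet()
        ls.add("glabella", 100, 50)
        ls.add("menton", 100, 250)
        rotated = rotate_landmarks(ls, theta, center=(100, 150))
        assert facial_rotation(rotated) == pytest.approx(theta, abs=1e-9)

    def test_coincident_points_rejected(self):
        ls = LandmarkSet()
        ls.add("glabella", 5, 5)
        ls.add("menton", 5, 5)
        with pytest.raises(GeometryError):
            facial_rotation(ls)


class TestCanthalTilt:
    def test_one_px_over_ten(self):
        ls = LandmarkSet()
        # exocanthion one px superior over 10 px lateral, both eyes
        ls.add("endocanthion_L", 0, 0)
        ls.add("exocanthion_L", 10, -1)
        ls.add("endocanthion_R", -20, 0)
        ls.add("exocanthion_R", -30, -1)
        expected = math.degrees(math.atan(1 / 10))
        assert canthal_tilt(ls, 0.0) == pytest.approx(expected, abs=1e-9)
        assert canthal_tilt(ls, 0.0) == pytest.approx(5.71, abs=0.005)

    @pytest.mark.parametrize("theta", [-10.0, -3.0, 4.0, 9.0])
    def test_rigid_rotation_invariance_at_zero_tilt(self, theta):
        ls = simple_eyes(tilt_px=0.0)
        rotated = rotate_landmarks(ls, theta, center=(700, 900))
        assert canthal_tilt(rotated, theta) == pytest.approx(0.0, abs=1e-9)

    def test_generator_tilt_recovered_under_rotation(self):
        spec = zero_sd(female_spec(), canthal_tilt_deg=(8.50, 0.0),
                       rotation_range=(7.0, 7.0))
        subj = sample_cohort(spec, 1, seed=3, render_eyes=False)[0]
        rot = facial_rotation(subj.landmarks)
        assert rot == pytest.approx(7.0, abs=1e-9)
        assert canthal_tilt(subj.landmarks, rot) == pytest.approx(8.50, abs=1e-6)

    def test_missing_canthus_is_schema_error(self):
        ls = LandmarkSet()
        ls.add("endocanthion_L", 0, 0)
        with pytest.raises(SchemaError):
            canthal_tilt(ls, 0.0)


class TestDistances:
    def test_facial_height(self, calib_01mm):
        ls = LandmarkSet()
        ls.add("trichion", 0, 0)
        ls.add("menton", 0, 1800)
        assert midline_distance(ls, "trichion", "menton", calib_01mm) == pytest.approx(18.0)

    def test_rotation_invariance(self, calib_01mm):
        ls = LandmarkSet()
        ls.add("trichion", 40, 10)
        ls.add("menton", 55, 1810)
        d0 = midline_distance(ls, "trichion", "menton", calib_01mm)
        d1 = midline_distance(
            rotate_landmarks(ls, 23.0, (40, 10)), "trichion", "menton", calib_01mm
        )
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_bilateral_is_lr_mean(self, calib_01mm):
        ls = LandmarkSet()
        ls.add("endocanthion_L", 0, 0)
        ls.add("exocanthion_L", 300, 0)
        ls.add("endocanthion_R", -100, 0)
        ls.add("exocanthion_R", -300, 0)
        got = bilateral_distance(ls, ("endocanthion", "exocanthion"), calib_01mm)
        assert got == pytest.approx(0.5 * (3.0 + 2.0))

    def test_missing_landmark_named(self, calib_01mm):
        ls = LandmarkSet("s9")
        ls.add("trichion", 0, 0)
        with pytest.raises(SchemaError, match="menton"):
            midline_distance(ls, "trichion", "menton", calib_01mm)


class TestHorizontalThirds:
    def midline(self, ys):
        ls = LandmarkSet()
        for name, y in zip(["trichion", "glabella", "subnasale", "menton"], ys):
            ls.add(name, 500.0, y)
        return ls

    def test_equal_spacing(self, calib_01mm):
        cm, props = horizontal_thirds(self.midline([0, 600, 1200, 1800]), calib_01mm)
        assert props == pytest.approx((1 / 3, 1 / 3, 1 / 3))
        assert cm == pytest.approx((6.0, 6.0, 6.0))

    def test_proportions_sum_exactly_one(self, calib_01mm):
        _, props = horizontal_thirds(self.midline([3, 611, 1234, 1807]), calib_01mm)
        assert props[0] + props[1] + props[2] == 1.0

    def test_rotation_leaves_proportions(self, calib_01mm):
        ls = self.midline([0, 590, 1230, 1800])
        _, p0 = horizontal_thirds(ls, calib_01mm)
        _, p1 = horizontal_thirds(rotate_landmarks(ls, 10.0, (500, 900)), calib_01mm)
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_generator_proportions_recovered(self, calib_01mm):
        spec = zero_sd(
            female_spec(),
            upper_third_prop=(0.324, 0.0),
            middle_third_prop=(0.344, 0.0),
            lower_third_prop=(0.332, 0.0),
        )
        subj = sample_cohort(spec, 1, seed=0, render_eyes=False)[0]
        _, props = horizontal_thirds(subj.landmarks, exact_calibration(subj))
        assert props == pytest.approx((0.324, 0.344, 0.332), abs=1e-9)

    def test_non_monotone_order_rejected(self, calib_01mm):
        with pytest.raises(GeometryError):
            horizontal_thirds(self.midline([0, 1200, 600, 1800]), calib_01mm)


class TestVerticalThirds:
    def test_documented_split(self):
        assert vertical_thirds(simple_eyes()) == pytest.approx((0.311, 0.374, 0.315))

    def test_equal_spacing(self):
        ls = LandmarkSet()
        for name, x in zip(
            ["exocanthion_R", "endocanthion_R", "endocanthion_L", "exocanthion_L"],
            [0, 100, 200, 300],
        ):
            ls.add(name, float(x), 50.0)
        assert vertical_thirds(ls) == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_sum_exactly_one(self):
        props = vertical_thirds(simple_eyes(tilt_px=17.0))
        assert props[0] + props[1] + props[2] == 1.0

    def test_rigid_rotation_invariance(self):
        ls = simple_eyes()
        p0 = vertical_thirds(ls)
        p1 = vertical_thirds(rotate_landmarks(ls, 25.0, (700, 900)))
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_crossed_ordering_rejected(self):
        ls = LandmarkSet()
        for name, x in zip(
            ["exocanthion_R", "endocanthion_R", "endocanthion_L", "exocanthion_L"],
            [0, 200, 100, 300],
        ):
            ls.add(name, float(x), 50.0)
        with pytest.raises(GeometryError):
            vertical_thirds(ls)


def brow_face(a1_deg, a3_deg, med_px=300.0, lat_px=160.0):
    """Symmetric brows with known limb angles relative to a horizontal IP line."""
    ls = LandmarkSet()
    ls.add("pupil_L", 300, 900)
    ls.add("pupil_R", -300, 900)
    r1, r3 = math.radians(a1_deg), math.radians(a3_deg)
    for side, sgn in (("L", 1.0), ("R", -1.0)):
        ax = sgn * 300.0
        ls.add(f"brow_apex_{side}", ax, 700.0)
        ls.add(f"brow_medial_{side}", ax - sgn * med_px * math.cos(r1),
               700.0 + med_px * math.sin(r1))
        ls.add(f"brow_lateral_{side}", ax + sgn * lat_px * math.cos(r3),
               700.0 + lat_px * math.sin(r3))
        ls.add(f"endocanthion_{side}", sgn * 150.0, 900.0)
        ls.add(f"exocanthion_{side}", sgn * 450.0, 890.0)
    return ls


class TestBrowMetrics:
    def test_flat_brow_degenerate_angles(self, calib_01mm):
        out = brow_metrics(brow_face(0.0, 0.0), calib_01mm)
        assert out["brow_angle_1_deg"] == pytest.approx(0.0, abs=1e-9)
        assert out["brow_angle_2_deg"] == pytest.approx(180.0, abs=1e-9)
        assert out["brow_angle_3_deg"] == pytest.approx(0.0, abs=1e-9)

    def test_thirty_degree_limbs(self, calib_01mm):
        out = brow_metrics(brow_face(30.0, 30.0), calib_01mm)
        assert out["brow_angle_1_deg"] == pytest.approx(30.0, abs=1e-9)
        assert out["brow_angle_2_deg"] == pytest.approx(120.0, abs=1e-9)
        assert out["brow_angle_3_deg"] == pytest.approx(30.0, abs=1e-9)

    def test_length_additivity(self, calib_01mm):
        out = brow_metrics(brow_face(12.0, 35.0, med_px=300.0, lat_px=160.0), calib_01mm)
        assert out["medial_brow_length_cm"] == pytest.approx(3.0)
        assert out["lateral_brow_length_cm"] == pytest.approx(1.6)
        assert out["total_brow_length_cm"] == pytest.approx(4.6)

    def test_angles_invariant_to_rigid_rotation(self, calib_01mm):
        ls = brow_face(15.0, 40.0)
        out0 = brow_metrics(ls, calib_01mm)
        out1 = brow_metrics(rotate_landmarks(ls, 12.0, (0, 800)), calib_01mm, rotation=12.0)
        for key in ("brow_angle_1_deg", "brow_angle_2_deg", "brow_angle_3_deg"):
            assert out1[key] == pytest.approx(out0[key], abs=1e-9)

    def test_coincident_brow_points_rejected(self, calib_01mm):
        ls = brow_face(10.0, 10.0, med_px=0.0)
        with pytest.raises(GeometryError):
            brow_metrics(ls, calib_01mm)

    def test_vertical_canthus_brow_mode(self, calib_01mm):
        ls = brow_face(0.0, 0.0)
        out = brow_metrics(ls, calib_01mm, canthus_brow_mode="vertical")
        # flat brow at y=700, canthi at y=900/890 -> vertical gaps 200 and 190 px
        assert out["medial_canthus_to_medial_brow_cm"] == pytest.approx(2.0)
        assert out["lateral_canthus_to_lateral_brow_cm"] == pytest.approx(1.9)

    def test_unknown_mode_rejected(self, calib_01mm):
        with pytest.raises(ParameterError):
            brow_metrics(brow_face(10, 10), calib_01mm, canthus_brow_mode="manhattan")


class TestScleralShow:
    def eye_pair(self, gap_px):
        ls = LandmarkSet()
        for side, x in (("L", 300.0), ("R", -300.0)):
            ls.add(f"iris_inferior_{side}", x, 950.0)
            ls.add(f"lowerlid_margin_{side}", x, 950.0 + gap_px)
        return ls

    def test_positive_gap_flags(self, calib_01mm):
        # iris border 2 px above the lid margin -> +0.2 mm, flagged
        flag, combined, per_eye = scleral_show(self.eye_pair(+2.0), calib_01mm)
        assert flag is True
        assert combined == pytest.approx(0.2)
        assert per_eye["L"] == pytest.approx(0.2)

    def test_zero_gap_not_flagged(self, calib_01mm):
        flag, combined, _ = scleral_show(self.eye_pair(0.0), calib_01mm)
        assert flag is False
        assert combined == 0.0

    def test_negative_gap_not_flagged(self, calib_01mm):
        flag, combined, _ = scleral_show(self.eye_pair(-5.0), calib_01mm)
        assert flag is False
        assert combined == pytest.approx(-0.5)


class TestFacialRatios:
    def test_golden_ratio(self):
        rec = MeasurementRecord(
            facial_height_cm=16.18, bigonial_width_cm=10.0, bizygomatic_width_cm=11.0
        )
        r = facial_ratios(rec)
        assert r[0] == pytest.approx(1.618)

    def test_identity_ratio(self):
        rec = MeasurementRecord(
            facial_height_cm=13.0, bigonial_width_cm=11.0, bizygomatic_width_cm=13.0
        )
        assert facial_ratios(rec)[1] == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        rec = MeasurementRecord(
            facial_height_cm=13.0, bigonial_width_cm=0.0, bizygomatic_width_cm=13.0
        )
        with pytest.raises(ParameterError):
            facial_ratios(rec)


class TestMeasureSubject:
    def test_zero_noise_equals_truth(self):
        subjects = sample_cohort(female_spec(), 5, seed=11, render_eyes=False)
        for subj in subjects:
            rec = measure_subject(subj.landmarks, exact_calibration(subj)).to_dict()
            for key, expected in subj.truth.items():
                assert rec[key] == pytest.approx(expected, abs=1e-6), key

    def test_rotate_and_rescale_invariance(self):
        subj = sample_cohort(female_spec(), 1, seed=5, render_eyes=False)[0]
        calib = exact_calibration(subj)
        rec0 = measure_subject(subj.landmarks, calib).to_dict()
        rotated = rotate_landmarks(subj.landmarks, 8.0, (500.0, 500.0))
        scaled = LandmarkSet(rotated.subject_id)
        for name, p in rotated.points.items():
            scaled.add(name, 2.0 * p.x, 2.0 * p.y)
        calib2 = make_calibration(2.0 * calib.wtw_px_mean, calib.wtw_reference_mm)
        rec1 = measure_subject(scaled, calib2).to_dict()
        for key, v0 in rec0.items():
            if key in ("subject_id", "facial_rotation_deg"):
                continue
            assert rec1[key] == pytest.approx(v0, abs=1e-6), key
        assert rec1["facial_rotation_deg"] == pytest.approx(
            rec0["facial_rotation_deg"] + 8.0, abs=1e-6
        )

    def test_total_brow_consistency(self):
        for subj in sample_cohort(female_spec(), 8, seed=21, render_eyes=False):
            rec = measure_subject(subj.landmarks, exact_calibration(subj))
            assert rec.total_brow_length_cm == pytest.approx(
                rec.medial_brow_length_cm + rec.lateral_brow_length_cm, abs=1e-12
            )

    def test_missing_core_is_schema_error_with_subject(self):
        subj = sample_cohort(female_spec(), 1, seed=2, render_eyes=False)[0]
        del subj.landmarks.points["trichion"]
        with pytest.raises(SchemaError, match=subj.subject_id):
            measure_subject(subj.landmarks, exact_calibration(subj))
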