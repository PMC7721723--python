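"""Cross-sectional morphometry: perpendicular areas, stations, segments."""
import numpy as np
import pytest

from airwaykit.centerline import Centerline, extract_centerline
from airwaykit.errors import OrderingError, StationRangeError
from airwaykit.geometry import (DEFAULT_STATION_OFFSETS_MM, AirwaySegments,
                                area_profile, cross_section_at,
                                partition_segments, pharyngeal_length,
                                segment_volumes)


def _axis_centerline(mask, length):
    c = mask.origin_mm + (np.array(mask.shape) // 2) * mask.spacing_mm
    z = np.arange(0.0, length + 1e-9, mask.spacing_mm[2])
    pts = np.column_stack([np.full_like(z, c[0]), np.full_like(z, c[1]), z])
    return Centerline.from_points(pts)


class TestCrossSection:
    def test_cylinder_area_native_voxel(self, tube_fine):
        """Digital r = 0.5 mm cylinder at the 20 um study voxel: pi r^2 +/- 2%."""
        _, mask, truth = tube_fine
        cl = _axis_centerline(mask, truth.length_true_mm)
        cs = cross_section_at(mask, cl, truth.length_true_mm / 2)
        assert cs.area_mm2 == pytest.approx(np.pi * 0.25, rel=0.02)
        assert np.allclose(cs.plane_normal, [0, 0, 1])

    def test_tilted_cylinder_perpendicular_not_axial(self, tilted_cylinder):
        """30-degree tilt: the perpendicular section stays pi r^2, clearly
        distinct from the elliptical axial-slice area pi r^2 / cos(30)."""
        mask = tilted_cylinder
        t = np.deg2rad(30.0)
        axis = np.array([np.sin(t), 0.0, np.cos(t)])
        start = np.array([0.8, 0.8, 0.0])
        cl = Centerline.from_points([start, start + 2.4 * axis])
        cs = cross_section_at(mask, cl, 1.2)
        true_area = np.pi * 0.25
        assert cs.area_mm2 == pytest.approx(true_area, rel=0.02)
        axial = true_area / np.cos(t)
        assert abs(cs.area_mm2 - axial) > 0.10 * true_area

    def test_out_of_range_station_rejected(self, tube_005):
        _, mask, truth = tube_005
        cl = _axis_centerline(mask, truth.length_true_mm)
        with pytest.raises(StationRangeError):
            cross_section_at(mask, cl, truth.length_true_mm + 1.0)

    def test_boundary_clip_flags_truncation(self):
        """A lumen filling the whole array is clipped by the volume edge."""
        from airwaykit.volume import BinaryMask

        mask = BinaryMask(np.ones((12, 12, 12), dtype=bool), [0.1] * 3, [0, 0, 0])
        cl = Centerline.from_points([[0.55, 0.55, 0.0], [0.55, 0.55, 1.1]])
        with pytest.warns(UserWarning, match="clipped"):
            cs = cross_section_at(mask, cl, 0.55)
        assert cs.truncated


class TestAreaProfile:
    def test_nine_stations_by_default(self, mouse_005):
        _, mask, lms, _ = mouse_005
        cl = Centerline.from_points([[0, 0, 0], [0, 0, 16.0]])
        s_hp = cl.project_point(np.asarray(lms.get("hard_palate_edge")))
        prof = area_profile(mask, cl, s_hp)
        assert len(prof) == 9
        assert [p.station_label_mm for p in prof] == list(DEFAULT_STATION_OFFSETS_MM)

    def test_uniform_cylinder_equal_areas(self, tube_005):
        _, mask, truth = tube_005
        cl = _axis_centerline(mask, truth.length_true_mm)
        prof = area_profile(mask, cl, 4.5, offsets_mm=(3, 2, 1, 0, -1, -2, -3, -4, -5))
        areas = np.array([p.area_mm2 for p in prof])
        assert np.ptp(areas) / areas.mean() < 0.02

    def test_venturi_minimum_at_anchor(self):
        """Anchored at the throat center, the station battery bottoms at 0."""
        from airwaykit.phantoms import make_venturi_phantom

        _, mask, truth = make_venturi_phantom(
            0.8, 0.4, l_inlet_mm=3.0, l_throat_mm=1.0, l_outlet_mm=3.0,
            taper_len_mm=2.0, spacing_mm=0.04,
        )
        cl = _axis_centerline(mask, truth.length_true_mm)
        s_throat = truth.landmark_truth["throat_center"][2]
        prof = area_profile(mask, cl, s_throat)
        areas = {p.station_label_mm: p.area_mm2 for p in prof if not p.missing}
        assert min(areas, key=areas.get) == 0.0

    def test_out_of_range_stations_flagged_missing(self, tube_005):
        _, mask, truth = tube_005
        cl = _axis_centerline(mask, truth.length_true_mm)
        prof = area_profile(mask, cl, 1.0)  # labels +2, +3 fall off the rostral end
        missing = {p.station_label_mm for p in prof if p.missing}
        assert missing == {2.0, 3.0}
        assert sum(not p.missing for p in prof) == 7

    def test_scaled_phantom_areas_scale_quadratically(self, mouse_005, mouse_scaled_005):
        _, mask, _, _ = mouse_005
        _, mask_s, _, _ = mouse_scaled_005
        cl = Centerline.from_points([[0, 0, 0], [0, 0, 16.0]])
        a = [c.area_mm2 for c in area_profile(mask, cl, 9.0)]
        b = [c.area_mm2 for c in area_profile(mask_s, cl, 9.0)]
        ratio = np.array(b) / np.array(a)
        assert ratio == pytest.approx(np.full_like(ratio, 0.64), rel=0.05)


class TestSegments:
    def test_mouse_boundaries_within_one_voxel(self, mouse_005):
        _, mask, lms, truth = mouse_005
        cl = extract_centerline(mask, [0, 0, 0.0], [0, 0, 16.0 - 0.05])
        segs = partition_segments(cl, lms)
        assert segs.s_meatus_merge == pytest.approx(4.0, abs=0.05)
        assert segs.s_hard_palate == pytest.approx(9.0, abs=0.05)

    def test_equidistant_landmark_ratio(self, tube_005):
        _, mask, truth = tube_005
        cl = _axis_centerline(mask, truth.length_true_mm)
        c = mask.origin_mm + (np.array(mask.shape) // 2) * mask.spacing_mm
        L = truth.length_true_mm
        lms = {
            "meatus_merge": [c[0], c[1], 0.25 * L],
            "hard_palate_edge": [c[0], c[1], 0.50 * L],
            "epiglottis": [c[0], c[1], 0.75 * L],
        }
        segs = partition_segments(cl, lms)
        spans = (segs.s_meatus_merge, segs.s_hard_palate - segs.s_meatus_merge,
                 segs.s_epiglottis - segs.s_hard_palate)
        assert spans == pytest.approx((2.5, 2.5, 2.5), abs=1e-6)

    def test_reversed_landmarks_rejected(self, tube_005):
        _, mask, truth = tube_005
        cl = _axis_centerline(mask, truth.length_true_mm)
        c = mask.origin_mm + (np.array(mask.shape) // 2) * mask.spacing_mm
        lms = {
            "meatus_merge": [c[0], c[1], 2.0],
            "hard_palate_edge": [c[0], c[1], 7.0],
            "epiglottis": [c[0], c[1], 4.0],  # rostral to the hard palate
        }
        with pytest.raises(OrderingError):
            partition_segments(cl, lms)


class TestVolumes:
    def test_additivity_exact_and_halves_equal(self, tube_005):
        _, mask, truth = tube_005
        cl = _axis_centerline(mask, truth.length_true_mm)
        segs = AirwaySegments(2.0, 5.0, 9.0, 10.0)
        vn, vp, vt = segment_volumes(mask, cl, segs)
        assert vn + vp == vt  # partition: exact
        segs_half = AirwaySegments(2.0, 5.0, 9.9999, 10.0001)
        vn, vp, _ = segment_volumes(mask, cl, segs_half)
        assert vn == pytest.approx(vp, rel=0.01)

    def test_mouse_volumes_within_3pc_of_truth(self, mouse_005):
        _, mask, lms, truth = mouse_005
        cl = extract_centerline(mask, [0, 0, 0.0], [0, 0, 16.0 - 0.05])
        segs = partition_segments(cl, lms)
        vn, vp, _ = segment_volumes(mask, cl, segs)
        assert vn == pytest.approx(truth.segment_volumes_mm3["nasal"], rel=0.03)
        assert vp == pytest.approx(truth.segment_volumes_mm3["pharyngeal"], rel=0.03)


class TestPharyngealLength:
    def test_phantom_span_recovered_within_one_voxel(self, mouse_005):
        _, mask, lms, truth = mouse_005
        cl = extract_centerline(mask, [0, 0, 0.0], [0, 0, 16.0 - 0.05])
        s_hp = cl.project_point(np.asarray(lms.get("hard_palate_edge")))
        s_ary = cl.project_point(np.asarray(lms.get("arytenoid")))
        assert pharyngeal_length(cl, s_hp, s_ary) == pytest.approx(
            truth.pharyngeal_length_mm, abs=mask.spacing_mm[0]
        )

    def test_degenerate_and_reversed(self, tube_005):
        _, mask, truth = tube_005
        cl = _axis_centerline(mask, truth.length_true_mm)
        assert pharyngeal_length(cl, 4.0, 4.0) == 0.0
        with pytest.raises(OrderingError):
            pharyngeal_length(cl, 6.0, 4.0)

    def test_straight_tube_equals_euclidean(self, tube_005):
        _, mask, truth = tube_005
        cl = _axis_centerline(mask, truth.length_true_mm)
        p1, p2 = cl.point_at(2.0), cl.point_at(8.5)
        assert pharyngeal_length(cl, 2.0, 8.5) == pytest.approx(
            np.linalg.norm(np.asarray(p2) - np.asarray(p1)), abs=1e-9
        )
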