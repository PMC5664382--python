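"""ROI geometry: circles, splines, polygons, rasters, landmark extension."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from shapely.geometry import Point, Polygon

import facecolor as fc
from facecolor.landmarks import spline_closed


def _with_points(landmarks, updates):
    """Copy of a landmark set with selected 1-based points replaced."""
    pts = landmarks.points.copy()
    for i, xy in updates.items():
        pts[i - 1] = xy
    return fc.LandmarkSet(pts, landmarks.image_width, landmarks.image_height)


def _roi(rois, name):
    return next(r for r in rois if r.name == name)


class TestCircleRois:
    def test_nose_circle_from_bridge_points(self, face):
        _, lm, _, _ = face
        lm2 = _with_points(lm, {30: (100.0, 100.0), 31: (100.0, 120.0)})
        nose = _roi(fc.circle_rois(lm2), "nose")
        np.testing.assert_allclose(nose.center, [100.0, 110.0])
        assert nose.radius == pytest.approx(14.0)

    def test_chin_circle_from_chin_and_lip_points(self, face):
        _, lm, _, _ = face
        lm2 = _with_points(lm, {9: (100.0, 200.0), 58: (100.0, 180.0)})
        chin = _roi(fc.circle_rois(lm2), "chin")
        np.testing.assert_allclose(chin.center, [100.0, 188.0])
        assert chin.radius == pytest.approx(6.4)

    def test_returns_seven_circles(self, face):
        _, lm, _, _ = face
        rois = fc.circle_rois(lm)
        assert len(rois) == 7
        assert {r.name for r in rois} == set(fc.landmarks.CIRCLE_REGION_NAMES)

    def test_translation_equivariance(self, face):
        _, lm, _, _ = face
        shift = np.array([50.0, 30.0])
        moved = fc.LandmarkSet(lm.points + shift, 512, 512)
        for a, b in zip(fc.circle_rois(lm), fc.circle_rois(moved)):
            np.testing.assert_allclose(b.center, a.center + shift)
            assert b.radius == pytest.approx(a.radius)

    def test_uniform_scaling_equivariance(self, face):
        _, lm, _, _ = face
        scaled = fc.LandmarkSet(lm.points * 2.0, 512, 512)
        for a, b in zip(fc.circle_rois(lm), fc.circle_rois(scaled)):
            np.testing.assert_allclose(b.center, a.center * 2.0)
            assert b.radius == pytest.approx(a.radius * 2.0)

    def test_radius_distance_ratios_are_structural(self, face):
        _, lm, _, _ = face
        rois = {r.name: r for r in fc.circle_rois(lm)}
        for name, anchor, ratio in [("nose", 31, 1.4), ("forehead", 22, 0.7),
                                    ("chin", 58, 0.8)]:
            d = np.hypot(*(rois[name].center - lm.pt(anchor)))
            assert rois[name].radius / d == pytest.approx(ratio, rel=1e-14)

    def test_coincident_points_raise(self, face):
        _, lm, _, _ = face
        lm2 = _with_points(lm, {30: (100.0, 100.0), 31: (100.0, 100.0)})
        with pytest.raises(fc.GeometryError):
            fc.circle_rois(lm2)


class TestSplineClosed:
    def test_passes_through_all_knots(self):
        square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        curve = spline_closed(square, 400)
        assert cdist(square, curve).min(axis=1).max() < 1e-9

    def test_approximates_circle_through_circular_knots(self):
        t = np.linspace(0, 2 * np.pi, 9)[:-1]
        r = 10.0
        knots = np.column_stack([r * np.cos(t), r * np.sin(t)])
        curve = spline_closed(knots, 400)
        assert np.abs(np.hypot(curve[:, 0], curve[:, 1]) - r).max() < 0.05 * r

    def test_reflection_symmetric_knots_give_symmetric_curve(self):
        knots = np.array([[1, 0], [0.5, 0.8], [-0.5, 0.8], [-1, 0],
                          [-0.5, -0.8], [0.5, -0.8]], float)
        curve = spline_closed(knots, 300)
        mirrored = curve * [1, -1]
        assert cdist(mirrored, curve).min(axis=1).max() < 1e-9

    def test_duplicate_consecutive_knots_raise(self):
        pts = np.array([[0, 0], [1, 1], [1, 1], [0, 2]], float)
        with pytest.raises(fc.GeometryError):
            spline_closed(pts)

    def test_too_few_samples_raise(self):
        pts = np.array([[0, 0], [1, 0], [0, 1]], float)
        with pytest.raises(fc.GeometryError):
            spline_closed(pts, 2)


class TestLipRegion:
    def test_mask_area_between_inner_and_outer_areas(self, face):
        _, lm, _, _ = face
        roi = fc.lip_region(lm)
        outer_area = Polygon(roi.outer).area
        inner_area = Polygon(roi.holes[0]).area
        mask = fc.rasterize(roi, lm.image_height, lm.image_width)
        assert inner_area < mask.sum() < outer_area

    def test_inner_knots_on_outer_ring_raise(self, face):
        _, lm, _, _ = face
        pts = lm.points.copy()
        pts[60:68] = pts[48:56]  # inner boundary collapsed onto outer
        with pytest.raises(fc.GeometryError):
            fc.lip_region(fc.LandmarkSet(pts, 256, 256))

    def test_lip_and_whole_face_masks_disjoint(self, face_masks):
        assert not (face_masks.masks["lip"] & face_masks.masks["whole_face"]).any()


class TestWholeFaceRegion:
    def test_circle_centers_inside_outer_boundary(self, face):
        _, lm, _, _ = face
        outer = Polygon(fc.whole_face_region(lm).outer)
        for roi in fc.circle_rois(lm):
            assert outer.contains(Point(*roi.center))

    def test_holes_excluded_from_mask(self, face_masks):
        wf = face_masks.masks["whole_face"]
        for name, hole in face_masks.holes.items():
            assert not (wf & hole).any(), name

    def test_mask_smaller_than_control_point_hull(self, face):
        _, lm, _, _ = face
        ctrl = np.vstack([lm.pts(1, 17), lm.pts(73, 69)])
        hull_area = Polygon(ctrl).convex_hull.area
        mask = fc.rasterize(fc.whole_face_region(lm), lm.image_height,
                            lm.image_width)
        assert mask.sum() < hull_area


class TestRasterize:
    def test_circle_count_matches_brute_force(self):
        roi = fc.CircleROI("c", np.array([5.0, 5.0]), 3.0)
        mask = fc.rasterize(roi, 10, 10)
        count = sum(
            (c + 0.5 - 5.0) ** 2 + (r + 0.5 - 5.0) ** 2 <= 9.0
            for r in range(10) for c in range(10))
        assert mask.sum() == count

    def test_tiny_circle_covers_no_pixel_center(self):
        roi = fc.CircleROI("c", np.array([5.0, 5.0]), 0.1)
        assert not fc.rasterize(roi, 10, 10).any()

    def test_circle_outside_image_cropped_silently(self):
        roi = fc.CircleROI("c", np.array([100.0, 100.0]), 3.0)
        assert not fc.rasterize(roi, 10, 10).any()

    def test_bad_dimensions_raise(self):
        roi = fc.CircleROI("c", np.array([1.0, 1.0]), 1.0)
        with pytest.raises(fc.GeometryError):
            fc.rasterize(roi, 0, 10)

    def test_masks_deterministic(self, face):
        _, lm, _, _ = face
        a = fc.build_masks(lm)
        b = fc.build_masks(lm)
        for name in a.masks:
            np.testing.assert_array_equal(a.masks[name], b.masks[name])


class TestExtendLandmarks:
    def test_68_points_extended_to_79(self, face):
        _, lm, _, _ = face
        out = fc.extend_landmarks(lm.points[:68], 256, 256)
        assert out.points.shape == (79, 2)
        assert out.extrapolated
        brow_r = lm.points[17:22].mean(axis=0)
        brow_l = lm.points[22:27].mean(axis=0)
        # forehead points above (smaller y than) both eyebrow centroids
        assert np.all(out.points[68:73, 1] < min(brow_r[1], brow_l[1]))

    def test_79_point_input_passes_through(self, face):
        _, lm, _, _ = face
        out = fc.extend_landmarks(lm.points, 256, 256)
        np.testing.assert_array_equal(out.points, lm.points)
        assert not out.extrapolated

    def test_symmetric_face_gives_symmetric_extension(self, face):
        # the fixture face is bilaterally symmetric about its midline
        _, lm, _, _ = face
        out = fc.extend_landmarks(lm.points[:68], 256, 256)
        cx = lm.pt(28)[0]  # nose bridge sits on the midline
        forehead = out.points[68:73]
        mirrored = np.column_stack([2 * cx - forehead[::-1, 0],
                                    forehead[::-1, 1]])
        np.testing.assert_allclose(forehead, mirrored, atol=1e-6)
        brow_top = out.points[73:79]
        np.testing.assert_allclose(brow_top[:3, 0], 2 * cx - brow_top[3:, 0][::-1],
                                   atol=1e-6)
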