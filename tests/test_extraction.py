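"""Object features, classification rules, hole filling, and POI refinement."""

import numpy as np
import pytest
from shapely import contains_xy
from shapely.geometry import Polygon

from dasypop.extraction import (
    ClassificationRules,
    POIRecord,
    SegmentObject,
    classify_buildings,
    fill_holes,
    length_width_ratio,
    rectangular_fit,
    refine_residential,
    sample_validation_points,
    segment,
    shape_index,
)
from dasypop.scene import IndexKind, IndexRaster

from conftest import make_scene


def obj_from_mask(mask, pixel_size=2.5):
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    return SegmentObject(1, rows, cols, pixel_size)


class TestShapeIndex:
    @pytest.mark.parametrize("shape,expected", [
        ((4, 4), 1.0),                      # 16 edges / (4 * sqrt(16))
        ((2, 8), 1.25),                     # 20 / (4 * 4)
        ((1, 10), 22 / (4 * np.sqrt(10))),  # thin line
    ])
    def test_solid_rectangles(self, shape, expected):
        assert shape_index(obj_from_mask(np.ones(shape, bool))) == pytest.approx(expected)


class TestLengthWidthRatio:
    @pytest.mark.parametrize("shape,expected", [((4, 4), 1.0), ((3, 9), 3.0), ((2, 8), 4.0)])
    def test_rectangles(self, shape, expected):
        assert length_width_ratio(obj_from_mask(np.ones(shape, bool))) == pytest.approx(expected)

    def test_convex_blob_matches_hull_oracle(self, rng):
        # random blob: compare against min-area box of pixel-corner hull computed by shapely
        mask = np.zeros((12, 12), bool)
        mask[3:9, 2:10] = True
        mask[4:8, 1] = True
        obj = obj_from_mask(mask)
        got = length_width_ratio(obj)
        pts = []
        for r, c in zip(*np.nonzero(mask)):
            pts.extend([(c - .5, r - .5), (c + .5, r - .5), (c - .5, r + .5), (c + .5, r + .5)])
        from shapely.geometry import MultiPoint
        rect = MultiPoint(pts).convex_hull.minimum_rotated_rectangle
        xy = np.asarray(rect.exterior.coords)[:4]
        s1 = np.linalg.norm(xy[1] - xy[0])
        s2 = np.linalg.norm(xy[2] - xy[1])
        assert got == pytest.approx(max(s1, s2) / min(s1, s2))


class TestRectangularFit:
    def test_solid_rectangle_is_one(self):
        assert rectangular_fit(obj_from_mask(np.ones((3, 7), bool))) == pytest.approx(1.0)

    def test_plus_pentomino_matches_overlap_enumeration(self):
        plus = np.zeros((3, 3), bool)
        plus[1, :] = True
        plus[:, 1] = True
        obj = obj_from_mask(plus)
        got = rectangular_fit(obj)
        # oracle: equal-area rectangle with bbox orientation/aspect, centred on
        # the centroid; count member pixel centres inside it
        from shapely.geometry import MultiPoint
        pts = []
        for r, c in zip(*np.nonzero(plus)):
            pts.extend([(c - .5, r - .5), (c + .5, r - .5), (c - .5, r + .5), (c + .5, r + .5)])
        rect = MultiPoint(pts).convex_hull.minimum_rotated_rectangle
        xy = np.asarray(rect.exterior.coords)[:4]
        e1, e2 = xy[1] - xy[0], xy[2] - xy[1]
        area_rect = np.linalg.norm(e1) * np.linalg.norm(e2)
        scale = np.sqrt(5.0 / area_rect)
        centre = np.array([1.0, 1.0])  # (x=col, y=row) centroid of the plus
        corners = centre + np.array([
            (e1 * scale + e2 * scale) / 2, (e1 * scale - e2 * scale) / 2,
            (-e1 * scale - e2 * scale) / 2, (-e1 * scale + e2 * scale) / 2,
        ])
        poly = Polygon(corners[[0, 1, 2, 3]]).convex_hull.buffer(1e-9)
        rows, cols = np.nonzero(plus)
        inside = contains_xy(poly, cols.astype(float), rows.astype(float))
        assert got == pytest.approx(inside.sum() / 5.0)

    def test_l_shape_below_one(self):
        L = np.zeros((5, 5), bool)
        L[:, 0] = True
        L[4, :] = True
        assert rectangular_fit(obj_from_mask(L)) < 1.0


class TestClassification:
    GOOD = {"index_mean": 7.0, "brightness_mean": 150.0, "ndvi_mean": 0.0,
            "lw_ratio": 2.0, "rect_fit": 0.9, "shape_index": 1.2}

    def make_obj(self, **overrides):
        obj = SegmentObject(1, np.array([0]), np.array([0]), 2.5)
        obj.features = {**self.GOOD, **overrides}
        return obj

    def test_all_rules_pass(self):
        objs = classify_buildings([self.make_obj()], ClassificationRules())
        assert objs[0].is_building

    @pytest.mark.parametrize("overrides", [
        {"ndvi_mean": 0.3}, {"index_mean": 5.0}, {"brightness_mean": 100.0},
        {"lw_ratio": 6.0}, {"lw_ratio": 1.0}, {"rect_fit": 0.4}, {"shape_index": 3.0},
    ])
    def test_single_rule_failure_rejects(self, overrides):
        objs = classify_buildings([self.make_obj(**overrides)], ClassificationRules())
        assert not objs[0].is_building

    def test_labels_equal_bruteforce_conjunction(self, rng):
        rules = ClassificationRules()
        objs = []
        for i in range(50):
            objs.append(self.make_obj(
                index_mean=rng.uniform(0, 12), brightness_mean=rng.uniform(80, 200),
                ndvi_mean=rng.uniform(-0.2, 0.4), lw_ratio=rng.uniform(1, 6),
                rect_fit=rng.uniform(0.2, 1.0), shape_index=rng.uniform(1.0, 4.0)))
        classify_buildings(objs, rules)
        for o in objs:
            f = o.features
            expected = (f["index_mean"] >= 6 and f["brightness_mean"] >= 136
                        and f["ndvi_mean"] < 0.1 and 1.5 <= f["lw_ratio"] <= 4.5
                        and f["rect_fit"] >= 0.6 and f["shape_index"] <= 2.6)
            assert o.is_building == expected

    def test_monotone_in_threshold_relaxation(self, rng):
        strict = ClassificationRules()
        relaxed = ClassificationRules(index_min=3.0, brightness_min=100.0, ndvi_max=0.3,
                                      lw_ratio_min=1.0, lw_ratio_max=6.0,
                                      rect_fit_min=0.3, shape_index_max=4.0)
        objs = [self.make_obj(index_mean=rng.uniform(0, 12), lw_ratio=rng.uniform(1, 6))
                for _ in range(30)]
        before = [o.is_building for o in classify_buildings(objs, strict)]
        after = [o.is_building for o in classify_buildings(objs, relaxed)]
        for b, a in zip(before, after):
            assert a or not b  # relaxing never removes a building


class TestSegment:
    def make_index_scene(self, values):
        values = np.asarray(values, dtype=float)
        ones = np.full(values.shape, 50.0)
        scene = make_scene(ones, ones, ones, ones)
        return scene, IndexRaster(values, IndexKind.MBI)

    def test_two_disjoint_blobs_give_two_objects(self):
        v = np.zeros((10, 10))
        v[1:3, 1:3] = 10
        v[6:9, 6:9] = 10
        scene, index = self.make_index_scene(v)
        assert len(segment(scene, index, threshold=6.0)) == 2

    def test_empty_support_gives_no_objects(self):
        scene, index = self.make_index_scene(np.zeros((5, 5)))
        assert segment(scene, index, threshold=6.0) == []

    def test_mismatched_shapes_rejected(self):
        scene, _ = self.make_index_scene(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="co-registered"):
            segment(scene, IndexRaster(np.zeros((6, 6)), IndexKind.MBI), 1.0)


class TestFillHoles:
    def test_solid_mask_unchanged(self):
        m = np.ones((6, 6), bool)
        np.testing.assert_array_equal(fill_holes(m, 5), m)

    def test_small_hole_filled(self):
        m = np.ones((9, 9), bool)
        m[3:6, 3:6] = False
        assert fill_holes(m, 5).all()

    def test_large_hole_kept_open(self):
        m = np.ones((13, 13), bool)
        m[2:11, 2:11] = False  # 9x9 hole, larger than the 5x5 box
        out = fill_holes(m, 5)
        np.testing.assert_array_equal(out, m)

    def test_never_shrinks_and_never_merges(self):
        m = np.zeros((10, 14), bool)
        m[2:8, 1:6] = True
        m[2:8, 8:13] = True
        m[4, 3] = False  # small hole in the first object
        out = fill_holes(m, 5)
        assert (out >= m).all()
        from scipy import ndimage
        _, n = ndimage.label(out, structure=np.ones((3, 3)))
        assert n == 2


class TestRefineResidential:
    def scene(self):
        z = np.full((20, 20), 50.0)
        return make_scene(z, z, z, z, pixel_size=1.0)

    def building_at(self, r, c):
        obj = SegmentObject(1, np.array([r]), np.array([c]), 1.0)
        obj.is_building = True
        return obj

    def test_nearby_residential_poi_keeps_building(self):
        scene = self.scene()
        b = self.building_at(5, 5)
        x, y = scene.pixel_to_world(np.array([5]), np.array([5]))
        pois = [POIRecord(x[0] + 10, y[0], "residential")]
        assert refine_residential([b], pois, radius_m=50, scene=scene) == [b]

    def test_nearest_category_rule(self):
        # nearest POI is commercial even though a residential one is in range
        scene = self.scene()
        b = self.building_at(5, 5)
        x, y = scene.pixel_to_world(np.array([5]), np.array([5]))
        pois = [POIRecord(x[0] + 2, y[0], "commercial"),
                POIRecord(x[0] + 8, y[0], "residential")]
        assert refine_residential([b], pois, radius_m=50, scene=scene) == []

    def test_empty_poi_set_drops_all_with_warning(self):
        b = self.building_at(3, 3)
        with pytest.warns(UserWarning, match="no POIs"):
            assert refine_residential([b], [], 50, self.scene()) == []

    def test_agrees_with_exhaustive_nearest_scan(self, rng):
        scene = self.scene()
        buildings = [self.building_at(int(r), int(c))
                     for r, c in rng.integers(0, 20, (15, 2))]
        cats = ["residential", "commercial", "financial", "entertainment"]
        pois = [POIRecord(rng.uniform(0, 20), rng.uniform(-20, 0), cats[i % 4])
                for i in range(12)]
        kept = refine_residential(buildings, pois, radius_m=8.0, scene=scene)
        expected = []
        for b in buildings:
            x, y = scene.pixel_to_world(np.array([b.centroid_rc[0]]), np.array([b.centroid_rc[1]]))
            d = [np.hypot(p.x - x[0], p.y - y[0]) for p in pois]
            i = int(np.argmin(d))
            if d[i] <= 8.0 and pois[i].category == "residential":
                expected.append(b)
        assert kept == expected

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            POIRecord(0, 0, "factory")


class TestValidationSampling:
    def test_stratified_counts_and_truth_labels(self):
        mask = np.zeros((30, 30), bool)
        mask[5:15, 5:15] = True
        rows, cols, truth = sample_validation_points(mask, 100, seed=0)
        assert len(rows) == 100
        np.testing.assert_array_equal(mask[rows, cols], truth)
        assert truth.sum() == 50
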