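"""Thresholding, shadow masks, length measurement, and height assignment."""

import math

import numpy as np
import pytest

from dasypop.scene import IndexKind, IndexRaster, SolarGeometry
from dasypop.shadow import (
    ShadowComponent,
    ShadowConfig,
    assign_heights,
    building_height,
    ciit_shadow,
    component_filter,
    height_error_table,
    local_variance,
    mbcv_threshold,
    shadow_components,
    shadow_length,
    shadow_mask,
)
from dasypop.extraction import SegmentObject
from dasypop.morphology import MorphConfig, msi

from conftest import make_scene


def mbcv_oracle(values, n_bins=256):
    """Exhaustive scan over all candidate bin-boundary thresholds."""
    v = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    p = hist / hist.sum()
    centres = (edges[:-1] + edges[1:]) / 2
    bcv = np.full(n_bins - 1, -1.0)
    for k in range(n_bins - 1):
        w0 = p[:k + 1].sum()
        w1 = 1 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = (p[:k + 1] * centres[:k + 1]).sum() / w0
        mu1 = (p[k + 1:] * centres[k + 1:]).sum() / w1
        bcv[k] = w0 * w1 * (mu0 - mu1) ** 2
    best = np.flatnonzero(bcv >= bcv.max() * (1.0 - 1e-9))
    return float(np.mean(edges[best + 1]))


class TestMbcvThreshold:
    def test_two_pure_modes_split_cleanly(self):
        v = np.array([0.0] * 500 + [255.0] * 500)
        t = mbcv_threshold(v)
        assert 0 < t < 255
        assert ((v < t) == (v == 0)).all()

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(5):
            v = rng.uniform(0, 255, 400)
            assert mbcv_threshold(v) == pytest.approx(mbcv_oracle(v))

    def test_bimodal_mixture_low_misclassification(self):
        rng = np.random.default_rng(7)
        lo = rng.normal(50, 10, 5000)
        hi = rng.normal(200, 10, 5000)
        v = np.concatenate([lo, hi])
        t = mbcv_threshold(v)
        err = ((lo >= t).sum() + (hi < t).sum()) / 10000
        assert err < 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            mbcv_threshold(np.full(10, 3.0))


class TestShadowMask:
    def test_vegetation_and_water_removed(self):
        idx = IndexRaster(np.array([[10.0, 10.0, 10.0, 0.0]]), IndexKind.MSI)
        ndvi = np.array([[0.0, 0.5, 0.0, 0.0]])   # pixel 1 vegetated
        ndwi = np.array([[0.0, 0.0, 0.5, 0.0]])   # pixel 2 water
        mask = shadow_mask(idx, ndvi, ndwi, ShadowConfig())
        np.testing.assert_array_equal(mask, [[True, False, False, False]])


class TestComponentFilter:
    def test_speckle_and_road_removed(self):
        mask = np.zeros((50, 50), bool)
        mask[2, 2] = True              # 1-pixel speckle (6.25 m2 < 30)
        mask[10:12, 5:45] = True       # 2x40 road strip, lw = 20
        mask[30:36, 30:36] = True      # compact 6x6 shadow
        comps = component_filter(mask, min_area_m2=30.0, max_lw_ratio=15.0, pixel_size=2.5)
        assert len(comps) == 1
        assert comps[0].n_pixels == 36

    def test_counts_match_exhaustive_scan(self, rng):
        mask = rng.random((40, 40)) > 0.8
        from scipy import ndimage
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        keep = 0
        for i in range(1, n + 1):
            rows, cols = np.nonzero(labels == i)
            if len(rows) * 2.5**2 < 30.0:
                continue
            from dasypop.extraction import length_width_ratio
            probe = SegmentObject(i, rows, cols, 2.5)
            if length_width_ratio(probe) > 15.0:
                continue
            keep += 1
        assert len(component_filter(mask, 30.0, 15.0, 2.5)) == keep


class TestCiit:
    def test_flat_image_empty_mask(self):
        z = np.full((10, 10), 80.0)
        scene = make_scene(z, z, z, z)
        assert not ciit_shadow(scene).any()

    def test_variance_peaks_at_step_edge(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 1.0
        var = local_variance(img, 3)
        assert var[:, 4:6].max() > 0
        assert var[:, 0:3].max() == 0

    def test_pipeline_equals_stage_composition(self):
        rng = np.random.default_rng(3)
        bands = [rng.uniform(10, 250, (8, 8)) for _ in range(4)]
        scene = make_scene(*bands)
        from dasypop.scene import c3_index, compute_ndvi, compute_ndwi

        cfg = ShadowConfig()
        var = local_variance(c3_index(scene).values, 3)
        expected = shadow_mask(IndexRaster(var, IndexKind.C3),
                               compute_ndvi(scene).values, compute_ndwi(scene).values, cfg)
        np.testing.assert_array_equal(ciit_shadow(scene, cfg), expected)


class TestShadowLength:
    def comp(self, mask, pixel_size=2.5):
        r, c = np.nonzero(np.asarray(mask, bool))
        return ShadowComponent(1, r, c, pixel_size)

    def test_axis_aligned_shadow_due_north(self):
        solar = SolarGeometry(45.0, 180.0)  # shadow points north
        mask = np.zeros((20, 20), bool)
        mask[5:15, 3:7] = True              # 10 rows along the shadow axis, 4 wide
        comp = self.comp(mask)
        L = shadow_length(comp, solar, 2.5)
        assert L == pytest.approx(25.0)
        np.testing.assert_allclose(comp.line_lengths_m, 25.0)

    def test_single_pixel_is_one_pixel_long(self):
        comp = self.comp(np.ones((1, 1), bool))
        assert shadow_length(comp, SolarGeometry(45, 180), 2.5) == pytest.approx(2.5)

    def test_rotated_rectangle_within_one_pixel(self):
        solar = SolarGeometry(45.0, 210.0)  # shadow azimuth 30 deg
        theta = math.radians(30)
        d = np.array([-math.cos(theta), math.sin(theta)])
        rr, cc = np.meshgrid(np.arange(80), np.arange(80), indexing="ij")
        along = (rr - 40) * d[0] + (cc - 40) * d[1]
        across = (rr - 40) * -d[1] + (cc - 40) * d[0]
        mask = (np.abs(along) <= 10) & (np.abs(across) <= 2.5)
        L = shadow_length(self.comp(mask), solar, 2.5)
        true_len = 21 * 2.5  # 21-pixel extent along the axis
        assert abs(L - true_len) <= 2.5

    def test_anchor_is_sun_side_pixel(self):
        solar = SolarGeometry(45.0, 180.0)  # sun due south: anchor at max row
        mask = np.zeros((10, 4), bool)
        mask[2:8, 1:3] = True
        comp = self.comp(mask)
        shadow_length(comp, solar, 2.5)
        assert comp.anchor_rc[0] == 7.0


class TestBuildingHeight:
    def test_zero_length_zero_height(self, solar):
        assert building_height(0.0, solar) == 0.0

    def test_forty_five_degrees_identity(self):
        assert building_height(10.0, SolarGeometry(45.0, 180.0)) == pytest.approx(10.0)

    def test_study_altitude(self):
        # L = 5 m at beta = 68.68 deg
        assert building_height(5.0, SolarGeometry(68.68, 180.0)) == pytest.approx(12.81, abs=0.01)

    def test_monotone_in_length_and_altitude(self):
        s1, s2 = SolarGeometry(30.0, 0.0), SolarGeometry(60.0, 0.0)
        assert building_height(5.0, s1) < building_height(10.0, s1)
        assert building_height(5.0, s1) < building_height(5.0, s2)

    def test_negative_length_rejected(self, solar):
        with pytest.raises(ValueError):
            building_height(-1.0, solar)


class TestAssignHeights:
    def building(self, r, c):
        obj = SegmentObject(1, np.array([r]), np.array([c]), 2.5)
        obj.is_building = True
        return obj

    def comp_at(self, r, c, length_px, solar, pixel_size=2.5):
        rows = np.arange(r, r + length_px)
        cols = np.full(length_px, c)
        comp = ShadowComponent(1, rows, cols, pixel_size)
        shadow_length(comp, solar, pixel_size)
        return comp

    def test_adjacent_shadow_transfers_height(self):
        solar = SolarGeometry(45.0, 180.0)
        comp = self.comp_at(4, 5, 4, solar)   # L = 10 m -> H = 10 m
        b = self.building(8, 5)
        assign_heights([b], [comp], solar, 2.5)
        assert b.height_m == pytest.approx(10.0)

    def test_idw_midpoint_of_two_samples(self):
        solar = SolarGeometry(45.0, 180.0)
        c1 = self.comp_at(0, 0, 4, solar)     # anchor (3, 0), H ~ 10
        c2 = self.comp_at(0, 20, 5, solar)    # anchor (4, 20), H ~ 12.5
        b = self.building(4, 10)              # nearly equidistant laterally
        assign_heights([b], [c1, c2], solar, 2.5, max_distance_m=None)
        lo, hi = sorted([c1.length_m, c2.length_m])
        assert lo < b.height_m < hi

    def test_no_shadows_fall_back_to_default(self, solar):
        b = self.building(2, 2)
        with pytest.warns(UserWarning, match="no shadow"):
            assign_heights([b], [], solar, 2.5, default_height_m=7.0)
        assert b.height_m == 7.0


class TestHeightErrorTable:
    def test_perfect_estimates_all_in_first_bin(self):
        t = height_error_table(np.array([3.0, 8.0]), np.array([3.0, 8.0]))
        assert t["counts"][0] == 2 and t["counts"][1:].sum() == 0
        assert t["rmse"] == 0.0

    def test_published_count_to_percentage_conversion(self):
        # the colour-invariant route's 574 validation points
        counts = np.array([208, 124, 93, 66, 58, 25])
        errors = np.concatenate([
            np.full(n, e) for n, e in zip(counts, [1.0, 3.0, 6.0, 8.0, 11.0, 14.0])
        ])
        t = height_error_table(errors, np.zeros_like(errors))
        np.testing.assert_array_equal(t["counts"], counts)
        np.testing.assert_allclose(
            t["percentages"], [36.24, 21.60, 16.20, 11.50, 10.10, 4.36], atol=0.005)

    def test_random_errors_match_manual_histogram(self, rng):
        est = rng.uniform(0, 30, 200)
        ref = rng.uniform(0, 30, 200)
        t = height_error_table(est, ref)
        manual, _ = np.histogram(np.abs(est - ref), bins=[0, 2.5, 5, 7.5, 10, 12.5, np.inf])
        np.testing.assert_array_equal(t["counts"], manual)


class TestShadowComponentsEndToEnd:
    def test_synthetic_shadow_recovered_from_msi(self):
        # dark block on bright background; MSI -> threshold -> component -> L
        z = np.full((40, 40), 180.0)
        z[10:14, 8:20] = 25.0  # 4 rows x 12 cols dark shadow
        scene = make_scene(z, z, z, z, altitude=45.0, azimuth=90.0)  # shadow axis west
        cfg = MorphConfig(s_min=2, s_max=16, delta_s=7)
        comps = shadow_components(scene, msi(scene, cfg), ShadowConfig())
        assert len(comps) == 1
        # scan lines run east-west: length = 12 px * 2.5 m
        assert comps[0].length_m == pytest.approx(30.0)
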