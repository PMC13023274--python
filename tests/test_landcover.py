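"""Imagery workflow: building masking, denoising, K-means segmentation,
polygonization, green flagging, labeling, clipping."""

import numpy as np
import pytest
import shapely
from shapely.geometry import box
from shapely.ops import unary_union

import catrange as cr
from catrange.landcover import Segmentation
from catrange.types import RGBImage


def flat_image(colors, blocks, pixel_size=0.6, origin=(0.0, None)):
    """Image of horizontal color blocks: ``blocks`` rows per color."""
    rows = sum(blocks)
    data = np.zeros((rows, 20, 3))
    r = 0
    for c, h in zip(colors, blocks):
        data[r:r + h] = c
        r += h
    y0 = rows * pixel_size if origin[1] is None else origin[1]
    return RGBImage(data=data, origin=(origin[0], y0), pixel_size=pixel_size)


class TestMaskBuildings:
    def test_empty_building_set_is_identity(self):
        img = flat_image([(10, 20, 30)], [10])
        out = cr.mask_buildings(img, [])
        assert np.array_equal(out.data, img.data)
        assert not out.nodata.any()

    def test_building_covering_whole_image(self):
        img = flat_image([(10, 20, 30)], [10])
        big = box(-5, -5, 100, 100)
        out = cr.mask_buildings(img, [big])
        assert out.nodata.all()

    def test_pixel_count_matches_center_rule_oracle(self):
        """A 10x10 m footprint at 0.6 m/pixel masks the pixels whose centers
        it contains (~278 by area)."""
        img = flat_image([(10, 20, 30)], [40])  # 40x20 px at 0.6 m
        bld = box(0.05, 0.05, 10.05, 10.05)
        out = cr.mask_buildings(img, [bld])
        X, Y = img.pixel_centers()
        expected = shapely.contains_xy(bld, X.ravel(), Y.ravel()).sum()
        assert out.nodata.sum() == expected
        assert abs(expected - 100.0 / 0.36) < 40  # near the area-based count

    def test_disjoint_frame_errors(self):
        img = flat_image([(10, 20, 30)], [10])
        with pytest.raises(ValueError, match="frame"):
            cr.mask_buildings(img, [box(1e6, 1e6, 1e6 + 5, 1e6 + 5)])


class TestDenoise:
    def test_constant_image_unchanged(self):
        img = flat_image([(77, 77, 77)], [12])
        out = cr.denoise(img, cr.SegmentationConfig(denoise_strength=8.0))
        assert np.allclose(out.data, img.data, atol=1.0)

    def test_zero_strength_is_identity(self):
        rng = np.random.default_rng(0)
        img = RGBImage(rng.uniform(0, 255, (15, 15, 3)), (0, 15 * 0.6), 0.6)
        out = cr.denoise(img, cr.SegmentationConfig(denoise_strength=0.0))
        assert np.array_equal(out.data, img.data)

    def test_speckle_variance_reduced_within_blocks(self):
        rng = np.random.default_rng(1)
        img = flat_image([(50, 60, 70), (180, 170, 160)], [15, 15])
        noisy = np.clip(img.data + rng.normal(0, 12, img.data.shape), 0, 255)
        noisy_img = RGBImage(noisy, img.origin, img.pixel_size)
        out = cr.denoise(noisy_img, cr.SegmentationConfig(denoise_strength=10.0))
        for sl in (slice(0, 15), slice(15, 30)):
            assert out.data[sl].var() < noisy[sl].var()


class TestKmeansSegment:
    def test_recovers_flat_color_regions_exactly(self):
        colors = [(i * 30, 255 - i * 30, i * 10) for i in range(7)]
        img = flat_image(colors, [4] * 7)
        seg = cr.kmeans_segment(img, cr.SegmentationConfig(k=7, seed=0))
        # each block maps to exactly one cluster, and blocks to distinct ones
        block_labels = [np.unique(seg.labels[i * 4:(i + 1) * 4]) for i in range(7)]
        assert all(len(b) == 1 for b in block_labels)
        assert len({b[0] for b in block_labels}) == 7

    def test_at_most_k_labels(self):
        rng = np.random.default_rng(3)
        img = RGBImage(rng.uniform(0, 255, (25, 25, 3)), (0, 25 * 0.6), 0.6)
        seg = cr.kmeans_segment(img, cr.SegmentationConfig(k=7, seed=1))
        assert len(np.unique(seg.labels)) <= 7

    def test_two_color_image_perfect_partition(self):
        img = flat_image([(0, 0, 0), (255, 255, 255)], [5, 5])
        seg = cr.kmeans_segment(img, cr.SegmentationConfig(k=2, seed=0))
        assert (seg.labels[:5] == 0).all() and (seg.labels[5:] == 1).all()

    def test_fewer_colors_than_k_reduces_with_warning(self):
        img = flat_image([(0, 0, 0), (255, 255, 255)], [5, 5])
        with pytest.warns(UserWarning, match="reducing k"):
            seg = cr.kmeans_segment(img, cr.SegmentationConfig(k=5, seed=0))
        assert len(np.unique(seg.labels)) == 2

    def test_labels_ordered_by_luminance(self):
        img = flat_image([(250, 250, 250), (5, 5, 5)], [5, 5])
        seg = cr.kmeans_segment(img, cr.SegmentationConfig(k=2, seed=0))
        assert seg.labels[0, 0] == 1  # bright block gets the higher label
        assert seg.labels[-1, -1] == 0


class TestPolygonize:
    def test_uniform_grid_single_polygon(self):
        seg = Segmentation(np.zeros((6, 8), dtype=int), np.zeros((1, 3)), (0, 6), 1.0)
        polys = cr.polygonize(seg)
        assert len(polys) == 1
        assert polys[0].geometry.area == pytest.approx(48.0)

    def test_checkerboard_one_polygon_per_square(self):
        labels = np.indices((6, 6)).sum(axis=0) % 2
        seg = Segmentation(labels, np.zeros((2, 3)), (0, 6), 1.0)
        polys = cr.polygonize(seg)
        assert len(polys) == 36
        assert all(p.geometry.area == pytest.approx(1.0) for p in polys)

    def test_area_conservation_on_random_grids(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            labels = rng.integers(0, 4, (rng.integers(4, 30), rng.integers(4, 30)))
            seg = Segmentation(labels, np.zeros((4, 3)), (3.0, 11.0), 0.6)
            polys = cr.polygonize(seg)
            total = sum(p.geometry.area for p in polys)
            assert total == pytest.approx(labels.size * 0.36, rel=1e-9)

    def test_matches_pixelwise_union_oracle(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 3, (12, 14))
        seg = Segmentation(labels, np.zeros((3, 3)), (0.0, 12.0), 1.0)
        polys = cr.polygonize(seg)
        for lab in range(3):
            rr, cc = np.nonzero(labels == lab)
            oracle = unary_union([box(c, 12 - r - 1, c + 1, 12 - r) for r, c in zip(rr, cc)])
            mine = unary_union([p.geometry for p in polys if p.cluster_id == lab])
            assert mine.symmetric_difference(oracle).area < 1e-9

    def test_buildings_reinserted_as_structures(self):
        seg = Segmentation(np.zeros((4, 4), dtype=int), np.zeros((1, 3)), (0, 4), 1.0)
        bld = box(1, 1, 2, 2)
        polys = cr.polygonize(seg, buildings=[bld])
        assert polys[-1].landcover == "Structures"
        assert polys[-1].cluster_id == -1

    def test_empty_grid_errors(self):
        seg = Segmentation(np.full((3, 3), -1), np.zeros((1, 3)), (0, 3), 1.0)
        with pytest.raises(ValueError, match="empty"):
            cr.polygonize(seg)


class TestFlagGreen:
    def test_green_dominant_cluster_flagged(self):
        seg_colors = np.array([[40, 120, 50], [120, 120, 120]])
        polys = [cr.LandCoverPolygon(box(0, 0, 1, 1), cluster_id=0),
                 cr.LandCoverPolygon(box(1, 0, 2, 1), cluster_id=1)]
        out = cr.flag_green(polys, seg_colors, cr.SegmentationConfig(green_margin=10))
        assert out[0].is_green and not out[1].is_green

    def test_override_wins_regardless_of_color(self):
        seg_colors = np.array([[120, 120, 120]])
        polys = [cr.LandCoverPolygon(box(0, 0, 1, 1), cluster_id=0)]
        out = cr.flag_green(polys, seg_colors, overrides={0: True})
        assert out[0].is_green


class TestAssignLabels:
    def test_complete_table_labels_everything(self):
        polys = [cr.LandCoverPolygon(box(0, 0, 1, 1), cluster_id=0),
                 cr.LandCoverPolygon(box(1, 0, 2, 1), cluster_id=1)]
        lc = cr.assign_labels(polys, {0: "Roads", 1: "Natural"})
        assert lc.labels == {"Roads", "Natural"}

    def test_missing_cluster_errors_naming_it(self):
        polys = [cr.LandCoverPolygon(box(0, 0, 1, 1), cluster_id=3)]
        with pytest.raises(ValueError, match=r"\[3\]"):
            cr.assign_labels(polys, {0: "Roads"})

    def test_unknown_class_errors_naming_valid_labels(self):
        polys = [cr.LandCoverPolygon(box(0, 0, 1, 1), cluster_id=0)]
        with pytest.raises(ValueError, match="Roads"):
            cr.assign_labels(polys, {0: "Swamp"})


class TestClipToRegion:
    def test_region_inside_single_polygon(self):
        lc = cr.LandCoverMap([cr.LandCoverPolygon(box(0, 0, 10, 10), landcover="Natural")])
        region = box(2, 2, 4, 4)
        out = cr.clip_to_region(lc, region)
        assert len(out) == 1
        assert out.total_area() == pytest.approx(4.0)

    def test_region_equal_to_extent_unchanged(self):
        lc = cr.LandCoverMap([cr.LandCoverPolygon(box(0, 0, 10, 10), landcover="Natural")])
        out = cr.clip_to_region(lc, box(0, 0, 10, 10))
        assert out.total_area() == pytest.approx(100.0)

    def test_circle_on_boundary_splits_evenly(self):
        lc = cr.LandCoverMap([
            cr.LandCoverPolygon(box(-50, -50, 0, 50), landcover="Roads"),
            cr.LandCoverPolygon(box(0, -50, 50, 50), landcover="Open urban"),
        ])
        circle = shapely.Point(0, 0).buffer(10, quad_segs=64)
        out = cr.clip_to_region(lc, circle)
        a = {p.landcover: p.area for p in out.polygons}
        assert a["Roads"] == pytest.approx(a["Open urban"], rel=1e-9)

    def test_disjoint_region_warns_and_empties(self):
        lc = cr.LandCoverMap([cr.LandCoverPolygon(box(0, 0, 1, 1), landcover="Natural")])
        with pytest.warns(UserWarning, match="does not overlap"):
            out = cr.clip_to_region(lc, box(5, 5, 6, 6))
        assert len(out) == 0


class TestRoundTrip:
    def test_synthetic_imagery_round_trip_recovers_truth_areas(self):
        """rasterize -> denoise -> segment -> polygonize -> label by majority
        overlap recovers ground-truth class areas within 2% on noise-free
        imagery with unique per-class colors."""
        cfg = cr.LandscapeSimConfig(extent=(0, 0, 60, 60), pixel_size=0.6, seed=21)
        img, truth = cr.simulate_imagery(cfg)
        n_classes = len(truth.labels)
        polys, seg = cr.segment_image(
            img, config=cr.SegmentationConfig(k=n_classes, seed=0, denoise_strength=0.0)
        )
        table = cr.label_table_from_truth(polys, truth)
        recovered = cr.assign_labels(polys, table)
        total = truth.total_area()
        for cls in truth.labels:
            t_area = truth.class_geometry(cls).area
            r_area = recovered.class_geometry(cls).area
            assert abs(r_area - t_area) <= 0.02 * total

    def test_determinism(self):
        cfg = cr.LandscapeSimConfig(extent=(0, 0, 30, 30), pixel_size=0.6, seed=5)
        img, truth = cr.simulate_imagery(cfg)
        k = len(truth.labels)
        a, _ = cr.segment_image(img, config=cr.SegmentationConfig(k=k, seed=3))
        b, _ = cr.segment_image(img, config=cr.SegmentationConfig(k=k, seed=3))
        assert [p.geometry.wkt for p in a] == [p.geometry.wkt for p in b]

    def test_green_flags_recovered_from_palette(self):
        cfg = cr.LandscapeSimConfig(extent=(0, 0, 40, 40), pixel_size=0.6, seed=8)
        img, truth = cr.simulate_imagery(cfg)
        k = len(truth.labels)
        polys, seg = cr.segment_image(
            img, config=cr.SegmentationConfig(k=k, seed=0, denoise_strength=0.0)
        )
        table = cr.label_table_from_truth(polys, truth)
        recovered = cr.assign_labels(polys, table)
        for p in recovered.polygons:
            assert p.is_green == (p.landcover in cr.GREEN_CLASSES)
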