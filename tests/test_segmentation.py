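"""Segmentation stages: edges, projection, contour filling, splitting."""
from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import feature as sk_feature

from organoidq import (
    FormatError,
    InputError,
    PipelineParams,
    SceneConfig,
    contours_to_objects,
    detect_edges,
    generate_scene,
    object_center,
    project_edges,
    remove_small_components,
    segment_field,
    split_touching,
)
from organoidq.config import SegmentationParams
from organoidq.segmentation import EdgeMap

from conftest import boundary_ring, disc_mask


def _disc_image(radius=20, size=64, fg=40, bg=220):
    img = np.full((size, size), bg, dtype=np.uint8)
    img[disc_mask(radius, size)] = fg
    return img


class TestDetectEdges:
    def test_constant_plane_yields_no_edges(self):
        em = detect_edges(np.full((40, 40), 120, dtype=np.uint8))
        assert not em.data.any()

    def test_dark_disc_matches_reference_hysteresis_implementation(self):
        img = _disc_image()
        em = detect_edges(img, sigma=2.0, t_low=0.1, t_high=0.2)
        ref = sk_feature.canny(img.astype(np.float64) / 255.0, sigma=2.0,
                               low_threshold=0.1, high_threshold=0.2)
        assert np.array_equal(em.data, ref)
        # the edge forms a closed ring near the disc boundary
        filled = ndi.binary_fill_holes(em.data)
        assert filled.sum() > em.data.sum()
        dist_to_boundary = ndi.distance_transform_edt(~boundary_ring(disc_mask(20, 64)))
        assert dist_to_boundary[em.data].max() <= 3

    def test_vertical_step_gives_single_vertical_line(self):
        img = np.zeros((40, 40), dtype=np.uint8)
        img[:, 20:] = 200
        em = detect_edges(img, sigma=1.5)
        cols = np.nonzero(em.data)[1]
        assert em.data.any()
        assert np.ptp(cols) <= 1  # one straight line

    def test_non_2d_rejected(self):
        with pytest.raises(InputError):
            detect_edges(np.zeros((4, 4, 4)))

    def test_bad_thresholds_rejected(self):
        with pytest.raises(InputError):
            detect_edges(_disc_image(), t_low=0.5, t_high=0.2)


class TestRemoveSmallComponents:
    def test_size_threshold_semantics(self):
        edges = np.zeros((60, 60), bool)
        edges[5, 5:10] = True  # 5 px component
        edges[30:35, 10:20] = True  # 50 px component
        out = remove_small_components(EdgeMap(edges), min_px=10)
        assert out.data.sum() == 50
        assert not out.data[5, 5:10].any()

    def test_min_px_one_is_identity(self):
        rng = np.random.default_rng(2)
        edges = rng.random((50, 50)) < 0.1
        out = remove_small_components(EdgeMap(edges), min_px=1)
        assert np.array_equal(out.data, edges)

    def test_matches_brute_force_component_filter(self):
        rng = np.random.default_rng(5)
        edges = rng.random((80, 80)) < 0.12
        min_px = 6
        out = remove_small_components(EdgeMap(edges), min_px=min_px)
        # oracle: label 8-connected components, keep those >= min_px
        lab, n = ndi.label(edges, structure=np.ones((3, 3), int))
        keep = np.zeros_like(edges)
        for i in range(1, n + 1):
            comp = lab == i
            if comp.sum() >= min_px:
                keep |= comp
        assert np.array_equal(out.data, keep)

    def test_min_px_zero_rejected(self):
        with pytest.raises(InputError):
            remove_small_components(EdgeMap(np.zeros((4, 4), bool)), min_px=0)


class TestProjectEdges:
    def test_single_map_identity(self):
        rng = np.random.default_rng(0)
        m = rng.random((30, 30)) < 0.2
        assert np.array_equal(project_edges([EdgeMap(m)]), m)

    def test_disjoint_edges_both_present(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[3, :] = True
        b[:, 7] = True
        proj = project_edges([EdgeMap(a, 0), EdgeMap(b, 1)])
        assert proj[3, :].all() and proj[:, 7].all()

    def test_equals_pixelwise_or_oracle(self):
        rng = np.random.default_rng(9)
        maps = [rng.random((40, 50)) < 0.15 for _ in range(5)]
        proj = project_edges([EdgeMap(m, i) for i, m in enumerate(maps)])
        oracle = np.zeros((40, 50), bool)
        for m in maps:
            for r in range(40):
                for c in range(50):
                    oracle[r, c] |= m[r, c]
        assert np.array_equal(proj, oracle)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(FormatError):
            project_edges([EdgeMap(np.zeros((4, 4), bool)),
                           EdgeMap(np.zeros((5, 4), bool), 1)])

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            project_edges([])


class TestContoursToObjects:
    def test_closed_ring_fills_to_disc_area(self):
        ring = boundary_ring(disc_mask(20, 64))
        seg = contours_to_objects(ring, close_radius=2, min_object_area=100)
        assert len(seg.objects) == 1
        area = seg.objects[0].area_px
        assert abs(area - math.pi * 20**2) / (math.pi * 20**2) <= 0.02

    def test_three_px_gap_bridged_by_closing(self):
        ring = boundary_ring(disc_mask(20, 64))
        top = np.nonzero(ring)[0].min()
        gap = ring.copy()
        gap[top:top + 2, 31:34] = False  # 3-px breach at the top
        assert ring.sum() - gap.sum() == 3
        seg = contours_to_objects(gap, close_radius=2, min_object_area=100)
        assert len(seg.objects) == 1
        assert seg.objects[0].area_px > 1000  # filled, not just the arc

    def test_small_blob_filtered_by_min_area(self):
        blob = np.zeros((40, 40), bool)
        blob[10:12, 10:15] = True  # 10 px
        seg = contours_to_objects(blob, close_radius=0, min_object_area=50)
        assert seg.objects == []

    def test_area_matches_label_pixel_count(self):
        ring = boundary_ring(disc_mask(15, 48))
        seg = contours_to_objects(ring, 2, 50)
        for o in seg.objects:
            assert o.area_px == int((seg.labels == o.object_id).sum())


class TestObjectCenter:
    def test_centered_disc(self):
        assert object_center(disc_mask(10, 65, (32, 32))) == (32, 32)

    def test_horizontal_line_tie_broken_to_left(self):
        mask = np.zeros((5, 11), bool)
        mask[2, 2:9] = True  # 1x7 line
        # brute force: distance to background is 1 for every pixel -> all tie
        center = object_center(mask)
        assert center == (2, 2)

    def test_center_attains_max_distance_everywhere(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            mask = ndi.binary_dilation(
                rng.random((40, 40)) < 0.02, iterations=rng.integers(2, 6)
            )
            mask = ndi.binary_fill_holes(mask)
            lab, n = ndi.label(mask)
            if n == 0:
                continue
            mask = lab == 1
            r, c = object_center(mask)
            dist = ndi.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
            assert mask[r, c]
            assert dist[r, c] == dist[mask].max()

    def test_brute_force_distance_oracle_on_line(self):
        mask = np.zeros((5, 11), bool)
        mask[2, 2:9] = True
        # oracle: for each pixel compute min distance to any background pixel
        pix = np.argwhere(mask)
        bg = np.argwhere(~np.pad(mask, 1))
        best = None
        for p in pix:
            d = np.sqrt(((bg - (p + 1)) ** 2).sum(axis=1)).min()
            if best is None or d > best[0] + 1e-12:
                best = (d, tuple(p))
        assert object_center(mask) == best[1]

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            object_center(np.zeros((5, 5), bool))


def _seg_from_mask(mask: np.ndarray):
    from organoidq.segmentation import SegmentationResult, _records_from_labels

    labels = ndi.label(mask, structure=np.ones((3, 3), int))[0].astype(np.int32)
    return SegmentationResult(labels, _records_from_labels(labels))


class TestSplitTouching:
    def test_single_disc_unchanged(self):
        seg = _seg_from_mask(disc_mask(20, 64))
        out = split_touching(seg, 15, 5.0, 200)
        assert len(out.objects) == 1
        assert out.objects[0].area_px == seg.objects[0].area_px

    def test_two_overlapping_discs_split_conserving_area(self):
        mask = np.zeros((100, 120), bool)
        rr, cc = np.mgrid[:100, :120]
        mask |= (rr - 50) ** 2 + (cc - 45) ** 2 <= 400
        mask |= (rr - 50) ** 2 + (cc - 75) ** 2 <= 400
        union_area = int(mask.sum())
        seg = _seg_from_mask(mask)
        out = split_touching(seg, 15, 5.0, 200)
        assert len(out.objects) == 2
        assert sum(o.area_px for o in out.objects) == union_area

    def test_dumbbell_below_separation_stays_single(self):
        mask = np.zeros((80, 100), bool)
        rr, cc = np.mgrid[:80, :100]
        mask |= (rr - 40) ** 2 + (cc - 42) ** 2 <= 121  # r=11, centers 8 apart
        mask |= (rr - 40) ** 2 + (cc - 50) ** 2 <= 121
        seg = _seg_from_mask(mask)
        out = split_touching(seg, min_peak_separation=10, min_peak_height=5.0,
                             min_object_area=50)
        assert len(out.objects) == 1

    def test_foreground_conserved(self, default_segmentation):
        seg = default_segmentation
        total = int((seg.labels > 0).sum())
        assert sum(o.area_px for o in seg.objects) == total


class TestSegmentField:
    def test_ten_disjoint_spheroids_recovered(self):
        cfg = SceneConfig(n_spheroid=10, n_budding=0, n_junk=0, seed=7)
        stack, truth = generate_scene(cfg)
        seg = segment_field(stack)
        assert len(seg.objects) == 10

    def test_blank_stack_yields_no_objects(self):
        stack, _ = generate_scene(SceneConfig(n_spheroid=0, n_budding=0,
                                              n_junk=0, seed=3))
        seg = segment_field(stack)
        assert seg.objects == []

    def test_deterministic(self, default_scene, default_segmentation):
        stack, _ = default_scene
        again = segment_field(stack, PipelineParams().segmentation)
        assert np.array_equal(again.labels, default_segmentation.labels)

    def test_label_partition_and_areas(self, default_segmentation):
        seg = default_segmentation
        present = set(np.unique(seg.labels)) - {0}
        assert present == set(seg.object_ids)
        for o in seg.objects:
            mask = seg.labels == o.object_id
            assert o.area_px == int(mask.sum())
            assert mask[o.center]  # center inside its object

    def test_recovery_on_no_overlap_scene(self, default_scene, default_segmentation):
        from organoidq import match_objects

        _, truth = default_scene
        matching = match_objects(default_segmentation, truth)
        nonjunk = truth.nonjunk_ids()
        assert all(matching[t] is not None for t in nonjunk)
        for t in nonjunk:
            rec = default_segmentation.get(matching[t])
            assert abs(rec.area_px - truth.areas[t]) / truth.areas[t] <= 0.05

    def test_min_object_area_monotonicity(self, default_scene):
        stack, _ = default_scene
        counts = []
        for area in (200, 900, 2500):
            p = SegmentationParams(min_object_area=area)
            counts.append(len(segment_field(stack, p).objects))
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[2] < counts[0]
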