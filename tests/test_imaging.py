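"""Imaging path: segmentation, labeling, arena detection, area filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import chemotax as ct
from chemotax.imaging import LabeledObject, otsu_threshold_hist

from conftest import match_centroids


def otsu_brute_force(counts: np.ndarray) -> int:
    """Exhaustive between-class-variance maximization over all 256 splits.

    Class 0 holds intensities <= t, class 1 intensities > t; variances are
    compared as exact rationals so near-ties cannot flip the argmax; the
    smallest maximizing t wins.
    """
    from fractions import Fraction

    best_t, best_v = 0, Fraction(-1)
    for t in range(255):
        lo = [int(v) for v in counts[: t + 1]]
        hi = [int(v) for v in counts[t + 1 :]]
        w0, w1 = sum(lo), sum(hi)
        if w0 == 0 or w1 == 0:
            continue
        mu0 = Fraction(sum(i * v for i, v in enumerate(lo)), w0)
        mu1 = Fraction(sum((t + 1 + i) * v for i, v in enumerate(hi)), w1)
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_maximizer(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 1000, size=256)
        counts[rng.integers(0, 256, size=rng.integers(0, 200))] = 0
        if np.count_nonzero(counts) < 2:
            counts[[10, 200]] = [5, 5]
        assert otsu_threshold_hist(counts) == otsu_brute_force(counts)

    def test_two_level_image(self):
        img = np.full((100, 100), 10, dtype=np.uint8)
        img.ravel()[:1000] = 200
        t = ct.otsu_threshold(img)
        assert 10 <= t < 200
        mask = ct.segment_foreground(img)
        assert mask.sum() == 1000 or mask.sum() >= 1000  # closing may fill gaps
        assert np.all(img[mask] == 200) or mask[img == 200].all()

    def test_constant_image_warns_and_returns_empty(self):
        img = np.full((50, 50), 128, dtype=np.uint8)
        with pytest.warns(UserWarning, match="constant image"):
            mask = ct.segment_foreground(img)
        assert not mask.any()

    def test_foreground_is_strictly_above_threshold(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, size=(60, 60)).astype(np.uint8)
        t = ct.otsu_threshold(img)
        from skimage.morphology import closing, footprint_rectangle

        expected = closing(img > t, footprint_rectangle((3, 3)))
        assert np.array_equal(ct.segment_foreground(img), expected)


class TestLabeling:
    def test_empty_mask_gives_no_objects(self):
        objects, _ = ct.label_components(np.zeros((20, 20), dtype=bool))
        assert objects == []

    def test_two_disjoint_squares_analytic_centroids(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:13, 14:17] = True
        objects, _ = ct.label_components(mask)
        assert len(objects) == 2
        objects.sort(key=lambda o: o.centroid_x)
        assert objects[0].area == objects[1].area == 9
        assert (objects[0].centroid_x, objects[0].centroid_y) == (3.0, 3.0)
        assert (objects[1].centroid_x, objects[1].centroid_y) == (15.0, 11.0)

    def test_synthetic_arena_object_count(self, full_scale_arena):
        spec, img, _ = full_scale_arena
        mask = ct.segment_foreground(img)
        objects, _ = ct.label_components(mask)
        assert len(objects) == spec.worm_count + 1  # worms + insert ring


class TestArenaDetection:
    def test_single_arena_w_matches_ground_truth(self, full_scale_arena, located_full_scale):
        _, _, gt = full_scale_arena
        det = located_full_scale[0].detection
        assert abs(det.w - gt.w_px) <= 2.0
        assert det.test_side == gt.test_side

    def test_apices_near_ground_truth(self, full_scale_arena, located_full_scale):
        _, _, gt = full_scale_arena
        det = located_full_scale[0].detection
        for found, true in zip((det.apex_test, det.apex_control), gt.apex_coords):
            assert abs(found[0] - true[0]) <= 2.0

    def test_multi_plate_row_major_ids(self, multi_plate_scan):
        img, truths = multi_plate_scan
        scan = ct.GrayscaleScan(img, dpi=150, image_id="M")
        s2 = (150 / 1200) ** 2
        tables = ct.locate_worms(
            scan, min_area=max(3, int(50 * s2)), max_area=max(12, int(2500 * s2)),
            wells_per_plate=4, expected_plates=2,
        )
        assert [t.arena_id for t in tables] == [
            f"M_{p}_{w}" for p in (1, 2) for w in "ABCD"
        ]
        # row-major detections align with the rendered lane order
        assert [t.count for t in tables] == [gt.worm_count for gt in truths]

    def test_blank_scan_raises_detection_error(self):
        img = np.full((200, 200), 20, dtype=np.uint8)
        img[50, 50] = 250  # a speck, but no insert
        scan = ct.GrayscaleScan(img, dpi=1200)
        with pytest.raises(ct.ArenaDetectionError, match="insert"):
            ct.locate_worms(scan)


class TestAreaFilter:
    def test_strict_bounds(self):
        objects = [
            LabeledObject(label=i, centroid_x=0, centroid_y=0, area=a, bbox=(0, 0, 1, 1))
            for i, a in enumerate([10, 50, 51, 2499, 2500, 3000])
        ]
        kept = ct.filter_worm_objects(objects)
        assert [o.area for o in kept] == [51, 2499]

    def test_empty_input(self):
        assert ct.filter_worm_objects([]) == []

    @given(st.lists(st.integers(1, 5000), max_size=50))
    def test_idempotent(self, areas):
        objects = [
            LabeledObject(label=i, centroid_x=0, centroid_y=0, area=a, bbox=(0, 0, 1, 1))
            for i, a in enumerate(areas)
        ]
        once = ct.filter_worm_objects(objects)
        assert ct.filter_worm_objects(once) == once

    def test_oversized_clump_excluded_from_location_table(self, full_scale_arena):
        spec, img, gt = full_scale_arena
        img = img.copy()
        # paint a worm-bright clump (> 2,500 px) in a free interior spot
        free = (gt.label_image == 0) & ~gt.insert_mask
        interior = np.zeros_like(free)
        (tx, ty), (cx, _) = gt.apex_coords
        x0, x1 = int(min(tx, cx)) + 400, int(max(tx, cx)) - 400
        interior[ty - 200 : ty + 200, x0:x1] = True
        from scipy.ndimage import minimum_filter

        ok = minimum_filter((free & interior).astype(np.uint8), size=90)
        ys, xs = np.nonzero(ok)
        r, c = ys[0], xs[0]
        img[r - 30 : r + 30, c - 30 : c + 30] = spec.worm_intensity
        tables = ct.locate_worms(
            ct.GrayscaleScan(img, dpi=1200, image_id="CL"), wells_per_plate=1
        )
        assert tables[0].count == spec.worm_count


class TestLocateWorms:
    def test_recovers_all_worms_within_tolerance(self, full_scale_arena, located_full_scale):
        spec, _, gt = full_scale_arena
        table = located_full_scale[0]
        assert table.count == spec.worm_count
        d = match_centroids(
            table.rows[["x_px", "y_px"]].to_numpy(), np.array(gt.true_centroids)
        )
        assert np.all(d <= 1.5)

    def test_count_conservation(self, full_scale_arena, located_full_scale):
        """Rows written equal the number of objects that pass the filter."""
        _, img, _ = full_scale_arena
        mask = ct.segment_foreground(img)
        objects, labels = ct.label_components(mask)
        scan = ct.GrayscaleScan(img, dpi=1200)
        dets = ct.detect_arenas(objects, scan, wells_per_plate=1, label_image=labels)
        non_insert = [o for o in objects if o.label != dets[0].insert_label]
        kept = ct.filter_worm_objects(non_insert)
        assert located_full_scale[0].count == len(kept)

    def test_rerun_is_deterministic(self, full_scale_arena):
        _, img, _ = full_scale_arena
        scan = ct.GrayscaleScan(img, dpi=1200, image_id="D")
        t1 = ct.locate_worms(scan, wells_per_plate=1)[0]
        t2 = ct.locate_worms(scan, wells_per_plate=1)[0]
        assert t1.rows.equals(t2.rows)

    def test_count_agreement_across_fixtures(self):
        """Detected vs true counts across small random fixtures: slope ~ 1."""
        true_counts, found_counts = [], []
        scale = 300 / 1200
        for i, n in enumerate(range(6, 46, 8)):
            spec = ct.SyntheticArenaSpec(
                dpi=300,
                image_width_px=int(3300 * scale),
                image_height_px=int(1100 * scale),
                worm_count=n,
                worm_area_range=(int(200 * scale**2), int(900 * scale**2)),
                seed=60 + i,
            )
            img, gt = ct.render_arena(spec)
            tab = ct.locate_worms(
                ct.GrayscaleScan(img, dpi=300),
                min_area=int(50 * scale**2), max_area=int(2500 * scale**2),
                wells_per_plate=1,
            )[0]
            true_counts.append(gt.worm_count)
            found_counts.append(tab.count)
        fit = ct.agreement_stats(true_counts, found_counts)
        assert abs(fit.slope - 1.0) < 0.05 and fit.r_squared > 0.99

    def test_tiff_round_trip(self, tmp_path, full_scale_arena):
        _, img, _ = full_scale_arena
        path = tmp_path / "scan.tiff"
        ct.write_scan(path, img)
        back = ct.read_scan(path)
        assert np.array_equal(back.pixels, img)
        assert back.image_id == "scan"
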