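"""Blob detection, adaptive flood fill, shape filter and weak labels."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_laplace, median_filter
from skimage.morphology import disk

from apobd import (
    BlobDetection,
    BlobParams,
    detect_blobs_log,
    floodfill_adaptive,
    generate_weak_labels,
    iou,
    median_remove_in_roi,
    rescale_to_8bit,
    shape_filter,
)
from apobd.blob_ops import RoICandidate

from conftest import cell_union


def gaussian_spot(shape, center, sigma, amp=200.0, bg=20.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return bg + amp * np.exp(-d2 / (2 * sigma**2))


def log_response_argmax(image, sigmas):
    """Brute-force scale-normalized LoG maximum over a sigma grid."""
    best = None
    for s in sigmas:
        resp = -(s**2) * gaussian_laplace(np.asarray(image, float), s)
        idx = np.unravel_index(np.argmax(resp), resp.shape)
        if best is None or resp[idx] > best[0]:
            best = (resp[idx], idx, s)
    return best[1], best[2]


class TestRescale:
    def test_full_16bit_range(self):
        img = np.array([[0.0, 65535.0]])
        out = rescale_to_8bit(img)
        np.testing.assert_allclose(out, [[0.0, 255.0]])

    def test_two_values_map_to_extremes(self):
        img = np.array([[100.0, 300.0], [100.0, 300.0]])
        out = rescale_to_8bit(img)
        assert set(np.unique(out)) == {0.0, 255.0}

    def test_constant_image_maps_to_zeros(self):
        assert rescale_to_8bit(np.full((4, 4), 7.0)).max() == 0.0


class TestDetectBlobs:
    def test_blank_image_gives_no_blobs(self):
        assert detect_blobs_log(np.zeros((64, 64))) == []

    def test_single_spot_matches_bruteforce_center(self):
        img = rescale_to_8bit(gaussian_spot((100, 120), (50, 60), sigma=2.0))
        blobs = detect_blobs_log(img)
        assert len(blobs) == 1
        ref_center, _ = log_response_argmax(
            img / 255.0, np.linspace(1.6, 6.0, 8))
        assert abs(blobs[0].center[0] - 50) <= 1
        assert abs(blobs[0].center[1] - 60) <= 1
        assert abs(blobs[0].center[0] - ref_center[0]) <= 1
        assert abs(blobs[0].center[1] - ref_center[1]) <= 1

    def test_dark_blob_detected_via_inversion(self):
        img = 255.0 - rescale_to_8bit(
            gaussian_spot((80, 80), (40, 40), sigma=2.5))
        blobs = detect_blobs_log(img)
        assert len(blobs) == 1
        assert blobs[0].polarity == -1

    def test_two_separated_spots(self):
        img = gaussian_spot((100, 100), (30, 30), 2.0) + gaussian_spot(
            (100, 100), (70, 70), 2.0) - 20.0
        blobs = detect_blobs_log(rescale_to_8bit(img))
        assert len(blobs) == 2

    def test_empty_sigma_range_errors(self):
        with pytest.raises(ValueError):
            detect_blobs_log(np.zeros((10, 10)), sigma_range=(3.0, 1.0))

    def test_circular_area_convention(self):
        b = BlobDetection(center=(0, 0), scale_sigma=2.0)
        assert b.circular_area_px == pytest.approx(np.pi * (2 * 2**0.5) ** 2)


class TestFloodfillAdaptive:
    def test_uniform_disk_recovered_exactly(self):
        img = np.full((60, 60), 50.0)
        rr, cc = np.mgrid[:60, :60]
        disk_mask = (rr - 30) ** 2 + (cc - 30) ** 2 <= 4.7**2  # 69 px
        img[disk_mask] = 200.0
        area = int(disk_mask.sum())
        blob = BlobDetection(center=(30.0, 30.0),
                             scale_sigma=np.sqrt(78 / np.pi) / np.sqrt(2))
        cand = floodfill_adaptive(img, blob, tolerance_grid=range(1, 150))
        np.testing.assert_array_equal(cand.mask, disk_mask)
        assert cand.area_px == area
        # any tolerance below the 150-step keeps the disk; smallest wins
        assert cand.tolerance_used == 1.0

    def test_zero_tolerance_gives_constant_region(self):
        img = np.zeros((20, 20))
        img[5:8, 5:8] = 9.0
        blob = BlobDetection(center=(6.0, 6.0), scale_sigma=1.2)
        cand = floodfill_adaptive(img, blob, tolerance_grid=[0.0])
        np.testing.assert_array_equal(cand.mask, img == 9.0)

    def test_background_seed_floods_connected_region(self):
        img = np.zeros((20, 20))
        img[10:, :] = 100.0
        blob = BlobDetection(center=(2.0, 2.0), scale_sigma=2.0)
        cand = floodfill_adaptive(img, blob, tolerance_grid=[255.0])
        assert cand.area_px == 400  # whole image within tolerance

    def test_seed_out_of_bounds_errors(self):
        blob = BlobDetection(center=(99.0, 5.0), scale_sigma=1.5)
        with pytest.raises(ValueError):
            floodfill_adaptive(np.zeros((20, 20)), blob)


def _cand(aspect, area):
    return RoICandidate(
        mask=np.ones((1, 1), bool), area_px=area, aspect_ratio=aspect,
        centroid=(0.0, 0.0), tolerance_used=1.0)


class TestShapeFilter:
    @pytest.mark.parametrize(
        "aspect,area,kept,reason",
        [
            (0.90, 100, True, None),
            (0.50, 100, False, "aspect"),
            (0.90, 300, False, "area"),
            (0.90, 10, False, "area"),
            (0.85, 20, True, None),     # boundaries inclusive
            (0.85, 200, True, None),
            (0.8499, 100, False, "aspect"),
        ],
    )
    def test_threshold_rules(self, aspect, area, kept, reason):
        k, r = shape_filter([_cand(aspect, area)])
        assert bool(k) == kept
        if not kept:
            assert reason in r[0].rejection_reason

    def test_filter_is_monotone_in_thresholds(self):
        rng = np.random.default_rng(10)
        cands = [_cand(rng.uniform(0.3, 1.0), int(rng.integers(5, 400)))
                 for _ in range(200)]
        base_kept, _ = shape_filter(cands)
        tighter_aspect, _ = shape_filter(cands, min_aspect=0.95)
        tighter_area, _ = shape_filter(cands, area_range=(40, 150))
        assert len(tighter_aspect) <= len(base_kept)
        assert len(tighter_area) <= len(base_kept)
        assert set(id(c) for c in tighter_aspect) <= set(id(c) for c in base_kept)


class TestMedianRemove:
    def test_spot_in_attention_erased_to_background(self):
        img = np.full((40, 40), 100.0)
        rr, cc = np.mgrid[:40, :40]
        spot = (rr - 20) ** 2 + (cc - 20) ** 2 <= 2**2
        img[spot] = 250.0
        attention = (rr - 20) ** 2 + (cc - 20) ** 2 <= 8**2
        out = median_remove_in_roi(img, attention, kernel_radius=3)
        assert np.all(np.abs(out[spot] - 100.0) <= 1.0)
        # oracle: disk-kernel median of the original image
        ref = median_filter(img, footprint=disk(3))
        np.testing.assert_array_equal(out[attention], ref[attention])

    def test_pixels_outside_attention_untouched(self):
        rng = np.random.default_rng(11)
        img = rng.random((30, 30)) * 255
        attention = np.zeros((30, 30), bool)
        attention[5:10, 5:10] = True
        out = median_remove_in_roi(img, attention)
        np.testing.assert_array_equal(out[~attention], img[~attention])

    def test_empty_attention_is_identity(self):
        img = np.random.default_rng(12).random((20, 20))
        np.testing.assert_array_equal(
            median_remove_in_roi(img, np.zeros((20, 20), bool)), img)

    def test_invalid_kernel_radius(self):
        with pytest.raises(ValueError):
            median_remove_in_roi(np.zeros((5, 5)), np.ones((5, 5), bool), 0)


def _flat_disk(img, center, radius, value):
    rr, cc = np.mgrid[: img.shape[0], : img.shape[1]]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    img[mask] = value
    return mask


class TestGenerateWeakLabels:
    def _frame_with_apobds(self):
        """3 in-band ApoBDs plus one oversized artifact, no cells."""
        img = np.full((160, 160), 500.0)
        masks = []
        for center in ((30, 30), (30, 120), (120, 30)):
            masks.append(_flat_disk(img, center, 4.5, 2000.0))  # ~63 px
        big = _flat_disk(img, (115, 115), 11.0, 2000.0)  # ~380 px: oversized
        return img, masks, big

    def test_counts_and_erasure(self):
        img, small_masks, big = self._frame_with_apobds()
        cells = np.zeros(img.shape, bool)
        attention = np.ones(img.shape, bool)
        entry = generate_weak_labels(img, cells, attention)
        assert entry.instances.n_instances == 3
        # oversized object erased toward the flat background
        img8 = rescale_to_8bit(img)
        bg_level = img8[0, 0]
        assert np.all(np.abs(entry.filtered_image[big] - bg_level) <= 1.0)
        # each kept instance overlaps one of the true small disks
        for i in range(1, 4):
            inst = entry.instances.instance(i)
            assert max(iou(inst, m) for m in small_masks) >= 0.5

    def test_kept_instance_pixels_never_modified(self):
        img, _, _ = self._frame_with_apobds()
        entry = generate_weak_labels(img, np.zeros(img.shape, bool),
                                     np.ones(img.shape, bool))
        img8 = rescale_to_8bit(img)
        kept_px = entry.instances.labels > 0
        np.testing.assert_array_equal(entry.filtered_image[kept_px],
                                      img8[kept_px])

    def test_blank_frame_is_identity(self):
        img = np.full((80, 80), 300.0)  # no blobs at all
        entry = generate_weak_labels(img, np.zeros(img.shape, bool),
                                     np.ones(img.shape, bool))
        assert entry.instances.n_instances == 0
        np.testing.assert_array_equal(entry.filtered_image,
                                      rescale_to_8bit(img))

    def test_blob_inside_cell_mask_excluded(self):
        img = np.full((80, 80), 500.0)
        spot = _flat_disk(img, (40, 40), 4.5, 2000.0)
        cells = np.zeros(img.shape, bool)
        cells[30:50, 30:50] = True
        entry = generate_weak_labels(img, cells, np.ones(img.shape, bool))
        assert entry.instances.n_instances == 0

    def test_recall_on_simulator_truth(self, event_sim):
        """Weak labels recover >=80% of simulated ApoBDs at IoU 0.5."""
        truth = event_sim.truth
        matched = total = 0
        for t in (3, 4, 5):
            frame = event_sim.video.frames[t]
            cells = cell_union(truth.cells, t, frame.shape)
            entry = generate_weak_labels(frame.phase, cells,
                                         np.ones(frame.shape, bool))
            ti = truth.apobd_instances[t]
            for i in range(1, ti.n_instances + 1):
                total += 1
                tm = ti.instance(i)
                best = 0.0
                for j in range(1, entry.instances.n_instances + 1):
                    best = max(best, iou(tm, entry.instances.instance(j)))
                matched += best >= 0.5
        assert total >= 3
        assert matched / total >= 0.8
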