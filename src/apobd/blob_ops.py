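"""Classical ApoBD detection operators and weak-label dataset generation.

Apoptotic bodies appear in phase contrast as small bright or dark blobs
outside the cell bodies.  This module detects them with a
scale-normalized Laplacian-of-Gaussian (LoG) filter run at both
polarities, grows a pixel mask for each detection by flood filling at an
adaptively chosen intensity tolerance, filters the masks by shape
(aspect ratio >= 0.85, area within 20-200 px), and assembles the
survivors into weak instance labels suitable for training a
segmentation model.  Detections that fail the shape filter are erased
from the image by a disk-kernel median blur restricted to an attention
region, so that a model trained on the filtered images never sees an
unannotated ApoBD-like object.

Free parameters the source procedure leaves open (LoG sigma range and
response threshold, flood-fill tolerance grid) default to values that
work well on the bundled simulator and are exposed on
:class:`BlobParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import median_filter
from skimage.feature import blob_log
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import flood

from .data_model import InstanceMask, mask_to_rle

__all__ = [
    "BlobDetection",
    "RoICandidate",
    "WeakLabelEntry",
    "BlobParams",
    "rescale_to_8bit",
    "detect_blobs_log",
    "floodfill_adaptive",
    "shape_filter",
    "median_remove_in_roi",
    "generate_weak_labels",
    "weak_labels_to_coco",
]

#: LoG blob radius convention: r = sqrt(2) * sigma.
LOG_RADIUS_FACTOR = math.sqrt(2.0)


@dataclass(frozen=True)
class BlobDetection:
    """One LoG detection: center, scale and the implied circular area."""

    center: Tuple[float, float]  # (row, col)
    scale_sigma: float
    polarity: int = 1  # +1 bright blob, -1 dark blob

    @property
    def radius(self) -> float:
        return LOG_RADIUS_FACTOR * self.scale_sigma

    @property
    def circular_area_px(self) -> float:
        return math.pi * self.radius**2


@dataclass
class RoICandidate:
    """A flood-filled blob region with its shape descriptors."""

    mask: np.ndarray
    area_px: int
    aspect_ratio: float
    centroid: Tuple[float, float]
    tolerance_used: float
    blob: Optional[BlobDetection] = None
    rejection_reason: Optional[str] = None


@dataclass
class WeakLabelEntry:
    """Filtered image plus the instance labels derived from kept RoIs."""

    filtered_image: np.ndarray
    instances: InstanceMask
    kept: List[RoICandidate]
    rejected: List[RoICandidate]


@dataclass(frozen=True)
class BlobParams:
    """Tunables of the detection / weak-label pipeline.

    ``min_sigma``..``max_sigma`` span ApoBD radii of roughly 2-8 px
    (areas 20-200 px) under the r = sqrt(2)*sigma convention.
    ``log_threshold`` applies to the scale-normalized LoG response of
    the image rescaled to [0, 1].
    """

    min_sigma: float = 1.6
    max_sigma: float = 6.0
    num_sigma: int = 8
    log_threshold: float = 0.12
    tolerance_grid: Tuple[float, ...] = tuple(float(t) for t in range(1, 51))
    min_aspect: float = 0.85
    area_range: Tuple[float, float] = (20.0, 200.0)
    kernel_radius: int = 3
    dedup_dist: float = 2.0
    erase_area_cap: float = 800.0  # larger floods are background escapes


def rescale_to_8bit(image: np.ndarray) -> np.ndarray:
    """Linearly map an image onto [0, 255] (min -> 0, max -> 255).

    A constant image maps to all zeros.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) * 255.0 / (hi - lo)


def detect_blobs_log(
    image: np.ndarray,
    sigma_range: Tuple[float, float] = (BlobParams.min_sigma, BlobParams.max_sigma),
    threshold: float = BlobParams.log_threshold,
    num_sigma: int = BlobParams.num_sigma,
    dedup_dist: float = BlobParams.dedup_dist,
) -> List[BlobDetection]:
    """Detect bright and dark blobs via scale-normalized LoG maxima.

    The detector runs on the image and on its inversion (ApoBDs appear
    in both polarities) and merges the two detection sets, dropping the
    weaker of any pair of centers closer than ``dedup_dist`` pixels.
    """
    if len(sigma_range) != 2 or sigma_range[1] < sigma_range[0]:
        raise ValueError("sigma_range must be a nonempty (min, max) pair")
    img = np.asarray(image, dtype=float) / 255.0
    hits: List[BlobDetection] = []
    for pol, plane in ((1, img), (-1, img.max() - img)):
        for r, c, s in blob_log(
            plane,
            min_sigma=sigma_range[0],
            max_sigma=sigma_range[1],
            num_sigma=num_sigma,
            threshold=threshold,
        ):
            hits.append(BlobDetection(center=(float(r), float(c)),
                                      scale_sigma=float(s), polarity=pol))
    # deduplicate across polarities by center distance
    kept: List[BlobDetection] = []
    for b in hits:
        dup = False
        for other in kept:
            d = math.dist(b.center, other.center)
            if d < dedup_dist:
                dup = True
                break
        if not dup:
            kept.append(b)
    return kept


def _aspect_ratio(mask: np.ndarray) -> Tuple[float, Tuple[float, float]]:
    """Minor/major axis ratio of the best-fit ellipse, and the centroid.

    A single pixel (zero-length major axis) counts as perfectly round
    (ratio 1); a strictly linear region has ratio 0.
    """
    props = regionprops(mask.astype(np.uint8))
    if not props:
        return 0.0, (float("nan"), float("nan"))
    p = props[0]
    centroid = (float(p.centroid[0]), float(p.centroid[1]))
    if p.axis_major_length == 0:
        return 1.0, centroid
    return float(p.axis_minor_length / p.axis_major_length), centroid


def floodfill_adaptive(
    image: np.ndarray,
    blob: BlobDetection,
    tolerance_grid: Sequence[float] = BlobParams.tolerance_grid,
) -> RoICandidate:
    """Flood fill from the blob center at the best intensity tolerance.

    For each tolerance, 4-connected pixels whose intensity differs from
    the seed pixel by at most the tolerance are accepted; the candidate
    whose pixel area is closest to the circular area implied by the blob
    scale wins, ties going to the smaller tolerance.
    """
    img = np.asarray(image, dtype=float)
    seed = (int(round(blob.center[0])), int(round(blob.center[1])))
    if not (0 <= seed[0] < img.shape[0] and 0 <= seed[1] < img.shape[1]):
        raise ValueError(f"blob seed {seed} outside image {img.shape}")
    if len(tolerance_grid) == 0:
        raise ValueError("tolerance_grid must be nonempty")
    target = blob.circular_area_px
    best_mask = None
    best_diff = math.inf
    for tol in sorted(tolerance_grid):
        mask = flood(img, seed, tolerance=tol, connectivity=1)
        area = int(np.count_nonzero(mask))
        diff = abs(area - target)
        if diff < best_diff:  # strict: ties keep the smaller tolerance
            best_mask, best_diff, best_tol, best_area = mask, diff, tol, area
        if area > target and area - target > best_diff:
            break  # flood area is monotone in tolerance; no better fit ahead
    aspect, centroid = _aspect_ratio(best_mask)
    return RoICandidate(
        mask=best_mask,
        area_px=best_area,
        aspect_ratio=aspect,
        centroid=centroid,
        tolerance_used=float(best_tol),
        blob=blob,
    )


def shape_filter(
    candidates: Iterable[RoICandidate],
    min_aspect: float = BlobParams.min_aspect,
    area_range: Tuple[float, float] = BlobParams.area_range,
) -> Tuple[List[RoICandidate], List[RoICandidate]]:
    """Keep round, ApoBD-sized RoIs; record a reason on each rejection.

    A candidate is kept iff ``aspect_ratio >= min_aspect`` and
    ``area_range[0] <= area_px <= area_range[1]`` (boundaries
    inclusive).  Low aspect ratios reject elongated noise such as
    nanowell edges; the area band rejects debris and merged regions.
    """
    kept: List[RoICandidate] = []
    rejected: List[RoICandidate] = []
    lo, hi = area_range
    for cand in candidates:
        reasons = []
        if cand.aspect_ratio < min_aspect:
            reasons.append("aspect")
        if not lo <= cand.area_px <= hi:
            reasons.append("area")
        if reasons:
            cand.rejection_reason = "+".join(reasons)
            rejected.append(cand)
        else:
            cand.rejection_reason = None
            kept.append(cand)
    return kept, rejected


def median_remove_in_roi(
    image: np.ndarray,
    attention: np.ndarray,
    kernel_radius: int = BlobParams.kernel_radius,
) -> np.ndarray:
    """Median-blur (disk kernel) only the pixels inside the attention mask.

    Pixels inside ``attention`` are replaced by the disk-kernel median
    of the *original* image at that pixel; pixels outside are returned
    bit-exactly unchanged.
    """
    img = np.asarray(image, dtype=float)
    att = np.asarray(attention, dtype=bool)
    if att.shape != img.shape:
        raise ValueError("attention geometry does not match image")
    if kernel_radius < 1:
        raise ValueError("kernel_radius must be >= 1")
    if not att.any():
        return img.copy()
    blurred = median_filter(img, footprint=disk(kernel_radius))
    return np.where(att, blurred, img)


def _masked_median_erase(
    image: np.ndarray,
    erase: np.ndarray,
    protected: np.ndarray,
    kernel_radius: int,
) -> np.ndarray:
    """Erase a region by disk-kernel medians of non-object neighbors.

    A plain median blur is edge-preserving and cannot remove an object
    wider than its kernel, so the region is peeled from the outside in:
    each erased pixel takes the disk-kernel median of pixels that are
    neither awaiting erasure nor protected (kept-instance pixels), and
    freshly filled pixels become sources for the next, deeper layer.
    Pixels outside ``erase`` are returned unchanged.
    """
    img = np.asarray(image, dtype=float).copy()
    remaining = np.asarray(erase, dtype=bool).copy()
    valid = ~remaining & ~np.asarray(protected, dtype=bool)
    if not remaining.any():
        return img
    h, w = img.shape
    fp = disk(kernel_radius).astype(bool)
    offsets = np.argwhere(fp) - kernel_radius
    from scipy.ndimage import binary_dilation

    while remaining.any():
        rim = remaining & binary_dilation(valid, structure=fp)
        if not rim.any():
            break  # unreachable pixels (fully enclosed by protected area)
        coords = np.argwhere(rim)
        fills = []
        for r, c in coords:
            neigh = [
                img[r + dr, c + dc]
                for dr, dc in offsets
                if 0 <= r + dr < h and 0 <= c + dc < w
                and valid[r + dr, c + dc]
            ]
            fills.append(float(np.median(neigh)))
        for (r, c), v in zip(coords, fills):
            img[r, c] = v
        valid |= rim
        remaining &= ~rim
    return img


def generate_weak_labels(
    frame: np.ndarray,
    cell_masks: np.ndarray,
    attention: np.ndarray,
    params: BlobParams = BlobParams(),
) -> WeakLabelEntry:
    """Run the full weak-label pipeline on one phase-contrast frame.

    Steps: rescale to 8-bit -> LoG blob detection (both polarities) ->
    drop blobs centered inside a cell mask -> adaptive flood fill per
    blob -> shape filter -> instance labels from the kept RoIs.
    Rejected RoIs (and the footprints of their source blobs) are erased
    from the returned image by disk-kernel median filling restricted to
    the attention mask (see :func:`_masked_median_erase`); pixels of
    kept instances are never modified.
    """
    img8 = rescale_to_8bit(frame)
    cells = np.asarray(cell_masks, dtype=bool)
    att = np.asarray(attention, dtype=bool)
    if cells.shape != img8.shape or att.shape != img8.shape:
        raise ValueError("frame, cell_masks and attention must share geometry")

    blobs = detect_blobs_log(
        img8,
        sigma_range=(params.min_sigma, params.max_sigma),
        threshold=params.log_threshold,
        num_sigma=params.num_sigma,
        dedup_dist=params.dedup_dist,
    )
    extracellular = [
        b for b in blobs
        if not cells[int(round(b.center[0])), int(round(b.center[1]))]
    ]
    candidates = [
        floodfill_adaptive(img8, b, params.tolerance_grid)
        for b in extracellular
    ]
    kept, rejected = shape_filter(
        candidates, min_aspect=params.min_aspect, area_range=params.area_range
    )

    labels = np.zeros(img8.shape, dtype=int)
    final_kept: List[RoICandidate] = []
    for cand in kept:
        fresh = cand.mask & (labels == 0)
        if not fresh.any():
            continue  # fully swallowed by an earlier kept instance
        labels[cand.mask] = len(final_kept) + 1
        final_kept.append(cand)
    instances = InstanceMask.from_labels(labels)
    kept_pixels = labels > 0

    erase = np.zeros(img8.shape, dtype=bool)
    rr, cc = np.ogrid[: img8.shape[0], : img8.shape[1]]
    for cand in rejected:
        # a flood that escaped into the background is not an object to
        # erase: fall back to the blob's circular footprint
        if cand.area_px <= params.erase_area_cap:
            erase |= cand.mask
        if cand.blob is not None:
            r0, c0 = cand.blob.center
            erase |= (rr - r0) ** 2 + (cc - c0) ** 2 <= (
                cand.blob.radius + params.kernel_radius) ** 2
    erase &= att
    erase &= ~kept_pixels
    filtered = _masked_median_erase(
        img8, erase, kept_pixels, params.kernel_radius)
    return WeakLabelEntry(
        filtered_image=filtered,
        instances=instances,
        kept=final_kept,
        rejected=rejected,
    )


def weak_labels_to_coco(
    entries: Sequence[Tuple[str, WeakLabelEntry]],
) -> dict:
    """Assemble weak-label entries into a COCO-style annotation dict.

    ``entries`` pairs an image identifier (e.g. file name) with its
    :class:`WeakLabelEntry`.  Instances are stored as uncompressed
    row-major run-length masks under the standard ``images`` /
    ``annotations`` / ``categories`` keys.
    """
    images, annotations = [], []
    ann_id = 1
    for img_id, (name, entry) in enumerate(entries, start=1):
        h, w = entry.instances.labels.shape
        images.append({"id": img_id, "file_name": name,
                       "height": h, "width": w})
        for i in range(1, entry.instances.n_instances + 1):
            mask = entry.instances.instance(i)
            rows, cols = np.nonzero(mask)
            bbox = [int(cols.min()), int(rows.min()),
                    int(cols.max() - cols.min() + 1),
                    int(rows.max() - rows.min() + 1)]
            annotations.append({
                "id": ann_id,
                "image_id": img_id,
                "category_id": 1,
                "segmentation": mask_to_rle(mask),
                "area": int(mask.sum()),
                "bbox": bbox,
                "iscrowd": 0,
            })
            ann_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "apoptotic_body"}],
    }
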