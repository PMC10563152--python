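"""Per-frame ApoBD presence classification and evaluation utilities.

The pipeline's first stage decides, frame by frame, whether a nanowell
shows released apoptotic bodies.  This module defines the classifier
contract (any callable mapping a frame to a label and a score), a
classical baseline built on the blob operators — positive when at least
``min_blobs`` extracellular blobs survive the shape filter — plus the
nanowell-grouped k-fold splitter and the standard classification
metrics used to compare classifiers.  Deep-network classifiers can be
plugged in through the same contract; nothing downstream depends on how
the per-frame labels were produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .blob_ops import (
    BlobParams,
    detect_blobs_log,
    floodfill_adaptive,
    rescale_to_8bit,
    shape_filter,
)
from .data_model import MultiChannelFrame

__all__ = [
    "FrameLabel",
    "ConfusionCounts",
    "baseline_classifier",
    "count_filtered_blobs",
    "grouped_kfold",
    "classification_metrics",
    "attention_provider",
]


@dataclass(frozen=True)
class FrameLabel:
    """One per-frame classification decision."""

    nanowell_id: str
    frame_index: int
    positive: bool  # ApoBD present
    score: float = 0.0  # in [0, 1]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def count_filtered_blobs(
    phase: np.ndarray,
    cell_masks: np.ndarray,
    params: BlobParams = BlobParams(),
) -> int:
    """Number of extracellular blobs surviving the shape filter."""
    img8 = rescale_to_8bit(phase)
    cells = np.asarray(cell_masks, dtype=bool)
    if cells.shape != img8.shape:
        raise ValueError("cell_masks geometry does not match frame")
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
    kept, _ = shape_filter(
        candidates, min_aspect=params.min_aspect, area_range=params.area_range
    )
    return len(kept)


def baseline_classifier(
    frame: MultiChannelFrame,
    cell_masks: np.ndarray,
    params: BlobParams = BlobParams(),
    min_blobs: int = 1,
    saturation: int = 5,
    nanowell_id: str = "",
) -> FrameLabel:
    """Classical ApoBD-presence classifier.

    Positive iff at least ``min_blobs`` extracellular blobs survive the
    shape filter on the phase channel; the score is the kept-blob count
    normalized by ``saturation`` and clipped to [0, 1].
    """
    n_kept = count_filtered_blobs(frame.phase, cell_masks, params)
    return FrameLabel(
        nanowell_id=nanowell_id,
        frame_index=frame.frame_index,
        positive=n_kept >= min_blobs,
        score=min(1.0, n_kept / saturation),
    )


def grouped_kfold(
    items: Sequence,
    k: int = 5,
    seed: int = 0,
) -> List[int]:
    """Assign items to k folds, keeping each nanowell in a single fold.

    ``items`` may be objects with a ``nanowell_id`` attribute or plain
    nanowell-id strings.  Nanowells are shuffled with ``seed`` and dealt
    round-robin, so fold sizes differ by at most one nanowell.  Returns
    the fold index of each item.
    """
    ids = [
        it.nanowell_id if hasattr(it, "nanowell_id") else it for it in items
    ]
    wells = sorted(set(ids))
    if k < 1 or k > len(wells):
        raise ValueError(
            f"k={k} must lie in 1..{len(wells)} (distinct nanowells)"
        )
    rng = np.random.default_rng(seed)
    order = [wells[i] for i in rng.permutation(len(wells))]
    fold_of: Dict[Hashable, int] = {w: i % k for i, w in enumerate(order)}
    return [fold_of[i] for i in ids]


def classification_metrics(counts: ConfusionCounts) -> Dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion counts.

    A metric with a zero denominator (e.g. precision with no positive
    predictions) is reported as NaN.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    total = counts.total
    if total == 0:
        raise ValueError("no evaluated frames")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan") if (np.isnan(precision) or np.isnan(recall)) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision,
            "recall": recall, "f1": f1}


def attention_provider(
    frame: MultiChannelFrame,
    params: BlobParams = BlobParams(),
) -> np.ndarray:
    """Baseline saliency mask: all blob footprints, dilated.

    Stands in for a gradient-based class-activation map: the union of
    every LoG detection's circular footprint, dilated by the median
    kernel radius so that downstream in-RoI blurring is fully covered.
    A frame without detections yields an empty mask.
    """
    img8 = rescale_to_8bit(frame.phase)
    blobs = detect_blobs_log(
        img8,
        sigma_range=(params.min_sigma, params.max_sigma),
        threshold=params.log_threshold,
        num_sigma=params.num_sigma,
        dedup_dist=params.dedup_dist,
    )
    mask = np.zeros(img8.shape, dtype=bool)
    rr, cc = np.ogrid[: img8.shape[0], : img8.shape[1]]
    for b in blobs:
        r0, c0 = b.center
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= (b.radius + 1) ** 2
    if mask.any():
        mask = binary_dilation(mask, structure=disk(params.kernel_radius))
    return mask
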