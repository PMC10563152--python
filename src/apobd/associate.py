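"""Mapping segmented apoptotic bodies to the dying cell.

Once an apoptosis event has been called, the released vesicles identify
the cell that produced them: ApoBDs cluster around their cell of
origin, so the cell with the least average centroid distance to the
ApoBD instances is assigned as the apoptotic cell.  A majority vote
over a short window of frames (the three frames from onset, by
default) removes rare per-frame failures such as a missed cell
detection.

The reference segmenter here is the classical blob pipeline (LoG
detection, adaptive flood fill, shape filter) applied to the raw phase
frame; a trained instance-segmentation network can be substituted
through the same ``ApoBDInstanceSet`` interface.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .blob_ops import (
    BlobParams,
    detect_blobs_log,
    floodfill_adaptive,
    rescale_to_8bit,
    shape_filter,
)
from .data_model import CellRecord, InstanceMask, MultiChannelFrame

__all__ = [
    "ApoBDInstanceSet",
    "AssociationResult",
    "segment_apobds_reference",
    "mean_distance",
    "assign_apoptotic_cell",
    "majority_vote",
    "associate_event",
]


@dataclass
class ApoBDInstanceSet:
    """Segmented ApoBD instances of one frame, with centroids."""

    frame_index: int
    instances: InstanceMask
    centroids: List[Tuple[float, float]]

    @property
    def n(self) -> int:
        return self.instances.n_instances


@dataclass
class AssociationResult:
    """Per-frame winners, the vote record and the final assignment."""

    per_frame_winner: Dict[int, Optional[int]]
    per_frame_distances: Dict[int, Dict[int, float]]
    apoptotic_cell_id: Optional[int]


def segment_apobds_reference(
    frame: MultiChannelFrame,
    cell_masks: np.ndarray,
    params: BlobParams = BlobParams(),
) -> ApoBDInstanceSet:
    """Segment ApoBDs in one frame with the classical blob pipeline.

    Kept candidates become instances; blobs centered inside a cell mask
    are excluded, so instance pixels seeded outside cells never start
    from the cell body.
    """
    img8 = rescale_to_8bit(frame.phase)
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
    labels = np.zeros(img8.shape, dtype=int)
    for i, cand in enumerate(kept, start=1):
        labels[cand.mask & ~cells] = i
    instances = InstanceMask.from_labels(labels)
    return ApoBDInstanceSet(
        frame_index=frame.frame_index,
        instances=instances,
        centroids=instances.centroids(),
    )


def mean_distance(cell: CellRecord, apobds: ApoBDInstanceSet) -> float:
    """Mean Euclidean distance from the cell centroid to ApoBD centroids."""
    if apobds.n == 0:
        raise ValueError("no ApoBD instances to measure against")
    t = apobds.frame_index
    if not cell.present(t):
        raise ValueError(f"cell {cell.cell_id} absent in frame {t}")
    c = cell.centroids[t]
    return float(np.mean([math.dist(c, a) for a in apobds.centroids]))


def assign_apoptotic_cell(
    cells: Sequence[CellRecord],
    apobds: ApoBDInstanceSet,
) -> int:
    """The cell with the least average distance to the ApoBDs.

    Only cells present in the ApoBD frame compete; exact ties go to the
    smaller cell id.
    """
    present = [c for c in cells if c.present(apobds.frame_index)]
    if not present:
        raise ValueError("no cells present in frame")
    dists = {c.cell_id: mean_distance(c, apobds) for c in present}
    return min(dists, key=lambda cid: (dists[cid], cid))


def majority_vote(
    per_frame_winners: Sequence[Optional[int]],
    per_frame_distances: Optional[Sequence[Dict[int, float]]] = None,
) -> int:
    """Final apoptotic cell from per-frame winners.

    Frames without ApoBDs abstain (winner ``None``).  The cell winning
    a strict majority of the voting frames is returned; without a
    strict majority the tie is broken toward the cell with the smallest
    mean of its per-frame mean distances over the frames where it was a
    candidate.
    """
    votes = [w for w in per_frame_winners if w is not None]
    if not votes:
        raise ValueError("all frames abstained; no vote possible")
    counts = Counter(votes)
    top_id, top_n = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n * 2 > len(votes):
        return top_id
    if per_frame_distances is None:
        return top_id  # no distances available: fall back to plurality
    means: Dict[int, List[float]] = {}
    for dists in per_frame_distances:
        for cid, d in (dists or {}).items():
            means.setdefault(cid, []).append(d)
    if not means:
        return top_id
    return min(means, key=lambda cid: (float(np.mean(means[cid])), cid))


def associate_event(
    frames: Sequence[MultiChannelFrame],
    cells: Sequence[CellRecord],
    onset_frame: int,
    window: int = 3,
    params: BlobParams = BlobParams(),
) -> AssociationResult:
    """Identify the apoptotic cell over a voting window starting at onset.

    Segments ApoBDs in each of the ``window`` frames from
    ``onset_frame``, assigns a per-frame winner by least average
    distance, and resolves the final identity by majority vote.
    """
    winners: Dict[int, Optional[int]] = {}
    all_dists: Dict[int, Dict[int, float]] = {}
    for t in range(onset_frame, min(onset_frame + window, len(frames))):
        frame = frames[t]
        cell_union = np.zeros(frame.shape, dtype=bool)
        for c in cells:
            if c.present(t):
                cell_union |= np.asarray(c.masks[t], dtype=bool)
        apobds = segment_apobds_reference(frame, cell_union, params)
        if apobds.n == 0:
            winners[t] = None
            all_dists[t] = {}
            continue
        present = [c for c in cells if c.present(t)]
        dists = {c.cell_id: mean_distance(c, apobds) for c in present}
        all_dists[t] = dists
        winners[t] = min(dists, key=lambda cid: (dists[cid], cid))
    frame_order = sorted(winners)
    final = None
    if any(w is not None for w in winners.values()):
        final = majority_vote(
            [winners[t] for t in frame_order],
            [all_dists[t] for t in frame_order],
        )
    return AssociationResult(
        per_frame_winner=winners,
        per_frame_distances=all_dists,
        apoptotic_cell_id=final,
    )
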