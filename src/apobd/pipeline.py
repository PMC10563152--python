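"""End-to-end nanowell analysis: classify -> onset -> associate -> profile.

Glues the stage modules together for one nanowell video, given cell
records (from the bundled fluorescence segmenter, the simulator truth,
or an external cell-tracking pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .associate import AssociationResult, associate_event
from .blob_ops import BlobParams
from .classify import FrameLabel, baseline_classifier
from .data_model import ApoptosisEvent, CellRecord, NanowellVideo
from .interaction import (
    annexin_validity,
    classify_localization,
    detect_contacts,
)
from .temporal import OnsetCall, detect_onset

__all__ = ["VideoAnalysis", "analyze_video"]


@dataclass
class VideoAnalysis:
    """Everything the pipeline derives from one nanowell video."""

    frame_labels: List[FrameLabel]
    onset: OnsetCall
    association: Optional[AssociationResult]
    event: Optional[ApoptosisEvent]


def analyze_video(
    video: NanowellVideo,
    cells: Sequence[CellRecord],
    params: BlobParams = BlobParams(),
    min_run: int = 3,
    contact_min_frames: int = 4,
    vote_window: int = 3,
) -> VideoAnalysis:
    """Run the full label-free apoptosis pipeline on one video.

    Per-frame ApoBD presence is decided by the baseline classifier,
    the onset called by the ``min_run`` consecutive-frame rule, the
    apoptotic cell identified by least-average-distance association
    with majority voting, killing attributed when a qualified
    effector-target contact overlaps or precedes the onset, and the
    Annexin-V channel (when present) assessed at the onset frame
    against the apoptotic cell mask.
    """
    labels: List[FrameLabel] = []
    for frame in video.frames:
        t = frame.frame_index
        union = np.zeros(frame.shape, dtype=bool)
        for c in cells:
            if c.present(t):
                union |= np.asarray(c.masks[t], dtype=bool)
        labels.append(baseline_classifier(
            frame, union, params=params, nanowell_id=video.nanowell_id))

    onset = detect_onset([int(l.positive) for l in labels], min_run=min_run)
    if not onset.is_event:
        return VideoAnalysis(frame_labels=labels, onset=onset,
                             association=None, event=None)

    assoc = associate_event(video.frames, cells, onset.onset_frame,
                            window=vote_window, params=params)
    cell_id = assoc.apoptotic_cell_id

    effectors = [c for c in cells if c.cell_type == "effector"]
    targets = [c for c in cells if c.cell_type == "target"]
    contacts = detect_contacts(effectors, targets, len(video),
                               min_frames=contact_min_frames)
    killing = any(
        ci.target_id == cell_id and ci.start_frame <= onset.onset_frame
        for ci in contacts
    ) if cell_id is not None else bool(contacts)

    event = ApoptosisEvent(
        nanowell_id=video.nanowell_id,
        onset_frame=onset.onset_frame,
        apoptotic_cell_id=cell_id,
        killing=killing,
    )
    frame0 = video.frames[onset.onset_frame]
    dying = next((c for c in cells if c.cell_id == cell_id), None)
    if "annexin" in frame0.channels and dying is not None \
            and dying.present(onset.onset_frame):
        assessment = annexin_validity(
            frame0.channels["annexin"], dying.masks[onset.onset_frame])
        event.annexin_valid = assessment.valid
        event.annexin_iou = assessment.iou_vs_cell
        if assessment.valid:
            event.annexin_distribution = classify_localization(assessment)
    return VideoAnalysis(frame_labels=labels, onset=onset,
                         association=assoc, event=event)
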