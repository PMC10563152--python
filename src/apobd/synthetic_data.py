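"""Synthetic nanowell videos and binary label sequences with known truth.

The simulator emulates the imagery of a nanowell cytotoxicity assay:
a phase-contrast channel showing 1-5 textured cell bodies and, after a
configurable apoptosis onset frame, a burst of small bright or dark
extracellular vesicles (apoptotic bodies, ApoBDs); fluorescence channels
for the effector dye, the target dye and Annexin-V that are consistent
with the ground-truth cell masks.  Roughly 30% of apoptotic events carry
a detectable Annexin-V signal, matching what is observed in real
melanoma-TIL killing assays; the rest leave the Annexin channel dark.

Appearance is stylized, not photorealistic: cells are dark textured
disks with a bright halo, ApoBDs are soft-edged spots of random polarity
whose pixel areas are drawn inside the downstream shape-filter band.
Every ground-truth quantity a downstream stage predicts (onset frame,
apoptotic cell identity, per-frame ApoBD instance masks, cell tracks,
contact intervals, Annexin validity) is returned alongside the video.

The module also generates pure binary per-frame label sequences for
evaluating the temporal onset-calling rule in isolation: fixed-length
sequences in which at most a configured fraction of frames is positive,
the event class containing a qualifying run of consecutive positives and
the non-event class containing none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .data_model import (
    CellRecord,
    InstanceMask,
    MultiChannelFrame,
    NanowellVideo,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimOutput",
    "simulate_video",
    "simulate_label_sequences",
    "longest_positive_run",
    "first_run_start",
]

# Rendering levels (16-bit scale).  Chosen for a phase-contrast-like
# look with comfortable contrast against the default read noise.
_BG_PHASE = 1000.0
_CELL_INTERIOR = 600.0
_CELL_HALO = 1700.0
_APOBD_AMP = 600.0
_FLUOR_LEVEL = 3000.0
_FLUOR_BG = 100.0
_ANNEXIN_LEVEL = 2500.0


@dataclass
class SimConfig:
    """Parameters of one simulated nanowell video.

    Defaults describe a typical killing-assay nanowell: a 256x256 crop
    containing one effector and two target cells of 8-14 px radius,
    releasing 3-12 ApoBDs of 20-200 px area at the onset frame, with a
    30% chance that the event is Annexin-V positive.
    """

    image_size: Tuple[int, int] = (256, 256)
    n_effectors: int = 1
    n_targets: int = 2
    cell_radius_px: Tuple[float, float] = (8.0, 14.0)
    apobd_area_px: Tuple[float, float] = (20.0, 200.0)
    apobd_count_at_burst: Tuple[int, int] = (3, 12)
    onset_frame: Optional[int] = None
    n_frames: int = 10
    annexin_positive_prob: float = 0.3
    annexin_localized_prob: float = 0.5
    motion_sigma_px: float = 1.0
    noise_sigma: float = 25.0
    contact_frames: int = 0  # pre-onset effector/target overlap run (killing)
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.cell_radius_px, self.apobd_area_px,
                       self.apobd_count_at_burst):
            if hi < lo:
                raise ValueError("range must be nonempty (lo <= hi)")
        for p in (self.annexin_positive_prob, self.annexin_localized_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.onset_frame is not None and not (
            0 <= self.onset_frame < self.n_frames
        ):
            raise ValueError("onset_frame must satisfy 0 <= onset < n_frames")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated video."""

    onset_frame: Optional[int]
    apoptotic_cell_id: Optional[int]
    cells: List[CellRecord]
    apobd_instances: Dict[int, InstanceMask]  # frame -> instances
    contact_intervals: List[Tuple[int, int, int, int]]  # (eff, tgt, start, end)
    annexin_valid: bool
    annexin_localized: bool


@dataclass
class SimOutput:
    video: NanowellVideo
    truth: SimTruth


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _disk_mask(shape: Tuple[int, int], center: Tuple[float, float],
               radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _soft_disk(shape: Tuple[int, int], center: Tuple[float, float],
               radius: float) -> np.ndarray:
    """Disk with a ~1 px linear edge ramp, for flood-fill-friendly spots."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    return np.clip((radius + 0.5 - d), 0.0, 1.0)


def longest_positive_run(labels: Sequence[int]) -> int:
    """Length of the longest run of consecutive positive labels."""
    best = cur = 0
    for v in labels:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def first_run_start(labels: Sequence[int], min_run: int) -> Optional[int]:
    """Start index of the first run of >= min_run positives, or None."""
    cur = 0
    for i, v in enumerate(labels):
        cur = cur + 1 if v else 0
        if cur >= min_run:
            return i - min_run + 1
    return None


# ---------------------------------------------------------------------------
# Video simulation
# ---------------------------------------------------------------------------


def _place_cells(cfg: SimConfig, rng: np.random.Generator
                 ) -> Tuple[List[float], List[np.ndarray]]:
    """Radii and initial centers for all cells, non-overlapping."""
    h, w = cfg.image_size
    n = cfg.n_effectors + cfg.n_targets
    radii = [rng.uniform(*cfg.cell_radius_px) for _ in range(n)]
    centers: List[np.ndarray] = []
    for i in range(n):
        # keep a margin wide enough for the ApoBD corona to stay in-field
        margin = radii[i] + 30
        if 2 * margin + 20 > min(h, w):
            margin = radii[i] + 6
        for _ in range(500):
            cand = np.array([rng.uniform(margin, h - margin),
                             rng.uniform(margin, w - margin)])
            if all(
                np.linalg.norm(cand - c) >= radii[i] + radii[j] + 6
                for j, c in enumerate(centers)
            ):
                centers.append(cand)
                break
        else:
            raise RuntimeError(
                "could not place cells without overlap; "
                "reduce cell count/radius or enlarge the image"
            )
    return radii, centers


def _cell_tracks(cfg: SimConfig, rng: np.random.Generator,
                 radii: List[float], centers: List[np.ndarray],
                 apoptotic_idx: Optional[int],
                 ) -> List[List[np.ndarray]]:
    """Random-walk tracks; the dying cell stops moving at onset.

    During a simulated killing contact, the first effector is pulled onto
    the apoptotic target so their masks overlap for the contact run.
    """
    h, w = cfg.image_size
    n = len(radii)
    tracks: List[List[np.ndarray]] = [[] for _ in range(n)]
    pos = [c.copy() for c in centers]
    onset = cfg.onset_frame
    contact_start = (
        None if (cfg.contact_frames <= 0 or onset is None)
        else max(0, onset - cfg.contact_frames)
    )
    for t in range(cfg.n_frames):
        for i in range(n):
            freeze = (
                apoptotic_idx is not None
                and i == apoptotic_idx
                and onset is not None
                and t >= onset
            )
            if t > 0 and not freeze:
                step = rng.normal(0.0, cfg.motion_sigma_px, size=2)
                pos[i] = pos[i] + step
            margin = radii[i] + 3
            pos[i] = np.clip(pos[i], margin, [h - margin, w - margin])
            tracks[i].append(pos[i].copy())
        # killing contact: effector 0 overlaps the apoptotic target
        if (
            contact_start is not None
            and contact_start <= t < onset  # type: ignore[operator]
            and cfg.n_effectors >= 1
            and apoptotic_idx is not None
        ):
            eff, tgt = 0, apoptotic_idx
            direction = tracks[eff][t] - tracks[tgt][t]
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 0 else np.array([1.0, 0.0])
            gap = 0.7 * (radii[eff] + radii[tgt])  # guaranteed mask overlap
            tracks[eff][t] = tracks[tgt][t] + direction * gap
            pos[eff] = tracks[eff][t].copy()
    return tracks


def _place_apobds(cfg: SimConfig, rng: np.random.Generator,
                  radii: List[float], tracks: List[List[np.ndarray]],
                  apoptotic_idx: int) -> List[Tuple[np.ndarray, float, float]]:
    """(center, radius, polarity) per ApoBD, clear of all post-onset cells."""
    h, w = cfg.image_size
    onset = cfg.onset_frame
    assert onset is not None
    # keep clear of every cell position from onset to the end
    keepout: List[Tuple[np.ndarray, float]] = []
    for i, track in enumerate(tracks):
        for t in range(onset, cfg.n_frames):
            keepout.append((track[t], radii[i]))
    n_apobds = int(rng.integers(cfg.apobd_count_at_burst[0],
                                cfg.apobd_count_at_burst[1] + 1))
    anchor = tracks[apoptotic_idx][onset]
    r_cell = radii[apoptotic_idx]
    placed: List[Tuple[np.ndarray, float, float]] = []
    for _ in range(n_apobds):
        area = rng.uniform(*cfg.apobd_area_px)
        rad = math.sqrt(area / math.pi)
        ok = False
        for attempt in range(400):
            slack = min(attempt / 40.0, 10.0)  # bounded ring widening
            dist = rng.uniform(r_cell + rad + 3,
                               r_cell + rad + 16 + slack)
            ang = rng.uniform(0, 2 * math.pi)
            cand = anchor + dist * np.array([math.sin(ang), math.cos(ang)])
            if not (rad + 4 <= cand[0] <= h - rad - 4
                    and rad + 4 <= cand[1] <= w - rad - 4):
                continue
            if any(np.linalg.norm(cand - c) < rad + cr + 4
                   for c, cr in keepout):
                continue
            if any(np.linalg.norm(cand - pc) < rad + pr + 6
                   for pc, pr, _ in placed):
                continue
            ok = True
            break
        if ok:
            polarity = 1.0 if rng.random() < 0.5 else -1.0
            placed.append((cand, rad, polarity))
    if not placed:
        raise RuntimeError("could not place any ApoBD around the dying cell")
    return placed


def simulate_video(config: SimConfig) -> SimOutput:
    """Render one nanowell video together with its ground truth.

    Deterministic given ``config.seed``.  When ``onset_frame`` is set, a
    randomly chosen target cell (or any cell, if no targets are
    configured) releases a burst of ApoBDs visible from the onset frame
    onward; with probability ``annexin_positive_prob`` the event also
    lights up the Annexin-V channel, either evenly over the dying cell
    or localized toward the nearest effector.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    n_cells = cfg.n_effectors + cfg.n_targets
    if n_cells < 1:
        raise ValueError("need at least one cell")

    radii, centers = _place_cells(cfg, rng)
    # cell ids: effectors 1..nE, targets nE+1..nE+nT
    cell_types = ["effector"] * cfg.n_effectors + ["target"] * cfg.n_targets
    apoptotic_idx: Optional[int] = None
    if cfg.onset_frame is not None:
        target_idxs = [i for i, ty in enumerate(cell_types) if ty == "target"]
        pool = target_idxs if target_idxs else list(range(n_cells))
        apoptotic_idx = int(rng.choice(pool))
    tracks = _cell_tracks(cfg, rng, radii, centers, apoptotic_idx)

    apobds: List[Tuple[np.ndarray, float, float]] = []
    if cfg.onset_frame is not None:
        apobds = _place_apobds(cfg, rng, radii, tracks, apoptotic_idx)

    annexin_valid = False
    annexin_localized = False
    if cfg.onset_frame is not None:
        annexin_valid = bool(rng.random() < cfg.annexin_positive_prob)
        annexin_localized = bool(rng.random() < cfg.annexin_localized_prob)

    frames: List[MultiChannelFrame] = []
    cells = [CellRecord(cell_id=i + 1, cell_type=cell_types[i])
             for i in range(n_cells)]
    apobd_instances: Dict[int, InstanceMask] = {}

    for t in range(cfg.n_frames):
        phase = np.full((h, w), _BG_PHASE)
        eff_chan = np.full((h, w), _FLUOR_BG)
        tgt_chan = np.full((h, w), _FLUOR_BG)
        ann_chan = np.zeros((h, w))
        cell_masks_t: List[np.ndarray] = []
        for i in range(n_cells):
            c = tracks[i][t]
            mask = _disk_mask((h, w), tuple(c), radii[i])
            cell_masks_t.append(mask)
            interior = _disk_mask((h, w), tuple(c), radii[i] - 1.5)
            halo = mask & ~interior
            texture = rng.normal(0.0, 60.0, size=(h, w))
            phase[interior] = _CELL_INTERIOR + texture[interior]
            phase[halo] = _CELL_HALO
            fluor = _soft_disk((h, w), tuple(c), radii[i]) * _FLUOR_LEVEL
            if cell_types[i] == "effector":
                eff_chan += fluor
            else:
                tgt_chan += fluor
            cells[i].masks[t] = mask
            cells[i].centroids[t] = (float(c[0]), float(c[1]))

        # ApoBD burst, visible from the onset frame onward
        if cfg.onset_frame is not None and t >= cfg.onset_frame:
            labels = np.zeros((h, w), dtype=int)
            for k, (pc, rad, pol) in enumerate(apobds, start=1):
                spot = _soft_disk((h, w), tuple(pc), rad)
                phase += pol * _APOBD_AMP * spot
                labels[_disk_mask((h, w), tuple(pc), rad)] = k
            apobd_instances[t] = InstanceMask(labels=labels,
                                             n_instances=len(apobds))

        # Annexin-V: nonzero only for annexin-valid events, from onset on
        if annexin_valid and t >= cfg.onset_frame:  # type: ignore[operator]
            dying = cell_masks_t[apoptotic_idx]
            if annexin_localized:
                patch = _localized_annexin_region(
                    cfg, tracks, radii, apoptotic_idx, t)
            else:
                patch = dying
            signal = np.where(patch, _ANNEXIN_LEVEL, 0.0)
            signal = gaussian_filter(signal, 1.0)
            signal += np.where(signal > 0,
                               rng.normal(0, cfg.noise_sigma, (h, w)), 0.0)
            ann_chan += np.clip(signal, 0, None)

        phase += rng.normal(0.0, cfg.noise_sigma, size=(h, w))
        eff_chan += rng.normal(0.0, cfg.noise_sigma, size=(h, w))
        tgt_chan += rng.normal(0.0, cfg.noise_sigma, size=(h, w))
        frames.append(MultiChannelFrame(
            phase=np.clip(phase, 0, 65535),
            channels={
                "effector": np.clip(eff_chan, 0, 65535),
                "target": np.clip(tgt_chan, 0, 65535),
                "annexin": np.clip(ann_chan, 0, 65535),
            },
            frame_index=t,
        ))

    video = NanowellVideo(
        nanowell_id=f"sim_{cfg.seed:06d}", frames=frames)
    contacts = _scan_contacts(cells, cfg.n_effectors, cfg.n_frames)
    truth = SimTruth(
        onset_frame=cfg.onset_frame,
        apoptotic_cell_id=None if apoptotic_idx is None else apoptotic_idx + 1,
        cells=cells,
        apobd_instances=apobd_instances,
        contact_intervals=contacts,
        annexin_valid=annexin_valid,
        annexin_localized=annexin_localized,
    )
    return SimOutput(video=video, truth=truth)


def _localized_annexin_region(cfg: SimConfig, tracks, radii,
                              apoptotic_idx: int, t: int) -> np.ndarray:
    """Membrane patch of the dying cell facing the nearest effector.

    The patch hugs the cell boundary from the inside (Annexin-V binds
    the dying cell's membrane), sized at ~55% of the cell radius so a
    localized event stays detectable (mask IoU above the 0.1 validity
    bound) yet clearly below the 0.5 even-distribution bound.
    """
    h, w = cfg.image_size
    c_dying = tracks[apoptotic_idx][t]
    r_cell = radii[apoptotic_idx]
    others = [tracks[i][t] for i in range(cfg.n_effectors)] or [
        np.array([h / 2.0, w / 2.0])]
    nearest = min(others, key=lambda c: np.linalg.norm(c - c_dying))
    direction = nearest - c_dying
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 0 else np.array([1.0, 0.0])
    r_patch = 0.55 * r_cell
    spot_center = c_dying + direction * (r_cell - r_patch)
    return _disk_mask((h, w), tuple(spot_center), r_patch)


def _scan_contacts(cells: List[CellRecord], n_effectors: int,
                   n_frames: int) -> List[Tuple[int, int, int, int]]:
    """Maximal mask-overlap runs for every effector/target pair."""
    intervals = []
    effectors = [c for c in cells if c.cell_type == "effector"]
    targets = [c for c in cells if c.cell_type == "target"]
    for e in effectors:
        for g in targets:
            start = None
            for t in range(n_frames):
                overlap = (
                    e.present(t) and g.present(t)
                    and bool(np.any(e.masks[t] & g.masks[t]))
                )
                if overlap and start is None:
                    start = t
                elif not overlap and start is not None:
                    intervals.append((e.cell_id, g.cell_id, start, t - 1))
                    start = None
            if start is not None:
                intervals.append((e.cell_id, g.cell_id, start, n_frames - 1))
    return intervals


# ---------------------------------------------------------------------------
# Binary label-sequence generation
# ---------------------------------------------------------------------------


def simulate_label_sequences(
    n_per_class: int,
    length: int = 10,
    max_positive_fraction: float = 0.5,
    min_run: int = 3,
    seed: int = 0,
) -> List[Tuple[List[int], bool, Optional[int]]]:
    """Generate event and non-event binary label sequences.

    Returns ``n_per_class`` event sequences followed by ``n_per_class``
    non-event sequences, each a tuple ``(labels, is_event, onset)``.
    Event sequences contain at least one run of ``min_run`` consecutive
    positive frames and ``onset`` is the first frame of the first such
    run; non-event sequences contain no qualifying run and onset None.
    In both classes the number of positive frames never exceeds
    ``ceil(max_positive_fraction * length)``; the positive count is
    drawn uniformly over the feasible counts and positions are placed by
    rejection sampling until the class constraint holds.
    """
    if length < min_run:
        raise ValueError("length must be >= min_run")
    if not 0 < max_positive_fraction <= 1:
        raise ValueError("max_positive_fraction must lie in (0, 1]")
    max_pos = math.ceil(max_positive_fraction * length)
    if min_run > max_pos:
        raise ValueError(
            f"infeasible: min_run={min_run} exceeds allowed positives {max_pos}"
        )
    rng = np.random.default_rng(seed)
    out: List[Tuple[List[int], bool, Optional[int]]] = []
    for is_event in (True, False):
        counts = (range(min_run, max_pos + 1) if is_event
                  else range(0, max_pos + 1))
        counts = list(counts)
        for _ in range(n_per_class):
            for _attempt in range(10_000):
                n_pos = int(rng.choice(counts))
                labels = [0] * length
                for idx in rng.choice(length, size=n_pos, replace=False):
                    labels[int(idx)] = 1
                qualifies = longest_positive_run(labels) >= min_run
                if qualifies == is_event:
                    break
            else:  # pragma: no cover - rejection sampling exhausted
                raise RuntimeError("rejection sampling failed")
            onset = first_run_start(labels, min_run) if is_event else None
            out.append((labels, is_event, onset))
    return out
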