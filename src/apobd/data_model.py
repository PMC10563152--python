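"""Core domain types, mask/image metrics and nanowell video I/O.

A nanowell video is an ordered stack of multi-channel frames: one
phase-contrast channel plus up to three fluorescence channels (effector
membrane dye, target membrane dye, Annexin-V).  All downstream stages —
blob detection, classification, onset calling, association — operate on
these containers and on the three pixel metrics defined here
(intersection-over-union of binary masks, Pearson correlation of
intensity images, Otsu thresholding).

Conventions
-----------
* Coordinates are ``(row, col)``, 0-based.
* A binary mask is a 2-D boolean :class:`numpy.ndarray`; a pixel is in
  or out, there is no sub-pixel membership.
* Binarization against an Otsu threshold is strict: ``pixel > t`` is
  foreground, ties fall to background.
* Raw input is 16-bit grayscale TIFF; internal processing is float.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import tifffile

__all__ = [
    "CHANNEL_NAMES",
    "MultiChannelFrame",
    "NanowellVideo",
    "InstanceMask",
    "CellRecord",
    "ApoptosisEvent",
    "iou",
    "pcc",
    "otsu_threshold",
    "binarize",
    "read_video",
    "write_video",
    "mask_to_rle",
    "rle_to_mask",
]

#: Channel names recognised in the on-disk layout.
CHANNEL_NAMES = ("phase", "effector", "target", "annexin")

_FRAME_RE = re.compile(r"^frame_(\d+)_([a-z]+)\.tif{1,2}$")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MultiChannelFrame:
    """One time point of a nanowell: phase image plus fluorescence channels.

    Parameters
    ----------
    phase
        2-D non-negative intensity array (phase contrast).
    channels
        Mapping from channel name (any subset of ``effector``, ``target``,
        ``annexin``) to a 2-D intensity array of the same shape.
    frame_index
        Non-negative position of this frame in its video.
    """

    phase: np.ndarray
    channels: Dict[str, np.ndarray] = field(default_factory=dict)
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValueError("phase image must be 2-D")
        if not np.all(np.isfinite(self.phase)) or np.any(self.phase < 0):
            raise ValueError("phase intensities must be finite and >= 0")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        for name, img in list(self.channels.items()):
            img = np.asarray(img, dtype=float)
            if img.shape != self.phase.shape:
                raise ValueError(
                    f"channel {name!r} shape {img.shape} != phase {self.phase.shape}"
                )
            if not np.all(np.isfinite(img)) or np.any(img < 0):
                raise ValueError(f"channel {name!r} has non-finite or negative values")
            self.channels[name] = img

    @property
    def shape(self) -> Tuple[int, int]:
        return self.phase.shape


@dataclass
class NanowellVideo:
    """Ordered multi-channel frames for one nanowell (default 5 min/frame)."""

    nanowell_id: str
    frames: List[MultiChannelFrame]
    frame_interval_minutes: float = 5.0

    def __post_init__(self) -> None:
        if self.frame_interval_minutes <= 0:
            raise ValueError("frame_interval_minutes must be positive")
        for t, fr in enumerate(self.frames):
            if fr.frame_index != t:
                raise ValueError("frame_index values must be 0..n-1 consecutive")
            if fr.shape != self.frames[0].shape:
                raise ValueError("all frames must share geometry")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.frames[0].shape


@dataclass
class InstanceMask:
    """Labelled pixel mask: 0 = background, instances labelled 1..n."""

    labels: np.ndarray
    n_instances: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        present = set(np.unique(self.labels).tolist()) - {0}
        expected = set(range(1, self.n_instances + 1))
        if present != expected:
            raise ValueError(
                f"labels present {sorted(present)} != expected 1..{self.n_instances}"
            )

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "InstanceMask":
        """Build from an arbitrary labelled array, relabelling to 1..n."""
        labels = np.asarray(labels)
        ids = [int(v) for v in np.unique(labels) if v != 0]
        out = np.zeros_like(labels, dtype=int)
        for new, old in enumerate(ids, start=1):
            out[labels == old] = new
        return cls(labels=out, n_instances=len(ids))

    def instance(self, i: int) -> np.ndarray:
        """Boolean mask of instance ``i`` (1-based)."""
        if not 1 <= i <= self.n_instances:
            raise IndexError(f"instance {i} out of range 1..{self.n_instances}")
        return self.labels == i

    def centroids(self) -> List[Tuple[float, float]]:
        """(row, col) centroid of each instance, in label order."""
        return [
            tuple(np.mean(np.argwhere(self.labels == i), axis=0))
            for i in range(1, self.n_instances + 1)
        ]


@dataclass
class CellRecord:
    """One tracked cell: per-frame mask and centroid where present."""

    cell_id: int
    cell_type: str  # "effector" | "target"
    masks: Dict[int, np.ndarray] = field(default_factory=dict)
    centroids: Dict[int, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_id <= 0:
            raise ValueError("cell_id must be a positive integer")
        if self.cell_type not in ("effector", "target"):
            raise ValueError("cell_type must be 'effector' or 'target'")
        for t, mask in self.masks.items():
            if t in self.centroids:
                r, c = self.centroids[t]
                rows, cols = np.nonzero(mask)
                if len(rows) and not (
                    rows.min() <= r <= rows.max() and cols.min() <= c <= cols.max()
                ):
                    raise ValueError(
                        f"cell {self.cell_id} frame {t}: centroid outside mask bbox"
                    )

    def present(self, t: int) -> bool:
        return t in self.masks


@dataclass
class ApoptosisEvent:
    """A called apoptosis event and its Annexin-V assessment."""

    nanowell_id: str
    onset_frame: int
    apoptotic_cell_id: Optional[int] = None
    killing: bool = False
    annexin_valid: Optional[bool] = None
    annexin_iou: Optional[float] = None
    annexin_distribution: Optional[str] = None  # "even" | "localized"


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks.

    ``IoU(A, B) = |A ∩ B| / |A ∪ B|``.  Raises if the masks differ in
    geometry or are both empty (the ratio is undefined).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask geometry mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("IoU undefined: both masks empty")
    return np.count_nonzero(a & b) / union


def pcc(image_x: np.ndarray, image_y: np.ndarray) -> float:
    """Pearson correlation coefficient of two images over flattened pixels."""
    x = np.asarray(image_x, dtype=float).ravel()
    y = np.asarray(image_y, dtype=float).ravel()
    if np.asarray(image_x).shape != np.asarray(image_y).shape:
        raise ValueError("image geometry mismatch")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("PCC undefined for a zero-variance input")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu's threshold: maximises between-class variance of the histogram.

    The threshold is searched exhaustively over the distinct gray
    levels of the image (no histogram binning), with pixels strictly
    above the threshold counting as foreground; this keeps the strictly
    -greater binarization convention exact for integer-valued data.
    Binarize downstream as ``pixel > threshold``.  Raises on a constant
    image, where no threshold separates two classes.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("Otsu threshold undefined for a constant image")
    uniq, counts = np.unique(img.ravel(), return_counts=True)
    n = img.size
    csum = np.cumsum(counts)
    wsum = np.cumsum(uniq * counts)
    n_bg = csum[:-1].astype(float)
    n_fg = n - n_bg
    mu_bg = wsum[:-1] / n_bg
    mu_fg = (wsum[-1] - wsum[:-1]) / n_fg
    score = n_bg * n_fg * (mu_bg - mu_fg) ** 2
    i = int(np.argmax(score))
    # midpoint between the two classes' nearest levels, so the threshold
    # falls strictly between background and foreground values
    return float(0.5 * (uniq[i] + uniq[i + 1]))


def binarize(image: np.ndarray, threshold: Optional[float] = None) -> np.ndarray:
    """Binarize an image, by Otsu's threshold when none is given."""
    if threshold is None:
        threshold = otsu_threshold(image)
    return np.asarray(image, dtype=float) > threshold


# ---------------------------------------------------------------------------
# Video I/O:  <nanowell_id>/frame_<t>_<channel>.tif
# ---------------------------------------------------------------------------


def write_video(video: NanowellVideo, path: str | Path) -> Path:
    """Write a video as per-frame 16-bit TIFFs under ``path/nanowell_id/``.

    Layout: ``<nanowell_id>/frame_<t>_<channel>.tif`` with channel in
    ``{phase, effector, target, annexin}``.
    """
    root = Path(path) / video.nanowell_id
    root.mkdir(parents=True, exist_ok=True)
    for fr in video.frames:
        planes = {"phase": fr.phase, **fr.channels}
        for name, img in planes.items():
            arr = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
            tifffile.imwrite(root / f"frame_{fr.frame_index:04d}_{name}.tif", arr)
    meta = {
        "nanowell_id": video.nanowell_id,
        "n_frames": len(video),
        "frame_interval_minutes": video.frame_interval_minutes,
        "channels": sorted(video.frames[0].channels),
    }
    (root / "video.json").write_text(json.dumps(meta, indent=1))
    return root


def read_video(path: str | Path) -> NanowellVideo:
    """Read a nanowell video written in the per-frame TIFF layout.

    Raises if frame numbering has a gap or a channel file present for one
    frame is missing for another.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"no such video directory: {root}")
    found: Dict[int, Dict[str, Path]] = {}
    for f in root.iterdir():
        m = _FRAME_RE.match(f.name)
        if m:
            t, chan = int(m.group(1)), m.group(2)
            if chan not in CHANNEL_NAMES:
                raise ValueError(f"unknown channel {chan!r} in {f.name}")
            found.setdefault(t, {})[chan] = f
    if not found:
        raise FileNotFoundError(f"no frame TIFFs found under {root}")
    indices = sorted(found)
    if indices != list(range(len(indices))):
        missing = sorted(set(range(indices[-1] + 1)) - set(indices))
        raise ValueError(f"gap in frame numbering: missing frames {missing}")
    channels = set(found[0])
    if "phase" not in channels:
        raise ValueError("frame 0 lacks a phase channel file")
    frames = []
    for t in indices:
        if set(found[t]) != channels:
            raise ValueError(
                f"frame {t}: channels {sorted(found[t])} != frame 0 {sorted(channels)}"
            )
        planes = {c: tifffile.imread(found[t][c]) for c in channels}
        frames.append(
            MultiChannelFrame(
                phase=planes.pop("phase"), channels=planes, frame_index=t
            )
        )
    interval = 5.0
    meta_file = root / "video.json"
    if meta_file.exists():
        interval = float(json.loads(meta_file.read_text()).get(
            "frame_interval_minutes", 5.0))
    return NanowellVideo(
        nanowell_id=root.name, frames=frames, frame_interval_minutes=interval
    )


# ---------------------------------------------------------------------------
# Run-length mask codec for the JSON annotation sidecar
# ---------------------------------------------------------------------------


def mask_to_rle(mask: np.ndarray) -> dict:
    """Encode a boolean mask as uncompressed row-major run lengths.

    The counts alternate background/foreground starting with background,
    matching the common uncompressed-RLE convention of COCO-style
    annotation files (but row-major, consistent with our (row, col)
    convention).
    """
    m = np.asarray(mask, dtype=bool).ravel()
    counts: List[int] = []
    val = False
    run = 0
    for px in m:
        if px == val:
            run += 1
        else:
            counts.append(run)
            val = px
            run = 1
    counts.append(run)
    return {"size": list(np.asarray(mask).shape), "counts": counts}


def rle_to_mask(rle: Mapping) -> np.ndarray:
    """Decode :func:`mask_to_rle` output back to a boolean mask."""
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for run in rle["counts"]:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    if pos != h * w:
        raise ValueError("RLE counts do not cover the mask")
    return flat.reshape(h, w)
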