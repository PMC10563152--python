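"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the library code paths (and, where feasible,
vectorized shortcuts) so they can serve as oracles for the package's
metrics and the onset detector.
"""

from __future__ import annotations

import numpy as np


def iou_bruteforce(a, b) -> float:
    """Pixel-counting IoU with an explicit loop."""
    a = np.asarray(a, dtype=bool).ravel()
    b = np.asarray(b, dtype=bool).ravel()
    inter = union = 0
    for x, y in zip(a.tolist(), b.tolist()):
        if x and y:
            inter += 1
        if x or y:
            union += 1
    if union == 0:
        raise ZeroDivisionError
    return inter / union


def pcc_bruteforce(x, y) -> float:
    """Pearson correlation from explicit sum formulas."""
    xs = [float(v) for v in np.asarray(x).ravel()]
    ys = [float(v) for v in np.asarray(y).ravel()]
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    vx = sum((a - mx) ** 2 for a in xs)
    vy = sum((b - my) ** 2 for b in ys)
    return cov / (vx * vy) ** 0.5


def otsu_bruteforce(image) -> float:
    """Exhaustive search of the between-class-variance maximizer.

    Scans every distinct gray level as a candidate threshold (pixels
    strictly above the threshold are foreground) and returns the
    candidate maximizing  w_bg * w_fg * (mu_bg - mu_fg)^2.
    """
    vals = np.sort(np.asarray(image, dtype=float).ravel())
    levels = np.unique(vals)
    best_t, best_v = None, -1.0
    for t in levels[:-1]:  # top level leaves an empty foreground
        bg = vals[vals <= t]
        fg = vals[vals > t]
        v = len(bg) * len(fg) * (bg.mean() - fg.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return float(best_t)


def onset_bruteforce(labels, min_run=3):
    """Scan every window of length min_run; return first all-positive start."""
    labels = list(labels)
    for start in range(0, len(labels) - min_run + 1):
        if all(labels[start : start + min_run]):
            return start
    return None
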