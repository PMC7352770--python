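"""Independent oracles used by the test suite.

The maxima enumerator here is deliberately written as an exhaustive
pixel-by-pixel scan with its own plateau flood fill, sharing no code path
with the package's counter beyond the Gaussian blur preprocessing.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import gaussian


def enumerate_maxima(
    gamma: np.ndarray,
    labels: np.ndarray,
    blur_sigma: float,
    prominence: float,
) -> dict[int, int]:
    """Exhaustive local-maxima count per nucleus.

    A maximum is a pixel, or a connected plateau of equal-valued pixels
    counted once, whose value is >= all 8-neighbors (plateaus with any
    strictly higher adjacent pixel are shoulders, not maxima).  The plateau's
    representative pixel (row-major first) must lie in a nucleus, and the
    height above the within-nucleus minimum of the blurred channel must
    exceed ``prominence`` times the nucleus' (max - min) range.
    """
    img = gaussian(np.asarray(gamma, dtype=float), sigma=blur_sigma, preserve_range=True)
    h, w = img.shape
    pad = np.pad(img, 1, constant_values=-np.inf)
    shifts = [
        pad[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dy, dx) != (0, 0)
    ]
    neigh_max = np.maximum.reduce(shifts)
    strict = img > neigh_max
    ties = img == neigh_max

    reps: list[tuple[int, int]] = [tuple(p) for p in np.argwhere(strict)]
    visited = np.zeros((h, w), dtype=bool)
    for r0, c0 in np.argwhere(ties & ~strict):
        if visited[r0, c0]:
            continue
        v = img[r0, c0]
        stack = [(int(r0), int(c0))]
        visited[r0, c0] = True
        component = []
        is_max = True
        while stack:
            y, x = stack.pop()
            component.append((y, x))
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == dx == 0:
                        continue
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        if img[yy, xx] == v:
                            if not visited[yy, xx]:
                                visited[yy, xx] = True
                                stack.append((yy, xx))
                        elif img[yy, xx] > v:
                            is_max = False
        if is_max:
            reps.append(min(component))

    stats = {}
    for l in np.unique(labels):
        if l == 0:
            continue
        vals = img[labels == l]
        stats[int(l)] = (vals.min(), vals.max())
    counts = {l: 0 for l in stats}
    for r, c in reps:
        l = int(labels[r, c])
        if l == 0:
            continue
        bg, mx = stats[l]
        span = mx - bg
        if span > 0 and (img[r, c] - bg) > prominence * span:
            counts[l] += 1
    return counts


def match_points(truth_pts, detected_pts, tol: float = 3.0) -> int:
    """Greedy nearest-neighbor matching of detected to true spot positions
    within ``tol`` px; returns the number of matched pairs."""
    truth = [tuple(map(float, p)) for p in truth_pts]
    det = [tuple(map(float, p)) for p in detected_pts]
    matched = 0
    used = set()
    for t in truth:
        best, best_d = None, tol
        for j, d in enumerate(det):
            if j in used:
                continue
            dist = np.hypot(t[0] - d[0], t[1] - d[1])
            if dist <= best_d:
                best, best_d = j, dist
        if best is not None:
            used.add(best)
            matched += 1
    return matched
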