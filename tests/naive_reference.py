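"""Naive per-pixel reference implementations of the segmentation operators.

Everything here is written with explicit double loops and breadth-first
flood fills, independently of the vectorised operators, and is used as the
exactness oracle: on the same inputs the reference and the package must
produce bit-identical masks. Reference statistics (means/SDs) are taken
with numpy over pixel values collected in row-major order, which is the
same accumulation the vectorised code performs via boolean indexing.
"""

from __future__ import annotations

from collections import deque

import numpy as np

FOUR = ((-1, 0), (1, 0), (0, -1), (0, 1))
EIGHT = FOUR + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def naive_centroid(mask: np.ndarray) -> tuple[float, float]:
    rows, cols = [], []
    nr, nc = mask.shape
    for r in range(nr):
        for c in range(nc):
            if mask[r, c]:
                rows.append(r)
                cols.append(c)
    return float(np.mean(np.array(rows, dtype=float))), float(np.mean(np.array(cols, dtype=float)))


def _angle(r, c, center, spacing):
    dr = (r - center[0]) * spacing[0]
    dc = (c - center[1]) * spacing[1]
    return float(np.degrees(np.arctan2(dr, dc))) % 360.0


def _ang_diff(a, b):
    return abs((a - b + 180.0) % 360.0 - 180.0)


def naive_place_remote_roi(myo, injured_center, width, spacing=(1.0, 1.0)):
    center = naive_centroid(myo)
    target = (injured_center + 180.0) % 360.0
    nr, nc = myo.shape
    roi = np.zeros_like(myo, dtype=bool)
    for r in range(nr):
        for c in range(nc):
            if myo[r, c]:
                if width == 360.0 or _ang_diff(_angle(r, c, center, spacing), target) <= width / 2.0:
                    roi[r, c] = True
    return roi


def _collect(values, mask):
    out = []
    nr, nc = mask.shape
    for r in range(nr):
        for c in range(nc):
            if mask[r, c]:
                out.append(values[r, c])
    return np.array(out, dtype=float)


def naive_mean_sd(values, mask):
    sample = _collect(values, mask)
    return float(np.mean(sample)), float(np.std(sample, ddof=1))


def naive_segment_aar(t1, myo, roi, multiplier=2.0):
    mean, sd = naive_mean_sd(t1, roi)
    thr = mean + multiplier * sd
    nr, nc = myo.shape
    aar = np.zeros_like(myo, dtype=bool)
    for r in range(nr):
        for c in range(nc):
            if myo[r, c] and not roi[r, c] and t1[r, c] > thr:
                aar[r, c] = True
    return aar, thr


def _flood_from_border(blocked: np.ndarray) -> np.ndarray:
    """Pixels 4-connected to the image border through ``~blocked``."""
    nr, nc = blocked.shape
    reached = np.zeros_like(blocked, dtype=bool)
    queue = deque()
    for r in range(nr):
        for c in (0, nc - 1):
            if not blocked[r, c] and not reached[r, c]:
                reached[r, c] = True
                queue.append((r, c))
    for c in range(nc):
        for r in (0, nr - 1):
            if not blocked[r, c] and not reached[r, c]:
                reached[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in FOUR:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not blocked[rr, cc] and not reached[rr, cc]:
                reached[rr, cc] = True
                queue.append((rr, cc))
    return reached


def naive_ring_holes(mask: np.ndarray, myo: np.ndarray) -> np.ndarray:
    outside = _flood_from_border(myo)
    cavity = ~myo & ~outside
    enclosing = mask | cavity
    background = _flood_from_border(enclosing)
    return ~enclosing & ~background & myo


def naive_segment_lge(lge_si, myo, roi, multiplier=5.0, mvo_multiplier=2.0):
    mean, sd = naive_mean_sd(lge_si, roi)
    thr = mean + multiplier * sd
    nr, nc = myo.shape
    initial = np.zeros_like(myo, dtype=bool)
    for r in range(nr):
        for c in range(nc):
            if myo[r, c] and lge_si[r, c] > thr:
                initial[r, c] = True
    mvo_thr = mean + mvo_multiplier * sd
    holes = naive_ring_holes(initial, myo)
    mvo = np.zeros_like(myo, dtype=bool)
    for r in range(nr):
        for c in range(nc):
            if holes[r, c] and lge_si[r, c] < mvo_thr:
                mvo[r, c] = True
    return initial | mvo, thr, mvo


def _components(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    """4-connected components as pixel lists (BFS, row-major discovery)."""
    nr, nc = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(nr):
        for c in range(nc):
            if mask[r, c] and not seen[r, c]:
                comp = []
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    rr, cc = queue.popleft()
                    comp.append((rr, cc))
                    for dr, dc in FOUR:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < nr and 0 <= c2 < nc and mask[r2, c2] and not seen[r2, c2]:
                            seen[r2, c2] = True
                            queue.append((r2, c2))
                comps.append(comp)
    return comps


def naive_segment_imh(t2star, aar, t2star_cutoff=20.0, multiplier=2.0):
    nr, nc = aar.shape
    eroded = np.zeros_like(aar, dtype=bool)
    for r in range(nr):
        for c in range(nc):
            if aar[r, c]:
                ok = True
                for dr, dc in FOUR:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < nr and 0 <= cc < nc and aar[rr, cc]):
                        ok = False
                        break
                eroded[r, c] = ok
    periphery = aar & ~eroded
    mean, sd = naive_mean_sd(t2star, periphery)
    thr = mean - multiplier * sd
    candidate = np.zeros_like(aar, dtype=bool)
    for r in range(nr):
        for c in range(nc):
            if aar[r, c] and t2star[r, c] < thr:
                candidate[r, c] = True
    out = np.zeros_like(aar, dtype=bool)
    for comp in _components(candidate):
        grid = np.zeros_like(aar, dtype=bool)
        for r, c in comp:
            grid[r, c] = True
        # row-major collection mirrors boolean-index ordering
        if float(np.mean(_collect(t2star, grid))) < t2star_cutoff:
            out |= grid
    return out


def naive_auc(scores, labels) -> float:
    """All-pairs ordering probability with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
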