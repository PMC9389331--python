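"""Independent oracles shared by the test modules.

Everything here is deliberately naive — per-cell loops, brute-force
enumeration, stratified Monte-Carlo point sampling — so it cannot share a
bug with the vectorized implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

from tomatodet.geometry import Circle


class MonteCarloCiou:
    """Stratified (jittered-grid) point-sampling estimate of circle IOU.

    Samples ``side**2 >= 1e6`` jittered grid points in the bounding square
    of the first circle; the intersection area is the in-both fraction
    scaled by the square's area, the union follows from the exact disc
    areas.  The jitter is drawn once and shared across pairs, which only
    correlates the (unbiased, ~1e-4) per-pair errors.
    """

    def __init__(self, side: int = 1024, seed: int = 42):
        rng = np.random.default_rng(seed)
        n = side * side
        ix, iy = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        px = (-1.0 + 2.0 * (ix.ravel() + rng.random(n)) / side).astype(np.float32)
        py = (-1.0 + 2.0 * (iy.ravel() + rng.random(n)) / side).astype(np.float32)
        pp = px * px + py * py
        keep = pp <= 1.0
        self.n = n
        self.px, self.py, self.pp = px[keep], py[keep], pp[keep]

    def intersection(self, a: Circle, b: Circle) -> float:
        qx = (b.cx - a.cx) / a.r
        qy = (b.cy - a.cy) / a.r
        qr = b.r / a.r
        t = self.pp - (2.0 * qx) * self.px - (2.0 * qy) * self.py
        frac = np.count_nonzero(t <= qr * qr - qx * qx - qy * qy) / self.n
        return frac * 4.0 * a.r * a.r

    def ciou(self, a: Circle, b: Circle) -> float:
        inter = self.intersection(a, b)
        union = math.pi * (a.r**2 + b.r**2) - inter
        return inter / union


def looped_focal_loss(y_hat: np.ndarray, y: np.ndarray, alpha: float, beta: float,
                      eps: float = 1e-4) -> float:
    """Per-cell loop re-implementation of the penalty-reduced focal loss
    for a single (C, H, W) image."""
    n_pos = 0
    total = 0.0
    c, h, w = y.shape
    for ci in range(c):
        for yy in range(h):
            for xx in range(w):
                p = min(max(float(y_hat[ci, yy, xx]), eps), 1 - eps)
                t = float(y[ci, yy, xx])
                if t == 1.0:
                    n_pos += 1
                    total += (1 - p) ** alpha * math.log(p)
                else:
                    total += (1 - t) ** beta * p**alpha * math.log(1 - p)
    return -total / max(n_pos, 1)


def looped_masked_l1(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Loop re-implementation of the keypoint-masked mean L1 loss."""
    n = 0
    total = 0.0
    ch, h, w = pred.shape
    for yy in range(h):
        for xx in range(w):
            if mask[yy, xx]:
                n += 1
                for ci in range(ch):
                    total += abs(float(pred[ci, yy, xx]) - float(target[ci, yy, xx]))
    return total / n if n else 0.0


def brute_force_peaks(plane: np.ndarray) -> set[tuple[int, int]]:
    """Cells >= all existing 8-neighbors, by explicit comparison."""
    h, w = plane.shape
    peaks = set()
    for yy in range(h):
        for xx in range(w):
            ok = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == dx == 0:
                        continue
                    ny, nx = yy + dy, xx + dx
                    if 0 <= ny < h and 0 <= nx < w and plane[ny, nx] > plane[yy, xx]:
                        ok = False
            if ok:
                peaks.add((xx, yy))
    return peaks


def brute_force_greedy_nms(circles, threshold):
    """O(n^2) greedy suppression, scores descending."""
    from tomatodet.geometry import ciou

    ordered = sorted(circles, key=lambda c: (-(c.score or 1.0), c.cy, c.cx))
    kept = []
    for cand in ordered:
        if all(ciou(cand, k) < threshold for k in kept):
            kept.append(cand)
    return kept


def brute_force_greedy_match(dets, gts, threshold):
    """Explicit greedy assignment enumeration: detections by descending
    score claim the best remaining ground truth."""
    from tomatodet.geometry import ciou

    order = sorted(range(len(dets)), key=lambda i: (-(dets[i].score or 1.0), i))
    taken = set()
    matches = []
    for di in order:
        best, best_iou = None, threshold
        for gi in range(len(gts)):
            if gi in taken:
                continue
            v = ciou(dets[di], gts[gi])
            if v >= best_iou:
                best, best_iou = gi, v
        if best is not None:
            taken.add(best)
            matches.append((di, best))
    return matches


def brute_force_ap(points: list[tuple[float, float]]) -> float:
    """All-point interpolated AP by direct enumeration over the recall
    grid of the curve points."""
    pts = sorted(points)
    ap = 0.0
    prev_r = 0.0
    for r, _ in pts:
        p_best = max(p for rr, p in pts if rr >= r)
        ap += (r - prev_r) * p_best
        prev_r = r
    return 100.0 * ap


def random_circle_pair(rng, r_lo=1.0, r_hi=100.0, d_factor=3.0):
    r1 = rng.uniform(r_lo, r_hi)
    r2 = rng.uniform(r_lo, r_hi)
    d = rng.uniform(0.0, d_factor * (r1 + r2))
    theta = rng.uniform(0.0, 2 * math.pi)
    a = Circle(rng.uniform(-50, 50), rng.uniform(-50, 50), r1)
    b = Circle(a.cx + d * math.cos(theta), a.cy + d * math.sin(theta), r2)
    return a, b
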