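"""Decoding predicted maps into bounding circles.

A detection is a local peak of the (post-sigmoid) heatmap: a cell whose
value is greater than or equal to each of its 8-connected neighbors.  The
top-N peaks become circles by adding the predicted sub-cell offset to the
cell coordinate, scaling back to input pixels by the stride, and reading
the radius off the radius map at the same cell.  An optional greedy
cIOU-based NMS is provided as a post-filter; the keypoint formulation
itself does not require one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Circle, ciou

__all__ = ["DetectionSet", "extract_peaks", "decode_circles", "circle_nms"]


@dataclass
class DetectionSet:
    """Decoded circles with confidences for one image."""

    circles: list[Circle] = field(default_factory=list)
    image_id: str = ""
    input_dims: tuple[int, int] = (0, 0)

    def __len__(self) -> int:
        return len(self.circles)

    def __iter__(self):
        return iter(self.circles)


def extract_peaks(heatmap: np.ndarray, n_max: int = 100) -> list[tuple[int, int, int, float]]:
    """Cells that dominate their 8-connected neighborhood, best first.

    Border cells compare only against neighbors that exist; ties with a
    neighbor ("greater or equal") keep both cells.  Returns at most
    ``n_max`` tuples ``(col, row, class_id, score)`` sorted by descending
    score, then class, row, column for determinism.

    Parameters
    ----------
    heatmap : (C, H, W) post-sigmoid scores in [0, 1].
    """
    hm = np.asarray(heatmap)
    if hm.ndim == 2:
        hm = hm[None]
    c, h, w = hm.shape
    padded = np.pad(hm, ((0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
    neighborhood = np.full_like(hm, -np.inf)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            np.maximum(neighborhood, padded[:, 1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w],
                       out=neighborhood)
    is_peak = hm >= neighborhood
    cls_idx, rows, cols = np.nonzero(is_peak)
    scores = hm[cls_idx, rows, cols]
    # descending score; ties broken row-major within class
    order = np.lexsort((cols, rows, cls_idx, -scores))[:n_max]
    return [
        (int(cols[i]), int(rows[i]), int(cls_idx[i]), float(scores[i])) for i in order
    ]


def decode_circles(
    heatmap: np.ndarray,
    offsets: np.ndarray,
    radii: np.ndarray,
    stride: int = 4,
    n_max: int = 100,
    score_threshold: float = 0.3,
    image_id: str = "",
) -> DetectionSet:
    """Turn predicted maps into scored bounding circles in input pixels.

    For each retained peak at cell ``(x, y)``: center is
    ``(x + dx, y + dy) * stride``, radius is the radius-map value at the
    cell times ``stride``, and the score is the heatmap value itself.
    Peaks scoring below ``score_threshold`` and peaks with non-positive
    decoded radius are dropped.

    Raises
    ------
    ValueError
        If map shapes are mutually inconsistent.
    """
    heatmap = np.asarray(heatmap)
    offsets = np.asarray(offsets)
    radii = np.asarray(radii)
    if heatmap.ndim == 2:
        heatmap = heatmap[None]
    if radii.ndim == 2:
        radii = radii[None]
    c, h, w = heatmap.shape
    if offsets.shape != (2, h, w) or radii.shape != (c, h, w):
        raise ValueError(
            f"inconsistent map shapes: heatmap {heatmap.shape}, "
            f"offsets {offsets.shape}, radii {radii.shape}"
        )
    circles: list[Circle] = []
    for x, y, cls, score in extract_peaks(heatmap, n_max):
        if score < score_threshold:
            continue
        r = float(radii[cls, y, x]) * stride
        if r <= 0:
            continue
        cx = (x + float(offsets[0, y, x])) * stride
        cy = (y + float(offsets[1, y, x])) * stride
        circles.append(Circle(cx, cy, r, score=min(1.0, max(0.0, score)), class_id=cls))
    return DetectionSet(circles, image_id=image_id, input_dims=(w * stride, h * stride))


def circle_nms(dets: DetectionSet, ciou_threshold: float = 0.5) -> DetectionSet:
    """Greedy non-maximum suppression on circle IOU.

    Walking detections in descending score order, a circle is dropped when
    its cIOU with an already-kept higher-scoring circle reaches the
    threshold.  Idempotent.
    """
    if not 0.0 < ciou_threshold < 1.0:
        raise ValueError(f"ciou_threshold must lie in (0, 1), got {ciou_threshold}")
    ordered = sorted(
        dets.circles, key=lambda c: (-(c.score if c.score is not None else 1.0), c.cy, c.cx)
    )
    kept: list[Circle] = []
    for cand in ordered:
        if all(ciou(cand, k) < ciou_threshold for k in kept):
            kept.append(cand)
    return DetectionSet(kept, image_id=dets.image_id, input_dims=dets.input_dims)
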