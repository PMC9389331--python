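"""Ground-truth encoding for keypoint-based circle detection.

Each annotated circle becomes (i) a Gaussian splat on the class heatmap,
peaking at 1 at the discretized center cell, (ii) a sub-cell offset target
that restores the fractional position lost to the stride-``K`` grid, and
(iii) a radius target in output-grid units.  Overlapping Gaussians combine
by element-wise max so heatmap values stay in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .geometry import Circle, ciou

logger = logging.getLogger(__name__)

__all__ = ["TargetMaps", "gaussian_sigma", "splat_gaussian", "encode", "CenterOutsideImageError"]


class CenterOutsideImageError(ValueError):
    """An annotated circle center falls outside the image frame."""


@dataclass
class TargetMaps:
    """Per-image training targets on the stride-``K`` output grid.

    Attributes
    ----------
    heatmap : (C, H/K, W/K) float32 in [0, 1]
        Gaussian keypoint heatmap; value 1 exactly at encoded center cells.
    offsets : (2, H/K, W/K) float64
        (dx, dy) sub-cell offsets, populated only at keypoint cells,
        each component in [0, 1).
    radii : (C, H/K, W/K) float64
        Radius targets in output-grid units, populated at keypoint cells.
    keypoint_mask : (H/K, W/K) bool
        Marks the cells that carry regression targets.
    stride : int
        Output downsampling ratio K.
    """

    heatmap: np.ndarray
    offsets: np.ndarray
    radii: np.ndarray
    keypoint_mask: np.ndarray
    stride: int

    @property
    def num_keypoints(self) -> int:
        return int(self.keypoint_mask.sum())


def _displacement_iou_coeff(iou_floor: float = 0.7) -> float:
    """Largest displacement (as a fraction of r) keeping cIOU >= iou_floor.

    For two equal discs the cIOU depends only on d/r, so the threshold
    displacement is ``coeff * r`` with a universal coefficient found once by
    bisection.
    """
    lo, hi = 0.0, 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        c0 = Circle(0.0, 0.0, 1.0)
        c1 = Circle(mid, 0.0, 1.0)
        if ciou(c0, c1) >= iou_floor:
            lo = mid
        else:
            hi = mid
    return lo


_DISPLACEMENT_COEFF = _displacement_iou_coeff(0.7)


def gaussian_sigma(radius_out: float) -> float:
    """Kernel standard deviation for a circle of the given output-grid radius.

    The Gaussian radius is the largest center displacement that keeps the
    circle-IOU between a disc and its displaced copy at or above 0.7;
    sigma is one third of that radius (with a floor of 2 output cells on
    the radius, i.e. 2/3 on sigma), so that nearby cells are softly
    penalty-reduced rather than treated as hard negatives.

    Parameters
    ----------
    radius_out : float
        Object radius expressed in output cells (r / K), > 0.

    Raises
    ------
    ValueError
        If ``radius_out`` is not strictly positive (invalid annotation).
    """
    if not radius_out > 0:
        raise ValueError(f"annotation radius must be > 0 output cells, got {radius_out}")
    gaussian_radius = _DISPLACEMENT_COEFF * radius_out
    return max(gaussian_radius, 2.0) / 3.0


def splat_gaussian(plane: np.ndarray, center: tuple[float, float], sigma: float) -> np.ndarray:
    """Render one unnormalized Gaussian onto a heatmap plane, in place.

    The kernel ``exp(-((x - px)^2 + (y - py)^2) / (2 sigma^2))`` is
    evaluated on a window truncated at 3 sigma and combined with the
    existing plane by element-wise max; the cell at the rounded center is
    forced to exactly 1.

    Parameters
    ----------
    plane : (H, W) array, modified in place and returned.
    center : (x, y) continuous cell coordinates of the discretized keypoint.
    sigma : kernel standard deviation in output cells.
    """
    h, w = plane.shape
    px, py = center
    ix, iy = int(px), int(py)
    if not (0 <= ix < w and 0 <= iy < h):
        raise CenterOutsideImageError(f"splat center {center} outside plane {w}x{h}")
    radius = max(1, int(math.ceil(3.0 * sigma)))
    x0, x1 = max(0, ix - radius), min(w, ix + radius + 1)
    y0, y1 = max(0, iy - radius), min(h, iy + radius + 1)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    kernel = np.exp(-((xs - px) ** 2 + (ys - py) ** 2) / (2.0 * sigma * sigma))
    np.maximum(plane[y0:y1, x0:x1], kernel, out=plane[y0:y1, x0:x1])
    plane[iy, ix] = 1.0
    return plane


def encode(
    circles: list[Circle],
    image_dims: tuple[int, int],
    stride: int = 4,
    num_classes: int = 1,
) -> TargetMaps:
    """Encode ground-truth circles into training target maps.

    Each circle's center ``p`` maps to the output cell ``floor(p / K)``;
    the heatmap receives a Gaussian with sigma from :func:`gaussian_sigma`
    evaluated at ``r / K``, the offset target is the discarded fractional
    part, and the radius target is ``r / K``.  Two circles landing on the
    same cell collide: the larger radius wins and a warning is logged.

    Parameters
    ----------
    circles : annotated objects, centers inside the image.
    image_dims : (W, H) input image size, both divisible by ``stride``.
    stride : output downsampling ratio K.
    num_classes : number of class planes C.

    Raises
    ------
    CenterOutsideImageError
        If any circle center lies outside ``[0, W) x [0, H)``.
    ValueError
        If the image dimensions are not divisible by ``stride``.
    """
    w, h = image_dims
    if w % stride or h % stride:
        raise ValueError(f"image dims {image_dims} not divisible by stride {stride}")
    ow, oh = w // stride, h // stride
    heatmap = np.zeros((num_classes, oh, ow), dtype=np.float32)
    # float64 regression targets: the encode -> decode round trip is then
    # bit-exact (stride is a power of two, so p/K and its split are exact)
    offsets = np.zeros((2, oh, ow), dtype=np.float64)
    radii = np.zeros((num_classes, oh, ow), dtype=np.float64)
    mask = np.zeros((oh, ow), dtype=bool)

    # larger radius wins a cell collision
    order = sorted(range(len(circles)), key=lambda i: circles[i].r)
    for i in order:
        c = circles[i]
        if not (0 <= c.cx < w and 0 <= c.cy < h):
            raise CenterOutsideImageError(
                f"circle center ({c.cx}, {c.cy}) outside image {w}x{h}"
            )
        fx, fy = c.cx / stride, c.cy / stride
        cx_cell, cy_cell = int(fx), int(fy)
        r_out = c.r / stride
        if mask[cy_cell, cx_cell]:
            logger.warning(
                "keypoint collision at cell (%d, %d): keeping larger radius", cx_cell, cy_cell
            )
        sigma = gaussian_sigma(r_out)
        splat_gaussian(heatmap[c.class_id], (float(cx_cell), float(cy_cell)), sigma)
        offsets[0, cy_cell, cx_cell] = fx - cx_cell
        offsets[1, cy_cell, cx_cell] = fy - cy_cell
        radii[c.class_id, cy_cell, cx_cell] = r_out
        mask[cy_cell, cx_cell] = True

    return TargetMaps(heatmap, offsets, radii, mask, stride)
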