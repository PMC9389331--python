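"""Exact circle geometry for bounding-circle detection.

A detected object is a disc (center, radius).  Similarity between two discs
is measured by the circle IOU (cIOU): the ratio of the intersection area to
the union area, available in closed form from the two radii and the center
distance via circular-segment geometry.  The closed form is only derived on
the "lens" regime ``|r1 - r2| <= d <= r1 + r2``; outside it the value is
extended by continuity (disjoint discs overlap nothing, a contained disc
overlaps completely), which is what greedy matching and NMS need on
arbitrary pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Circle",
    "center_distance",
    "intersection_area",
    "union_area",
    "ciou",
    "ciou_matrix",
]


@dataclass
class Circle:
    """A detected or ground-truth object: a disc in continuous pixel coords.

    Parameters
    ----------
    cx, cy : float
        Center, 0-based pixel coordinates (continuous).
    r : float
        Radius in pixels, strictly positive.
    score : float or None
        Detection confidence in [0, 1]; ``None`` for ground truth.
    class_id : int
        Category index (single-class fruit detection uses 0).
    """

    cx: float
    cy: float
    r: float
    score: float | None = None
    class_id: int = 0

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"circle radius must be > 0, got {self.r}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def area(self) -> float:
        return math.pi * self.r * self.r


def center_distance(a: Circle, b: Circle) -> float:
    """Euclidean distance between the two centers, in pixels."""
    return math.hypot(a.cx - b.cx, a.cy - b.cy)


def _aperture_angles(r1: float, r2: float, d: float) -> tuple[float, float]:
    """Half-aperture angles of the lens at each center.

    ``aperture_a`` is subtended at the center of the circle with radius
    ``r1``, ``aperture_b`` at the other.  Arguments of arccos are clamped to
    [-1, 1]: at the tangency boundaries floating-point drift otherwise
    pushes them fractionally outside the domain and yields NaN.
    """
    aperture_a = math.acos(min(1.0, max(-1.0, (r1 * r1 + d * d - r2 * r2) / (2.0 * r1 * d))))
    aperture_b = math.acos(min(1.0, max(-1.0, (r2 * r2 + d * d - r1 * r1) / (2.0 * r2 * d))))
    return aperture_a, aperture_b


def intersection_area(a: Circle, b: Circle) -> float:
    """Area of overlap of two discs, in square pixels.

    Lens regime: sum of the two circular segments,
    ``a*r1^2 + b*r2^2 - r1^2 sin(2a)/2 - r2^2 sin(2b)/2`` with the
    half-aperture angles ``a``, ``b``.  Disjoint discs give 0; a disc
    nested inside the other gives the smaller disc's full area.
    """
    # canonical operand order makes the result exactly symmetric in (a, b)
    if (b.r, b.cx, b.cy) < (a.r, a.cx, a.cy):
        a, b = b, a
    d = center_distance(a, b)
    r1, r2 = a.r, b.r
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        rmin = min(r1, r2)
        return math.pi * rmin * rmin
    aperture_a, aperture_b = _aperture_angles(r1, r2, d)
    return (
        aperture_a * r1 * r1
        + aperture_b * r2 * r2
        - 0.5 * r1 * r1 * math.sin(2.0 * aperture_a)
        - 0.5 * r2 * r2 * math.sin(2.0 * aperture_b)
    )


def union_area(a: Circle, b: Circle) -> float:
    """Area covered by either disc: ``pi r1^2 + pi r2^2 - intersection``."""
    return a.area + b.area - intersection_area(a, b)


def ciou(a: Circle, b: Circle) -> float:
    """Circle IOU: intersection area over union area, in [0, 1].

    Symmetric in its arguments and invariant under rigid motions and
    uniform scaling applied to both discs.  Equals 1 only for identical
    discs and 0 for disjoint ones.
    """
    inter = intersection_area(a, b)
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def ciou_matrix(
    det_params: np.ndarray, gt_params: np.ndarray
) -> np.ndarray:
    """Pairwise cIOU between two sets of discs, vectorized.

    Parameters are ``(n, 3)`` arrays of columns ``(cx, cy, r)``.  Returns an
    ``(n_det, n_gt)`` float64 matrix.  Same regimes and clamping as the
    scalar path.
    """
    det_params = np.asarray(det_params, dtype=np.float64).reshape(-1, 3)
    gt_params = np.asarray(gt_params, dtype=np.float64).reshape(-1, 3)
    if det_params.shape[0] == 0 or gt_params.shape[0] == 0:
        return np.zeros((det_params.shape[0], gt_params.shape[0]))
    dx = det_params[:, None, 0] - gt_params[None, :, 0]
    dy = det_params[:, None, 1] - gt_params[None, :, 1]
    d = np.hypot(dx, dy)
    r1 = det_params[:, None, 2]
    r2 = gt_params[None, :, 2]

    with np.errstate(divide="ignore", invalid="ignore"):
        cos_a = np.clip((r1**2 + d**2 - r2**2) / (2.0 * r1 * d), -1.0, 1.0)
        cos_b = np.clip((r2**2 + d**2 - r1**2) / (2.0 * r2 * d), -1.0, 1.0)
    ap_a = np.arccos(cos_a)
    ap_b = np.arccos(cos_b)
    lens = (
        ap_a * r1**2
        + ap_b * r2**2
        - 0.5 * r1**2 * np.sin(2.0 * ap_a)
        - 0.5 * r2**2 * np.sin(2.0 * ap_b)
    )
    inter = np.where(
        d >= r1 + r2,
        0.0,
        np.where(d <= np.abs(r1 - r2), np.pi * np.minimum(r1, r2) ** 2, lens),
    )
    union = np.pi * r1**2 + np.pi * r2**2 - inter
    return inter / union


# Closed-form single-expression variant on the lens regime, kept separate so
# the algebraic identity with intersection/union can be asserted.
def ciou_lens_closed_form(a: Circle, b: Circle) -> float:
    """cIOU as the single closed-form ratio valid on the lens regime.

    ``[(2a - sin 2a) r1^2 + (2b - sin 2b) r2^2] /
    [(2pi - 2a + sin 2a) r1^2 + (2pi - 2b + sin 2b) r2^2]``

    Callers must ensure ``|r1 - r2| <= d <= r1 + r2``.
    """
    d = center_distance(a, b)
    r1, r2 = a.r, b.r
    aperture_a, aperture_b = _aperture_angles(r1, r2, d)
    num = (2 * aperture_a - math.sin(2 * aperture_a)) * r1 * r1 + (
        2 * aperture_b - math.sin(2 * aperture_b)
    ) * r2 * r2
    den = (2 * math.pi - 2 * aperture_a + math.sin(2 * aperture_a)) * r1 * r1 + (
        2 * math.pi - 2 * aperture_b + math.sin(2 * aperture_b)
    ) * r2 * r2
    return num / den
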