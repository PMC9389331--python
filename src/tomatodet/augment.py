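"""Annotation-consistent augmentation suite.

Six derived images per original: a horizontal flip, one scaled-and-cropped
variant, two brightness variants (one darkening draw in [0.6, 1) and one
brightening draw in (1, 1.4]), a gray-world color-balanced variant, and a
blurred copy of one randomly chosen derived image.  Geometric transforms
move the circle annotations consistently; photometric ones leave them
untouched.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import Circle
from .synthdata import ImageSample

logger = logging.getLogger(__name__)

__all__ = [
    "AugmentPlan",
    "hflip",
    "scale_crop",
    "brightness",
    "gray_world",
    "blur",
    "build_augmented_set",
    "write_count_table",
]


@dataclass
class AugmentPlan:
    """Expansion plan: per original, 1 flip + 1 scale/crop + 2 brightness +
    1 color balance + 1 blur (of a random derived image) + the original."""

    scale_range: tuple[float, float] = (0.75, 1.25)
    brightness_range: tuple[float, float] = (0.6, 1.4)
    blur_kernel: int = 5
    include_original: bool = True
    seed: int = 0


def _clone(sample: ImageSample, image: np.ndarray, circles=None) -> ImageSample:
    return ImageSample(
        image=image,
        circles=list(sample.circles) if circles is None else circles,
        lighting=sample.lighting,
        occlusion_labels=list(sample.occlusion_labels),
        occluded_fractions=list(sample.occluded_fractions),
        image_id=sample.image_id,
    )


def hflip(sample: ImageSample) -> ImageSample:
    """Mirror left-right; circle centers map ``cx -> (W - 1) - cx``."""
    w = sample.image.shape[1]
    circles = [replace(c, cx=(w - 1) - c.cx) for c in sample.circles]
    return _clone(sample, sample.image[:, ::-1].copy(), circles)


def scale_crop(
    sample: ImageSample,
    scale_range: tuple[float, float] = (0.75, 1.25),
    seed: int = 0,
) -> ImageSample:
    """Rescale by a sampled factor, then center-crop or zero-pad back to the
    original size.  Circles transform by the same similarity; circles whose
    centers leave the frame are dropped (their condition labels with them).
    """
    rng = np.random.default_rng(seed)
    factor = float(rng.uniform(*scale_range))
    h, w = sample.image.shape[:2]
    if factor == 1.0:
        return _clone(sample, sample.image.copy())
    zoomed = ndimage.zoom(sample.image, (factor, factor, 1.0), order=1)
    zh, zw = zoomed.shape[:2]
    out = np.zeros_like(sample.image)
    # offset from zoomed coords to output coords (centered)
    oy, ox = (h - zh) // 2, (w - zw) // 2
    src_y0, src_x0 = max(0, -oy), max(0, -ox)
    dst_y0, dst_x0 = max(0, oy), max(0, ox)
    copy_h = min(zh - src_y0, h - dst_y0)
    copy_w = min(zw - src_x0, w - dst_x0)
    out[dst_y0 : dst_y0 + copy_h, dst_x0 : dst_x0 + copy_w] = zoomed[
        src_y0 : src_y0 + copy_h, src_x0 : src_x0 + copy_w
    ]
    circles, labels, fracs = [], [], []
    for c, lab, frac in zip(
        sample.circles, sample.occlusion_labels or [""] * len(sample.circles),
        sample.occluded_fractions or [0.0] * len(sample.circles),
    ):
        cx = c.cx * factor + ox
        cy = c.cy * factor + oy
        if 0 <= cx < w and 0 <= cy < h:
            circles.append(replace(c, cx=cx, cy=cy, r=c.r * factor))
            labels.append(lab)
            fracs.append(frac)
    out_sample = _clone(sample, out, circles)
    out_sample.occlusion_labels = labels
    out_sample.occluded_fractions = fracs
    return out_sample


def brightness(sample: ImageSample, factor: float) -> ImageSample:
    """Multiply all pixel intensities by ``factor`` in [0.6, 1.4], clipped
    to 8-bit range; annotations unchanged."""
    if not 0.6 <= factor <= 1.4:
        raise ValueError(f"brightness factor {factor} outside [0.6, 1.4]")
    img = np.clip(sample.image.astype(np.float64) * factor, 0, 255).astype(np.uint8)
    return _clone(sample, img)


def gray_world(sample: ImageSample) -> ImageSample:
    """Gray-world color balancing: scale each channel so its mean matches
    the mean of the three channel means; a zero-mean channel is left
    unscaled with a warning."""
    img = sample.image.astype(np.float64)
    means = img.mean(axis=(0, 1))
    target = means.mean()
    gains = np.ones(3)
    for ch in range(3):
        if means[ch] == 0:
            logger.warning("gray_world: channel %d has zero mean, left unscaled", ch)
        else:
            gains[ch] = target / means[ch]
    out = np.clip(img * gains[None, None, :], 0, 255).astype(np.uint8)
    return _clone(sample, out)


def blur(sample: ImageSample, kernel_size: int = 5) -> ImageSample:
    """Gaussian smoothing (sigma scaled to the odd kernel size); annotations
    unchanged."""
    if kernel_size % 2 == 0:
        raise ValueError(f"blur kernel size must be odd, got {kernel_size}")
    if kernel_size == 1:
        return _clone(sample, sample.image.copy())
    sigma = 0.3 * ((kernel_size - 1) * 0.5 - 1) + 0.8
    img = ndimage.gaussian_filter(
        sample.image.astype(np.float64), sigma=(sigma, sigma, 0.0), truncate=(kernel_size // 2) / sigma
    )
    return _clone(sample, np.clip(img, 0, 255).astype(np.uint8))


def build_augmented_set(
    samples: list[ImageSample], plan: AugmentPlan | None = None
) -> tuple[list[ImageSample], dict[str, int]]:
    """Expand a sample list per the plan; returns (augmented list, counts).

    The count table keys are ``original, flip, scale_crop, brightness,
    color_balance, blur, total``; with the default plan an input of n
    originals yields 7n images with category counts (n, n, n, 2n, n, n).
    """
    plan = plan or AugmentPlan()
    rng = np.random.default_rng(plan.seed)
    out: list[ImageSample] = []
    counts = dict.fromkeys(
        ("original", "flip", "scale_crop", "brightness", "color_balance", "blur"), 0
    )
    for sample in samples:
        if plan.include_original:
            out.append(sample)
            counts["original"] += 1
        lo, hi = plan.brightness_range
        derived = [
            ("flip", hflip(sample)),
            ("scale_crop", scale_crop(sample, plan.scale_range, seed=int(rng.integers(2**31)))),
            ("brightness", brightness(sample, float(rng.uniform(lo, 1.0)))),
            ("brightness", brightness(sample, float(rng.uniform(np.nextafter(1.0, 2.0), hi)))),
            ("color_balance", gray_world(sample)),
        ]
        for name, aug in derived:
            out.append(aug)
            counts[name] += 1
        victim = derived[int(rng.integers(len(derived)))][1]
        out.append(blur(victim, plan.blur_kernel))
        counts["blur"] += 1
    counts["total"] = len(out)
    return out, counts


def write_count_table(path, counts: dict[str, int]) -> None:
    """Write the per-category expansion counts as a two-column CSV."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["category", "count"])
        for key, value in counts.items():
            writer.writerow([key, value])
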