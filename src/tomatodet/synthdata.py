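"""Synthetic greenhouse-style scenes with exact circle annotations.

Real fruit imagery for this task is not publicly deposited, so the rest of
the package is exercised on rendered scenes that emulate its structure:
roughly circular shaded fruits of varying radius over green clutter, with
controllable fruit overlap, leaf occlusion (slight < 50% of the fruit
covered vs severe >= 50%), an illumination mode (uniform, sunlight-style
gradient, or dim shading) and optional blur.  Every scene is a pure
function of its seed, and every annotation is exact by construction —
encode/decode round trips and training-recovery tests consume them as
ground truth.

Annotations use a plain-text dialect: first line is the object count, each
following line is ``class_id cx cy r`` in input-pixel units (0-based,
2-decimal floats); detection files append a 4-decimal score column.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .geometry import Circle

__all__ = [
    "SceneConfig",
    "ImageSample",
    "generate_scene",
    "generate_dataset",
    "read_annotations",
    "write_annotations",
    "AnnotationFormatError",
]


class AnnotationFormatError(ValueError):
    """A malformed annotation line, reported with file and line number."""


@dataclass
class SceneConfig:
    """Knobs of the scene generator; defaults give a learnable 64x64 scene.

    ``occluder_coverage`` is the requested fraction of a fruit's disc hidden
    by a leaf when an occluder is drawn; the realized fraction is measured
    by pixel counting and recorded per fruit.
    """

    image_dims: tuple[int, int] = (64, 64)
    n_fruits: tuple[int, int] = (1, 4)
    radius_range: tuple[float, float] = (6.0, 11.0)
    overlap_probability: float = 0.25
    occluder_probability: float = 0.35
    occluder_coverage: tuple[float, float] = (0.1, 0.6)
    illumination: str = "uniform"  # uniform | gradient | low
    clutter_density: float = 6.0  # distractor blobs per 64x64 tile
    blur_probability: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for p in (self.overlap_probability, self.occluder_probability, self.blur_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.radius_range[0] <= 0:
            raise ValueError("radius range must be positive")
        if self.illumination not in ("uniform", "gradient", "low"):
            raise ValueError(f"unknown illumination mode {self.illumination!r}")


@dataclass
class ImageSample:
    """A rendered scene plus its exact ground truth and condition labels."""

    image: np.ndarray  # (H, W, 3) uint8
    circles: list[Circle]
    lighting: str = "sunlight"  # sunlight | shading
    occlusion_labels: list[str] = field(default_factory=list)  # none | slight | severe
    occluded_fractions: list[float] = field(default_factory=list)
    image_id: str = ""


def _segment_offset_for_coverage(coverage: float) -> float:
    """Chord offset t/r such that the circular segment beyond it covers
    the requested fraction of the disc (bisection on the segment area)."""
    lo, hi = -1.0, 1.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        theta = math.acos(max(-1.0, min(1.0, mid)))
        frac = (theta - mid * math.sin(theta)) / math.pi
        if frac > coverage:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _render_fruit(img, mask_owner, idx, cx, cy, r, rng):
    h, w, _ = img.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    # slight eccentricity (<= 5%) so fruits are only roughly circular
    ecc = rng.uniform(0.0, 0.05)
    phi = rng.uniform(0.0, math.pi)
    dx, dy = xs - cx, ys - cy
    u = dx * math.cos(phi) + dy * math.sin(phi)
    v = -dx * math.sin(phi) + dy * math.cos(phi)
    rho2 = (u / r) ** 2 + (v / (r * (1.0 - ecc))) ** 2
    inside = rho2 <= 1.0
    shade = np.sqrt(np.clip(1.0 - rho2, 0.0, 1.0))
    base = np.array([rng.uniform(185, 235), rng.uniform(30, 70), rng.uniform(25, 55)])
    for ch in range(3):
        img[..., ch][inside] = base[ch] * (0.55 + 0.45 * shade[inside])
    # specular highlight
    hx, hy = cx - 0.35 * r, cy - 0.35 * r
    spec = np.exp(-(((xs - hx) ** 2 + (ys - hy) ** 2) / (2 * (0.18 * r) ** 2)))
    for ch in range(3):
        img[..., ch][inside] = np.clip(
            img[..., ch][inside] + 120 * spec[inside], 0, 255
        )
    mask_owner[inside] = idx
    return inside


def _draw_leaf(img, mask_owner, cx, cy, r, coverage, rng, disc=None):
    """Occlude a fruit with a leaf-green half-plane strip.

    The cut is placed at the chord whose far segment covers ``coverage`` of
    the fruit; when the rendered fruit mask is supplied the chord offset is
    the exact pixel quantile of the signed coordinate over that mask, which
    pins the realized coverage to the request up to discretization.
    """
    h, w, _ = img.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = rng.uniform(0.0, 2 * math.pi)
    nx, ny = math.cos(theta), math.sin(theta)
    signed = (xs - cx) * nx + (ys - cy) * ny
    if disc is not None and disc.any():
        t = float(np.quantile(signed[disc], 1.0 - coverage))
    else:
        t = _segment_offset_for_coverage(coverage) * r
    dist2 = (xs - cx) ** 2 + (ys - cy) ** 2
    strip = (signed >= t) & (dist2 <= (1.6 * r) ** 2)
    texture = 0.8 + 0.2 * np.sin(0.7 * xs + 0.9 * ys + rng.uniform(0, 6.28))
    leaf = np.array([rng.uniform(30, 60), rng.uniform(110, 160), rng.uniform(35, 70)])
    for ch in range(3):
        img[..., ch][strip] = leaf[ch] * texture[strip]
    mask_owner[strip] = -2  # occluder
    return strip


def generate_scene(cfg: SceneConfig, seed: int | None = None) -> ImageSample:
    """Render one annotated scene, fully determined by the seed.

    Fruits are placed with bounded retries; if a non-overlapping position
    cannot be found the scene simply carries fewer fruits.  The occluded
    fraction of each fruit is measured on the final ownership map (pixels
    claimed by later fruits or occluders), so overlap between fruits counts
    toward occlusion exactly as leaves do.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    w, h = cfg.image_dims

    # -- background: dark greenish texture + clutter ------------------------
    img = np.zeros((h, w, 3), dtype=np.float64)
    base = np.array([rng.uniform(35, 55), rng.uniform(55, 85), rng.uniform(30, 50)])
    noise = rng.normal(0.0, 6.0, size=(h, w, 1))
    img[:] = base[None, None, :] + noise
    n_clutter = rng.poisson(cfg.clutter_density * (w * h) / 4096.0)
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    for _ in range(n_clutter):
        ccx, ccy = rng.uniform(0, w), rng.uniform(0, h)
        a = rng.uniform(2, 8)
        b = a * rng.uniform(0.3, 1.0)
        phi = rng.uniform(0, math.pi)
        u = (xs - ccx) * math.cos(phi) + (ys - ccy) * math.sin(phi)
        v = -(xs - ccx) * math.sin(phi) + (ys - ccy) * math.cos(phi)
        blob = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        color = np.array(
            [rng.uniform(40, 90), rng.uniform(80, 150), rng.uniform(30, 80)]
        ) * rng.uniform(0.6, 1.2)
        for ch in range(3):
            img[..., ch][blob] = color[ch]

    # -- fruits --------------------------------------------------------------
    n_target = int(rng.integers(cfg.n_fruits[0], cfg.n_fruits[1] + 1))
    placed: list[tuple[float, float, float]] = []
    for _ in range(n_target):
        allow_overlap = rng.random() < cfg.overlap_probability and placed
        for _attempt in range(40):
            r = rng.uniform(*cfg.radius_range)
            cx = rng.uniform(r * 0.6, w - 1 - r * 0.6)
            cy = rng.uniform(r * 0.6, h - 1 - r * 0.6)
            dmin = min(
                (math.hypot(cx - px, cy - py) - (r + pr) for px, py, pr in placed),
                default=np.inf,
            )
            if allow_overlap:
                # want genuine but partial overlap with some placed fruit
                if -0.9 * r < dmin < -0.2 * r:
                    break
            elif dmin > 2.0:
                break
        else:
            continue
        placed.append((cx, cy, r))

    mask_owner = np.full((h, w), -1, dtype=np.int32)
    disc_masks = []
    for i, (cx, cy, r) in enumerate(placed):
        disc_masks.append(_render_fruit(img, mask_owner, i, cx, cy, r, rng))

    # -- occluders -----------------------------------------------------------
    for i, (cx, cy, r) in enumerate(placed):
        if rng.random() < cfg.occluder_probability:
            coverage = rng.uniform(*cfg.occluder_coverage)
            _draw_leaf(img, mask_owner, cx, cy, r, coverage, rng, disc=disc_masks[i])

    occluded_fractions = []
    occlusion_labels = []
    for i, disc in enumerate(disc_masks):
        total = int(disc.sum())
        visible = int((mask_owner[disc] == i).sum())
        frac = 1.0 - visible / max(total, 1)
        frac = min(frac, 0.999)
        occluded_fractions.append(frac)
        occlusion_labels.append("none" if frac < 0.05 else "slight" if frac < 0.5 else "severe")

    # -- illumination --------------------------------------------------------
    lighting = "sunlight"
    if cfg.illumination == "gradient":
        direction = rng.uniform(0, 2 * math.pi)
        ramp = (xs * math.cos(direction) + ys * math.sin(direction)) / max(w, h)
        ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-9)
        img *= (0.85 + 0.55 * ramp)[..., None]
    elif cfg.illumination == "low":
        img *= rng.uniform(0.45, 0.62)
        lighting = "shading"

    if rng.random() < cfg.blur_probability:
        img = ndimage.gaussian_filter(img, sigma=(1.0, 1.0, 0.0))

    image = np.clip(img, 0, 255).astype(np.uint8)
    circles = [Circle(cx, cy, r) for cx, cy, r in placed]
    return ImageSample(image, circles, lighting, occlusion_labels, occluded_fractions)


def write_annotations(path: str | Path, circles: list[Circle], scores: bool = False) -> None:
    """Write circles in the plain-text dialect (count line, then one circle
    per line); ``scores=True`` appends a 4-decimal confidence column."""
    lines = [str(len(circles))]
    for c in circles:
        row = f"{c.class_id} {c.cx:.2f} {c.cy:.2f} {c.r:.2f}"
        if scores:
            row += f" {c.score if c.score is not None else 1.0:.4f}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path) -> list[Circle]:
    """Read a circle annotation (or detection) file.

    Raises :class:`AnnotationFormatError` naming the file and 1-based line
    number on any malformed line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        return []
    try:
        count = int(lines[0].strip())
    except ValueError as exc:
        raise AnnotationFormatError(f"{path}:1: expected integer count") from exc
    circles = []
    for ln, raw in enumerate(lines[1 : count + 1], start=2):
        parts = raw.split()
        if len(parts) not in (4, 5):
            raise AnnotationFormatError(
                f"{path}:{ln}: expected 'class cx cy r [score]', got {len(parts)} fields"
            )
        try:
            cls = int(parts[0])
            cx, cy, r = (float(v) for v in parts[1:4])
            score = float(parts[4]) if len(parts) == 5 else None
        except ValueError as exc:
            raise AnnotationFormatError(f"{path}:{ln}: non-numeric field") from exc
        circles.append(Circle(cx, cy, r, score=score, class_id=cls))
    if len(circles) != count:
        raise AnnotationFormatError(
            f"{path}: header announced {count} circles, found {len(circles)}"
        )
    return circles


def generate_dataset(
    cfg: SceneConfig,
    n_train: int,
    n_test: int,
    out_dir: str | Path,
    shading_fraction: float = 0.5,
) -> Path:
    """Write a train/test split of scenes, annotations and a manifest.

    Roughly ``shading_fraction`` of the images are rendered in the dim
    "shading" mode and the rest with a sunlight-style gradient.  The
    manifest (CSV) carries one row per ground-truth circle: image id,
    split, lighting, circle index, occlusion label and measured occluded
    fraction.
    """
    out_dir = Path(out_dir)
    rows = []
    counter = 0
    for split, n in (("train", n_train), ("test", n_test)):
        img_dir = out_dir / split / "images"
        lab_dir = out_dir / split / "labels"
        img_dir.mkdir(parents=True, exist_ok=True)
        lab_dir.mkdir(parents=True, exist_ok=True)
        for i in range(n):
            mode = "low" if (i % max(1, round(1 / max(shading_fraction, 1e-9)))) == 0 else "gradient"
            if shading_fraction <= 0:
                mode = "gradient"
            scene_cfg = SceneConfig(**{**cfg.__dict__, "illumination": mode})
            sample = generate_scene(scene_cfg, seed=cfg.seed + counter)
            image_id = f"{split}_{i:05d}"
            sample.image_id = image_id
            Image.fromarray(sample.image).save(img_dir / f"{image_id}.png")
            write_annotations(lab_dir / f"{image_id}.txt", sample.circles)
            for j, c in enumerate(sample.circles):
                rows.append(
                    [image_id, split, sample.lighting, j,
                     sample.occlusion_labels[j], f"{sample.occluded_fractions[j]:.4f}"]
                )
            counter += 1
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["image_id", "split", "lighting", "circle_index", "occlusion", "occluded_fraction"]
        )
        writer.writerows(rows)
    return out_dir
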