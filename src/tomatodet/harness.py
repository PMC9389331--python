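"""Training, inference and evaluation orchestration.

The schedule follows the step-decay convention: a fixed initial learning
rate divided by a constant factor at listed epochs (defaults: 1.25e-4
divided by 10 at epochs 90 and 120 over 140 epochs, the full-scale
setting).  A ``desk_scale`` preset substitutes the tiny network, 64x64
scenes and a short high-learning-rate Adam schedule so the complete
pipeline — synthesize, train, detect, evaluate — runs in minutes on one
CPU core.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .decode import DetectionSet, circle_nms, decode_circles
from .evaluate import EvalReport, evaluate_detections
from .losses import compute_losses
from .network import CircleDetector, NetworkConfig, build_network, save_checkpoint
from .nn import Adam, Tensor
from .synthdata import ImageSample, read_annotations, write_annotations
from .targets import TargetMaps, encode

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "lr_at_epoch",
    "load_split",
    "train",
    "detect",
    "evaluate_cmd",
]

# channel statistics used to normalize images before the network
_MEAN, _STD = 0.408, 0.289


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults are the full-scale setting."""

    input_resolution: int = 512
    batch_size: int = 8
    initial_lr: float = 1.25e-4
    lr_drop_epochs: list[int] = field(default_factory=lambda: [90, 120])
    lr_drop_factor: float = 10.0
    total_epochs: int = 140
    seed: int = 0
    network: NetworkConfig = field(default_factory=lambda: NetworkConfig(preset="dla34_cbam"))
    lambda_off: float = 1.0
    lambda_r: float = 0.1
    alpha_focal: float = 2.0
    beta_focal: float = 4.0
    eval_ciou_threshold: float = 0.5
    confidence_threshold: float = 0.6
    score_floor: float = 0.3
    pr_floor: float = 0.05  # lower floor used to trace full PR curves
    n_max: int = 100
    validation_fraction: float = 0.1
    grad_clip_norm: float = 5.0

    def __post_init__(self):
        drops = list(self.lr_drop_epochs)
        if drops != sorted(set(drops)) or any(e >= self.total_epochs for e in drops):
            raise ValueError("lr_drop_epochs must be strictly increasing and < total_epochs")

    @classmethod
    def desk_scale(cls, seed: int = 0, epochs: int = 24, use_cbam: bool = True,
                   head_type: str = "circle") -> "TrainConfig":
        """Tiny-network CPU preset: 64x64 input, short Adam schedule."""
        drops = sorted({int(epochs * 0.7), int(epochs * 0.9)})
        return cls(
            input_resolution=64,
            batch_size=8,
            initial_lr=3e-3,
            lr_drop_epochs=[e for e in drops if 0 < e < epochs],
            lr_drop_factor=10.0,
            total_epochs=epochs,
            seed=seed,
            network=NetworkConfig(preset="tiny", seed=seed, use_cbam=use_cbam,
                                  head_type=head_type),
        )


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Step-decay schedule: initial rate divided by the drop factor once
    per listed drop epoch that has been reached."""
    if not 0 <= epoch < cfg.total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.total_epochs})")
    drops = sum(1 for e in cfg.lr_drop_epochs if e <= epoch)
    return cfg.initial_lr / (cfg.lr_drop_factor**drops)


def _normalize(image: np.ndarray) -> np.ndarray:
    """HWC uint8 -> CHW float32, zero-centered."""
    x = image.astype(np.float32) / 255.0
    return ((x - _MEAN) / _STD).transpose(2, 0, 1)


def load_split(data_dir: str | Path, split: str) -> list[ImageSample]:
    """Load images + annotations of one split written by the generator."""
    data_dir = Path(data_dir)
    img_dir = data_dir / split / "images"
    lab_dir = data_dir / split / "labels"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no such split directory: {img_dir}")
    samples = []
    for img_path in sorted(img_dir.glob("*.png")):
        image = np.asarray(Image.open(img_path).convert("RGB"))
        circles = read_annotations(lab_dir / f"{img_path.stem}.txt")
        samples.append(ImageSample(image=image, circles=circles, image_id=img_path.stem))
    return samples


def _size_targets(maps: TargetMaps, head_type: str) -> np.ndarray:
    """Radius target for the circle head; (w, h) = (2r, 2r) for the box head."""
    if head_type == "circle":
        return maps.radii
    return np.concatenate([2.0 * maps.radii, 2.0 * maps.radii], axis=0)


def train(
    cfg: TrainConfig,
    samples: list[ImageSample],
    out_dir: str | Path | None = None,
    val_samples: list[ImageSample] | None = None,
) -> tuple[CircleDetector, list[dict]]:
    """Train a detector; returns the best-validation-AP model and the log.

    Each epoch runs shuffled mini-batches through forward, the composite
    loss and one Adam step at the scheduled rate, then scores the
    validation split by AP.  With ``out_dir`` given, ``best.npz``,
    ``last.npz`` and ``train_log.json`` are written there.  A non-finite
    loss aborts with the offending batch index.
    """
    rng = np.random.default_rng(cfg.seed)
    model = build_network(cfg.network)
    k = cfg.network.output_stride

    if val_samples is None:
        n_val = int(round(cfg.validation_fraction * len(samples)))
        order = rng.permutation(len(samples))
        val_idx = set(order[:n_val].tolist())
        val_samples = [samples[i] for i in sorted(val_idx)]
        samples = [samples[i] for i in range(len(samples)) if i not in val_idx]
    if not samples:
        raise ValueError("no training samples")

    images = np.stack([_normalize(s.image) for s in samples])
    encoded = []
    for s in samples:
        h, w = s.image.shape[:2]
        maps = encode(s.circles, (w, h), stride=k, num_classes=cfg.network.num_classes)
        encoded.append(maps)
    heat = np.stack([m.heatmap for m in encoded])
    offs = np.stack([m.offsets for m in encoded]).astype(np.float32)
    sizes = np.stack(
        [_size_targets(m, cfg.network.head_type) for m in encoded]
    ).astype(np.float32)
    masks = np.stack([m.keypoint_mask for m in encoded])

    opt = Adam(model.parameters(), lr=cfg.initial_lr, clip_norm=cfg.grad_clip_norm)
    log: list[dict] = []
    best_ap, best_arrays = -1.0, None
    n = len(samples)
    for epoch in range(cfg.total_epochs):
        opt.lr = lr_at_epoch(epoch, cfg)
        model.train()
        perm = rng.permutation(n)
        sums = dict.fromkeys(("L_hm", "L_off", "L_r", "L_det"), 0.0)
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            y_hat, o_hat, s_hat = model(Tensor(images[idx]))
            total, breakdown = compute_losses(
                y_hat, o_hat, s_hat, heat[idx], offs[idx], sizes[idx], masks[idx],
                cfg.lambda_off, cfg.lambda_r, cfg.alpha_focal, cfg.beta_focal,
            )
            if not np.isfinite(total.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches} "
                    f"(images {idx.tolist()})"
                )
            model.zero_grad()
            total.backward()
            opt.step()
            for key in sums:
                sums[key] += getattr(breakdown, key)
            n_batches += 1
        entry = {
            "epoch": epoch,
            "lr": opt.lr,
            **{key: sums[key] / n_batches for key in sums},
        }
        if val_samples:
            val_report = _score(model, val_samples, cfg)
            entry["val_ap"] = val_report.ap
            if val_report.ap >= best_ap:
                best_ap = val_report.ap
                best_arrays = [a.copy() for a in model.state_arrays()]
        log.append(entry)
        logger.info(
            "epoch %d lr %.2e L_det %.4f%s", epoch, entry["lr"], entry["L_det"],
            f" val_ap {entry.get('val_ap', float('nan')):.2f}" if val_samples else "",
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out_dir / "last.npz", model)
        if best_arrays is not None:
            last = [a.copy() for a in model.state_arrays()]
            model.load_state_arrays(best_arrays)
            save_checkpoint(out_dir / "best.npz", model)
            model.load_state_arrays(last)
        (out_dir / "train_log.json").write_text(json.dumps(log, indent=1))
    if best_arrays is not None:
        model.load_state_arrays(best_arrays)
    model.eval()
    return model, log


def detect(
    model: CircleDetector,
    image: np.ndarray,
    score_threshold: float = 0.3,
    n_max: int = 100,
    nms_ciou: float | None = None,
    image_id: str = "",
) -> DetectionSet:
    """Run the detector on one HWC uint8 image.

    Images whose dimensions are not divisible by the output stride are
    zero-padded on the right/bottom and the detections are reported in the
    original coordinate frame (the padding transform is inverted; circles
    are translation-only under it).
    """
    k = model.cfg.output_stride
    h, w = image.shape[:2]
    div = model.input_divisor
    ph, pw = (-h) % div, (-w) % div
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)))
    model.eval()
    y_hat, o_hat, s_hat = model(Tensor(_normalize(image)[None]))
    size = s_hat.data[0]
    if model.cfg.head_type == "box":
        # box-head ablation: equivalent circle from predicted width/height
        size = 0.25 * (size[0:1] + size[1:2])
    dets = decode_circles(
        y_hat.data[0], o_hat.data[0], size, stride=k,
        n_max=n_max, score_threshold=score_threshold, image_id=image_id,
    )
    dets.input_dims = (w, h)
    dets.circles = [c for c in dets.circles if c.cx < w and c.cy < h]
    if nms_ciou is not None:
        dets = circle_nms(dets, nms_ciou)
    return dets


def _score(model: CircleDetector, samples: list[ImageSample], cfg: TrainConfig) -> EvalReport:
    per_image = []
    for s in samples:
        dets = detect(model, s.image, score_threshold=cfg.pr_floor, n_max=cfg.n_max)
        per_image.append((dets, s.circles))
    return evaluate_detections(
        per_image, cfg.eval_ciou_threshold, cfg.confidence_threshold
    )


def detect_dir(
    model: CircleDetector,
    image_dir: str | Path,
    out_dir: str | Path,
    score_threshold: float = 0.3,
    n_max: int = 100,
    nms_ciou: float | None = None,
) -> list[Path]:
    """Detect on every PNG/JPEG in a directory; write scored txt files."""
    image_dir, out_dir = Path(image_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    paths = sorted(
        [*image_dir.glob("*.png"), *image_dir.glob("*.jpg"), *image_dir.glob("*.jpeg")]
    )
    for path in paths:
        image = np.asarray(Image.open(path).convert("RGB"))
        dets = detect(model, image, score_threshold, n_max, nms_ciou, image_id=path.stem)
        out_path = out_dir / f"{path.stem}.txt"
        write_annotations(out_path, dets.circles, scores=True)
        written.append(out_path)
    return written


def _read_manifest(path: str | Path) -> dict[str, list[dict[str, str]]]:
    """Per-image ordered condition labels from the generator manifest."""
    per_image: dict[str, list[dict[str, str]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            labels = per_image.setdefault(row["image_id"], [])
            occ = row["occlusion"]
            labels.append(
                {
                    "lighting": row["lighting"],
                    # two-level occlusion scheme: unoccluded counts as slight
                    "occlusion": "severe" if occ == "severe" else "slight",
                }
            )
    return per_image


def evaluate_cmd(
    det_dir: str | Path,
    gt_dir: str | Path,
    manifest: str | Path | None = None,
    ciou_threshold: float = 0.5,
    confidence_threshold: float = 0.6,
    report_path: str | Path | None = None,
) -> EvalReport:
    """Evaluate detection txt files against ground-truth txt files.

    Every ground-truth file must have a detection counterpart; missing ids
    raise with the full list.  With a manifest, stratified lighting and
    occlusion tables are included.  ``report_path`` writes the report JSON
    plus a ``<stem>_pr.csv`` PR curve.
    """
    det_dir, gt_dir = Path(det_dir), Path(gt_dir)
    gt_files = sorted(gt_dir.glob("*.txt"))
    missing = [p.stem for p in gt_files if not (det_dir / p.name).is_file()]
    if missing:
        raise FileNotFoundError(f"no detection files for ids: {', '.join(missing)}")
    labels_by_image = _read_manifest(manifest) if manifest else None
    per_image, cond_labels = [], []
    for gt_path in gt_files:
        gts = read_annotations(gt_path)
        dets = read_annotations(det_dir / gt_path.name)
        per_image.append((dets, gts))
        if labels_by_image is not None:
            labels = labels_by_image.get(gt_path.stem, [])
            if len(labels) < len(gts):
                labels = labels + [
                    {"lighting": "sunlight", "occlusion": "slight"}
                ] * (len(gts) - len(labels))
            cond_labels.append(labels)
    report = evaluate_detections(
        per_image,
        ciou_threshold,
        confidence_threshold,
        cond_labels if labels_by_image is not None else None,
    )
    if report_path is not None:
        report_path = Path(report_path)
        report_path.parent.mkdir(parents=True, exist_ok=True)
        report_path.write_text(json.dumps(report.as_dict(), indent=1))
        with open(report_path.with_name(report_path.stem + "_pr.csv"), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["recall", "precision"])
            writer.writerows(report.pr_curve)
    return report
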