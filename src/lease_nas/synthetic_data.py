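"""Seeded generator of 4-class brain-MRI-like images, plus dataset I/O.

Real axial brain MRI cannot be redistributed here, so experiments run on a
synthetic emulation of the task: an elliptical "brain" on a dark background
with a class-specific bright structure:

* class 0 (glioma-like): an irregular bright blob at a random location in
  the upper interior of the brain;
* class 1 (meningioma-like): a bright crescent hugging the brain boundary;
* class 2 (pituitary-like): a small bright focus near the bottom-centre
  midline;
* class 3 (healthy): brain tissue only.

Classes are recoverable by construction: on noiseless images a hand-coded
location/intensity rule (:func:`rule_classify`) is exact. Default class
counts mirror the 2870-train / 394-test layout of the study data.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .explanations import LabeledBatch

__all__ = [
    "CLASS_NAMES",
    "SyntheticSpec",
    "generate_synthetic_mri",
    "rule_classify",
    "split_dataset",
    "load_image_folder",
    "save_image_folder",
    "default_augment",
]

CLASS_NAMES = ("glioma", "meningioma", "pituitary", "healthy")

# default per-class counts: 2870 training and 394 test images in total
TRAIN_COUNTS = (826, 822, 827, 395)
TEST_COUNTS = (100, 115, 74, 105)

_BG, _TISSUE, _BRIGHT = 0.03, 0.35, 0.95


@dataclass
class SyntheticSpec:
    image_size: int = 64
    counts: Tuple[int, int, int, int] = TRAIN_COUNTS
    noise_sd: float = 0.05
    rotation_deg: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if len(self.counts) != 4 or any(c < 1 for c in self.counts):
            raise ValueError("counts must be four integers >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _brain_mask(size: int, rng: np.random.Generator):
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2.0
    ay = size * rng.uniform(0.36, 0.42)
    ax = size * rng.uniform(0.30, 0.36)
    r = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    return (r <= 1.0), r, (cy, cx)


def _gaussian_spot(size, cy, cx, sigma):
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    return np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2)))


def _render_one(label: int, size: int, rng: np.random.Generator,
                noise_sd: float, rotation_deg: float) -> np.ndarray:
    mask, r2, (cy, cx) = _brain_mask(size, rng)
    img = np.full((size, size), _BG)
    img[mask] = _TISSUE
    sig = np.zeros((size, size))
    if label == 0:  # glioma-like: irregular interior blob, upper half
        bcy = cy - size * rng.uniform(0.06, 0.14)
        bcx = cx + size * rng.uniform(-0.08, 0.08)
        for _ in range(3):
            jy = bcy + size * rng.uniform(-0.03, 0.03)
            jx = bcx + size * rng.uniform(-0.03, 0.03)
            sigma = max(size * rng.uniform(0.035, 0.05), 1.2)
            sig = np.maximum(sig, _gaussian_spot(size, jy, jx, sigma))
    elif label == 1:  # meningioma-like: crescent at the rim
        band = (r2 > 0.72) & (r2 <= 1.0)
        theta = np.arctan2(
            np.mgrid[0:size, 0:size][0] - cy, np.mgrid[0:size, 0:size][1] - cx
        )
        t0 = rng.uniform(-np.pi, np.pi)
        width = rng.uniform(0.9, 1.3)
        ang = np.angle(np.exp(1j * (theta - t0)))
        sig = (band & (np.abs(ang) < width)).astype(np.float64)
        sig = ndimage.gaussian_filter(sig, size * 0.02)
    elif label == 2:  # pituitary-like: small bottom-centre focus
        fy = cy + size * rng.uniform(0.14, 0.20)
        fx = cx + size * rng.uniform(-0.05, 0.05)
        sig = _gaussian_spot(size, fy, fx, max(size * rng.uniform(0.022, 0.030), 1.2))
    img = np.where((sig > 0.35) & mask, _BRIGHT, img)
    if rotation_deg > 0:
        angle = rng.uniform(-rotation_deg, rotation_deg)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant",
                             cval=_BG)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_synthetic_mri(spec: SyntheticSpec) -> LabeledBatch:
    """Generate one labeled batch of synthetic 4-class brain images."""
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for label, count in enumerate(spec.counts):
        for _ in range(count):
            images.append(
                _render_one(label, spec.image_size, rng, spec.noise_sd,
                            spec.rotation_deg)
            )
            labels.append(label)
    arr = np.asarray(images, dtype=np.float32)[:, None, :, :]
    return LabeledBatch(images=arr, labels=np.asarray(labels))


def rule_classify(image: np.ndarray) -> int:
    """Hand-coded location/intensity rule; exact on noiseless images."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[0]
    size = img.shape[0]
    bright = img > 0.7
    if not bright.any():
        return 3
    ys, xs = np.nonzero(bright)
    cy = cx = (size - 1) / 2.0
    # normalized radial position of the farthest bright pixel
    ry = (ys - cy) / (size * 0.39)
    rx = (xs - cx) / (size * 0.33)
    if np.hypot(ry, rx).max() > 0.70:
        return 1  # rim-adjacent crescent
    if ys.mean() > cy + 0.08 * size:
        return 2  # small bottom-centre focus
    return 0


def split_dataset(data: LabeledBatch, fractions=(0.5, 0.5), seed: int = 0
                  ) -> Tuple[LabeledBatch, LabeledBatch]:
    """Label-stratified split into two disjoint, exhaustive parts.

    At a 50/50 split the per-class counts of the parts differ by at most 1.
    """
    if len(fractions) != 2 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be two numbers summing to 1")
    if min(fractions) <= 0:
        raise ValueError("both parts must be non-empty")
    rng = np.random.default_rng(seed)
    idx1, idx2 = [], []
    for cls in np.unique(data.labels):
        members = np.nonzero(data.labels == cls)[0]
        if len(members) < 2:
            raise ValueError(f"class {cls} has fewer than 2 examples")
        members = rng.permutation(members)
        n1 = int(round(fractions[0] * len(members)))
        n1 = min(max(n1, 1), len(members) - 1)
        idx1.extend(members[:n1])
        idx2.extend(members[n1:])
    idx1 = np.sort(np.asarray(idx1))
    idx2 = np.sort(np.asarray(idx2))
    return (
        LabeledBatch(data.images[idx1], data.labels[idx1]),
        LabeledBatch(data.images[idx2], data.labels[idx2]),
    )


def save_image_folder(batch: LabeledBatch, path, class_names=CLASS_NAMES,
                      manifest: bool = True) -> None:
    """Write a directory-per-class tree of 8-bit grayscale PNG files."""
    from PIL import Image

    root = Path(path)
    rows = []
    counters = {name: 0 for name in class_names}
    for img, label in zip(batch.images, batch.labels):
        name = class_names[int(label)]
        d = root / name
        d.mkdir(parents=True, exist_ok=True)
        arr = np.round(np.clip(img[0], 0, 1) * 255).astype(np.uint8)
        fname = f"{name}_{counters[name]:05d}.png"
        Image.fromarray(arr, mode="L").save(d / fname)
        rows.append({"filename": f"{name}/{fname}", "class": int(label)})
        counters[name] += 1
    if manifest:
        with open(root / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["filename", "class"])
            writer.writeheader()
            writer.writerows(rows)


def load_image_folder(path, image_size: int = 64, channels: int = 1
                      ) -> LabeledBatch:
    """Load a directory-per-class image tree (PNG/JPEG), resized and scaled.

    Class indices follow sorted directory-name order; unreadable files are
    skipped with a warning.
    """
    from PIL import Image

    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"image folder not found: {root}")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"no class subdirectories in {root}")
    images, labels = [], []
    skipped = 0
    for cls_idx, d in enumerate(class_dirs):
        files = sorted(
            f for f in d.iterdir()
            if f.suffix.lower() in (".png", ".jpg", ".jpeg")
        )
        if not files:
            raise FileNotFoundError(f"class directory {d} contains no images")
        for f in files:
            try:
                with Image.open(f) as im:
                    im = im.convert("L" if channels == 1 else "RGB")
                    im = im.resize((image_size, image_size), Image.BILINEAR)
                    arr = np.asarray(im, dtype=np.float32) / 255.0
            except Exception as exc:  # unreadable file
                warnings.warn(f"skipping unreadable image {f}: {exc}")
                skipped += 1
                continue
            if channels == 1:
                arr = arr[None, :, :]
            else:
                arr = arr.transpose(2, 0, 1)
            images.append(arr)
            labels.append(cls_idx)
    if skipped:
        warnings.warn(f"skipped {skipped} unreadable files in {root}")
    return LabeledBatch(np.asarray(images, dtype=np.float32),
                        np.asarray(labels))


def default_augment(images: np.ndarray, rng: np.random.Generator,
                    max_rotation: float = 10.0) -> np.ndarray:
    """Random horizontal flip plus a small rotation, per image."""
    out = np.empty_like(images)
    for i, img in enumerate(images):
        x = img
        if rng.random() < 0.5:
            x = x[:, :, ::-1]
        angle = rng.uniform(-max_rotation, max_rotation)
        x = ndimage.rotate(x, angle, axes=(1, 2), reshape=False, order=1,
                           mode="constant", cval=_BG)
        out[i] = x
    return np.clip(out, 0.0, 1.0)
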