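"""On-disk dataset layouts (PNG images + plain-text labels).

Classification sets are a directory per class of PNG images;
segmentation sets are parallel ``images/`` and ``masks/`` directories
with matching filenames, masks stored as single-channel PNGs holding one
integer label per pixel.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import List, Tuple

import numpy as np
from PIL import Image

__all__ = [
    "write_classification_dir",
    "read_classification_dir",
    "write_segmentation_dir",
    "read_segmentation_dir",
    "save_image",
    "load_image",
    "save_mask",
    "load_mask",
]


def save_image(path, image: np.ndarray) -> None:
    """Write a float [0, 1] (H, W, C) array as 8-bit PNG."""
    arr = np.clip(np.asarray(image) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def load_image(path) -> np.ndarray:
    """Read an image as float (H, W, 3) scaled to [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    return arr / 255.0


def save_mask(path, mask: np.ndarray) -> None:
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)


def load_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.int64)


def write_classification_dir(out_dir, images: np.ndarray, labels: np.ndarray) -> None:
    out = Path(out_dir)
    for i, (img, lab) in enumerate(zip(images, labels)):
        cls_dir = out / f"class_{int(lab)}"
        cls_dir.mkdir(parents=True, exist_ok=True)
        save_image(cls_dir / f"img_{i:05d}.png", img)


def read_classification_dir(data_dir) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Returns (images, integer labels, class names sorted alphabetically)."""
    root = Path(data_dir)
    classes = sorted(d.name for d in root.iterdir() if d.is_dir())
    if not classes:
        raise ValueError(f"no class subdirectories in {data_dir}")
    images, labels = [], []
    for ci, cname in enumerate(classes):
        for f in sorted((root / cname).iterdir()):
            images.append(load_image(f))
            labels.append(ci)
    return np.stack(images), np.asarray(labels), classes


def write_segmentation_dir(out_dir, images: np.ndarray, masks: np.ndarray) -> None:
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for i, (img, msk) in enumerate(zip(images, masks)):
        save_image(out / "images" / f"img_{i:05d}.png", img)
        save_mask(out / "masks" / f"img_{i:05d}.png", msk)


def read_segmentation_dir(data_dir) -> Tuple[np.ndarray, np.ndarray]:
    root = Path(data_dir)
    img_dir, msk_dir = root / "images", root / "masks"
    names = sorted(os.listdir(img_dir))
    if not names:
        raise ValueError(f"no images in {img_dir}")
    images = np.stack([load_image(img_dir / n) for n in names])
    masks = np.stack([load_mask(msk_dir / n) for n in names])
    return images, masks
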