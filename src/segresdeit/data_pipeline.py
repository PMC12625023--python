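"""Deterministic preprocessing of cytology image / mask pairs.

Every sample travels through the pipeline as an :class:`ImageMaskPair`:
a per-channel min-max normalised RGB image in ``[0, 1]``, a binary lesion
mask of the same height/width, and the image-level label derived from the
mask (positive iff any foreground pixel).  Resizing uses bilinear
interpolation for images and nearest-neighbour for masks so mask values stay
binary; overlapping patch grids are clamped at the margins so every pixel is
covered; the train/validation split is stratified on the label.

Coordinates are 0-based ``(row, col)``; patch windows are half-open
``[r, r+P) x [c, c+P)``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.transform import AffineTransform, resize as _sk_resize, warp as _sk_warp


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageMaskPair:
    """Normalised image + binary mask + derived image-level label."""

    image: np.ndarray  # (H, W, C) float in [0, 1]
    mask: np.ndarray  # (H, W) values in {0, 1}
    label: int  # 1 iff mask has any foreground pixel
    sample_id: str = ""

    def validate(self) -> "ImageMaskPair":
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask must share height and width")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary")
        if self.label != derive_label(self.mask):
            raise ValueError("label inconsistent with mask")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image values must lie in [0, 1]")
        return self


@dataclass
class PatchGrid:
    patch_size: int
    stride: int
    origins: list[tuple[int, int]]


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0
    stratify_on: str = "label"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def normalize_image(raw_image: np.ndarray) -> np.ndarray:
    """Per-channel min-max normalisation to [0, 1].

    A constant channel (max == min) maps to all zeros rather than failing.
    """
    raw_image = np.asarray(raw_image)
    if raw_image.size == 0:
        raise ValueError("empty image")
    if raw_image.ndim == 2:
        raw_image = raw_image[:, :, None]
    if raw_image.ndim != 3 or raw_image.shape[2] < 1:
        raise ValueError("expected a (H, W, C) image with at least one channel")
    x = raw_image.astype(np.float64)
    mins = x.min(axis=(0, 1), keepdims=True)
    maxs = x.max(axis=(0, 1), keepdims=True)
    span = maxs - mins
    out = np.zeros_like(x)
    np.divide(x - mins, span, out=out, where=span > 0)
    return out


def derive_label(mask: np.ndarray) -> int:
    """Image-level label: 1 iff the mask contains any foreground pixel."""
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask must contain only 0 and 1")
    return int(mask.any())


def resize_pair(pair: ImageMaskPair, target: tuple[int, int]) -> ImageMaskPair:
    """Resize image bilinearly and mask nearest-neighbour; re-derive the label.

    The label is recomputed because a tiny lesion can vanish under
    nearest-neighbour downscaling.
    """
    h, w = target
    if h <= 0 or w <= 0:
        raise ValueError("target dimensions must be positive")
    if (h, w) == pair.mask.shape:
        return ImageMaskPair(pair.image.copy(), pair.mask.copy(), pair.label,
                             pair.sample_id)
    image = _sk_resize(pair.image, (h, w), order=1, anti_aliasing=False,
                       preserve_range=True).clip(0.0, 1.0)
    mask = _sk_resize(pair.mask.astype(np.float64), (h, w), order=0,
                      anti_aliasing=False, preserve_range=True)
    mask = (mask > 0.5).astype(np.uint8)
    return ImageMaskPair(image, mask, derive_label(mask), pair.sample_id)


def build_patch_grid(image_dims: tuple[int, int], patch_size: int,
                     stride: int) -> PatchGrid:
    """Overlapping patch origins covering every pixel.

    Origins advance by `stride`; the final origin on each axis is clamped to
    ``dim - patch_size`` so margins are always covered.
    """
    h, w = image_dims
    if patch_size > min(h, w):
        raise ValueError("patch_size exceeds image dimensions")
    if not (0 < stride <= patch_size):
        raise ValueError("stride must satisfy 0 < stride <= patch_size")

    def axis_origins(dim: int) -> list[int]:
        xs = list(range(0, dim - patch_size + 1, stride))
        if xs[-1] != dim - patch_size:
            xs.append(dim - patch_size)
        return xs

    origins = [(r, c) for r in axis_origins(h) for c in axis_origins(w)]
    return PatchGrid(patch_size=patch_size, stride=stride, origins=origins)


def extract_patches(pair: ImageMaskPair, grid: PatchGrid) -> list[ImageMaskPair]:
    """Cut a pair into the grid's patches, re-deriving each patch label."""
    out = []
    p = grid.patch_size
    for i, (r, c) in enumerate(grid.origins):
        img = pair.image[r : r + p, c : c + p]
        msk = pair.mask[r : r + p, c : c + p]
        out.append(ImageMaskPair(img.copy(), msk.copy(), derive_label(msk),
                                 f"{pair.sample_id}_p{i}"))
    return out


def augment_pair(
    pair: ImageMaskPair,
    seed: int,
    max_rotation_deg: float = 15.0,
    zoom_range: tuple[float, float] = (0.8, 1.2),
    brightness_range: tuple[float, float] = (0.8, 1.2),
) -> ImageMaskPair:
    """Random flip / rotate / zoom / brightness augmentation.

    The identical spatial transform is applied to image (bilinear) and mask
    (nearest-neighbour); out-of-bounds regions are filled with 0 for both.
    Brightness scaling touches the image only and is clipped to [0, 1].
    Fully reproducible from `seed`.
    """
    rng = np.random.default_rng(seed)
    flip_h = rng.random() < 0.5
    flip_v = rng.random() < 0.5
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    zoom = rng.uniform(*zoom_range)
    brightness = rng.uniform(*brightness_range)

    image = pair.image
    mask = pair.mask
    if flip_h:
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    if flip_v:
        image = image[::-1, :]
        mask = mask[::-1, :]
    if angle != 0.0 or zoom != 1.0:
        h, w = mask.shape
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        tf = (
            AffineTransform(translation=-center)
            + AffineTransform(rotation=np.deg2rad(angle), scale=(zoom, zoom))
            + AffineTransform(translation=center)
        )
        inv = tf.inverse
        image = _sk_warp(image, inv, order=1, mode="constant", cval=0.0,
                         preserve_range=True)
        mask = _sk_warp(mask.astype(np.float64), inv, order=0, mode="constant",
                        cval=0.0, preserve_range=True)
        mask = (mask > 0.5).astype(np.uint8)
    else:
        image = np.ascontiguousarray(image)
        mask = np.ascontiguousarray(mask)
    image = np.clip(image * brightness, 0.0, 1.0)
    return ImageMaskPair(image, mask.astype(np.uint8), derive_label(mask),
                         pair.sample_id)


def stratified_split(
    labels: Sequence[int], spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation index split.

    The train set holds ``round(train_fraction * n)`` samples overall; that
    total is allocated across classes by largest fractional remainder so each
    class is split at the same fraction to within one sample.  Classes with
    fewer than 2 members go entirely to train (with a warning).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    rng = np.random.default_rng(spec.seed)
    n = labels.size
    n_train_total = int(round(spec.train_fraction * n))

    classes = np.unique(labels)
    idx_by_class = {c: np.where(labels == c)[0] for c in classes}
    forced_train: list[np.ndarray] = []
    splittable = []
    for c in classes:
        idx = idx_by_class[c]
        if idx.size < 2:
            warnings.warn(f"class {c} has fewer than 2 members; placed in train")
            forced_train.append(idx)
        else:
            splittable.append(c)
    n_forced = sum(ix.size for ix in forced_train)

    target = max(n_train_total - n_forced, 0)
    sizes = np.array([idx_by_class[c].size for c in splittable])
    exact = spec.train_fraction * sizes
    base = np.floor(exact).astype(int)
    base = np.minimum(base, sizes - 1)  # leave at least one per class for validation
    short = target - base.sum()
    if short > 0:
        order = np.argsort(-(exact - base), kind="stable")
        for j in order[: min(short, len(order))]:
            if base[j] < sizes[j] - 1:
                base[j] += 1

    train_parts, val_parts = list(forced_train), []
    for c, k in zip(splittable, base):
        idx = idx_by_class[c].copy()
        rng.shuffle(idx)
        train_parts.append(idx[:k])
        val_parts.append(idx[k:])
    train = np.sort(np.concatenate(train_parts)) if train_parts else np.array([], int)
    val = np.sort(np.concatenate(val_parts)) if val_parts else np.array([], int)
    return train, val


# ---------------------------------------------------------------------------
# external interfaces: PNG / CSV manifest / array cache
# ---------------------------------------------------------------------------


def load_pair(image_path: str | Path, mask_path: str | Path,
              sample_id: str = "", normalize: bool = True) -> ImageMaskPair:
    """Load an image (PNG/TIFF/JPEG) and its mask PNG; binarise the mask at >0.

    With ``normalize=True`` the image goes through per-channel min-max
    normalisation; otherwise 8-bit values are scaled by 1/255.
    """
    raw = np.asarray(Image.open(image_path).convert("RGB"))
    mask = np.asarray(Image.open(mask_path).convert("L"))
    mask = (mask > 0).astype(np.uint8)
    image = normalize_image(raw) if normalize else raw.astype(np.float64) / 255.0
    return ImageMaskPair(image, mask, derive_label(mask),
                         sample_id or Path(image_path).stem)


def read_manifest(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def load_dataset(manifest_path: str | Path, normalize: bool = True) -> list[ImageMaskPair]:
    root = Path(manifest_path).parent
    pairs = []
    for row in read_manifest(manifest_path):
        img = root / row["image_path"]
        msk = root / row["mask_path"]
        pairs.append(load_pair(img, msk, row["sample_id"], normalize=normalize))
    return pairs


def write_split_csv(path: str | Path, sample_ids: Sequence[str],
                    train_idx: np.ndarray, val_idx: np.ndarray) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "partition"])
        for i in train_idx:
            writer.writerow([sample_ids[i], "train"])
        for i in val_idx:
            writer.writerow([sample_ids[i], "validation"])


def save_cache(path: str | Path, pairs: Sequence[ImageMaskPair]) -> None:
    """Persist a split as stacked arrays for fast batch loading."""
    np.savez_compressed(
        path,
        images=np.stack([p.image for p in pairs]),
        masks=np.stack([p.mask for p in pairs]),
        labels=np.array([p.label for p in pairs]),
        sample_ids=np.array([p.sample_id for p in pairs]),
    )


def load_cache(path: str | Path) -> list[ImageMaskPair]:
    data = np.load(path, allow_pickle=False)
    return [
        ImageMaskPair(img, msk.astype(np.uint8), int(lab), str(sid))
        for img, msk, lab, sid in zip(
            data["images"], data["masks"], data["labels"], data["sample_ids"]
        )
    ]
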