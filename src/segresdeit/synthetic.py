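"""Synthetic bright-field cytology fixtures with exact ground truth.

Generates Pap-smear-like RGB images: a light, smoothly varying background
texture, scattered round "normal cell" blobs (small dark nuclei with faint
cytoplasm halos), and — with configurable probability — one or more compact
irregular "abnormal" lesion regions (radially perturbed star-convex polygons
with internal texture).  The binary mask is exactly the union of lesion
regions, so every sample's image-level label is known by construction and a
segmentation/classification model can be trained and scored end to end with
no external data.

What these fixtures do NOT emulate: real staining chemistry, overlapping
cell clusters, scanner artefacts, or class-conditional morphology subtler
than the geometry/contrast encoded here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage.draw import disk as _sk_disk, polygon as _sk_polygon

from .data_pipeline import ImageMaskPair, derive_label


@dataclass
class SynthConfig:
    """Generation parameters; fully reproducible from `seed`.

    Defaults are unit-test scale (64x64); integration tests use 256x256.
    """

    n_images: int = 16
    image_size: tuple[int, int] = (64, 64)
    lesion_probability: float = 0.5
    lesion_count_range: tuple[int, int] = (1, 2)
    lesion_radius_range: tuple[int, int] = (7, 13)
    background_cell_count: int = 12
    noise_sd: float = 0.02
    seed: int = 0


def _lesion_polygon(rng: np.random.Generator, center: tuple[float, float],
                    radius: float, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Star-convex radially perturbed polygon (always one connected region)."""
    n_vert = 24
    theta = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
    wobble = 1.0 + 0.35 * np.sin(theta * rng.integers(2, 5) + rng.uniform(0, 2 * np.pi))
    wobble += rng.normal(0, 0.05, n_vert)
    r = np.clip(radius * wobble, 2.0, None)
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    return _sk_polygon(rows, cols, shape=shape)


def _render_sample(rng: np.random.Generator, cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    h, w = cfg.image_size
    if h <= 0 or w <= 0:
        raise ValueError("image size must be positive")

    # light pinkish bright-field background with low-frequency texture
    base = np.array([0.88, 0.82, 0.86])
    image = np.broadcast_to(base, (h, w, 3)).copy()
    lowfreq = ndi.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=max(h, w) / 8)
    span = np.ptp(lowfreq)
    if span > 0:
        lowfreq = (lowfreq - lowfreq.min()) / span - 0.5
    image += 0.06 * lowfreq[:, :, None]

    # normal cells: faint cytoplasm halo + small dark blue nucleus
    for _ in range(cfg.background_cell_count):
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        halo_r = rng.uniform(3, 6) * min(h, w) / 64
        rr, cc = _sk_disk((r0, c0), halo_r, shape=(h, w))
        image[rr, cc] += np.array([-0.05, -0.03, 0.02])
        rr, cc = _sk_disk((r0, c0), max(halo_r * 0.4, 1.2), shape=(h, w))
        image[rr, cc] = np.array([0.30, 0.32, 0.55]) + rng.normal(0, 0.02, 3)

    # abnormal lesions: larger, dark purple, textured, irregular outline
    mask = np.zeros((h, w), dtype=np.uint8)
    if rng.random() < cfg.lesion_probability:
        lo, hi = cfg.lesion_count_range
        n_lesions = int(rng.integers(lo, hi + 1))
        scale = min(h, w) / 64
        for _ in range(n_lesions):
            radius = rng.uniform(*cfg.lesion_radius_range) * scale
            margin = radius + 2
            r0 = rng.uniform(margin, max(h - margin, margin + 1))
            c0 = rng.uniform(margin, max(w - margin, margin + 1))
            rr, cc = _lesion_polygon(rng, (r0, c0), radius, (h, w))
            if rr.size == 0:
                continue
            texture = 0.08 * np.sin(rr * 0.9) * np.cos(cc * 0.9)
            color = np.array([0.42, 0.22, 0.48])
            image[rr, cc] = color + texture[:, None] + rng.normal(0, 0.015, (rr.size, 3))
            mask[rr, cc] = 1

    if cfg.noise_sd > 0:
        image += rng.normal(0, cfg.noise_sd, image.shape)
    return np.clip(image, 0.0, 1.0), mask


def generate_dataset(config: SynthConfig) -> list[ImageMaskPair]:
    """Generate `config.n_images` image/mask pairs (bit-identical per seed)."""
    rng = np.random.default_rng(config.seed)
    pairs = []
    for i in range(config.n_images):
        image, mask = _render_sample(rng, config)
        pairs.append(
            ImageMaskPair(image, mask, derive_label(mask), f"synth_{config.seed}_{i:04d}")
        )
    return pairs


def write_fixture_set(pairs: Sequence[ImageMaskPair], directory: str | Path) -> Path:
    """Write PNG images + PNG masks + a CSV manifest; returns the manifest path.

    Images are quantised to 8-bit; masks use 0/255 and binarise back exactly
    on load through the data-pipeline loaders.
    """
    if not pairs:
        raise ValueError("cannot write an empty fixture set")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "image_path", "mask_path"])
        for pair in pairs:
            img_name = f"{pair.sample_id}.png"
            msk_name = f"{pair.sample_id}_mask.png"
            Image.fromarray(
                np.round(pair.image * 255).astype(np.uint8)
            ).save(directory / img_name)
            Image.fromarray((pair.mask * 255).astype(np.uint8)).save(directory / msk_name)
            writer.writerow([pair.sample_id, img_name, msk_name])
    return manifest
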