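"""Whole-slide tissue segmentation, patch extraction, and patch encoding.

Segmentation works on a downsampled copy of the slide: RGB is converted to
HSV, the saturation channel is thresholded (Otsu by default) to separate
stained tissue from the unstained background and holes, and the binary mask
is smoothed with a median filter and morphological closing. The mask is tiled
into grid-aligned, non-overlapping ``patch_size`` x ``patch_size`` tiles (in
level-0 pixels), keeping those whose tissue coverage reaches
``min_tissue_frac``. Each kept patch is resized to 224 x 224 and mapped to a
d-vector by a pluggable encoder callable; a deterministic statistics-based
toy encoder is provided for tests and synthetic experiments. Pretrained
pathology foundation models can be plugged in through the same interface.

The whole path operates on in-memory RGB arrays, so no slide files are needed;
pyramidal TIFFs can be loaded with tifffile and passed in as arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy import ndimage
from skimage import color, filters, morphology, transform

from .cohort_io import EmbeddingBag


@dataclass
class TissueMask:
    mask: np.ndarray  # bool, at 1/downsample scale
    downsample: int
    level0_shape: tuple[int, int]  # (height, width) of the source image

    def tissue_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


@dataclass
class PatchGrid:
    patch_size: int
    coords: np.ndarray  # (k, 2) level-0 (x, y) tile origins, 0-based
    tissue_frac: np.ndarray  # (k,) mask coverage per kept tile

    def __len__(self) -> int:
        return len(self.coords)


class PatchEncoder(Protocol):
    """Deterministic map from a 224 x 224 x 3 uint8 patch to a d-vector."""

    dim: int
    name: str

    def __call__(self, patch: np.ndarray) -> np.ndarray: ...


def segment_tissue(image: np.ndarray, downsample: int = 32,
                   sat_threshold: float | str = "auto",
                   blur_kernel: int = 7, close_kernel: int = 9) -> TissueMask:
    """Binary tissue mask from an RGB image (H x W x 3, uint8 or float)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    h, w = image.shape[:2]
    small = transform.resize(image, (max(1, h // downsample), max(1, w // downsample)),
                             preserve_range=True, anti_aliasing=True)
    sat = color.rgb2hsv(small / 255.0 if small.max() > 1.5 else small)[..., 1]
    if sat_threshold == "auto":
        if np.ptp(sat) < 1e-3:
            # uniform saturation: Otsu is undefined; fall back to a fixed cut
            # (all-background stays empty, a uniformly stained image is all tissue)
            thr = 0.05
        else:
            thr = filters.threshold_otsu(sat)
    else:
        thr = float(sat_threshold)
    mask = sat > thr
    if blur_kernel > 1:
        mask = ndimage.median_filter(mask.astype(np.uint8), size=blur_kernel).astype(bool)
    if close_kernel > 1:
        footprint = morphology.footprint_rectangle((close_kernel, close_kernel))
        mask = morphology.closing(mask, footprint)
    return TissueMask(mask, downsample, (h, w))


def extract_patches(tissue: TissueMask, patch_size: int = 512,
                    min_tissue_frac: float = 0.5) -> PatchGrid:
    """Grid-aligned non-overlapping tiles with tissue coverage >= threshold."""
    h, w = tissue.level0_shape
    ds = tissue.downsample
    block = max(1, patch_size // ds)
    coords, fracs = [], []
    for y in range(0, h - patch_size + 1, patch_size):
        for x in range(0, w - patch_size + 1, patch_size):
            my, mx = y // ds, x // ds
            sub = tissue.mask[my:my + block, mx:mx + block]
            frac = float(sub.mean()) if sub.size else 0.0
            if frac >= min_tissue_frac:
                coords.append((x, y))
                fracs.append(frac)
    return PatchGrid(patch_size,
                     np.array(coords, dtype=np.int64).reshape(-1, 2),
                     np.array(fracs, dtype=float))


def encode_patches(image: np.ndarray, grid: PatchGrid, encoder: PatchEncoder,
                   patient_id: str = "", target_size: int = 224) -> EmbeddingBag:
    """Resize each tile to ``target_size`` and encode it; bag rows follow grid order."""
    if len(grid) == 0:
        raise ValueError("no patches to encode (empty grid)")
    rows = []
    for x, y in grid.coords:
        patch = image[y:y + grid.patch_size, x:x + grid.patch_size]
        patch = transform.resize(patch, (target_size, target_size),
                                 preserve_range=True, anti_aliasing=True)
        vec = np.asarray(encoder(patch.astype(np.uint8)), dtype=np.float32)
        if vec.shape != (encoder.dim,):
            raise ValueError(
                f"encoder {encoder.name!r} returned shape {vec.shape}, expected ({encoder.dim},)")
        rows.append(vec)
    return EmbeddingBag(patient_id, np.stack(rows), coords=grid.coords.copy())


class ToyStatEncoder:
    """Deterministic toy encoder: per-channel mean, standard deviation and an
    8-bin intensity histogram, passed through a fixed seeded random projection.

    Stands in for pretrained encoders in tests; it separates patches by
    colour and texture but carries no learned histology semantics.
    """

    name = "toy-stats"

    def __init__(self, dim: int = 32, seed: int = 7):
        self.dim = dim
        rng = np.random.default_rng(seed)
        self._proj = rng.normal(0, 1.0 / np.sqrt(30), size=(30, dim))

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch, dtype=float)
        if patch.max() > 1.5:
            patch = patch / 255.0
        stats = []
        for c in range(3):
            ch = patch[..., c]
            stats.extend([ch.mean(), ch.std()])
            hist, _ = np.histogram(ch, bins=8, range=(0, 1))
            stats.extend(hist / ch.size)
        return (np.array(stats) @ self._proj).astype(np.float32)


def run_wsi_pipeline(image: np.ndarray, encoder: PatchEncoder, patient_id: str = "",
                     downsample: int = 32, patch_size: int = 512,
                     min_tissue_frac: float = 0.5, **seg_kwargs) -> EmbeddingBag | None:
    """Segment, tile and encode one slide image; None when no tissue found."""
    mask = segment_tissue(image, downsample=downsample, **seg_kwargs)
    grid = extract_patches(mask, patch_size, min_tissue_frac)
    if len(grid) == 0:
        return None
    return encode_patches(image, grid, encoder, patient_id)
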