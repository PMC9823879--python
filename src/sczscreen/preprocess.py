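"""Slice loading, resizing and threshold-based skull stripping.

All images are held as :class:`GrayImage`: a 2D float raster with 8-bit
semantics (values in [0, 255]) plus an optional boolean brain mask.
Volumes (NIfTI) are reduced to a centered block of axial slices, each
min-max scaled to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk
from skimage.transform import resize as _sk_resize

__all__ = ["GrayImage", "load_slices", "resize", "skull_strip"]


@dataclass
class GrayImage:
    """2D intensity raster in [0, 255] with an optional brain mask."""

    pixels: np.ndarray
    brain_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage requires a 2D raster")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.pixels.shape:
                raise ValueError("mask shape must equal pixel shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)

    def save_png(self, path) -> None:
        Image.fromarray(self.to_uint8()).save(path)


def _scale_slice(sl: np.ndarray) -> np.ndarray:
    """Min-max scale one slice to [0, 255]; a constant slice maps to 0."""
    lo, hi = float(sl.min()), float(sl.max())
    if hi <= lo:
        return np.zeros_like(sl, dtype=float)
    return (sl - lo) / (hi - lo) * 255.0


def load_slices(path, plane: str = "axial", n_slices: int = 30) -> list[GrayImage]:
    """Load a 2D image file or extract central axial slices from a NIfTI volume.

    2D files pass through unchanged (clipped to [0, 255]); volumes yield
    ``n_slices`` contiguous central slices along the axial (third) axis,
    each min-max scaled to [0, 255].
    """
    if plane != "axial":
        raise ValueError(f"unsupported plane {plane!r}")
    path = Path(path)
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
        if vol.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {vol.shape}")
        nz = vol.shape[2]
        if nz < n_slices:
            raise ValueError(f"volume has {nz} axial slices, {n_slices} requested")
        start = (nz - n_slices) // 2
        return [GrayImage(_scale_slice(vol[:, :, z])) for z in range(start, start + n_slices)]
    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    return [GrayImage(np.clip(arr, 0, 255))]


def resize(img: GrayImage, size: tuple[int, int] = (224, 224)) -> GrayImage:
    """Bilinear resize, re-clipped to [0, 255]; identity when shapes match."""
    if size[0] <= 0 or size[1] <= 0:
        raise ValueError("target size must be positive")
    if img.shape == tuple(size):
        return GrayImage(img.pixels.copy(), None if img.brain_mask is None else img.brain_mask.copy())
    out = _sk_resize(img.pixels, size, order=1, preserve_range=True, anti_aliasing=False)
    mask = None
    if img.brain_mask is not None:
        mask = _sk_resize(img.brain_mask.astype(float), size, order=0, preserve_range=True) > 0.5
    return GrayImage(np.clip(out, 0, 255), mask)


def skull_strip(img: GrayImage, erosion_radius: int = 6) -> GrayImage:
    """Remove the bright cranial rim with a threshold filter.

    Procedure: binarize at Otsu's single threshold; fill the head outline;
    erode the filled head by ``erosion_radius`` to obtain a core that the
    skull annulus cannot reach; keep bright components that touch the core
    (the annulus does not); the brain mask is the largest such component
    with its interior holes (CSF pockets) filled.  Pixels outside the mask
    are set to 0.
    """
    pixels = img.pixels
    if pixels.max() <= pixels.min():
        raise ValueError("no head found: empty foreground after thresholding")
    thr = threshold_otsu(pixels)
    bright = pixels > thr
    if not bright.any():
        raise ValueError("no head found: empty foreground after thresholding")
    head = ndi.binary_fill_holes(bright)
    core = ndi.binary_erosion(head, structure=disk(erosion_radius))
    labels = cc_label(bright)
    keep_ids = np.unique(labels[core & (labels > 0)])
    if keep_ids.size == 0:
        raise ValueError("no head found: nothing remains after rim removal")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=keep_ids)
    largest = keep_ids[int(np.argmax(sizes))]
    mask = ndi.binary_fill_holes(labels == largest)
    out = np.where(mask, pixels, 0.0)
    return GrayImage(out, mask)
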