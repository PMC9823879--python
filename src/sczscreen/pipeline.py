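"""High-level orchestration: slice -> features -> fused evaluation.

These helpers chain the stage modules with consistent defaults so the CLI,
the tests and phantom experiments run the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .deep_features import FixtureBackbone, extract_df
from .handcrafted_features import (
    HFBlock,
    assemble_hf,
    glcm_features,
    lbp_histogram,
    lbp_weighted_image,
)
from .mayfly import MayflyParams
from .preprocess import GrayImage, skull_strip
from .segmentation import MRFConfig, segment_slice

__all__ = ["extract_hf", "extract_features", "default_otsu_params"]


def default_otsu_params(seed: int = 0, n_flies: int = 16, max_iter: int = 60) -> MayflyParams:
    """Mayfly budget for the 2-D threshold search (a small swarm suffices)."""
    return MayflyParams.for_box(1.0, 254.0, 2, n_flies=n_flies, max_iter=max_iter, seed=seed)


def extract_hf(
    img: GrayImage,
    moa_params: Optional[MayflyParams] = None,
    mrf_cfg: Optional[MRFConfig] = None,
) -> HFBlock:
    """286-dim handcrafted block of one skull-stripped slice.

    GLCM descriptors from the segmented WM and GM maps plus weighted-LBP
    histograms (W = 1..4) over the whole brain mask.
    """
    if img.brain_mask is None:
        raise ValueError("extract_hf requires a brain mask (run skull_strip first)")
    tissues, _, _ = segment_slice(img, moa_params=moa_params, mrf_cfg=mrf_cfg)
    g_wm = glcm_features(tissues.wm_image, tissues.wm_mask, tissue="wm")
    g_gm = glcm_features(tissues.gm_image, tissues.gm_mask, tissue="gm")
    hists = []
    for w in (1, 2, 3, 4):
        codes, valid = lbp_weighted_image(img, w)
        hists.append(lbp_histogram(codes, valid, weight=w))
    return assemble_hf(g_wm, g_gm, hists)


def extract_features(
    images: Sequence[GrayImage],
    backbone=None,
    strip: bool = True,
    otsu_seed: int = 0,
    mrf_cfg: Optional[MRFConfig] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice handcrafted (n, 286) and deep (n, 1024) feature matrices."""
    backbone = FixtureBackbone() if backbone is None else backbone
    hf_rows = []
    stripped = []
    for i, img in enumerate(images):
        s = skull_strip(img) if strip or img.brain_mask is None else img
        stripped.append(s)
        hf_rows.append(extract_hf(s, moa_params=default_otsu_params(seed=otsu_seed + i), mrf_cfg=mrf_cfg).values)
    hf = np.vstack(hf_rows)
    df = extract_df(stripped, backbone)
    return hf, df
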