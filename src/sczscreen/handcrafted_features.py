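"""Handcrafted texture features: GLCM descriptors and weighted-LBP histograms.

The handcrafted block of one slice is the fixed-order concatenation

    [GLCM_WM(25), GLCM_GM(25), LBP_W1(59), LBP_W2(59), LBP_W3(59), LBP_W4(59)]

for a total of 286 named features.

GLCM descriptors are computed on masked tissue images (both pixels of a
pair must be in-mask), quantized to 8 gray levels over the fixed [0, 255]
range, symmetrized, normalized, and averaged over the four standard
directions at distance 1.

The weighted LBP compares each neighbor against a threshold that blends a
local reference — the average local gray level ALGL = (sum of the 8
neighbors + 8*center)/9 — with a global weighted gray level W*(mu+sigma),
where mu and sigma are the masked-image mean and standard deviation and
W in {1..4} is the weight control.  The comparison uses ties-as-one
(s(0) = 1).  Codes are pooled into the standard 59-bin uniform-pattern
histogram (58 uniform codes in ascending order, one pooled bin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.feature import graycomatrix

from .preprocess import GrayImage

__all__ = [
    "GLCM_NAMES",
    "GLCMFeatures",
    "LBPHistogram",
    "HFBlock",
    "glcm_features",
    "lbp_code",
    "lbp_weighted_image",
    "lbp_histogram",
    "assemble_hf",
    "hf_feature_names",
    "compute_glcm_descriptors",
    "uniform_bin_of_code",
    "N_UNIFORM_BINS",
]

GLCM_NAMES = [
    "contrast",
    "correlation",
    "energy",
    "homogeneity",
    "entropy",
    "dissimilarity",
    "maximum_probability",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "autocorrelation",
    "cluster_shade",
    "cluster_prominence",
    "inverse_difference",
    "inverse_difference_moment_normalized",
    "inverse_difference_normalized",
    "imc1",
    "imc2",
    "variance",
    "mean",
    "joint_max_row_mean",
    "trace",
    "marginal_uniformity",
]


@dataclass
class GLCMFeatures:
    values: np.ndarray  # length 25
    tissue: str  # "wm" or "gm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (25,):
            raise ValueError("GLCM feature vector must have length 25")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GLCM features must be finite")


@dataclass
class LBPHistogram:
    bins: np.ndarray  # length 59
    weight: int  # W in {1..4}

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (59,):
            raise ValueError("LBP histogram must have 59 bins")


@dataclass
class HFBlock:
    values: np.ndarray  # length 286
    names: list[str]


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def compute_glcm_descriptors(P: np.ndarray) -> np.ndarray:
    """The 25 descriptors of one normalized, symmetric co-occurrence matrix."""
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    i = np.arange(n, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    p_sum = np.zeros(2 * n - 1)  # p_{x+y}, k = 0 .. 2(n-1)
    p_diff = np.zeros(n)  # p_{|x-y|}
    np.add.at(p_sum, (I + J).astype(int).ravel(), P.ravel())
    np.add.at(p_diff, np.abs(I - J).astype(int).ravel(), P.ravel())
    k_sum = np.arange(2 * n - 1, dtype=float)
    k_diff = np.arange(n, dtype=float)

    contrast = float(((I - J) ** 2 * P).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float((((I - mu_x) * (J - mu_y)) * P).sum() / (sd_x * sd_y))
    else:
        correlation = 1.0
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + (I - J) ** 2)).sum())
    entropy = float(-_xlog2(P).sum())
    dissimilarity = float((np.abs(I - J) * P).sum())
    max_prob = float(P.max())
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = float(-_xlog2(p_sum).sum())
    diff_mean = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    diff_ent = float(-_xlog2(p_diff).sum())
    autocorr = float((I * J * P).sum())
    shade = float(((I + J - mu_x - mu_y) ** 3 * P).sum())
    prominence = float(((I + J - mu_x - mu_y) ** 4 * P).sum())
    inv_diff = float((P / (1.0 + np.abs(I - J))).sum())
    idmn = float((P / (1.0 + (I - J) ** 2 / n**2)).sum())
    idn = float((P / (1.0 + np.abs(I - J) / n)).sum())

    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-(P * log_pxy).sum())
    hxy2 = float(-_xlog2(pxy).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    variance = sd_x**2
    mean_idx = mu_x
    row_max_mean = float(P.max(axis=1).mean())
    trace = float(np.trace(P))
    marg_unif = float((px**2).sum())

    return np.array(
        [
            contrast,
            correlation,
            energy,
            homogeneity,
            entropy,
            dissimilarity,
            max_prob,
            sum_avg,
            sum_var,
            sum_ent,
            diff_var,
            diff_ent,
            autocorr,
            shade,
            prominence,
            inv_diff,
            idmn,
            idn,
            imc1,
            imc2,
            variance,
            mean_idx,
            row_max_mean,
            trace,
            marg_unif,
        ]
    )


def quantize(image: np.ndarray, levels: int = 8) -> np.ndarray:
    """Uniform quantization of [0, 255] intensities into ``levels`` bins."""
    q = (np.clip(image, 0, 255) * levels / 256.0).astype(int)
    return np.minimum(q, levels - 1)


def glcm_features(
    tissue_image: np.ndarray,
    mask: np.ndarray,
    tissue: str = "wm",
    levels: int = 8,
    distances: Sequence[int] = (1,),
    angles: Sequence[float] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4),
) -> GLCMFeatures:
    """Angle-averaged GLCM descriptors over the masked tissue image.

    Pairs are counted only when both pixels are in the mask (out-of-mask
    pixels are mapped to a sentinel level excluded from the matrix).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 in-mask pixels")
    q = quantize(np.asarray(tissue_image, dtype=float), levels)
    q = np.where(mask, q, levels).astype(np.uint8)  # sentinel = levels
    mats = graycomatrix(q, distances=list(distances), angles=list(angles), levels=levels + 1, symmetric=True)
    acc = np.zeros(25)
    n_used = 0
    for di in range(len(distances)):
        for ai in range(len(angles)):
            M = mats[:levels, :levels, di, ai].astype(float)
            s = M.sum()
            if s == 0:
                continue
            acc += compute_glcm_descriptors(M / s)
            n_used += 1
    if n_used == 0:
        raise ValueError("no in-mask pixel pairs for the GLCM")
    return GLCMFeatures(values=acc / n_used, tissue=tissue)


# ---------------------------------------------------------------------------
# weighted LBP

# neighbor order (bit q -> offset): E, NE, N, NW, W, SW, S, SE
NEIGHBOR_OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def lbp_code(center: float, neighbors: Sequence[float], threshold: Optional[float] = None) -> int:
    """8-bit LBP code; s = 1 iff neighbor >= threshold (default: the center)."""
    neighbors = list(neighbors)
    if len(neighbors) != 8:
        raise ValueError("exactly 8 neighbors required")
    thr = center if threshold is None else threshold
    code = 0
    for q, ng in enumerate(neighbors):
        if ng >= thr:
            code |= 1 << q
    return code


def _transitions(code: int) -> int:
    bits = [(code >> q) & 1 for q in range(8)]
    return sum(bits[q] != bits[(q + 1) % 8] for q in range(8))


_UNIFORM_CODES = [c for c in range(256) if _transitions(c) <= 2]  # 58 codes
_CODE_TO_BIN = np.full(256, 58, dtype=int)
for _b, _c in enumerate(_UNIFORM_CODES):
    _CODE_TO_BIN[_c] = _b
N_UNIFORM_BINS = 59


def uniform_bin_of_code(code: int) -> int:
    """Map an 8-bit code to its 59-bin slot (58 = pooled non-uniform bin)."""
    return int(_CODE_TO_BIN[code])


def lbp_weighted_image(
    img: GrayImage, W: int, mask: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-LBP code image for weight control W in {1..4}.

    The per-pixel comparison threshold is ``(ALGL + W*(mu+sigma)) / 2``
    with ALGL the local 3x3 weighted average and mu/sigma taken over the
    masked pixels.  Returns ``(codes, valid)`` where ``valid`` marks
    interior pixels whose full 8-neighborhood lies in the mask.
    """
    if W not in (1, 2, 3, 4):
        raise ValueError("W must be in {1, 2, 3, 4}")
    pixels = img.pixels
    mask = img.brain_mask if mask is None else mask
    if mask is None:
        mask = np.ones(pixels.shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    mu = float(pixels[mask].mean())
    sigma = float(pixels[mask].std())
    g_w = W * (mu + sigma)

    h, w = pixels.shape
    valid = mask.copy()
    valid[0, :] = valid[-1, :] = valid[:, 0] = valid[:, -1] = False
    neigh = np.empty((8, h, w))
    for q, (dy, dx) in enumerate(NEIGHBOR_OFFSETS):
        arr = np.full((h, w), np.nan)
        arr[max(-dy, 0) : h - max(dy, 0), max(-dx, 0) : w - max(dx, 0)] = pixels[
            max(dy, 0) : h + min(dy, 0), max(dx, 0) : w + min(dx, 0)
        ]
        neigh[q] = arr
        m = np.zeros((h, w), dtype=bool)
        m[max(-dy, 0) : h - max(dy, 0), max(-dx, 0) : w - max(dx, 0)] = mask[
            max(dy, 0) : h + min(dy, 0), max(dx, 0) : w + min(dx, 0)
        ]
        valid &= m

    algl = (np.nansum(neigh, axis=0) + 8.0 * pixels) / 9.0
    thr = (algl + g_w) / 2.0
    codes = np.zeros((h, w), dtype=np.uint8)
    for q in range(8):
        with np.errstate(invalid="ignore"):
            codes |= ((neigh[q] >= thr) << q).astype(np.uint8)
    codes[~valid] = 0
    return codes, valid


def lbp_histogram(codes: np.ndarray, valid: np.ndarray, weight: int = 1, normalize: bool = True) -> LBPHistogram:
    """59-bin uniform-pattern histogram over the valid coded pixels."""
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise ValueError("empty mask: no coded pixels")
    bins = _CODE_TO_BIN[codes[valid]]
    counts = np.bincount(bins, minlength=N_UNIFORM_BINS).astype(float)
    if normalize:
        counts /= counts.sum()
    return LBPHistogram(bins=counts, weight=weight)


# ---------------------------------------------------------------------------
# assembly


def hf_feature_names() -> list[str]:
    names = [f"glcm_wm_{n}" for n in GLCM_NAMES]
    names += [f"glcm_gm_{n}" for n in GLCM_NAMES]
    for w in (1, 2, 3, 4):
        names += [f"lbp_w{w}_bin{b:02d}" for b in range(N_UNIFORM_BINS)]
    return names


def assemble_hf(
    glcm_wm: GLCMFeatures,
    glcm_gm: GLCMFeatures,
    lbp_hists: Sequence[LBPHistogram],
) -> HFBlock:
    """Fixed-order 286-dim concatenation with a name-order check."""
    if glcm_wm.tissue != "wm" or glcm_gm.tissue != "gm":
        raise ValueError("GLCM blocks out of order: expected WM then GM")
    if len(lbp_hists) != 4 or [h.weight for h in lbp_hists] != [1, 2, 3, 4]:
        raise ValueError("LBP blocks out of order: expected weights 1, 2, 3, 4")
    values = np.concatenate([glcm_wm.values, glcm_gm.values] + [h.bins for h in lbp_hists])
    if values.shape != (286,):
        raise ValueError("handcrafted block must have length 286")
    return HFBlock(values=values, names=hf_feature_names())
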