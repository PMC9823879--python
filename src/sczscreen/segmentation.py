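"""Tri-level Otsu thresholding (mayfly-searched) and MRF label refinement.

The segmentation stage turns a skull-stripped slice into gray-matter and
white-matter maps in four steps: (i) a 256-bin histogram over the brain
mask, (ii) two thresholds maximizing Otsu's between-class variance, found
by the mayfly optimizer over the continuous (t1, t2) box, (iii) iterated
conditional modes on a Gaussian-likelihood + Potts energy to smooth the
initial labels, and (iv) tissue identification by intensity ordering
(CSF/dark < GM < WM under the T1-weighted convention).

ICM is run in checkerboard (red-black) order: all pixels of one parity are
updated simultaneously given the fixed other parity, which keeps every
update a conditional mode, so the energy trace is non-increasing.  Class
means and variances are re-estimated after each sweep; because the unary
term is the full Gaussian negative log-likelihood (including the log-sigma
normalization), re-estimation also never increases the energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mayfly import MayflyParams, optimize
from .preprocess import GrayImage

__all__ = [
    "MRFConfig",
    "TissueMaps",
    "histogram256",
    "otsu_trilevel_objective",
    "exhaustive_trilevel",
    "moa_otsu_trilevel",
    "thresholds_to_labels",
    "mrf_refine",
    "extract_tissues",
    "segment_slice",
]

logger = logging.getLogger(__name__)

OUTSIDE = 3  # label code for pixels excluded from the brain mask


def histogram256(img: GrayImage, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """256-bin intensity histogram over the (masked) image."""
    mask = img.brain_mask if mask is None else mask
    vals = img.pixels if mask is None else img.pixels[mask]
    if vals.size == 0:
        raise ValueError("empty mask: no pixels to histogram")
    counts, _ = np.histogram(np.clip(vals, 0, 255), bins=256, range=(0, 256))
    return counts.astype(np.int64)


def _class_stats(hist: np.ndarray):
    c = np.asarray(hist, dtype=float)
    if c.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    total = c.sum()
    if total <= 0:
        raise ValueError("histogram total must be positive")
    levels = np.arange(256, dtype=float)
    cw = np.concatenate([[0.0], np.cumsum(c)])  # cumulative mass
    cm = np.concatenate([[0.0], np.cumsum(c * levels)])  # cumulative first moment
    return total, cw, cm


def otsu_trilevel_objective(hist: np.ndarray, t1: int, t2: int) -> float:
    """Between-class variance of the 3-class split [0,t1], (t1,t2], (t2,255].

    Empty classes contribute zero.  Requires 0 < t1 < t2 < 255.
    """
    if t1 >= t2:
        raise ValueError("thresholds must satisfy t1 < t2")
    total, cw, cm = _class_stats(hist)
    mu_total = cm[256] / total
    var = 0.0
    edges = (0, int(t1) + 1, int(t2) + 1, 256)
    for lo, hi in zip(edges[:-1], edges[1:]):
        w = (cw[hi] - cw[lo]) / total
        if w <= 0:
            continue
        mu = (cm[hi] - cm[lo]) / (cw[hi] - cw[lo])
        var += w * (mu - mu_total) ** 2
    return float(var)


def exhaustive_trilevel(hist: np.ndarray) -> tuple[int, int, float]:
    """Exhaustive search over all integer pairs 0 < t1 < t2 < 255 (vectorized)."""
    total, cw, cm = _class_stats(hist)
    mu_total = cm[256] / total
    t1 = np.arange(1, 254)
    t2 = np.arange(2, 255)
    T1, T2 = np.meshgrid(t1, t2, indexing="ij")
    valid = T1 < T2

    def class_term(lo, hi):
        w = (cw[hi] - cw[lo]) / total
        m = cm[hi] - cm[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = np.where(w > 0, m / np.maximum(cw[hi] - cw[lo], 1e-300), 0.0)
        return np.where(w > 0, w * (mu - mu_total) ** 2, 0.0)

    val = (
        class_term(np.zeros_like(T1), T1 + 1)
        + class_term(T1 + 1, T2 + 1)
        + class_term(T2 + 1, np.full_like(T1, 256))
    )
    val = np.where(valid, val, -np.inf)
    i, j = np.unravel_index(int(np.argmax(val)), val.shape)
    return int(t1[i]), int(t2[j]), float(val[i, j])


def _pair_objective(hist: np.ndarray):
    """Continuous-position wrapper: round, sort, nudge degenerate pairs."""

    def f(x: np.ndarray) -> float:
        a, b = sorted(int(round(v)) for v in x)
        a = min(max(a, 1), 253)
        b = min(max(b, 2), 254)
        if a >= b:
            b = a + 1
        return otsu_trilevel_objective(hist, a, b)

    return f


def moa_otsu_trilevel(
    img: GrayImage,
    moa_params: Optional[MayflyParams] = None,
    mask: Optional[np.ndarray] = None,
) -> tuple[int, int, float]:
    """Mayfly search for the tri-level Otsu thresholds over the brain mask.

    Returns ``(t1, t2, objective_value)`` with t1 < t2.
    """
    hist = histogram256(img, mask)
    if moa_params is None:
        moa_params = MayflyParams.for_box(1.0, 254.0, 2, n_flies=20, max_iter=150, seed=0)
    res = optimize(_pair_objective(hist), moa_params)
    a, b = sorted(int(round(v)) for v in res.position)
    a = min(max(a, 1), 253)
    b = min(max(b, 2), 254)
    if a >= b:
        b = a + 1
    return a, b, otsu_trilevel_objective(hist, a, b)


def thresholds_to_labels(img: GrayImage, t1: int, t2: int, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Initial label map: 0 dark/CSF, 1 mid, 2 bright inside the mask; 3 outside."""
    mask = img.brain_mask if mask is None else mask
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    labels = np.full(img.shape, OUTSIDE, dtype=np.uint8)
    p = img.pixels
    labels[mask & (p <= t1)] = 0
    labels[mask & (p > t1) & (p <= t2)] = 1
    labels[mask & (p > t2)] = 2
    return labels


@dataclass
class MRFConfig:
    smoothness: float = 1.0
    neighborhood: int = 4
    max_sweeps: int = 50
    tol: float = 1e-3
    sigma_floor: float = 0.5  # intensity units; guards noiseless classes

    def __post_init__(self) -> None:
        if self.smoothness < 0:
            raise ValueError("smoothness must be non-negative")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be at least 1")
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")


_SHIFTS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_SHIFTS8 = _SHIFTS4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def _shifted(arr: np.ndarray, dy: int, dx: int, fill):
    out = np.full_like(arr, fill)
    h, w = arr.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    yd = slice(max(-dy, 0), h + min(-dy, 0))
    xd = slice(max(-dx, 0), w + min(-dx, 0))
    out[yd, xd] = arr[ys, xs]
    return out


def _estimate_params(pixels, labels, mask, n_classes, prev=None, floor=0.5):
    mus = np.empty(n_classes)
    sigmas = np.empty(n_classes)
    for k in range(n_classes):
        sel = mask & (labels == k)
        if sel.sum() == 0:
            if prev is None:
                mus[k], sigmas[k] = pixels[mask].mean(), max(pixels[mask].std(), floor)
            else:
                mus[k], sigmas[k] = prev[0][k], prev[1][k]
                logger.info("MRF class %d empty; parameters frozen", k)
            continue
        vals = pixels[sel]
        mus[k] = vals.mean()
        sigmas[k] = max(vals.std(), floor)
    return mus, sigmas


def _energy(pixels, labels, mask, mus, sigmas, cfg):
    k = labels[mask]
    unary = ((pixels[mask] - mus[k]) ** 2 / (2.0 * sigmas[k] ** 2) + np.log(sigmas[k])).sum()
    shifts = _SHIFTS4 if cfg.neighborhood == 4 else _SHIFTS8
    pair = 0.0
    for dy, dx in shifts[1::2]:  # each undirected pair once
        nb = _shifted(labels, dy, dx, OUTSIDE)
        nb_mask = _shifted(mask, dy, dx, False)
        both = mask & nb_mask
        pair += np.count_nonzero(both & (labels != nb))
    # shifts[1::2] covers (1,0),(0,1)[,(-1,1),(1,1)]: one direction per axis pair
    return float(unary + cfg.smoothness * pair)


def mrf_refine(
    img: GrayImage,
    init: np.ndarray,
    cfg: Optional[MRFConfig] = None,
    mask: Optional[np.ndarray] = None,
    n_classes: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """ICM refinement of threshold-initialized labels.

    Minimizes ``sum_p NLL(I_p | mu_l, sigma_l) + smoothness * #{disagreeing
    neighbor pairs}`` by checkerboard ICM with per-sweep re-estimation of
    the class parameters.  Returns ``(labels, energy_trace)``; the trace
    starts at the initial energy and is non-increasing.
    """
    cfg = MRFConfig() if cfg is None else cfg
    mask = img.brain_mask if mask is None else mask
    if mask is None:
        mask = init != OUTSIDE
    pixels = img.pixels
    labels = init.copy()
    labels[~mask] = OUTSIDE

    params = _estimate_params(pixels, labels, mask, n_classes, floor=cfg.sigma_floor)
    trace = [_energy(pixels, labels, mask, *params, cfg)]
    shifts = _SHIFTS4 if cfg.neighborhood == 4 else _SHIFTS8
    yy, xx = np.indices(img.shape)
    parity = (yy + xx) % 2
    n_mask = int(mask.sum())

    for _ in range(cfg.max_sweeps):
        mus, sigmas = params
        changed = 0
        for color in (0, 1):
            unary = (
                (pixels[..., None] - mus) ** 2 / (2.0 * sigmas**2) + np.log(sigmas)
            )  # (H, W, K)
            disagree = np.zeros(unary.shape)
            for dy, dx in shifts:
                nb = _shifted(labels, dy, dx, OUTSIDE)
                nb_mask = _shifted(mask, dy, dx, False)
                for k in range(n_classes):
                    disagree[..., k] += (nb_mask & (nb != k)).astype(float)
            cost = unary + cfg.smoothness * disagree
            new = np.argmin(cost, axis=-1).astype(np.uint8)
            upd = mask & (parity == color)
            changed += int(np.count_nonzero(labels[upd] != new[upd]))
            labels[upd] = new[upd]
        params = _estimate_params(pixels, labels, mask, n_classes, prev=params, floor=cfg.sigma_floor)
        trace.append(_energy(pixels, labels, mask, *params, cfg))
        if changed / max(n_mask, 1) < cfg.tol:
            break
    return labels, np.asarray(trace)


@dataclass
class TissueMaps:
    """Disjoint GM and WM masks with their masked-intensity images."""

    gm_mask: np.ndarray
    wm_mask: np.ndarray
    gm_image: np.ndarray
    wm_image: np.ndarray


def extract_tissues(img: GrayImage, labels: np.ndarray, mask: Optional[np.ndarray] = None) -> TissueMaps:
    """Assign the three refined classes by intensity ordering.

    Lowest class mean -> background/CSF, middle -> GM, highest -> WM.
    """
    mask = img.brain_mask if mask is None else mask
    if mask is None:
        mask = labels != OUTSIDE
    means = []
    for k in range(3):
        sel = mask & (labels == k)
        if sel.sum() == 0:
            raise ValueError("degenerate segmentation: fewer than 3 non-empty classes")
        means.append(img.pixels[sel].mean())
    order = np.argsort(means)  # [dark, gm, wm]
    gm_mask = mask & (labels == order[1])
    wm_mask = mask & (labels == order[2])
    return TissueMaps(
        gm_mask=gm_mask,
        wm_mask=wm_mask,
        gm_image=np.where(gm_mask, img.pixels, 0.0),
        wm_image=np.where(wm_mask, img.pixels, 0.0),
    )


def segment_slice(
    img: GrayImage,
    moa_params: Optional[MayflyParams] = None,
    mrf_cfg: Optional[MRFConfig] = None,
) -> tuple[TissueMaps, np.ndarray, np.ndarray]:
    """Threshold + refine + split one skull-stripped slice.

    Returns ``(tissues, labels, energy_trace)``.
    """
    if img.brain_mask is None:
        raise ValueError("segment_slice requires a brain mask (run skull_strip first)")
    t1, t2, _ = moa_otsu_trilevel(img, moa_params)
    init = thresholds_to_labels(img, t1, t2)
    labels, trace = mrf_refine(img, init, mrf_cfg)
    return extract_tissues(img, labels), labels, trace
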