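"""Deep-feature backbone contract, fixture backbone, and 1024 -> 512 reduction.

The pipeline consumes one 1024-float "deep feature" vector per slice from a
pluggable backbone.  Two backbones are provided:

* :class:`BackboneAdapter` wraps an externally supplied pretrained network
  (e.g. a VGG16 whose fully connected output, after 50% dropout, is 1024
  floats per 224x224 slice).  No weights are bundled.
* :class:`FixtureBackbone` is a deterministic stand-in for tests and
  phantom experiments: a fixed random projection of multi-scale image
  statistics (block means of the intensity and gradient-magnitude images
  at 32x32, 16x16 and 8x8, plus global moments).  It is linear in those
  statistics, so its output is Lipschitz on [0, 255] images with constant
  bounded by the projection's spectral norm, and the all-zero image maps
  exactly to the documented bias vector.

The 1024 -> 512 reduction ranks dimensions by absolute two-sample
t-statistic between classes on the *training* data and keeps the top 512;
the fitted index set is applied unchanged to validation data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize, rotate as _sk_rotate

from .preprocess import GrayImage

__all__ = [
    "DF_DIM",
    "REDUCED_DF_DIM",
    "FixtureBackbone",
    "BackboneAdapter",
    "extract_df",
    "DFReducer",
    "augment_rotations",
]

DF_DIM = 1024
REDUCED_DF_DIM = 512

_FIXTURE_SEED = 24601  # fixed: the fixture must be bit-identical everywhere


class FixtureBackbone:
    """Deterministic random-projection backbone (1024 outputs per slice)."""

    backbone_id = "fixture-v1"

    #: scales at which block means are taken
    SCALES = ((32, 32), (16, 16), (8, 8))

    def __init__(self) -> None:
        self._stats_dim = 2 * sum(a * b for a, b in self.SCALES) + 3
        rng = np.random.default_rng(_FIXTURE_SEED)
        self._A = rng.standard_normal((DF_DIM, self._stats_dim)) / np.sqrt(self._stats_dim)
        self._bias = rng.standard_normal(DF_DIM) * 0.1

    @property
    def bias(self) -> np.ndarray:
        """Output for the all-zero image (statistics vector is zero)."""
        return self._bias.copy()

    @property
    def lipschitz_bound(self) -> float:
        """Spectral-norm bound on output change per unit change in the
        (itself 1-Lipschitz-scaled) statistics vector."""
        return float(np.linalg.norm(self._A, 2))

    def statistics(self, pixels: np.ndarray) -> np.ndarray:
        p = np.asarray(pixels, dtype=float) / 255.0
        gy, gx = np.gradient(p)
        g = np.hypot(gy, gx)
        parts = []
        for shape in self.SCALES:
            parts.append(_sk_resize(p, shape, order=1, preserve_range=True, anti_aliasing=False).ravel())
        for shape in self.SCALES:
            parts.append(_sk_resize(g, shape, order=1, preserve_range=True, anti_aliasing=False).ravel())
        parts.append(np.array([p.mean(), p.std(), g.mean()]))
        return np.concatenate(parts)

    def __call__(self, img) -> np.ndarray:
        pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
        return self._A @ self.statistics(pixels) + self._bias


class BackboneAdapter:
    """Wrap a user-supplied callable under the backbone contract.

    The callable receives a (H, W) grayscale array in [0, 255] (replicate
    to 3 channels inside your function if the network needs RGB) and must
    return 1024 finite floats, deterministically given its weights.
    Recommended training-side defaults when fine-tuning a network for this
    pipeline: Adam, learning rate 1e-5, 50 epochs, rotation augmentation
    of +/-60 degrees in 10-degree steps.
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], backbone_id: str = "adapter"):
        self._fn = fn
        self.backbone_id = backbone_id

    def __call__(self, img) -> np.ndarray:
        pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
        out = np.asarray(self._fn(pixels), dtype=float).ravel()
        if out.shape != (DF_DIM,):
            raise ValueError(f"backbone returned {out.shape}, expected ({DF_DIM},)")
        if not np.all(np.isfinite(out)):
            raise ValueError("backbone returned non-finite values")
        return out


def extract_df(slices: Sequence, backbone) -> np.ndarray:
    """Per-slice 1024-dim deep feature matrix (n_slices, 1024)."""
    rows = []
    for img in slices:
        v = np.asarray(backbone(img), dtype=float).ravel()
        if v.shape != (DF_DIM,):
            raise ValueError(f"backbone output has length {v.size}, expected {DF_DIM}")
        if not np.all(np.isfinite(v)):
            raise ValueError("backbone output contains non-finite values")
        rows.append(v)
    return np.vstack(rows)


@dataclass
class DFReducer:
    """Supervised 50% reduction of the deep features by |t|-ranking.

    ``fit`` computes the absolute two-sample t-statistic of every dimension
    on the training folds and keeps the ``k`` (default 512) best.  Zero
    variance with equal means ranks last (t = 0); zero variance with
    different means ranks first (t = +inf).  Ties break toward the lower
    index.  ``fit_fold`` records provenance for the leakage guard.
    """

    k: int = REDUCED_DF_DIM
    selected_idx: Optional[np.ndarray] = None
    fit_fold: Optional[int] = None

    def fit(self, X: np.ndarray, y: np.ndarray, fold: Optional[int] = None) -> "DFReducer":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("DFReducer requires exactly two classes")
        a, b = X[y == classes[0]], X[y == classes[1]]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 samples per class")
        mean_diff = b.mean(axis=0) - a.mean(axis=0)
        va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
        se = np.sqrt(va / len(a) + vb / len(b))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(mean_diff) / se
        t[(se == 0) & (mean_diff != 0)] = np.inf
        t[(se == 0) & (mean_diff == 0)] = 0.0
        order = np.argsort(-t, kind="stable")  # stable: ties keep lower index first
        self.selected_idx = np.sort(order[: self.k])
        self.fit_fold = fold
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.selected_idx is None:
            raise RuntimeError("DFReducer is not fitted")
        return np.asarray(X, dtype=float)[:, self.selected_idx]


def augment_rotations(img: GrayImage, max_angle: int = 60, step: int = 10) -> list[GrayImage]:
    """Identity plus rotations at +/-step..max_angle degrees (13 variants
    with the defaults)."""
    out = [GrayImage(img.pixels.copy())]
    for a in range(step, max_angle + 1, step):
        for sign in (1, -1):
            rot = _sk_rotate(img.pixels, sign * a, preserve_range=True)
            out.append(GrayImage(np.clip(rot, 0, 255)))
    return out
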