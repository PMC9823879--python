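"""Mayfly wrapper selection of handcrafted features.

The selection objective is the dimension-normalized Cartesian (Euclidean)
distance between the two class centroids of z-scored training features,
restricted to the selected subset:

    fitness(mask) = || gap[mask] ||_2 / sqrt(k),   gap = mean_SCZ - mean_CON

Mayfly positions are continuous vectors in [0, 1]^d decoded to a subset by
thresholding at 0.5.  After the search, the best mask is coerced to
exactly ``k`` features by |gap| ranking: oversized masks drop their
smallest-gap members, undersized masks add the largest-gap outsiders.
The default target size is 103 of 286.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .mayfly import MayflyParams, optimize

__all__ = [
    "CDObjective",
    "SelectionMask",
    "fit_cd_objective",
    "cd_fitness",
    "coerce_mask",
    "moa_select",
    "HFSelector",
    "DEFAULT_K",
]

DEFAULT_K = 103


@dataclass
class CDObjective:
    """Class-centroid gap on z-scored training features."""

    gap: np.ndarray  # per-feature standardized mean difference (SCZ - CON)
    center: np.ndarray
    scale: np.ndarray
    zero_variance_idx: np.ndarray  # features whose scale was forced to 1


def fit_cd_objective(X: np.ndarray, y: np.ndarray) -> CDObjective:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    zero_var = np.flatnonzero(scale == 0)
    scale = np.where(scale == 0, 1.0, scale)
    Z = (X - center) / scale
    gap = Z[y == classes[1]].mean(axis=0) - Z[y == classes[0]].mean(axis=0)
    return CDObjective(gap=gap, center=center, scale=scale, zero_variance_idx=zero_var)


@dataclass
class SelectionMask:
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)

    @property
    def k(self) -> int:
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def to_json_dict(self, feature_names: Optional[Sequence[str]] = None) -> dict:
        idx = self.indices.tolist()
        d = {"k": self.k, "indices": idx}
        if feature_names is not None:
            d["features"] = [feature_names[i] for i in idx]
        return d


def cd_fitness(bits: np.ndarray, obj: CDObjective) -> float:
    """sqrt(k)-normalized centroid distance over the selected features;
    an empty mask scores -inf so it is never chosen."""
    bits = np.asarray(bits, dtype=bool)
    k = int(bits.sum())
    if k == 0:
        return -np.inf
    return float(np.linalg.norm(obj.gap[bits]) / np.sqrt(k))


def coerce_mask(bits: np.ndarray, gap: np.ndarray, k: int) -> np.ndarray:
    """Deterministically force exactly ``k`` selected features by |gap| rank."""
    bits = np.asarray(bits, dtype=bool).copy()
    strength = np.abs(gap)
    # stable order: higher |gap| first, ties toward the lower index
    order = np.argsort(-strength, kind="stable")
    if bits.sum() > k:
        selected = [i for i in order if bits[i]]
        for i in selected[k:]:
            bits[i] = False
    elif bits.sum() < k:
        for i in order:
            if bits.sum() >= k:
                break
            bits[i] = True
    return bits


def moa_select(
    X: np.ndarray,
    y: np.ndarray,
    k: int = DEFAULT_K,
    moa_params: Optional[MayflyParams] = None,
) -> tuple[SelectionMask, CDObjective]:
    """Mayfly search over [0, 1]^d for the k-feature mask maximizing the
    normalized centroid distance.  Returns the coerced mask plus the fitted
    objective (whose gap vector also drives the coercion)."""
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    if not (1 <= k <= d):
        raise ValueError(f"k must lie in [1, {d}]")
    obj = fit_cd_objective(X, y)
    if k == d:
        return SelectionMask(np.ones(d, dtype=bool)), obj
    if moa_params is None:
        moa_params = MayflyParams.for_box(0.0, 1.0, d, n_flies=30, max_iter=3000, seed=0)

    def fitness(x: np.ndarray) -> float:
        f = cd_fitness(x > 0.5, obj)
        return -1e9 if not np.isfinite(f) else f  # keep the objective finite

    res = optimize(fitness, moa_params)
    bits = coerce_mask(res.position > 0.5, obj.gap, k)
    return SelectionMask(bits), obj


@dataclass
class HFSelector:
    """Fold-scoped transformer: z-scoring + mayfly mask, fit on train only."""

    k: int = DEFAULT_K
    moa_params: Optional[MayflyParams] = None
    mask: Optional[SelectionMask] = None
    objective: Optional[CDObjective] = None
    fit_fold: Optional[int] = None

    def fit(self, X: np.ndarray, y: np.ndarray, fold: Optional[int] = None) -> "HFSelector":
        self.mask, self.objective = moa_select(X, y, k=self.k, moa_params=self.moa_params)
        self.fit_fold = fold
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mask is None:
            raise RuntimeError("HFSelector is not fitted")
        Z = (np.asarray(X, dtype=float) - self.objective.center) / self.objective.scale
        return Z[:, self.mask.bits]
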