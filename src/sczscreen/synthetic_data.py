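"""Synthetic phantoms and planted-signal feature tables.

The phantom is a deliberately cartoonish head slice — an elliptical skull
annulus, a dark subarachnoid gap, a gray-matter ribbon wrapped around a
white-matter core, and ventricular CSF pockets — with per-pixel ground
truth labels.  It provides controllable tissue statistics so that the
segmentation, texture and classification stages can be tested end to end
without any real MRI data.  A class-dependent texture perturbation of
configurable magnitude stands in for the (unknown) discriminative property
of patient scans.

``generate_feature_table`` builds standard-normal feature matrices with a
planted mean shift on a known index set, the test bed for wrapper feature
selection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .preprocess import GrayImage

__all__ = [
    "PhantomConfig",
    "PlantedTableConfig",
    "FeatureTable",
    "LABEL_NAMES",
    "generate_phantom",
    "generate_dataset",
    "save_phantoms",
    "generate_feature_table",
    "save_feature_table",
]

# ground-truth label codes
BACKGROUND, SKULL, CSF, GM, WM = 0, 1, 2, 3, 4
LABEL_NAMES = {BACKGROUND: "background", SKULL: "skull", CSF: "csf", GM: "gm", WM: "wm"}

CLASSES = ("CON", "SCZ")


@dataclass
class PhantomConfig:
    """Geometry, intensities and noise of the phantom head slice.

    Intensities follow the T1-weighted ordering csf < gm < wm with a bright
    skull rim.  ``class_effect`` is the magnitude (intensity units of the
    added field's standard deviation) of the SCZ-class texture perturbation;
    ``effect_mode`` selects what the perturbation changes.
    """

    image_size: tuple[int, int] = (224, 224)
    skull_intensity: int = 230
    csf_intensity: int = 50
    gm_intensity: int = 130
    wm_intensity: int = 200
    noise_sigma: float = 4.0
    class_effect: float = 0.0
    effect_mode: str = "texture"  # or "gm_fraction"
    n_per_class: int = 20
    seed: int = 0
    head_semiaxes: tuple[float, float] | None = None  # override, (ay, ax) pixels

    def __post_init__(self) -> None:
        for name in ("skull_intensity", "csf_intensity", "gm_intensity", "wm_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must lie in [0, 255]")
        if not (self.csf_intensity < self.gm_intensity < self.wm_intensity):
            raise ValueError("intensities must satisfy csf < gm < wm")
        if self.noise_sigma < 0 or self.class_effect < 0:
            raise ValueError("noise_sigma and class_effect must be non-negative")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be at least 1")
        if self.effect_mode not in ("texture", "gm_fraction"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")


def _ellipse(shape, center, semiaxes) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    ay, ax = semiaxes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _geometry(cfg: PhantomConfig) -> dict[str, np.ndarray]:
    """Nested-ellipse anatomy scaled from a 224x224 reference layout."""
    h, w = cfg.image_size
    s = min(h, w) / 224.0
    center = (h / 2.0, w / 2.0)
    if cfg.head_semiaxes is not None:
        head_ax = cfg.head_semiaxes
    else:
        head_ax = (100.0 * s, 85.0 * s)
    if head_ax[0] >= h / 2.0 or head_ax[1] >= w / 2.0:
        raise ValueError("degenerate geometry: head ellipse does not fit in the image")
    skull_th = 5.0 * s
    gap_th = 4.0 * s
    head = _ellipse(cfg.image_size, center, head_ax)
    skull_inner = _ellipse(cfg.image_size, center, (head_ax[0] - skull_th, head_ax[1] - skull_th))
    brain = _ellipse(
        cfg.image_size, center, (head_ax[0] - skull_th - gap_th, head_ax[1] - skull_th - gap_th)
    )
    wm = _ellipse(cfg.image_size, center, (52.0 * s, 40.0 * s))
    vent_l = _ellipse(cfg.image_size, (center[0], center[1] - 18.0 * s), (16.0 * s, 6.0 * s))
    vent_r = _ellipse(cfg.image_size, (center[0], center[1] + 18.0 * s), (16.0 * s, 6.0 * s))
    csf = (vent_l | vent_r) & wm
    return {
        "skull": head & ~skull_inner,
        "brain": brain,
        "wm": (wm & brain) & ~csf,
        "gm": brain & ~wm,
        "csf": csf,
    }


def _image_rng(cfg: PhantomConfig, class_label: str, index: int) -> np.random.Generator:
    # one seed per (dataset, class, slice) so every image is independently
    # reproducible regardless of generation order
    class_code = CLASSES.index(class_label)
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, class_code, index]))


def generate_phantom(
    cfg: PhantomConfig, class_label: str, index: int
) -> tuple[GrayImage, np.ndarray]:
    """Render one phantom slice plus its ground-truth label map.

    Returns ``(image, labels)`` with labels in {background, skull, csf,
    gm, wm}.  For the SCZ class the tissue texture (or the GM fraction,
    depending on ``effect_mode``) is perturbed by ``class_effect``.
    """
    if class_label not in CLASSES:
        raise ValueError(f"class_label must be one of {CLASSES}")
    rng = _image_rng(cfg, class_label, index)
    geo = _geometry(cfg)

    wm_mask, gm_mask, csf_mask = geo["wm"], geo["gm"], geo["csf"]
    if class_label == "SCZ" and cfg.effect_mode == "gm_fraction" and cfg.class_effect > 0:
        # thicken the GM ribbon by eroding the WM core proportionally
        shrink = max(1, int(round(cfg.class_effect)))
        wm_core = ndi.binary_erosion(wm_mask | csf_mask, iterations=shrink)
        moved = (wm_mask & ~wm_core)
        wm_mask = wm_mask & wm_core
        gm_mask = gm_mask | moved

    labels = np.zeros(cfg.image_size, dtype=np.uint8)
    labels[geo["skull"]] = SKULL
    labels[gm_mask] = GM
    labels[wm_mask] = WM
    labels[csf_mask] = CSF

    img = np.zeros(cfg.image_size, dtype=float)
    img[labels == SKULL] = cfg.skull_intensity
    img[labels == CSF] = cfg.csf_intensity
    img[labels == GM] = cfg.gm_intensity
    img[labels == WM] = cfg.wm_intensity

    if class_label == "SCZ" and cfg.effect_mode == "texture" and cfg.class_effect > 0:
        field_ = ndi.gaussian_filter(rng.standard_normal(cfg.image_size), sigma=2.0)
        field_ /= field_.std()
        img[gm_mask] += cfg.class_effect * field_[gm_mask]

    if cfg.noise_sigma > 0:
        img += rng.normal(0.0, cfg.noise_sigma, size=cfg.image_size)

    return GrayImage(np.clip(img, 0, 255)), labels


@dataclass
class PhantomDataset:
    images: list[GrayImage]
    label_maps: list[np.ndarray]
    classes: list[str]  # "CON"/"SCZ" per image
    indices: list[int]

    @property
    def y(self) -> np.ndarray:
        return np.array([CLASSES.index(c) for c in self.classes])


def generate_dataset(cfg: PhantomConfig) -> PhantomDataset:
    """``n_per_class`` phantoms per class, CON first, index-ordered."""
    images, maps, classes, indices = [], [], [], []
    for cls in CLASSES:
        for i in range(cfg.n_per_class):
            img, lab = generate_phantom(cfg, cls, i)
            images.append(img)
            maps.append(lab)
            classes.append(cls)
            indices.append(i)
    return PhantomDataset(images, maps, classes, indices)


def save_phantoms(dataset: PhantomDataset, outdir) -> Path:
    """Write slices as PNG plus a CSV manifest (filename, class, index)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "class", "index"])
        for img, cls, idx in zip(dataset.images, dataset.classes, dataset.indices):
            name = f"{cls.lower()}_{idx:03d}.png"
            img.save_png(outdir / name)
            writer.writerow([name, cls, idx])
    return manifest


# ---------------------------------------------------------------------------
# planted-signal feature tables


@dataclass
class PlantedTableConfig:
    """Standard-normal table with a mean shift planted on known columns."""

    n_per_class: int = 100
    n_features: int = 286
    informative_idx: Sequence[int] = field(default_factory=tuple)
    effect_size: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        idx = np.asarray(sorted(set(int(i) for i in self.informative_idx)), dtype=int)
        if idx.size > self.n_features:
            raise ValueError("more informative indices than features")
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_features):
            raise ValueError("informative_idx out of range")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        self.informative_idx = tuple(idx.tolist())


@dataclass
class FeatureTable:
    X: np.ndarray
    y: np.ndarray  # 0 = CON, 1 = SCZ
    informative_idx: tuple[int, ...]
    feature_names: list[str]


def generate_feature_table(cfg: PlantedTableConfig) -> FeatureTable:
    """Balanced two-class table; SCZ rows shifted by ``effect_size`` on the
    planted columns."""
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_per_class
    X = rng.standard_normal((n, cfg.n_features))
    y = np.repeat([0, 1], cfg.n_per_class)
    if cfg.informative_idx:
        X[np.ix_(y == 1, np.asarray(cfg.informative_idx))] += cfg.effect_size
    names = [f"f{j:03d}" for j in range(cfg.n_features)]
    return FeatureTable(X=X, y=y, informative_idx=cfg.informative_idx, feature_names=names)


def save_feature_table(table: FeatureTable, path) -> Path:
    """CSV with a header row and a final ``label`` column."""
    import pandas as pd

    path = Path(path)
    df = pd.DataFrame(table.X, columns=table.feature_names)
    df["label"] = table.y
    df.to_csv(path, index=False)
    return path
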