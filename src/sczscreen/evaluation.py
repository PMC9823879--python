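"""Serial feature fusion, binary classifiers, cross-validation and metrics.

The fused vector is the 512-dim reduced deep block followed by the 103
selected handcrafted features (615 floats).  Classification quality is
summarized by the confusion-count metric suite

    ACC = (TP+TN)/(TP+TN+FP+FN)      PRE = TP/(TP+FP)
    SEN = TP/(TP+FN)                 SPE = TN/(TN+FP)
    NPV = TN/(TN+FN)                 FS  = 2TP/(2TP+FN+FP)

each reported as a percentage rounded half-up to 4 decimals, with the
positive class being SCZ.  Cross-validation is stratified 5-fold by
default; when slices come from subjects, subject-grouped folding is
available so no subject straddles train and validation.  The per-run
report marks the best fold by ACC (ties broken by FS) and also carries the
fold mean.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .deep_features import DFReducer, REDUCED_DF_DIM
from .feature_selection import DEFAULT_K, HFSelector
from .mayfly import MayflyParams

__all__ = [
    "FUSED_DIM",
    "ConfusionCounts",
    "MetricsReport",
    "CVPlan",
    "CVResult",
    "CLASSIFIER_IDS",
    "fuse",
    "make_classifier",
    "compute_metrics",
    "make_cv_plan",
    "run_cv",
    "metrics_table",
]

FUSED_DIM = REDUCED_DF_DIM + DEFAULT_K  # 615


def fuse(df_reduced: np.ndarray, hf_selected: np.ndarray) -> np.ndarray:
    """Serial concatenation: reduced deep block first, handcrafted second."""
    df_reduced = np.asarray(df_reduced, dtype=float)
    hf_selected = np.asarray(hf_selected, dtype=float)
    if df_reduced.shape[-1] != REDUCED_DF_DIM:
        raise ValueError(f"deep block must have length {REDUCED_DF_DIM}")
    if hf_selected.shape[-1] != DEFAULT_K:
        raise ValueError(f"handcrafted block must have length {DEFAULT_K}")
    return np.concatenate([df_reduced, hf_selected], axis=-1)


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class MetricsReport:
    acc: float
    pre: float
    sen: float
    spe: float
    npv: float
    fs: float

    def as_dict(self) -> dict:
        return asdict(self)


def _pct(numer: int, denom: int, name: str) -> float:
    """Exact percentage rounded half-up to 4 decimals; NaN on 0 denominator."""
    if denom == 0:
        warnings.warn(f"{name} undefined: zero denominator", RuntimeWarning, stacklevel=3)
        return float("nan")
    val = (Decimal(numer) * 100) / Decimal(denom)
    return float(val.quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """ACC/PRE/SEN/SPE/NPV/FS percentages from one confusion quadruple."""
    if c.total == 0:
        raise ValueError("all counts are zero")
    return MetricsReport(
        acc=_pct(c.tp + c.tn, c.total, "ACC"),
        pre=_pct(c.tp, c.tp + c.fp, "PRE"),
        sen=_pct(c.tp, c.tp + c.fn, "SEN"),
        spe=_pct(c.tn, c.tn + c.fp, "SPE"),
        npv=_pct(c.tn, c.tn + c.fn, "NPV"),
        fs=_pct(2 * c.tp, 2 * c.tp + c.fn + c.fp, "FS"),
    )


# ---------------------------------------------------------------------------
# classifier registry

CLASSIFIER_IDS = (
    "softmax",
    "dt-coarse",
    "dt-medium",
    "dt-fine",
    "logistic",
    "naive-bayes",
    "svm-linear",
    "boosted-trees",
    "knn-coarse",
    "knn-medium",
    "knn-fine",
)


def make_classifier(classifier_id: str, seed: int = 0):
    """Instantiate a registry classifier; coarse/medium/fine tiers fix the
    capacity knobs (leaf counts 4/20/100, k = 100/10/1)."""
    registry = {
        "softmax": lambda: LogisticRegression(max_iter=2000, random_state=seed),
        "logistic": lambda: LogisticRegression(max_iter=2000, C=10.0, random_state=seed),
        "dt-coarse": lambda: DecisionTreeClassifier(max_leaf_nodes=4, random_state=seed),
        "dt-medium": lambda: DecisionTreeClassifier(max_leaf_nodes=20, random_state=seed),
        "dt-fine": lambda: DecisionTreeClassifier(max_leaf_nodes=100, random_state=seed),
        "naive-bayes": lambda: GaussianNB(),
        "svm-linear": lambda: LinearSVC(random_state=seed),
        "boosted-trees": lambda: GradientBoostingClassifier(
            max_depth=3, n_estimators=30, random_state=seed
        ),
        "knn-coarse": lambda: KNeighborsClassifier(n_neighbors=100),
        "knn-medium": lambda: KNeighborsClassifier(n_neighbors=10),
        "knn-fine": lambda: KNeighborsClassifier(n_neighbors=1),
    }
    if classifier_id not in registry:
        raise KeyError(f"unknown classifier {classifier_id!r}; known: {', '.join(CLASSIFIER_IDS)}")
    return registry[classifier_id]()


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVPlan:
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, val_idx) per fold
    grouping: str
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_cv_plan(
    labels: np.ndarray,
    n_folds: int = 5,
    grouping: str = "slice",
    groups: Optional[np.ndarray] = None,
    seed: int = 0,
) -> CVPlan:
    """Stratified slice-level folds, or subject-grouped folds so no subject
    spans train and validation."""
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    if grouping == "slice":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [(tr, va) for tr, va in splitter.split(idx, labels)]
    elif grouping == "subject":
        if groups is None:
            raise ValueError("grouping='subject' requires a groups array")
        splitter = GroupKFold(n_splits=n_folds)
        folds = [(tr, va) for tr, va in splitter.split(idx, labels, groups=np.asarray(groups))]
    else:
        raise ValueError("grouping must be 'slice' or 'subject'")
    return CVPlan(folds=folds, grouping=grouping, seed=seed)


@dataclass
class CVResult:
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[MetricsReport]
    best_fold: int
    best_metrics: MetricsReport
    mean_acc: float  # unrounded fraction in [0, 1], pooled over folds

    def to_json_dict(self) -> dict:
        return {
            "folds": [
                {**{k.upper(): getattr(c, k) for k in ("tp", "fn", "tn", "fp")}, **m.as_dict()}
                for c, m in zip(self.fold_counts, self.fold_metrics)
            ],
            "best_fold": self.best_fold,
            "best": self.best_metrics.as_dict(),
            "mean_acc": self.mean_acc,
        }


def _counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    pos, neg = 1, 0  # positive class = SCZ
    return ConfusionCounts(
        tp=int(np.sum((y_true == pos) & (y_pred == pos))),
        fn=int(np.sum((y_true == pos) & (y_pred == neg))),
        tn=int(np.sum((y_true == neg) & (y_pred == neg))),
        fp=int(np.sum((y_true == neg) & (y_pred == pos))),
    )


def run_cv(
    hf: Optional[np.ndarray],
    labels: np.ndarray,
    df: Optional[np.ndarray] = None,
    classifier: str = "softmax",
    plan: Optional[CVPlan] = None,
    select_k: int = DEFAULT_K,
    df_k: int = REDUCED_DF_DIM,
    selection_moa_params: Optional[MayflyParams] = None,
    seed: int = 0,
) -> CVResult:
    """Leakage-free cross-validated evaluation.

    Every stage transformer — the deep-feature |t| ranking and the
    handcrafted z-scoring + mayfly mask — is fit on the training indices of
    each fold only, then applied to the validation indices.  ``hf`` and/or
    ``df`` may be given; at least one is required.
    """
    labels = np.asarray(labels)
    if hf is None and df is None:
        raise ValueError("need handcrafted and/or deep features")
    n = len(labels)
    if plan is None:
        plan = make_cv_plan(labels, seed=seed)

    fold_counts: list[ConfusionCounts] = []
    for f, (tr, va) in enumerate(plan.folds):
        if np.unique(labels[tr]).size < 2 or np.unique(labels[va]).size < 2:
            raise ValueError(f"fold {f} contains a single class")
        blocks_tr, blocks_va = [], []
        if df is not None:
            reducer = DFReducer(k=min(df_k, df.shape[1])).fit(df[tr], labels[tr], fold=f)
            assert reducer.fit_fold == f, "leakage guard: reducer fit on a different fold"
            blocks_tr.append(reducer.transform(df[tr]))
            blocks_va.append(reducer.transform(df[va]))
        if hf is not None:
            params = selection_moa_params
            if params is not None:
                # fresh per-fold seed, same budget
                params = MayflyParams(
                    bounds=params.bounds,
                    n_flies=params.n_flies,
                    max_iter=params.max_iter,
                    c1=params.c1,
                    c2=params.c2,
                    beta=params.beta,
                    dance=params.dance,
                    dance_decay=params.dance_decay,
                    seed=params.seed + f,
                )
            selector = HFSelector(k=min(select_k, hf.shape[1]), moa_params=params)
            selector.fit(hf[tr], labels[tr], fold=f)
            assert selector.fit_fold == f, "leakage guard: selector fit on a different fold"
            blocks_tr.append(selector.transform(hf[tr]))
            blocks_va.append(selector.transform(hf[va]))
        X_tr = np.hstack(blocks_tr)
        X_va = np.hstack(blocks_va)
        clf = make_classifier(classifier, seed=seed)
        if classifier.startswith("knn"):
            clf.set_params(n_neighbors=min(clf.get_params()["n_neighbors"], len(tr)))
        clf.fit(X_tr, labels[tr])
        fold_counts.append(_counts_from_predictions(labels[va], clf.predict(X_va)))

    fold_metrics = [compute_metrics(c) for c in fold_counts]
    best = max(range(len(fold_metrics)), key=lambda i: (fold_metrics[i].acc, fold_metrics[i].fs))
    correct = sum(c.tp + c.tn for c in fold_counts)
    total = sum(c.total for c in fold_counts)
    return CVResult(
        fold_counts=fold_counts,
        fold_metrics=fold_metrics,
        best_fold=best,
        best_metrics=fold_metrics[best],
        mean_acc=correct / total,
    )


def metrics_table(
    counts: Sequence[ConfusionCounts], fold_names: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """One row per fold: counts, the six metrics, and a best-fold marker."""
    if len(counts) == 0:
        raise ValueError("at least one fold required")
    metrics = [compute_metrics(c) for c in counts]
    best = max(range(len(metrics)), key=lambda i: (metrics[i].acc, metrics[i].fs))
    if fold_names is None:
        fold_names = [f"Trial{i + 1}" for i in range(len(counts))]
    rows = []
    for name, c, m in zip(fold_names, counts, metrics):
        rows.append(
            {
                "fold": name,
                "TP": c.tp,
                "FN": c.fn,
                "TN": c.tn,
                "FP": c.fp,
                "ACC": m.acc,
                "PRE": m.pre,
                "SEN": m.sen,
                "SPE": m.spe,
                "NPV": m.npv,
                "FS": m.fs,
            }
        )
    table = pd.DataFrame(rows)
    table["best"] = [i == best for i in range(len(counts))]
    return table
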