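"""RBF-kernel SVM classification of real vs. pseudo small RNAs.

Covers stratified 10-partitioning, the 7-train / 2-validation / 1-test
rotation scheme with (C, gamma) grid search, confusion-based evaluation
metrics (Se/Sp/Pre/ACC as percentages), ROC/AUC, and a self-contained JSON
model serialization. Fitting is delegated to scikit-learn's SVC; the stored
model evaluates its own decision function sign(sum_i a_i y_i K(x, x_i) + b).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.svm import SVC

from .triplet_features import TripletVector, feature_matrix, triplet_alphabet

#: Conventional exponential grids for the (C, gamma) search.
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass
class LabeledDataset:
    vectors: np.ndarray
    labels: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.vectors) == len(self.labels) == len(self.ids)):
            raise ValueError("vectors, labels and ids must have equal length")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 or -1")

    @classmethod
    def from_vectors(
        cls,
        pos: Sequence[TripletVector],
        neg: Sequence[TripletVector],
        pos_ids: Sequence[str] | None = None,
        neg_ids: Sequence[str] | None = None,
    ) -> "LabeledDataset":
        X = np.vstack([feature_matrix(pos), feature_matrix(neg)])
        y = np.concatenate([np.ones(len(pos), int), -np.ones(len(neg), int)])
        ids = list(pos_ids or (f"pos_{i}" for i in range(len(pos))))
        ids += list(neg_ids or (f"neg_{i}" for i in range(len(neg))))
        return cls(X, y, ids)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.vectors[idx], self.labels[idx], [self.ids[i] for i in idx]
        )


@dataclass(frozen=True)
class ModelParams:
    C: float
    gamma: float
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


class TrainedModel:
    """Frozen RBF-SVM decision function with JSON round-tripping."""

    def __init__(
        self,
        support_vectors: np.ndarray,
        dual_coef: np.ndarray,
        intercept: float,
        params: ModelParams,
        feature_names: list[str] | None = None,
    ):
        self.support_vectors = np.asarray(support_vectors, dtype=float)
        self.dual_coef = np.asarray(dual_coef, dtype=float).ravel()
        self.intercept = float(intercept)
        self.params = params
        self.feature_names = feature_names or triplet_alphabet()

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        d2 = (
            (X**2).sum(axis=1)[:, None]
            - 2.0 * X @ self.support_vectors.T
            + (self.support_vectors**2).sum(axis=1)[None, :]
        )
        K = np.exp(-self.params.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(labels in {+1,-1}, decision scores); label +1 iff score > 0."""
        scores = self.decision_function(X)
        labels = np.where(scores > 0, 1, -1)
        return labels, scores

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "kernel": self.params.kernel,
            "C": self.params.C,
            "gamma": self.params.gamma,
            "intercept": self.intercept,
            "dual_coef": self.dual_coef.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "feature_names": self.feature_names,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls(
            support_vectors=np.array(doc["support_vectors"]),
            dual_coef=np.array(doc["dual_coef"]),
            intercept=doc["intercept"],
            params=ModelParams(C=doc["C"], gamma=doc["gamma"], kernel=doc["kernel"]),
            feature_names=doc["feature_names"],
        )


@dataclass
class FoldScheme:
    """k disjoint, exhaustive partitions preserving the class ratio."""

    partitions: list[np.ndarray]
    k: int = 10

    def rotation(self, r: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(train_idx, val_idx, test_idx) for rotation r: 7 train partitions,
        2 validation, 1 test."""
        test = self.partitions[r]
        val = np.concatenate(
            [self.partitions[(r + 1) % self.k], self.partitions[(r + 2) % self.k]]
        )
        train_parts = [
            self.partitions[(r + j) % self.k] for j in range(3, self.k)
        ]
        return np.concatenate(train_parts), val, test


def stratified_partition(data: LabeledDataset, k: int = 10, seed: int = 0) -> FoldScheme:
    """Shuffle each class and deal it into k near-equal chunks."""
    rng = np.random.default_rng(seed)
    per_class_chunks = []
    for label in (1, -1):
        idx = np.flatnonzero(data.labels == label)
        if len(idx) < k:
            raise ValueError(f"class {label:+d} has fewer than k={k} samples")
        rng.shuffle(idx)
        per_class_chunks.append(np.array_split(idx, k))
    partitions = [
        np.sort(np.concatenate([per_class_chunks[0][i], per_class_chunks[1][i]]))
        for i in range(k)
    ]
    return FoldScheme(partitions=partitions, k=k)


def train(data: LabeledDataset, params: ModelParams) -> TrainedModel:
    """Fit a soft-margin RBF SVM; deterministic given data order and params."""
    if len(set(np.unique(data.labels))) < 2:
        raise ValueError("training requires samples from both classes")
    svc = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
    svc.fit(data.vectors, data.labels)
    # classes_ is sorted [-1, 1]; decision_function > 0 <=> predicted +1
    return TrainedModel(
        support_vectors=svc.support_vectors_,
        dual_coef=svc.dual_coef_[0],
        intercept=float(svc.intercept_[0]),
        params=params,
    )


def grid_search(
    data: LabeledDataset,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> ModelParams:
    """(C, gamma) maximizing validation accuracy; ties -> smallest C then gamma."""
    if not C_grid or not gamma_grid:
        raise ValueError("grids must be nonempty")
    tr = data.subset(train_idx)
    val = data.subset(val_idx)
    best: tuple[float, float, float] | None = None  # (-acc, C, gamma)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            model = train(tr, ModelParams(C=C, gamma=gamma))
            labels, _ = model.predict(val.vectors)
            acc = float(np.mean(labels == val.labels))
            key = (-acc, C, gamma)
            if best is None or key < best:
                best = key
    return ModelParams(C=best[1], gamma=best[2])


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def se(self) -> float | None:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def sp(self) -> float | None:
        return _pct(self.tn, self.tn + self.fp)

    @property
    def pre(self) -> float | None:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def acc(self) -> float | None:
        return _pct(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "Se": self.se, "Sp": self.sp, "Pre": self.pre, "ACC": self.acc,
        }


def _pct(num: int, den: int) -> float | None:
    """Percentage, or None when the denominator is zero (undefined metric)."""
    if den == 0:
        return None
    return 100.0 * num / den


def evaluate(truth: Sequence[int] | np.ndarray, predicted: Sequence[int] | np.ndarray) -> EvalReport:
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError("truth and predictions must have equal length")
    if not (set(np.unique(t)) | set(np.unique(p))) <= {-1, 1}:
        raise ValueError("labels must be +1 or -1")
    return EvalReport(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == -1) & (p == 1))),
        tn=int(np.sum((t == -1) & (p == -1))),
        fn=int(np.sum((t == 1) & (p == -1))),
    )


@dataclass
class CrossValidationResult:
    reports: list[EvalReport]
    params: list[ModelParams]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean:
            for metric in ("Se", "Sp", "Pre", "ACC"):
                vals = [r.as_dict()[metric] for r in self.reports]
                vals = [v for v in vals if v is not None]
                if vals:
                    self.mean[metric] = float(np.mean(vals))
                    self.sd[metric] = float(np.std(vals, ddof=0))


def cross_validate(
    data: LabeledDataset,
    scheme: FoldScheme,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> CrossValidationResult:
    """The 7/2/1 rotation scheme: for each of k rotations, grid-search on
    train+validation partitions, then evaluate the selected model on the
    held-out test partition. Aggregates mean and population sd per metric."""
    reports, chosen = [], []
    for r in range(scheme.k):
        train_idx, val_idx, test_idx = scheme.rotation(r)
        params = grid_search(data, train_idx, val_idx, C_grid, gamma_grid)
        model = train(data.subset(train_idx), params)
        test = data.subset(test_idx)
        labels, _ = model.predict(test.vectors)
        reports.append(evaluate(test.labels, labels))
        chosen.append(params)
    return CrossValidationResult(reports=reports, params=chosen)


def roc(
    scores: Sequence[float] | np.ndarray, truth: Sequence[int] | np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold-swept (FPR, TPR) curve and its AUC."""
    t = np.asarray(truth, dtype=int)
    if len(set(np.unique(t))) < 2:
        raise ValueError("ROC requires both classes in the truth labels")
    fpr, tpr, _ = _sk_roc_curve(t, np.asarray(scores, dtype=float), pos_label=1)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def cv_report_tsv(result: CrossValidationResult) -> str:
    lines = ["rotation\tC\tgamma\tTP\tFP\tTN\tFN\tSe\tSp\tPre\tACC"]
    for i, (rep, par) in enumerate(zip(result.reports, result.params)):
        d = rep.as_dict()
        cells = [str(i), f"{par.C:g}", f"{par.gamma:g}",
                 str(rep.tp), str(rep.fp), str(rep.tn), str(rep.fn)]
        cells += ["NA" if d[m] is None else f"{d[m]:.2f}" for m in ("Se", "Sp", "Pre", "ACC")]
        lines.append("\t".join(cells))
    mean_cells = ["mean", "", "", "", "", "", ""] + [
        f"{result.mean.get(m, math.nan):.2f}" for m in ("Se", "Sp", "Pre", "ACC")
    ]
    sd_cells = ["sd", "", "", "", "", "", ""] + [
        f"{result.sd.get(m, math.nan):.2f}" for m in ("Se", "Sp", "Pre", "ACC")
    ]
    lines.append("\t".join(mean_cells))
    lines.append("\t".join(sd_cells))
    return "\n".join(lines) + "\n"
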