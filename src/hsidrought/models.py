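"""Classifier training, 7:3 splitting and performance reporting.

Three classifier families cover the study design: an RBF support-vector
machine, a random forest, and the one-block 1-D DenseNet.  Samples are
partitioned 70/30 into *calibration* and *prediction* sets, stratified
by treatment and (by default) grouped by plant so leaves of one plant
never straddle the split; fused young/mature pairs always move as one
unit.  Reports carry calibration/prediction accuracy, per-class
precision/recall/F1 in percent, the confusion matrix and one-vs-rest
ROC curves with AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .densenet1d import DenseNet1DClassifier

__all__ = [
    "SplitSpec",
    "ModelReport",
    "split",
    "train_svm",
    "train_rf",
    "train_densenet1d",
    "evaluate",
]


@dataclass
class SplitSpec:
    """Calibration/prediction partition: 70/30, stratified, plant-grouped."""

    ratio: float = 0.7
    stratified: bool = True
    seed: int = 0
    unit: str = "leaf"  # 'leaf' or 'pair'
    group_by_plant: bool = True


def split(labels: np.ndarray, spec: SplitSpec,
          groups: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Return (calibration_idx, prediction_idx).

    With ``groups`` (e.g. plant ids) all members of a group land on the
    same side; group label must be homogeneous.  Stratification targets
    ``ratio`` of the *samples* of each class in calibration.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 samples to split")
    rng = np.random.default_rng(spec.seed)
    calib: list[int] = []
    pred: list[int] = []
    if groups is None or not spec.group_by_plant:
        for c in classes if spec.stratified else [None]:
            idx = np.flatnonzero(labels == c) if c is not None else np.arange(labels.size)
            idx = idx[rng.permutation(idx.size)]
            n_cal = int(round(spec.ratio * idx.size))
            n_cal = min(max(n_cal, 1), idx.size - 1)
            calib.extend(idx[:n_cal])
            pred.extend(idx[n_cal:])
    else:
        groups = np.asarray(groups)
        for c in classes:
            cls_groups = np.unique(groups[labels == c])
            if cls_groups.size < 2:
                raise ValueError(
                    f"class {c} has a single plant group; grouped splitting needs >= 2 "
                    "(pass group_by_plant=False to split at the leaf level)"
                )
            cls_groups = cls_groups[rng.permutation(cls_groups.size)]
            target = spec.ratio * np.sum(labels == c)
            taken = 0
            cal_groups = []
            for g in cls_groups:
                size = int(np.sum((groups == g) & (labels == c)))
                # take the group if it brings us closer to the 70% target
                if abs(taken + size - target) <= abs(taken - target):
                    cal_groups.append(g)
                    taken += size
            if taken == 0:
                cal_groups.append(cls_groups[0])
            if taken == np.sum(labels == c):
                cal_groups.pop()
            in_cal = np.isin(groups, cal_groups) & (labels == c)
            calib.extend(np.flatnonzero(in_cal))
            pred.extend(np.flatnonzero(~in_cal & (labels == c)))
    return np.sort(np.array(calib, dtype=int)), np.sort(np.array(pred, dtype=int))


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0, gamma: str | float = "scale",
              seed: int = 0) -> Pipeline:
    """Standardize + RBF SVM with one-vs-rest decision scores."""
    _check_trainable(y)
    model = make_pipeline(
        StandardScaler(),
        SVC(kernel="rbf", C=C, gamma=gamma, decision_function_shape="ovr",
            random_state=seed),
    )
    return model.fit(X, y)


def train_rf(X: np.ndarray, y: np.ndarray, n_estimators: int = 500,
             max_features: str = "sqrt", max_depth: int | None = None,
             bootstrap: bool = True, seed: int = 0) -> RandomForestClassifier:
    _check_trainable(y)
    model = RandomForestClassifier(n_estimators=n_estimators, max_features=max_features,
                                   max_depth=max_depth, bootstrap=bootstrap,
                                   random_state=seed)
    return model.fit(X, y)


def train_densenet1d(X: np.ndarray, y: np.ndarray, seed: int = 0,
                     **params) -> Pipeline:
    _check_trainable(y)
    model = make_pipeline(StandardScaler(), DenseNet1DClassifier(seed=seed, **params))
    return model.fit(X, y)


def _check_trainable(y: np.ndarray) -> None:
    if len(y) == 0:
        raise ValueError("empty calibration set")
    if np.unique(y).size < 2:
        raise ValueError("calibration set holds a single class; nothing to learn")


@dataclass
class ModelReport:
    """Accuracies (percent), per-class metrics, confusion matrix, ROC."""

    acc_c: float
    acc_p: float
    precision: dict[int, float | None]
    recall: dict[int, float | None]
    f1: dict[int, float | None]
    confusion: np.ndarray
    roc: dict[int, dict] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "acc_c": self.acc_c,
            "acc_p": self.acc_p,
            "precision": {str(k): v for k, v in self.precision.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "f1": {str(k): v for k, v in self.f1.items()},
            "confusion": [[int(v) for v in row] for row in self.confusion],
            "roc": {str(k): {"fpr": list(map(float, v["fpr"])),
                             "tpr": list(map(float, v["tpr"])),
                             "auc": v["auc"]} for k, v in self.roc.items()},
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelReport":
        return cls(
            acc_c=d["acc_c"], acc_p=d["acc_p"],
            precision={int(k): v for k, v in d["precision"].items()},
            recall={int(k): v for k, v in d["recall"].items()},
            f1={int(k): v for k, v in d["f1"].items()},
            confusion=np.array(d["confusion"], dtype=int),
            roc={int(k): {"fpr": np.array(v["fpr"]), "tpr": np.array(v["tpr"]),
                          "auc": v["auc"]} for k, v in d["roc"].items()},
            flags=list(d.get("flags", [])),
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def write_csvs(self, prefix: str) -> None:
        """Write ``<prefix>_confusion.csv`` and ``<prefix>_roc.csv``."""
        classes = list(self.precision)
        with open(prefix + "_confusion.csv", "w") as fh:
            fh.write("actual\\predicted," + ",".join(map(str, classes)) + "\n")
            for c, row in zip(classes, self.confusion):
                fh.write(f"{c}," + ",".join(str(int(v)) for v in row) + "\n")
        with open(prefix + "_roc.csv", "w") as fh:
            fh.write("class,fpr,tpr\n")
            for c, curve in self.roc.items():
                for f, t in zip(curve["fpr"], curve["tpr"]):
                    fh.write(f"{c},{f:.6f},{t:.6f}\n")


def _class_scores(model, X: np.ndarray) -> np.ndarray | None:
    if hasattr(model, "decision_function"):
        s = model.decision_function(X)
        return s if s.ndim == 2 else np.column_stack([-s, s])
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)
    return None


def evaluate(model, calib: tuple[np.ndarray, np.ndarray],
             pred: tuple[np.ndarray, np.ndarray],
             classes: np.ndarray | None = None) -> ModelReport:
    """Compute the full report from a fitted model and the two splits.

    A class absent from the prediction set gets ``None`` metrics plus a
    flag (rather than silently reporting 0).
    """
    Xc, yc = calib
    Xp, yp = pred
    if classes is None:
        classes = np.unique(np.concatenate([yc, yp]))
    acc_c = 100.0 * float(np.mean(model.predict(Xc) == yc))
    yhat = model.predict(Xp)
    acc_p = 100.0 * float(np.mean(yhat == yp))
    cm = confusion_matrix(yp, yhat, labels=classes)
    precision: dict[int, float | None] = {}
    recall: dict[int, float | None] = {}
    f1: dict[int, float | None] = {}
    flags: list[str] = []
    for i, c in enumerate(classes):
        tp = cm[i, i]
        row = cm[i].sum()       # actual count of class c
        col = cm[:, i].sum()    # predicted count of class c
        if row == 0:
            precision[int(c)] = recall[int(c)] = f1[int(c)] = None
            flags.append(f"class {c} absent from prediction set; metrics undefined")
            continue
        p = 100.0 * tp / col if col > 0 else 0.0
        r = 100.0 * tp / row
        precision[int(c)] = float(p)
        recall[int(c)] = float(r)
        f1[int(c)] = float(2 * p * r / (p + r)) if (p + r) > 0 else 0.0
    roc: dict[int, dict] = {}
    scores = _class_scores(model, Xp)
    if scores is not None and scores.shape[1] == classes.size:
        for i, c in enumerate(classes):
            if np.unique(yp == c).size < 2:
                continue
            fpr, tpr, _ = roc_curve((yp == c).astype(int), scores[:, i])
            roc[int(c)] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
    return ModelReport(acc_c=acc_c, acc_p=acc_p, precision=precision,
                       recall=recall, f1=f1, confusion=cm, roc=roc, flags=flags)
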