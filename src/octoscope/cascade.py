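"""Multilayered (cascaded) SVM classification of the 9-feature descriptor.

Routing follows the screening logic: stage 1 separates healthy from
abnormal scans on the thickness/cyst features (f1-f4); abnormal scans go to
stage 2, which splits drusen-driven degeneration (ARMD) from the fluid
diseases on the RPE features (f6-f9); stage 3 separates retinal edema from
central serous chorioretinopathy on the cyst area and energy (f4, f5).
Each stage is an independently standardized binary SVM whose
hyperparameters are chosen by an inner stratified grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import (InsufficientTrainingClasses, InvalidFeatureVector,
                     InvalidFoldCount)
from .features import FEATURE_NAMES, FeatureVector

LABELS = ("healthy", "RE", "CSCR", "ARMD")
_KERNELS = {"rbf": "rbf", "mlp_sigmoid": "sigmoid"}

DEFAULT_STAGE_FEATURES = {
    1: ("f1", "f2", "f3", "f4"),
    2: ("f6", "f7", "f8", "f9"),
    3: ("f4", "f5"),
}


@dataclass
class CascadeConfig:
    kernel: str = "rbf"
    stage_features: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_FEATURES))
    c_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple = ("scale", 0.01, 0.1, 1.0)
    inner_cv: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.kernel not in _KERNELS:
            raise ValueError(f"kernel must be one of {sorted(_KERNELS)}")
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        for stage, feats in self.stage_features.items():
            bad = set(feats) - set(FEATURE_NAMES)
            if bad:
                raise ValueError(f"stage {stage} uses unknown features {bad}")


@dataclass
class TrainedCascade:
    """Three fitted binary stages plus routing metadata."""

    stage1: Pipeline       # healthy vs abnormal
    stage2: Pipeline       # ARMD vs fluid disease
    stage3: Pipeline       # RE vs CSCR
    config: CascadeConfig
    n_per_class: dict
    format_version: int = 1

    def predict(self, fv: "FeatureVector | np.ndarray | pd.Series") -> str:
        row = _as_row(fv)
        if self._route1(row) == "healthy":
            return "healthy"
        if self._route2(row) == "ARMD":
            return "ARMD"
        return self._route3(row)

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        return np.array([self.predict(r) for _, r in table.iterrows()])

    def _stage_input(self, row: pd.Series, stage: int) -> np.ndarray:
        feats = self.config.stage_features[stage]
        return row[list(feats)].to_numpy(dtype=np.float64).reshape(1, -1)

    def _route1(self, row): return self.stage1.predict(self._stage_input(row, 1))[0]
    def _route2(self, row): return self.stage2.predict(self._stage_input(row, 2))[0]
    def _route3(self, row): return self.stage3.predict(self._stage_input(row, 3))[0]


def _as_row(fv) -> pd.Series:
    if isinstance(fv, FeatureVector):
        row = pd.Series(fv.to_dict())
    elif isinstance(fv, pd.Series):
        row = fv[list(FEATURE_NAMES)].astype(float)
    else:
        arr = np.asarray(fv, dtype=np.float64).ravel()
        if arr.size != len(FEATURE_NAMES):
            raise InvalidFeatureVector(f"expected 9 features, got {arr.size}")
        row = pd.Series(arr, index=list(FEATURE_NAMES))
    if not np.isfinite(row.to_numpy(dtype=np.float64)).all():
        raise InvalidFeatureVector("non-finite feature value")
    return row


def _fit_stage(X: pd.DataFrame, y: np.ndarray, config: CascadeConfig) -> Pipeline:
    classes, counts = np.unique(y, return_counts=True)
    n_splits = int(min(config.inner_cv, counts.min()))
    pipe = Pipeline([("scale", StandardScaler()),
                     ("svm", SVC(kernel=_KERNELS[config.kernel]))])
    if n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
        search = GridSearchCV(pipe, {"svm__C": list(config.c_grid),
                                     "svm__gamma": list(config.gamma_grid)}, cv=cv)
        search.fit(X.to_numpy(dtype=np.float64), y)
        return search.best_estimator_
    pipe.fit(X.to_numpy(dtype=np.float64), y)
    return pipe


def train_cascade(features: pd.DataFrame, labels, config: CascadeConfig | None = None
                  ) -> TrainedCascade:
    """Fit the three-stage cascade on a labeled feature table."""
    config = config or CascadeConfig()
    config.validate()
    labels = np.asarray(labels)
    counts = {lab: int((labels == lab).sum()) for lab in LABELS}
    missing = [lab for lab, n in counts.items() if n < 2]
    if missing:
        raise InsufficientTrainingClasses(f"need >= 2 examples of {missing}")
    X = features[list(FEATURE_NAMES)]
    if not np.isfinite(X.to_numpy(dtype=np.float64)).all():
        raise InvalidFeatureVector("non-finite value in training features")

    y1 = np.where(labels == "healthy", "healthy", "abnormal")
    s1 = _fit_stage(X[list(config.stage_features[1])], y1, config)

    diseased = labels != "healthy"
    y2 = np.where(labels[diseased] == "ARMD", "ARMD", "fluid")
    s2 = _fit_stage(X.loc[diseased, list(config.stage_features[2])], y2, config)

    fluid = (labels == "RE") | (labels == "CSCR")
    s3 = _fit_stage(X.loc[fluid, list(config.stage_features[3])], labels[fluid], config)

    return TrainedCascade(stage1=s1, stage2=s2, stage3=s3, config=config,
                          n_per_class=counts)


def predict(model: TrainedCascade, fv) -> str:
    """Route one feature vector through the cascade; returns a class label."""
    return model.predict(fv)


def evaluate(model: TrainedCascade, features: pd.DataFrame, labels) -> dict:
    """Confusion matrix, 4-class accuracy, and binary sensitivity/specificity.

    Sensitivity counts any diseased scan flagged with any disease label as
    detected; specificity is the healthy-recognized-as-healthy rate.
    """
    labels = np.asarray(labels)
    preds = model.predict_table(features)
    return metrics_from_predictions(labels, preds)


def metrics_from_predictions(labels: np.ndarray, preds: np.ndarray) -> dict:
    labels = np.asarray(labels)
    preds = np.asarray(preds)
    cm = pd.DataFrame(0, index=list(LABELS), columns=list(LABELS))
    for truth, pred in zip(labels, preds):
        cm.loc[truth, pred] += 1
    accuracy = float((labels == preds).mean())
    dis = labels != "healthy"
    sens = float((preds[dis] != "healthy").mean()) if dis.any() else float("nan")
    hea = ~dis
    spec = float((preds[hea] == "healthy").mean()) if hea.any() else float("nan")
    return {"confusion_matrix": cm, "accuracy": accuracy,
            "sensitivity": sens, "specificity": spec}


def cross_validate(features: pd.DataFrame, labels, k: int,
                   config: CascadeConfig | None = None) -> dict:
    """Stratified k-fold evaluation with the full training pipeline per fold."""
    config = config or CascadeConfig()
    labels = np.asarray(labels)
    if k < 2:
        raise InvalidFoldCount(f"k must be >= 2, got {k}")
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise InvalidFoldCount(f"k={k} exceeds the smallest class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    fold_acc, all_true, all_pred = [], [], []
    X = features[list(FEATURE_NAMES)].reset_index(drop=True)
    for train_idx, test_idx in skf.split(X, labels):
        model = train_cascade(X.iloc[train_idx], labels[train_idx], config)
        preds = model.predict_table(X.iloc[test_idx])
        fold_acc.append(float((preds == labels[test_idx]).mean()))
        all_true.extend(labels[test_idx])
        all_pred.extend(preds)
    overall = metrics_from_predictions(np.array(all_true), np.array(all_pred))
    overall.update({"k": k, "fold_accuracies": fold_acc,
                    "mean_accuracy": float(np.mean(fold_acc))})
    return overall


def save_cascade(model: TrainedCascade, path) -> None:
    """Persist a trained cascade (joblib payload with a config header)."""
    payload = {"format_version": model.format_version,
               "config": asdict(model.config),
               "n_per_class": model.n_per_class,
               "stages": (model.stage1, model.stage2, model.stage3)}
    joblib.dump(payload, path)


def load_cascade(path) -> TrainedCascade:
    payload = joblib.load(path)
    cfg = CascadeConfig(**{**payload["config"],
                           "stage_features": {int(k): tuple(v) for k, v
                                              in payload["config"]["stage_features"].items()},
                           "c_grid": tuple(payload["config"]["c_grid"]),
                           "gamma_grid": tuple(payload["config"]["gamma_grid"])})
    s1, s2, s3 = payload["stages"]
    return TrainedCascade(stage1=s1, stage2=s2, stage3=s3, config=cfg,
                          n_per_class=payload["n_per_class"],
                          format_version=payload["format_version"])
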