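"""RBF-kernel SVM classification with grid-searched hyperparameters.

The classifier is a soft-margin SVM with the radial basis function kernel
``k(x, y) = exp(-gamma * ||x - y||^2)``.  The two hyperparameters are tuned
by exhaustive grid search over

    C     in {2^-3, 2^-1, ..., 2^13, 2^15}   (odd exponents, 10 values)
    gamma in {2^-15, 2^-13, ..., 2^1, 2^3}   (odd exponents, 10 values)

scored by mean stratified k-fold CV accuracy; ties resolve to the smallest
C, then the smallest gamma.  Features are standardized (zero mean, unit
variance, fitted on training data only) before the kernel sees them: RBF
distances are scale-sensitive and covariance-type components span orders of
magnitude.  Zero-variance features get unit scale rather than a division by
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import RegistryMismatchError
from .features import FeatureTable

__all__ = [
    "HyperParams",
    "TrainedModel",
    "default_grid",
    "grid_search",
    "train",
    "predict",
    "save_model",
    "load_model",
    "POS_LABEL",
    "NEG_LABEL",
]

POS_LABEL = "AOP"
NEG_LABEL = "non-AOP"


@dataclass(frozen=True)
class HyperParams:
    """Soft-margin cost C and RBF width gamma; both strictly positive."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be strictly positive")


def default_grid() -> tuple[list[float], list[float]]:
    """The 10 x 10 hyperparameter grid (C values, gamma values)."""
    C_values = [2.0**e for e in range(-3, 17, 2)]
    gamma_values = [2.0**e for e in range(-15, 5, 2)]
    return C_values, gamma_values


@dataclass
class TrainedModel:
    """A fitted scaler + SVM bundle with its feature registry and metadata."""

    params: HyperParams
    scaler: StandardScaler
    svc: SVC
    feature_names: list[str]
    pos_label: str = POS_LABEL
    neg_label: str = NEG_LABEL
    metadata: dict = field(default_factory=dict)


def grid_search(
    table: FeatureTable,
    folds: int = 5,
    seed: int = 0,
    grid: tuple[list[float], list[float]] | None = None,
) -> HyperParams:
    """Exhaustive (C, gamma) search by mean stratified k-fold CV accuracy.

    Ties resolve to the smallest C, then the smallest gamma; with a fixed
    seed the result is deterministic.
    """
    y = table.binary_labels()
    if len(np.unique(y)) != 2:
        raise ValueError("grid search requires both classes present")
    C_values, gamma_values = grid if grid is not None else default_grid()
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best: tuple[float, HyperParams] | None = None
    for C in sorted(C_values):
        for gamma in sorted(gamma_values):
            pipe = make_pipeline(StandardScaler(), SVC(C=C, gamma=gamma))
            acc = float(cross_val_score(pipe, table.X, y, cv=cv).mean())
            if best is None or acc > best[0]:
                best = (acc, HyperParams(C=C, gamma=gamma))
    assert best is not None
    return best[1]


def train(
    table: FeatureTable,
    params: HyperParams,
    metadata: dict | None = None,
    pos_label: str = POS_LABEL,
) -> TrainedModel:
    """Fit the scaler and the RBF-kernel SVM on a feature table."""
    y = table.binary_labels(pos_label)
    if len(np.unique(y)) != 2:
        raise ValueError("training requires both classes present")
    labels = set(np.unique(table.labels).tolist())
    neg_label = (labels - {pos_label}).pop()
    scaler = StandardScaler().fit(table.X)
    svc = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
    svc.fit(scaler.transform(table.X), y)
    return TrainedModel(
        params=params,
        scaler=scaler,
        svc=svc,
        feature_names=list(table.names),
        pos_label=pos_label,
        neg_label=neg_label,
        metadata=dict(metadata or {}),
    )


def _align_columns(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Reorder table columns to the model's registry; error on mismatch."""
    pos = {name: i for i, name in enumerate(table.names)}
    missing = [n for n in model.feature_names if n not in pos]
    extra = [n for n in table.names if n not in set(model.feature_names)]
    if missing or extra:
        raise RegistryMismatchError(
            "feature registry mismatch: "
            f"missing {missing[:5]}{'...' if len(missing) > 5 else ''}, "
            f"extra {extra[:5]}{'...' if len(extra) > 5 else ''}"
        )
    idx = np.array([pos[n] for n in model.feature_names])
    return table.X[:, idx]


def predict(
    model: TrainedModel, table: FeatureTable
) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and real-valued decision scores for each row.

    Scores are signed margin distances (positive = predicted positive
    class); they are the ranking input for ROC/AUC.  Columns are aligned by
    component name, so any consistent reordering of the table's features
    leaves predictions unchanged.
    """
    X = model.scaler.transform(_align_columns(model, table))
    scores = model.svc.decision_function(X)
    labels = np.where(scores > 0, model.pos_label, model.neg_label)
    return labels, scores


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model (parameters, scaler, SVM, registry, metadata)."""
    payload = {"format_version": 1, "model": model}
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format_version") != 1:
        raise ValueError(f"{path}: not a recognised model archive")
    return payload["model"]
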