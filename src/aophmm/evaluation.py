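"""Performance metrics and cross-validation protocols.

Metrics from pooled confusion counts (TP, TN, FP, FN):

    Sen = TP / (TP + FN)                       sensitivity (recall on AOPs)
    Spe = TN / (TN + FP)                       specificity
    Acc = (TP + TN) / n                        overall accuracy
    MCC = (TP*TN - FN*FP) /
          sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))  Matthews correlation

A zero MCC denominator yields MCC = 0 by convention; an undefined Sen or Spe
(empty class) is reported as 0 with an explicit ``*_defined`` flag rather
than silently.  AUC is the area under the ROC curve built by sweeping the
decision-score threshold (ties grouped) and integrating by trapezoid, which
equals the tie-corrected Mann-Whitney rank statistic.

Three protocols are provided: stratified k-fold CV (k = 10 by default),
jackknife (leave-one-out) CV, and an independent train/test split.  All
training-time computation — ANOVA feature selection, SMOTE oversampling,
feature scaling, hyperparameter grid search — is fitted inside each fold on
the training partition only; CV metrics are computed from confusion counts
pooled across folds (each sample is scored exactly once), and AUC from the
pooled decision scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import classifier as clf
from .classifier import HyperParams, TrainedModel, POS_LABEL
from .features import FeatureTable
from .resampling import smote, SMOTE_DEFAULT_K
from .selection import anova_f_scores, rank_features

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "PipelineConfig",
    "EvaluationReport",
    "metrics",
    "auc",
    "kfold_cv",
    "jackknife_cv",
    "independent_test",
]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    sen: float
    spe: float
    acc: float
    mcc: float
    sen_defined: bool = True
    spe_defined: bool = True


def metrics(counts: ConfusionCounts) -> Metrics:
    """Sen/Spe/Acc/MCC from confusion counts (see module docstring)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.n
    if n == 0:
        raise ValueError("no evaluated samples: all confusion counts are zero")
    sen_def = (tp + fn) > 0
    spe_def = (tn + fp) > 0
    sen = tp / (tp + fn) if sen_def else 0.0
    spe = tn / (tn + fp) if spe_def else 0.0
    acc = (tp + tn) / n
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / np.sqrt(denom) if denom > 0 else 0.0
    return Metrics(sen=sen, spe=spe, acc=acc, mcc=float(mcc),
                   sen_defined=sen_def, spe_defined=spe_def)


def auc(
    labels: np.ndarray, scores: np.ndarray, pos_label: str = POS_LABEL
) -> tuple[float, np.ndarray]:
    """AUC by trapezoid over the threshold-swept ROC curve.

    Returns the area and the ROC points as an array of (FPR, TPR) rows,
    starting at (0, 0) and ending at (1, 1).  All-tied scores give the
    chance diagonal and AUC = 0.5.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    y = (labels == pos_label).astype(int)
    if y.min() == y.max():
        raise ValueError("AUC requires both classes present")
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return area, np.column_stack([fpr, tpr])


@dataclass
class PipelineConfig:
    """What happens inside each training fold, in order.

    select_k:
        If set, keep the top-k features by ANOVA F score (fitted on the
        fold's training data).  None disables selection.
    smote / smote_k:
        Oversample the training minority class to 1:1 balance before
        scaling and fitting.
    grid_search / grid / inner_folds:
        If grid_search, tune (C, gamma) by inner stratified CV on the
        training partition; otherwise use ``params`` (or C=1 with
        gamma = 1/(d * Var) if ``params`` is None).
    resample_before_split:
        Compatibility mode: apply SMOTE to the whole dataset before the CV
        split.  This leaks synthetic copies of test points into training
        folds; a prominent warning is emitted.
    """

    select_k: int | None = None
    smote: bool = False
    smote_k: int = SMOTE_DEFAULT_K
    grid_search: bool = False
    grid: tuple[list[float], list[float]] | None = None
    inner_folds: int = 3
    params: HyperParams | None = None
    resample_before_split: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.params is not None:
            d["params"] = {"C": self.params.C, "gamma": self.params.gamma}
        return d


@dataclass
class EvaluationReport:
    """Pooled metrics, ROC, and per-fold details for one protocol run."""

    protocol: str
    counts: ConfusionCounts
    sen: float
    spe: float
    acc: float
    mcc: float
    auc: float
    roc: np.ndarray
    per_fold: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "counts": asdict(self.counts),
            "sen": self.sen,
            "spe": self.spe,
            "acc": self.acc,
            "mcc": self.mcc,
            "auc": self.auc,
            "roc": self.roc.tolist(),
            "per_fold": [
                {k: v for k, v in fold.items() if not isinstance(v, np.ndarray)}
                for fold in self.per_fold
            ],
            "config": self.config,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _fit_fold(
    train_table: FeatureTable, config: PipelineConfig, seed: int
) -> tuple[TrainedModel, dict]:
    """Fit selection -> SMOTE -> grid search -> scaler+SVM on one training set.

    Returns the model and a record of the fitted training-time state (used
    by reports and by the leakage canary test).
    """
    artifacts: dict = {}
    tbl = train_table
    if config.select_k is not None:
        f = anova_f_scores(tbl)
        top = rank_features(f)[: config.select_k]
        tbl = tbl.subset_features(top)
        artifacts["selected_names"] = list(tbl.names)
        artifacts["f_scores_sum"] = float(np.sum(f[np.isfinite(f)]))
    if config.smote:
        tbl, report = smote(tbl, k=config.smote_k, seed=seed)
        artifacts["n_synthetic"] = len(report.synthetic_ids)
    if config.grid_search:
        params = clf.grid_search(
            tbl, folds=config.inner_folds, seed=seed, grid=config.grid
        )
    elif config.params is not None:
        params = config.params
    else:
        # the 1/(d * Var) width heuristic; features are standardized to
        # unit variance before the kernel, so this reduces to 1/d.
        params = HyperParams(C=1.0, gamma=1.0 / tbl.n_features)
    model = clf.train(tbl, params)
    artifacts["params"] = {"C": params.C, "gamma": params.gamma}
    artifacts["scaler_mean"] = model.scaler.mean_.copy()
    artifacts["scaler_scale"] = model.scaler.scale_.copy()
    return model, artifacts


def _pool_protocol(
    config: PipelineConfig,
    table: FeatureTable,
    splits: list[tuple[np.ndarray, np.ndarray]],
    protocol: str,
    seed: int | None,
) -> EvaluationReport:
    y_true = table.binary_labels()
    pooled_scores = np.empty(table.n_samples)
    pooled_pred = np.empty(table.n_samples, dtype=int)
    per_fold: list[dict] = []
    base_seed = 0 if seed is None else seed
    for fi, (tr, te) in enumerate(splits):
        fold_seed = (base_seed * 1009 + fi) % _SEED_MOD
        model, artifacts = _fit_fold(table.subset_rows(tr), config, fold_seed)
        labels, scores = clf.predict(model, _project(table.subset_rows(te), model))
        pred = (labels == model.pos_label).astype(int)
        pooled_scores[te] = scores
        pooled_pred[te] = pred
        fold_counts = _counts_from(y_true[te], pred)
        fold = {"fold": fi, "seed": fold_seed, "test_size": len(te),
                "counts": asdict(fold_counts), **artifacts}
        if fold_counts.n >= 2:
            m = metrics(fold_counts)
            fold.update(sen=m.sen, spe=m.spe, acc=m.acc, mcc=m.mcc)
        per_fold.append(fold)
    counts = _counts_from(y_true, pooled_pred)
    m = metrics(counts)
    area, roc = auc(table.labels, pooled_scores)
    return EvaluationReport(
        protocol=protocol, counts=counts, sen=m.sen, spe=m.spe, acc=m.acc,
        mcc=m.mcc, auc=area, roc=roc, per_fold=per_fold,
        config=config.to_dict(), seed=seed,
    )


def _project(table: FeatureTable, model: TrainedModel) -> FeatureTable:
    """Restrict a table to the model's (possibly selected) feature subset."""
    if table.names == model.feature_names:
        return table
    pos = {name: i for i, name in enumerate(table.names)}
    idx = [pos[n] for n in model.feature_names if n in pos]
    if len(idx) != len(model.feature_names):
        return table  # let predict() raise its detailed mismatch error
    return table.subset_features(np.asarray(idx))


def _counts_from(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _maybe_presplit_smote(
    config: PipelineConfig, table: FeatureTable, seed: int
) -> tuple[PipelineConfig, FeatureTable]:
    if not config.resample_before_split:
        return config, table
    warnings.warn(
        "resample_before_split=True: SMOTE applied to the WHOLE dataset "
        "before cross-validation. Synthetic copies of test points leak into "
        "training folds; reported metrics are optimistically biased.",
        stacklevel=3,
    )
    table, _ = smote(table, k=config.smote_k, seed=seed)
    cfg = replace(config, smote=False, resample_before_split=False)
    return cfg, table


def kfold_cv(
    config: PipelineConfig, table: FeatureTable, k: int = 10, seed: int = 0
) -> EvaluationReport:
    """Stratified k-fold CV with the full pipeline refitted per fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if table.n_samples < k:
        raise ValueError(f"fewer samples ({table.n_samples}) than folds ({k})")
    config, table = _maybe_presplit_smote(config, table, seed)
    y = table.binary_labels()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = [(tr, te) for tr, te in skf.split(table.X, y)]
    return _pool_protocol(config, table, splits, f"{k}-fold", seed)


def jackknife_cv(
    config: PipelineConfig, table: FeatureTable, seed: int = 0
) -> EvaluationReport:
    """Leave-one-out CV: each sample scored by a model trained on the rest."""
    n = table.n_samples
    if n < 2:
        raise ValueError("jackknife needs at least 2 samples")
    config, table = _maybe_presplit_smote(config, table, seed)
    n = table.n_samples
    all_idx = np.arange(n)
    splits = [(np.delete(all_idx, i), np.array([i])) for i in range(n)]
    return _pool_protocol(config, table, splits, "jackknife", seed)


def independent_test(
    config: PipelineConfig,
    train_table: FeatureTable,
    test_table: FeatureTable,
    seed: int = 0,
) -> EvaluationReport:
    """Train once on one table, score a held-out table once.

    Selection, SMOTE, scaling and grid search touch only the training
    table.  Overlapping sample ids between the two tables are reported with
    a warning (they usually indicate a contaminated split).
    """
    if train_table.names != test_table.names:
        from .errors import RegistryMismatchError

        raise RegistryMismatchError(
            "train and test tables have different feature registries"
        )
    overlap = sorted(set(train_table.ids) & set(test_table.ids))
    if overlap:
        warnings.warn(
            f"{len(overlap)} id(s) appear in both train and test tables: "
            f"{overlap[:10]}{'...' if len(overlap) > 10 else ''}",
            stacklevel=2,
        )
    model, artifacts = _fit_fold(train_table, config, seed)
    labels, scores = clf.predict(model, _project(test_table, model))
    pred = (labels == model.pos_label).astype(int)
    y_true = test_table.binary_labels()
    counts = _counts_from(y_true, pred)
    m = metrics(counts)
    area, roc = auc(test_table.labels, scores)
    return EvaluationReport(
        protocol="independent", counts=counts, sen=m.sen, spe=m.spe,
        acc=m.acc, mcc=m.mcc, auc=area, roc=roc,
        per_fold=[{"fold": 0, "seed": seed, "test_size": test_table.n_samples,
                   **artifacts}],
        config=config.to_dict(), seed=seed,
    )
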