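"""ANOVA F-score feature ranking and stepwise incremental selection.

Each feature is scored by the one-way ANOVA F statistic between the two
classes — the ratio of the between-group sample variance to the within-group
sample variance:

    F = [ sum_g n_g (mean_g - grand_mean)^2 / (G - 1) ]
        / [ sum_g sum_i (x_gi - mean_g)^2 / (n - G) ]

with G = 2 groups.  Larger F means the feature separates the classes better.
Features are ranked by descending F (ties broken by ascending index; an
infinite-F sentinel — zero within-group variance but distinct group means —
ranks first).  The subset size is then chosen by a stepwise incremental
sweep: train the classifier on the top-s ranked features under k-fold
cross-validation for a grid of sizes s, and keep the smallest size that
attains the maximum CV accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureTable

__all__ = [
    "SelectionResult",
    "anova_f_scores",
    "rank_features",
    "incremental_selection",
]


@dataclass
class SelectionResult:
    """Outcome of ranking + incremental subset choice."""

    f_scores: np.ndarray
    ranking: np.ndarray  # permutation of feature indices, best first
    chosen: np.ndarray  # prefix of `ranking`
    curve: list[tuple[int, float]]  # (subset size, CV accuracy)
    step: int

    def to_dict(self) -> dict:
        return {
            "f_scores": [None if not np.isfinite(f) else float(f) for f in self.f_scores],
            "ranking": self.ranking.tolist(),
            "chosen": self.chosen.tolist(),
            "curve": [[int(s), float(a)] for s, a in self.curve],
            "step": self.step,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def plot_curve(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        sizes, accs = zip(*self.curve)
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(sizes, accs, marker="o", ms=3)
        ax.axvline(len(self.chosen), ls="--", color="grey", lw=0.8)
        ax.set_xlabel("number of top-ranked features")
        ax.set_ylabel("CV accuracy")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def anova_f_scores(table: FeatureTable) -> np.ndarray:
    """Per-feature two-group ANOVA F statistic.

    Degenerate features score 0 when both between- and within-group
    variances vanish, and +inf when the groups differ in mean but have zero
    within-group spread (a perfectly separating feature).
    """
    labels = np.unique(table.labels)
    if len(labels) != 2:
        raise ValueError(
            f"two classes required for ANOVA ranking, found {len(labels)}"
        )
    n = table.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for a within-group variance")
    X = table.X
    masks = [table.labels == lab for lab in labels]
    ns = np.array([m.sum() for m in masks], dtype=float)
    grand = X.mean(axis=0)
    means = np.stack([X[m].mean(axis=0) for m in masks])
    ss_between = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ss_within = sum(
        ((X[m] - means[i]) ** 2).sum(axis=0) for i, m in enumerate(masks)
    )
    ms_between = ss_between / (len(labels) - 1)
    ms_within = ss_within / (n - len(labels))

    f = np.zeros(table.n_features)
    # Guard against spurious tiny SS from floating-point cancellation.
    scale = np.maximum(np.abs(X).max(axis=0) ** 2, 1.0)
    tol = 1e-12 * scale
    zero_within = ms_within <= tol
    zero_between = ms_between <= tol
    regular = ~zero_within
    f[regular] = ms_between[regular] / ms_within[regular]
    f[zero_within & ~zero_between] = np.inf
    f[zero_within & zero_between] = 0.0
    return f


def rank_features(f_scores: np.ndarray) -> np.ndarray:
    """Indices sorted by descending F; ties broken by ascending index."""
    f_scores = np.asarray(f_scores, dtype=float)
    d = len(f_scores)
    # lexsort: last key is primary. Negate for descending; index breaks ties.
    return np.lexsort((np.arange(d), -f_scores))


def _default_classifier(C: float | None = None, gamma: float | str | None = None):
    return make_pipeline(
        StandardScaler(),
        SVC(C=C if C is not None else 1.0, gamma=gamma if gamma is not None else "scale"),
    )


def incremental_selection(
    table: FeatureTable,
    step: int = 5,
    folds: int = 10,
    seed: int = 0,
    sizes: list[int] | None = None,
    C: float | None = None,
    gamma: float | None = None,
) -> SelectionResult:
    """Choose the feature-subset size by a stepwise incremental CV sweep.

    Subset sizes are ``step, 2*step, ...`` up to the full feature count
    (always included), or an explicit ``sizes`` list.  For each size the
    classifier is trained on the top-ranked prefix under stratified k-fold
    CV; the chosen subset is the smallest size attaining the maximum mean
    accuracy (parsimony tie-break).  Fully reproducible given ``seed``.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if table.n_samples < folds:
        raise ValueError(
            f"fewer samples ({table.n_samples}) than folds ({folds})"
        )
    f = anova_f_scores(table)
    ranking = rank_features(f)
    d = table.n_features
    if sizes is None:
        sizes = list(range(step, d + 1, step))
        if not sizes or sizes[-1] != d:
            sizes.append(d)
    else:
        sizes = sorted({min(s, d) for s in sizes if s >= 1})
        if not sizes:
            raise ValueError("sizes list is empty after clipping")

    y = table.binary_labels()
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    curve: list[tuple[int, float]] = []
    for s in sizes:
        Xs = table.X[:, ranking[:s]]
        accs = cross_val_score(_default_classifier(C, gamma), Xs, y, cv=cv)
        curve.append((s, float(accs.mean())))

    best_acc = max(a for _, a in curve)
    best_size = min(s for s, a in curve if a >= best_acc)
    return SelectionResult(
        f_scores=f,
        ranking=ranking,
        chosen=ranking[:best_size],
        curve=curve,
        step=step,
    )
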