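"""Synthetic minority oversampling (SMOTE) to a 1:1 class balance.

New minority samples are synthesized by interpolation: take a minority
sample X, find its k nearest minority neighbours in feature space, pick one
neighbour N uniformly, and emit

    X' = X + u * (N - X),   u ~ Uniform(0, 1)

— a point on the segment between X and N.  Sampling repeats until the two
classes are balanced.  Minority samples are visited in seeded round-robin
order so each contributes before any repeats, and original rows pass through
untouched; synthetic rows are flagged by id.

Oversampling must only ever see training data: applying it before a
cross-validation split leaks interpolated copies of test points into
training folds and inflates every metric.  The evaluation protocols in this
package therefore apply SMOTE inside each fold; a compatibility switch for
whole-dataset oversampling exists but warns loudly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureTable

__all__ = ["ResampleReport", "smote", "SMOTE_DEFAULT_K"]

SMOTE_DEFAULT_K = 5


@dataclass
class ResampleReport:
    """Before/after class counts and provenance of the synthetic rows."""

    before: dict[str, int]
    after: dict[str, int]
    k: int
    seed: int
    synthetic_ids: list[str]

    def to_dict(self) -> dict:
        return {
            "before": self.before,
            "after": self.after,
            "k": self.k,
            "seed": self.seed,
            "n_synthetic": len(self.synthetic_ids),
            "synthetic_ids": self.synthetic_ids,
        }


def smote(
    table: FeatureTable, k: int = SMOTE_DEFAULT_K, seed: int = 0
) -> tuple[FeatureTable, ResampleReport]:
    """Oversample the minority class to a 1:1 balance.

    Parameters
    ----------
    table:
        Two-class feature table.  Already-balanced input is returned
        unchanged with a no-op report.
    k:
        Number of nearest minority neighbours to interpolate towards
        (Euclidean distance in the feature space as given).  Clamped with a
        warning if the minority class has fewer than k+1 members.
    seed:
        Seed for the round-robin shuffle, neighbour choice and interpolation
        coefficients; fixed seed gives bitwise-identical output.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts = table.class_counts()
    if len(counts) != 2:
        raise ValueError(f"SMOTE needs exactly two classes, found {len(counts)}")
    (lab_a, n_a), (lab_b, n_b) = sorted(counts.items(), key=lambda kv: kv[1])
    minority_label, n_min = lab_a, n_a
    n_maj = n_b
    before = dict(counts)

    if n_min == n_maj:
        report = ResampleReport(before=before, after=dict(counts), k=k,
                                seed=seed, synthetic_ids=[])
        return table, report
    if n_min < 2:
        raise ValueError(
            f"minority class {minority_label!r} has {n_min} sample(s); "
            "need at least 2 to interpolate"
        )
    if k > n_min - 1:
        warnings.warn(
            f"SMOTE k={k} exceeds minority size - 1 ({n_min - 1}); clamping",
            stacklevel=2,
        )
        k = n_min - 1

    rng = np.random.default_rng(seed)
    min_idx = np.flatnonzero(table.labels == minority_label)
    M = table.X[min_idx]  # minority block, n_min x d

    # k nearest minority neighbours of each minority sample (self excluded).
    d2 = ((M[:, None, :] - M[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    neighbours = np.argsort(d2, axis=1, kind="stable")[:, :k]  # n_min x k

    n_needed = n_maj - n_min
    order = rng.permutation(n_min)
    synth_rows = np.empty((n_needed, table.n_features))
    synth_ids: list[str] = []
    for t in range(n_needed):
        i = order[t % n_min]
        if t % n_min == n_min - 1:
            order = rng.permutation(n_min)  # reshuffle each round-robin pass
        j = neighbours[i, rng.integers(k)]
        u = rng.uniform()
        synth_rows[t] = M[i] + u * (M[j] - M[i])
        synth_ids.append(f"synthetic:{minority_label}:{t}")

    out = FeatureTable(
        X=np.vstack([table.X, synth_rows]),
        names=list(table.names),
        ids=list(table.ids) + synth_ids,
        labels=np.concatenate(
            [table.labels, np.full(n_needed, minority_label, dtype=table.labels.dtype)]
        ),
    )
    after = out.class_counts()
    report = ResampleReport(before=before, after=after, k=k, seed=seed,
                            synthetic_ids=synth_ids)
    return out, report
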