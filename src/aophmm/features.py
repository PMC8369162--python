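"""Fixed-length descriptors of profile matrices.

Three encoders turn an L x 20 position matrix (either the one-hot matrix B of
the sequence itself or the normalized profile-HMM matrix H) into a
fixed-length vector:

* **AAC** (amino-acid composition): per-column means, 20 components.
  For a one-hot matrix this is exactly the residue frequency of the sequence.
* **DPC** (dipeptide composition): averaged products of adjacent-row entries,
  ``y[i,j] = 1/(L-1) * sum_k m[k,i] * m[k+1,j]``, 400 components.  For a
  one-hot matrix this counts adjacent residue pairs.
* **ACC** (auto-cross-covariance): each profile column is treated as a series
  along the sequence and the lagged covariance between columns j and k is

      z[j,k,g] = 1/(L-g) * sum_{i=1..L-g} (m[i,j] - mean_j)(m[i+g,k] - mean_k)

  for lags g = 1..G, where mean_j is the mean over the *full* column.  Auto
  terms (j = k) capture periodicity within one residue preference; cross
  terms (j != k) capture lagged coupling between two preferences.  The full
  20 x 20 x G tensor is kept, giving 400*G components, flattened with the lag
  slowest, then j, then k.

ACC is mean-centered, so it is invariant to adding a constant to a column;
this is what makes it complementary to the composition encoders, which see
only the column means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AMINO_ACIDS
from .errors import EncodingError
from .profile_io import HMMProfile, ProteinSequence

__all__ = [
    "PositionMatrix",
    "FeatureVector",
    "FeatureTable",
    "one_hot_matrix",
    "aac",
    "dpc",
    "acc",
    "encode_dataset",
    "AAC_NAMES",
    "DPC_NAMES",
    "acc_names",
    "ENCODING_SCHEMES",
]

AAC_NAMES: list[str] = [f"AAC:{a}" for a in AMINO_ACIDS]
DPC_NAMES: list[str] = [
    f"DPC:{a}-{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS
]


def acc_names(G: int) -> list[str]:
    """Component labels of the ACC tensor, lag slowest, then j, then k."""
    return [
        f"ACC:j={a},k={b},g={g}"
        for g in range(1, G + 1)
        for a in AMINO_ACIDS
        for b in AMINO_ACIDS
    ]


@dataclass
class PositionMatrix:
    """An L x 20 matrix over the canonical residue columns.

    ``source`` records whether it is a one-hot encoding of the raw sequence
    or a normalized profile-HMM matrix; the invariants differ.
    """

    values: np.ndarray
    source: str  # "one-hot" or "hmm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_AMINO_ACIDS:
            raise ValueError(
                f"position matrix must be L x {N_AMINO_ACIDS}, got "
                f"{self.values.shape}"
            )
        if self.source not in ("one-hot", "hmm"):
            raise ValueError(f"unknown source tag {self.source!r}")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureVector:
    """A fixed-length descriptor with a named-component registry."""

    values: np.ndarray
    names: list[str]
    encoder: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")


@dataclass
class FeatureTable:
    """n samples x d named features, with class labels and identifiers."""

    X: np.ndarray
    names: list[str]
    ids: list[str]
    labels: np.ndarray  # class tags, e.g. "AOP" / "non-AOP"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        n, d = self.X.shape
        if len(self.names) != d:
            raise ValueError("names length must equal feature count")
        if len(self.ids) != n or len(self.labels) != n:
            raise ValueError("ids/labels length must equal row count")
        if len(set(self.names)) != d:
            raise ValueError("component names must be unique")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def binary_labels(self, pos_label: str = "AOP") -> np.ndarray:
        """0/1 vector with 1 for the positive class."""
        return (self.labels == pos_label).astype(int)

    def subset_rows(self, idx: Sequence[int] | np.ndarray) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            X=self.X[idx],
            names=list(self.names),
            ids=[self.ids[i] for i in idx],
            labels=self.labels[idx],
        )

    def subset_features(self, idx: Sequence[int] | np.ndarray) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            X=self.X[:, idx],
            names=[self.names[i] for i in idx],
            ids=list(self.ids),
            labels=self.labels.copy(),
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.names)
        df.insert(0, "id", self.ids)
        df.insert(1, "label", self.labels)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        if "id" not in df.columns or "label" not in df.columns:
            raise ValueError(f"{path}: missing 'id' or 'label' column")
        names = [c for c in df.columns if c not in ("id", "label")]
        return cls(
            X=df[names].to_numpy(dtype=float),
            names=names,
            ids=df["id"].astype(str).tolist(),
            labels=df["label"].to_numpy(),
        )


def one_hot_matrix(seq: ProteinSequence) -> PositionMatrix:
    """Binary L x 20 matrix with a single 1 per row at the residue's column."""
    idx = np.array([AA_INDEX[a] for a in seq.residues])
    m = np.zeros((len(seq), N_AMINO_ACIDS))
    m[np.arange(len(seq)), idx] = 1.0
    return PositionMatrix(values=m, source="one-hot")


def aac(m: PositionMatrix) -> FeatureVector:
    """Amino-acid composition: per-column mean over the L positions."""
    if m.length < 1:
        raise EncodingError("empty position matrix")
    return FeatureVector(
        values=m.values.mean(axis=0),
        names=list(AAC_NAMES),
        encoder="aac",
    )


def dpc(m: PositionMatrix) -> FeatureVector:
    """Dipeptide composition from adjacent-row products.

    Component (i, j) averages ``m[k,i] * m[k+1,j]`` over the L-1 adjacent
    position pairs, row-major over the canonical residue order.
    """
    L = m.length
    if L < 2:
        raise EncodingError(
            f"sequence too short for dipeptides (L={L}, need L >= 2)"
        )
    v = m.values
    pair = v[:-1].T @ v[1:] / (L - 1)  # 20 x 20, [i, j]
    return FeatureVector(
        values=pair.ravel(),
        names=list(DPC_NAMES),
        encoder="dpc",
    )


def acc(m: PositionMatrix, G: int) -> FeatureVector:
    """Auto-cross-covariance descriptor up to maximum lag G.

    Returns 400*G components ordered lag-slowest, then leading column j,
    then lagged column k.  The column mean is taken over the full column
    for both factors, so the output is invariant under per-column shifts.
    """
    L = m.length
    if G < 1 or G > L - 1:
        raise EncodingError(
            f"lag bound G={G} invalid for length L={L}: need 1 <= G <= L-1"
        )
    centered = m.values - m.values.mean(axis=0)
    blocks = []
    for g in range(1, G + 1):
        z = centered[: L - g].T @ centered[g:] / (L - g)  # 20 x 20, [j, k]
        blocks.append(z.ravel())
    return FeatureVector(
        values=np.concatenate(blocks),
        names=acc_names(G),
        encoder="acc",
        params={"G": G},
    )


ENCODING_SCHEMES = ("seq-aac", "seq-dpc", "hmm-aac", "hmm-dpc", "acc")


def _position_matrix(item: ProteinSequence | HMMProfile, scheme: str) -> PositionMatrix:
    if scheme.startswith("seq-"):
        if not isinstance(item, ProteinSequence):
            raise EncodingError(
                f"scheme {scheme!r} needs sequences, got {type(item).__name__}"
            )
        return one_hot_matrix(item)
    if not isinstance(item, HMMProfile):
        raise EncodingError(
            f"scheme {scheme!r} needs profiles, got {type(item).__name__}"
        )
    return PositionMatrix(values=item.matrix, source="hmm")


def encode_dataset(
    items: Iterable[ProteinSequence | HMMProfile],
    labels: Sequence[str],
    scheme: str,
    G: int | None = None,
) -> FeatureTable:
    """Encode a dataset of sequences or profiles with one shared registry.

    ``scheme`` is one of ``seq-aac``, ``seq-dpc``, ``hmm-aac``, ``hmm-dpc``
    (composition encoders on the one-hot or HMM matrix) or ``acc`` (the
    auto-cross-covariance transform of the HMM matrix; requires ``G``).
    Items failing an encoder precondition are reported together by id.
    """
    items = list(items)
    if scheme not in ENCODING_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {ENCODING_SCHEMES}")
    if scheme == "acc" and (G is None or G < 1):
        raise ValueError("scheme 'acc' requires a positive maximum lag G")
    if len(labels) != len(items):
        raise ValueError("labels length must equal item count")

    rows: list[np.ndarray] = []
    names: list[str] | None = None
    failures: list[str] = []
    for item in items:
        try:
            pm = _position_matrix(item, scheme)
            if scheme.endswith("aac"):
                fv = aac(pm)
            elif scheme.endswith("dpc"):
                fv = dpc(pm)
            else:
                fv = acc(pm, G)  # type: ignore[arg-type]
            rows.append(fv.values)
            names = fv.names
        except EncodingError as exc:
            failures.append(f"{item.id}: {exc}")
    if failures:
        raise EncodingError(
            f"{len(failures)} item(s) failed {scheme!r} encoding:\n  "
            + "\n  ".join(failures)
        )
    return FeatureTable(
        X=np.vstack(rows),
        names=list(names or []),
        ids=[item.id for item in items],
        labels=np.asarray(list(labels)),
    )
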