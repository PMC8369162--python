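"""Synthetic profiles with planted class structure.

Real benchmark data for this problem requires building profile HMMs with an
external homology search against a multi-gigabyte database.  This module
instead generates profile matrices whose class signal is planted by
construction, so every downstream stage — encoding, ranking, oversampling,
classification, cross-validation — can be exercised and verified without
any download.

Two kinds of signal can be planted in the positive class:

* **column-mean shifts**: chosen residue columns get a higher baseline
  frequency, a composition-level difference visible to the AAC/DPC encoders
  (and to nothing in the mean-centered ACC transform);
* **lagged coupling**: the value at position ``i + g*`` in column ``k*`` is
  nudged toward the value at position ``i`` in column ``j*``, creating a
  positive covariance at exactly the planted lag — an order-level difference
  visible only to the ACC component (j*, k*, g*).

Rows are independent per-column Gaussian draws around the class baseline,
clipped to [0, 1]; they are not constrained to sum to 1, mirroring the fact
that normalized profile emission rows need not either.  Generation is pure
given the seed.

:func:`write_hhm` is the inverse of the profile reader's normalization
(scores ``x = round(-1000 * log2(f))``, ``*`` for f = 0) and exists so that
parser round-trips can be tested against files this package wrote itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS, N_AMINO_ACIDS
from .features import FeatureTable
from .profile_io import HMMProfile

__all__ = [
    "PlantedSignal",
    "FixtureSpec",
    "default_planted_spec",
    "default_weak_spec",
    "default_null_spec",
    "make_profiles",
    "make_sequences",
    "write_hhm",
    "write_fixture_dir",
    "make_separable_table",
    "POS_LABEL",
    "NEG_LABEL",
]

POS_LABEL = "AOP"
NEG_LABEL = "non-AOP"


@dataclass(frozen=True)
class PlantedSignal:
    """Class difference planted into positive-class profiles.

    shift_columns / shift:
        Residue columns whose baseline frequency is raised by ``shift`` in
        the positive class (composition signal).
    coupling_pairs / coupling_lag / coupling_strength:
        Lagged coupling: for each column pair (j, k), positive-class
        profiles get ``m[i+lag, k] <- (1-rho) * m[i+lag, k] + rho * m[i, j]``
        for every admissible i, with rho = coupling_strength.  This creates
        a positive covariance at exactly that lag in each planted (j, k)
        component — order signal spread over several residue pairs, the way
        a real class difference touches many profile columns rather than
        one.  Strength 0 disables it.
    """

    shift_columns: tuple[int, ...] = ()
    shift: float = 0.0
    coupling_pairs: tuple[tuple[int, int], ...] = ((0, 2),)
    coupling_lag: int = 3
    coupling_strength: float = 0.0

    @property
    def is_null(self) -> bool:
        return self.shift == 0.0 and self.coupling_strength == 0.0

    def acc_component_names(self) -> list[str]:
        """Registry names of the ACC components the coupling plants."""
        return [
            f"ACC:j={AMINO_ACIDS[j]},k={AMINO_ACIDS[k]},g={self.coupling_lag}"
            for j, k in self.coupling_pairs
        ]


@dataclass(frozen=True)
class FixtureSpec:
    """Sizes, noise level and planted signal of a synthetic dataset."""

    n_pos: int = 29
    n_neg: int = 171
    length_range: tuple[int, int] = (50, 70)
    signal: PlantedSignal = field(default_factory=PlantedSignal)
    noise_scale: float = 0.08
    baseline: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class counts must be >= 1")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.signal.coupling_strength and self.signal.coupling_lag >= lo:
            raise ValueError(
                "coupling lag must be smaller than the minimum length"
            )
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")


def default_planted_spec(seed: int = 0, n_pos: int = 29, n_neg: int = 171) -> FixtureSpec:
    """The standard strong-signal fixture: lag-3 coupling plus a small
    composition shift, at a 1:6 class imbalance."""
    return FixtureSpec(
        n_pos=n_pos,
        n_neg=n_neg,
        signal=PlantedSignal(
            shift_columns=(4, 11),
            shift=0.03,
            coupling_pairs=((0, 2), (5, 7), (10, 12), (15, 17), (3, 8), (6, 14)),
            coupling_lag=3,
            coupling_strength=0.5,
        ),
        seed=seed,
    )


def default_weak_spec(seed: int = 0, n_pos: int = 29, n_neg: int = 171) -> FixtureSpec:
    """A class-overlap fixture: the same lag-3 coupling as the standard
    planted spec but at low strength and with no composition shift, so the
    classes overlap and the 1:6 imbalance actually biases the classifier.
    This is the regime where minority oversampling has something to fix;
    with a cleanly separable signal both balanced and unbalanced training
    saturate sensitivity."""
    return FixtureSpec(
        n_pos=n_pos,
        n_neg=n_neg,
        signal=PlantedSignal(
            shift_columns=(),
            shift=0.0,
            coupling_pairs=((0, 2), (5, 7), (10, 12), (15, 17), (3, 8), (6, 14)),
            coupling_lag=3,
            coupling_strength=0.15,
        ),
        seed=seed,
    )


def default_null_spec(seed: int = 0, n_per_class: int = 100) -> FixtureSpec:
    """Exchangeable classes (no planted signal), balanced so that chance
    accuracy is 0.5."""
    return FixtureSpec(n_pos=n_per_class, n_neg=n_per_class,
                       signal=PlantedSignal(), seed=seed)


def make_profiles(spec: FixtureSpec) -> tuple[list[HMMProfile], list[str]]:
    """Generate profiles and class labels according to ``spec``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    sig = spec.signal
    profiles: list[HMMProfile] = []
    labels: list[str] = []
    n_total = spec.n_pos + spec.n_neg
    for idx in range(n_total):
        positive = idx < spec.n_pos
        L = int(rng.integers(lo, hi + 1))
        m = spec.baseline + spec.noise_scale * rng.standard_normal((L, N_AMINO_ACIDS))
        if positive and sig.shift != 0.0:
            m[:, list(sig.shift_columns)] += sig.shift
        if positive and sig.coupling_strength > 0.0:
            rho, g = sig.coupling_strength, sig.coupling_lag
            for j, k in sig.coupling_pairs:
                m[g:, k] = (1 - rho) * m[g:, k] + rho * m[:-g, j]
        m = np.clip(m, 0.0, 1.0)
        label = POS_LABEL if positive else NEG_LABEL
        profiles.append(HMMProfile(id=f"{'pos' if positive else 'neg'}{idx:04d}", matrix=m))
        labels.append(label)
    return profiles, labels


def make_sequences(profiles: list[HMMProfile], seed: int = 0) -> list[str]:
    """Random residue strings matching each profile's length (for FASTA
    output; the letters carry no class signal)."""
    rng = np.random.default_rng(seed)
    seqs = []
    for p in profiles:
        idx = rng.integers(0, N_AMINO_ACIDS, size=p.length)
        seqs.append("".join(AMINO_ACIDS[i] for i in idx))
    return seqs


def write_hhm(
    profile: HMMProfile,
    path: str | Path,
    residue_order: str | list[str] = AMINO_ACIDS,
) -> None:
    """Write a profile as a minimal ``.hhm``-dialect file.

    Frequencies become integer scores ``round(-1000 * log2(f))`` and zero
    frequencies the ``*`` token, so reading the file back and normalizing
    recovers the matrix within integer-rounding error.  ``residue_order``
    controls the emission-column ordering (useful for testing that parsing
    is order-independent).
    """
    residue_order = list(residue_order)
    if sorted(residue_order) != sorted(AMINO_ACIDS):
        raise ValueError("residue_order must be a permutation of the 20 amino acids")
    path = Path(path)
    col_of = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    perm = [col_of[aa] for aa in residue_order]
    mat = profile.matrix[:, perm]
    lines = [
        "HHsearch 1.5",
        f"NAME  {profile.id}",
        f"LENG  {profile.length} match states, {profile.length} columns in multiple alignment",
        "#",
        "NULL   " + "\t".join(["3706"] * 20),
        "HMM    " + "\t".join(residue_order),
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D",
        "       0\t*\t*\t*\t*\t*\t*\t0\t0\t0",
    ]
    for i, row in enumerate(mat, start=1):
        cells = []
        for f in row:
            if f <= 0.0:
                cells.append("*")
            else:
                cells.append(str(int(round(-1000.0 * np.log2(min(f, 1.0))))))
        res = residue_order[int(np.argmax(row))]
        lines.append(f"{res} {i}    " + "\t".join(cells))
        lines.append("       0\t*\t*\t*\t*\t*\t*\t0\t0\t0")
    lines.append("//")
    path.write_text("\n".join(lines) + "\n")


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Emit a complete on-disk fixture: FASTA, per-profile ``.hhm`` files,
    and a labels TSV.  Returns a manifest of what was written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles, labels = make_profiles(spec)
    seqs = make_sequences(profiles, seed=spec.seed)
    fasta = out_dir / "sequences.fasta"
    with open(fasta, "w") as fh:
        for p, s in zip(profiles, seqs):
            fh.write(f">{p.id}\n{s}\n")
    hhm_dir = out_dir / "hhm"
    hhm_dir.mkdir(exist_ok=True)
    for p in profiles:
        write_hhm(p, hhm_dir / f"{p.id}.hhm")
    labels_path = out_dir / "labels.tsv"
    with open(labels_path, "w") as fh:
        fh.write("id\tlabel\n")
        for p, lab in zip(profiles, labels):
            fh.write(f"{p.id}\t{lab}\n")
    return {
        "fasta": str(fasta),
        "hhm_dir": str(hhm_dir),
        "labels": str(labels_path),
        "n_pos": spec.n_pos,
        "n_neg": spec.n_neg,
    }


def make_separable_table(
    n: int, d: int, margin: float, seed: int = 0
) -> FeatureTable:
    """Two unit-variance Gaussian blobs whose means are ``margin`` pooled
    standard deviations apart (Euclidean), for classifier tests."""
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    n_neg = n - n_pos
    offset = margin / np.sqrt(d)
    X_pos = rng.standard_normal((n_pos, d)) + offset
    X_neg = rng.standard_normal((n_neg, d))
    X = np.vstack([X_pos, X_neg])
    labels = np.array([POS_LABEL] * n_pos + [NEG_LABEL] * n_neg)
    ids = [f"s{i:04d}" for i in range(n)]
    return FeatureTable(X=X, names=[f"f{i}" for i in range(d)], ids=ids,
                        labels=labels)
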