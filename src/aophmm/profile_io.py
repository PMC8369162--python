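"""Protein sequences and profile-HMM input.

A profile HMM built by iterative homology search (e.g. HHblits against a
clustered sequence database) summarizes, for every match state of a query
protein of length L, the residue preferences of its homologs.  HHsuite's
``.hhm`` text format stores these as 30 columns per match state; only the
first 20 — the amino-acid emission scores — carry the evolutionary signal the
downstream encoders consume, so the 7 transition and 3 diversity columns are
ignored.

Emission scores are scaled negative log-frequencies, ``x = -1000 * log2(f)``,
with the ``*`` token standing for a zero frequency.  :func:`normalize_profile`
inverts this scaling,

    f(x) = 0        if x = '*'
    f(x) = 2^(-x/1000)   otherwise,

mapping every cell into [0, 1] and reordering columns into the canonical
alphabetical residue order, yielding the L x 20 frequency matrix ``H`` that
all feature encoders operate on.
"""

from __future__ import annotations

import gzip
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabet import AMINO_ACIDS, N_AMINO_ACIDS
from .errors import (
    ExternalToolError,
    FastaParseError,
    HHMParseError,
    SequenceValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinSequence",
    "RawHMMProfile",
    "HMMProfile",
    "read_fasta",
    "parse_hhm",
    "normalize_profile",
    "run_hhblits",
    "write_profile_tsv",
    "read_profile_tsv",
]


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence over the 20 standard amino acids."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(self.residues) - set(AMINO_ACIDS))
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: non-standard residue code(s) "
                f"{''.join(bad)!r}; only the 20 standard amino acids are "
                "accepted"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class RawHMMProfile:
    """Emission scores of a ``.hhm`` file, before normalization.

    ``scores`` is an L x 20 float array in the column order of the source
    file; missing emissions (the ``*`` token) are stored as NaN.
    """

    id: str
    length: int
    scores: np.ndarray
    residue_order: list[str] = field(default_factory=lambda: list(AMINO_ACIDS))

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (self.length, N_AMINO_ACIDS):
            raise HHMParseError(
                f"profile {self.id!r}: score grid shape {self.scores.shape} "
                f"does not match declared length {self.length}"
            )
        finite = self.scores[~np.isnan(self.scores)]
        if finite.size and finite.min() < 0:
            raise HHMParseError(
                f"profile {self.id!r}: negative emission score encountered"
            )


@dataclass
class HMMProfile:
    """Normalized L x 20 emission-frequency matrix, columns in A..Y order."""

    id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_AMINO_ACIDS:
            raise ValueError(
                f"profile {self.id!r}: matrix must be L x {N_AMINO_ACIDS}, "
                f"got shape {self.matrix.shape}"
            )
        if self.matrix.shape[0] == 0:
            raise ValueError(f"profile {self.id!r}: zero-length profile")
        if self.matrix.min() < 0.0 or self.matrix.max() > 1.0:
            raise ValueError(
                f"profile {self.id!r}: frequencies must lie in [0, 1]"
            )

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(
    path: str | Path, on_invalid: str = "error"
) -> list[ProteinSequence]:
    """Read a FASTA file (plain or gzipped) into validated sequences.

    Parameters
    ----------
    path:
        FASTA file path.
    on_invalid:
        ``"error"`` (default) raises on records containing non-standard
        residues such as X, Z or B; ``"skip"`` drops them with a logged
        warning instead.
    """
    if on_invalid not in ("error", "skip"):
        raise ValueError(f"on_invalid must be 'error' or 'skip', got {on_invalid!r}")
    path = Path(path)
    with _open_maybe_gzip(path) as handle:
        # Bio.SeqIO silently yields nothing for a non-FASTA text file, so
        # sanity-check the first non-blank line ourselves.
        pos = handle.tell()
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno} does not start a FASTA "
                        f"record: {line.strip()[:40]!r}"
                    )
                break
        handle.seek(pos)
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            try:
                records.append(ProteinSequence(rec.id, str(rec.seq).upper()))
            except SequenceValidationError:
                if on_invalid == "skip":
                    logger.warning("skipping invalid record %r", rec.id)
                else:
                    raise
    return records


def parse_hhm(path: str | Path) -> RawHMMProfile:
    """Parse the emission block of an HHsuite ``.hhm`` file.

    Captures the 20 amino-acid emission scores of every match-state line;
    ``*`` tokens become NaN ("missing").  The declared ``LENG`` must equal
    the number of match-state lines found.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    name: str | None = None
    leng: int | None = None
    residue_order: list[str] | None = None
    start = None
    for i, line in enumerate(lines):
        if line.startswith("NAME"):
            parts = line.split(maxsplit=1)
            name = parts[1].split()[0] if len(parts) > 1 else None
        elif line.startswith("LENG"):
            try:
                leng = int(line.split()[1])
            except (IndexError, ValueError) as exc:
                raise HHMParseError(f"{path}: unreadable LENG line: {line!r}") from exc
        elif line.startswith("HMM"):
            residue_order = line.split()[1:]
            start = i
            break
    if leng is None:
        raise HHMParseError(f"{path}: missing LENG header")
    if start is None or residue_order is None:
        raise HHMParseError(f"{path}: missing HMM emission-block header")
    if len(residue_order) != N_AMINO_ACIDS or set(residue_order) != set(AMINO_ACIDS):
        raise HHMParseError(
            f"{path}: HMM header must list the 20 amino acids, got "
            f"{residue_order}"
        )
    residue_set = set(residue_order)

    rows: list[list[float]] = []
    for line in lines[start + 1 :]:
        stripped = line.strip()
        if stripped == "//":
            break
        toks = stripped.split()
        if len(toks) >= 2 and toks[0] in residue_set and toks[1].isdigit():
            if len(toks) < 2 + N_AMINO_ACIDS:
                raise HHMParseError(
                    f"{path}: truncated emission line at match state "
                    f"{len(rows) + 1}: expected {N_AMINO_ACIDS} scores, "
                    f"found {len(toks) - 2}"
                )
            row = []
            for tok in toks[2 : 2 + N_AMINO_ACIDS]:
                if tok == "*":
                    row.append(np.nan)
                else:
                    row.append(float(int(tok)))
            rows.append(row)
    if len(rows) != leng:
        raise HHMParseError(
            f"{path}: LENG declares {leng} match states but "
            f"{len(rows)} emission lines were parsed"
        )
    return RawHMMProfile(
        id=name or path.stem,
        length=leng,
        scores=np.array(rows, dtype=float),
        residue_order=list(residue_order),
    )


def normalize_profile(raw: RawHMMProfile) -> HMMProfile:
    """Map emission scores to frequencies in [0, 1] and canonicalize columns.

    Each score ``x`` becomes ``2**(-x/1000)``; missing cells become 0.
    Columns are permuted from the source file's residue order into the fixed
    alphabetical order so that downstream feature names are stable.
    """
    with np.errstate(over="ignore"):
        freq = np.where(np.isnan(raw.scores), 0.0, 2.0 ** (-raw.scores / 1000.0))
    perm = [raw.residue_order.index(aa) for aa in AMINO_ACIDS]
    return HMMProfile(id=raw.id, matrix=freq[:, perm])


def write_profile_tsv(profile: HMMProfile, path: str | Path) -> None:
    """Cache a normalized profile as a tab-separated matrix with header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#id={profile.id}\tL={profile.length}\n")
        fh.write("\t".join(AMINO_ACIDS) + "\n")
        np.savetxt(fh, profile.matrix, fmt="%.9g", delimiter="\t")


def read_profile_tsv(path: str | Path) -> HMMProfile:
    """Read a profile cached by :func:`write_profile_tsv`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#id="):
            raise HHMParseError(f"{path}: not a cached profile (bad header)")
        pid = header.split("\t")[0][len("#id=") :]
        fh.readline()  # residue-order line
        matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return HMMProfile(id=pid, matrix=matrix)


def run_hhblits(
    seq: ProteinSequence,
    database: str | Path,
    iterations: int = 2,
    executable: str = "hhblits",
) -> RawHMMProfile:
    """Build a profile for one sequence by calling an external HHblits.

    This is a thin invocation hook: it requires the HHblits executable and a
    sequence database (e.g. Uniclust30) on the host, neither of which is
    bundled.  ``iterations`` is the number of search iterations (HHblits
    ``-n``).
    """
    if iterations <= 0:
        raise ValueError(f"iterations must be positive, got {iterations}")
    exe = shutil.which(executable)
    if exe is None:
        raise ExternalToolError(
            f"external dependency missing: executable {executable!r} not "
            "found on PATH"
        )
    database = Path(database)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        fasta = tmp / "query.fasta"
        fasta.write_text(f">{seq.id}\n{seq.residues}\n")
        out_hhm = tmp / "query.hhm"
        cmd = [
            exe,
            "-i", str(fasta),
            "-d", str(database),
            "-n", str(iterations),
            "-ohhm", str(out_hhm),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalToolError(
                f"hhblits exited with status {proc.returncode}: "
                f"{proc.stderr.strip()[-500:]}"
            )
        if not out_hhm.exists():
            raise ExternalToolError("hhblits produced no .hhm output")
        return parse_hhm(out_hhm)
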