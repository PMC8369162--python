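"""Canonical amino-acid alphabet shared by all encoders.

Columns of every profile matrix and every composition descriptor follow the
alphabetical one-letter ordering A C D E F G H I K L M N P Q R S T V W Y,
which is also the column order HHsuite writes in ``.hhm`` emission blocks.
Keeping one fixed ordering makes feature names stable, so a feature-index
subset chosen on one dataset is portable to another.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_AMINO_ACIDS: int = 20

#: Residue codes that appear in real sequence databases but carry ambiguous
#: meaning; records containing them are rejected (or skipped on request).
AMBIGUOUS_CODES: frozenset[str] = frozenset("XZBJUO")
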