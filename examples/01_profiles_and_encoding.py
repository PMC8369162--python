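"""Read a profile HMM, normalize it, and encode it three ways.

Builds a small synthetic fixture on disk, parses one ``.hhm`` file back,
applies the score -> frequency normalization, and prints the dimensionality
and a few components of the AAC, DPC and ACC descriptors.
"""

import tempfile
from pathlib import Path

from aophmm import normalize_profile, parse_hhm
from aophmm import synthetic as syn
from aophmm.features import PositionMatrix, aac, acc, dpc
from aophmm.synthetic import FixtureSpec, PlantedSignal

with tempfile.TemporaryDirectory() as tmp:
    spec = FixtureSpec(n_pos=2, n_neg=2, length_range=(40, 50),
                       signal=PlantedSignal(), seed=0)
    manifest = syn.write_fixture_dir(spec, tmp)
    hhm_path = next(Path(manifest["hhm_dir"]).glob("*.hhm"))

    raw = parse_hhm(hhm_path)
    profile = normalize_profile(raw)
    print(f"profile {profile.id}: {profile.length} match states, "
          f"frequencies in [{profile.matrix.min():.3f}, {profile.matrix.max():.3f}]")

    pm = PositionMatrix(values=profile.matrix, source="hmm")
    for name, fv in [("AAC", aac(pm)), ("DPC", dpc(pm)), ("ACC(G=10)", acc(pm, G=10))]:
        print(f"{name:>9}: {len(fv.values):>5} components; "
              f"first three: {[f'{v:.4f}' for v in fv.values[:3]]} "
              f"({', '.join(fv.names[:3])})")

# The AAC components are mean residue frequencies; DPC components average
# adjacent-position frequency products; ACC components are lagged
# covariances between residue-preference columns (mean-centered, so they
# ignore composition differences and see only sequence-order structure).
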