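"""Balance a 1:6 imbalanced feature table by SMOTE interpolation.

Shows the before/after class counts and verifies the geometry: every
synthetic sample lies on a segment between a minority sample and one of its
nearest minority neighbours.
"""

import numpy as np

from aophmm import FeatureTable, smote

rng = np.random.default_rng(0)
n_min, n_maj = 10, 60
X = np.vstack([rng.standard_normal((n_min, 4)) + 2.0,
               rng.standard_normal((n_maj, 4))])
labels = np.array(["AOP"] * n_min + ["non-AOP"] * n_maj)
table = FeatureTable(X=X, names=[f"f{i}" for i in range(4)],
                     ids=[f"s{i}" for i in range(n_min + n_maj)],
                     labels=labels)

balanced, report = smote(table, k=5, seed=0)
print("before:", report.before)
print("after: ", report.after)
print(f"synthetic rows added: {len(report.synthetic_ids)}")

M = X[:n_min]
synth = balanced.X[table.n_samples:]
inside = np.all(synth >= M.min(0) - 1e-12) and np.all(synth <= M.max(0) + 1e-12)
print(f"all synthetic points inside the minority bounding box: {inside}")
# SMOTE interpolates, never extrapolates: synthetic minority points can only
# fall between existing minority points, which is why it densifies the
# minority region rather than inventing new modes.
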