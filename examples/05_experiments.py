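"""Lag sweep and ablation experiments.

The lag sweep shows the maximum-lag parameter G interacting with the
planted lag: accuracy jumps once G reaches the lag at which the coupling
was planted.  The ablation compares raw ACC features, ACC + ANOVA
selection, and ACC + ANOVA + SMOTE under identical folds.
"""

import aophmm
from aophmm import synthetic as syn

spec = syn.default_planted_spec(seed=2)
profiles, labels = syn.make_profiles(spec)
config = aophmm.PipelineConfig(select_k=30, smote=True)

print("lag sweep (planted coupling at lag 3):")
df = aophmm.g_sweep(profiles, labels, [1, 2, 3, 4, 5],
                    config=config, folds=5, seed=3)
print(df.round(3).to_string(index=False))

print("\nablation at G=3:")
df = aophmm.ablation(profiles, labels, G=3, select_k=30, folds=5, seed=3)
print(df.round(3).to_string(index=False))
# In the sweep, G=1 and G=2 see only noise (accuracy near the majority
# rate with zero-ish MCC); from G=3 on the planted covariance is in the
# feature set and accuracy jumps.  In the ablation, selection removes the
# thousands of noise components that drown the signal in the RBF distance.
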