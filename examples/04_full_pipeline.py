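"""The full pipeline under 10-fold cross-validation.

ACC encoding (G=10) -> fold-internal ANOVA selection -> fold-internal SMOTE
-> RBF-SVM grid search -> pooled metrics, on the 1:6 imbalanced fixture with
a planted lag-3 signal (n=200).  Takes ~20 s on one CPU.
"""

import aophmm
from aophmm import synthetic as syn

spec = syn.default_planted_spec(seed=1)
profiles, labels = syn.make_profiles(spec)
table = aophmm.encode_dataset(profiles, labels, scheme="acc", G=10)
print(f"{table.n_samples} samples x {table.n_features} ACC components "
      f"({labels.count('AOP')} AOP / {labels.count('non-AOP')} non-AOP)")

config = aophmm.PipelineConfig(select_k=40, smote=True,
                               grid_search=True, inner_folds=3)
report = aophmm.kfold_cv(config, table, k=10, seed=1)
print(f"10-fold CV (pooled): Acc={report.acc:.3f} Sen={report.sen:.3f} "
      f"Spe={report.spe:.3f} MCC={report.mcc:.3f} AUC={report.auc:.3f}")
print(f"confusion counts: TP={report.counts.tp} TN={report.counts.tn} "
      f"FP={report.counts.fp} FN={report.counts.fn}")
# Accuracy well above the 0.855 majority-vote baseline, together with high
# sensitivity, means the classifier found the planted minority-class signal
# rather than defaulting to the majority class; AUC near 1 confirms the
# decision scores rank nearly all positives above negatives.
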