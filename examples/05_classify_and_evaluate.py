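"""Cross-validated stress classification on a small synthetic cohort.

Uses a 4-subject cohort to keep the example fast; the full protocol runs
12 subjects (see scripts/acceptance.py).
"""

import pandas as pd

import eogstress as eog
from eogstress.evaluation import (
    kfold10_evaluate,
    loso_evaluate,
    majority_class_rate,
)

config = eog.SynthConfig(n_subjects=4, seed=3)
tables = []
for session, _ in eog.generate_cohort(config):
    prep = eog.preprocess_session(session)
    events = eog.detect_blinks(prep.eog_v, session.sampling_rate)
    tables.append(eog.build_feature_table(session, prep, events))
table = pd.concat(tables, ignore_index=True)

baseline = majority_class_rate(table["label2"])
print(f"{len(table)} windows from {config.n_subjects} subjects; "
      f"majority-class baseline = {baseline:.3f}")

spec = eog.default_model_spec("rf", "two")
kfold = kfold10_evaluate(table, spec, seed=0)
loso = loso_evaluate(table, spec, seed=0)

m = kfold.mean_metrics
print(f"\nrandom forest, 10-fold: accuracy {m['accuracy']:.3f}, "
      f"precision {m['precision']:.3f}, recall {m['recall']:.3f}, "
      f"F1 {m['f1']:.3f}, specificity {m['specificity']:.3f}")
print(f"random forest, LOSO:    accuracy {loso.mean_metrics['accuracy']:.3f} "
      f"({len(loso.fold_metrics)} folds, one per held-out subject)")
print("per-task accuracy (LOSO):",
      {t: round(a, 3) for t, a in sorted((loso.per_task or {}).items())})
print("\n10-fold mixes each subject's overlapping windows across train and "
      "test, so it is more optimistic than LOSO, which measures "
      "generalization to an unseen subject.")
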