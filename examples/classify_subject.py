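"""Within-subject single-trial classification of a high-SNR session.

Extracts the compressibility feature matrix (trials x channels) for a
signal-dominated synthetic subject, evaluates SVM-RBF (nested-tuned) and
5-NN with leave-one-out cross-validation, and prints the confusion-derived
metrics and AUC.
"""

import pandas as pd

from erpcode import HIGH_SNR_DEMO, validate_config
from erpcode.classify import evaluate_subject
from erpcode.pipeline import _synthetic_epochs, extract_features

cfg = validate_config(HIGH_SNR_DEMO).settings
epochs = _synthetic_epochs(cfg, subject_seed=cfg["seed"])
matrices, stats = extract_features(epochs, cfg)
frame = pd.concat([m.to_frame() for m in matrices.values()],
                  ignore_index=True)
x = frame[[c for c in frame.columns
           if c not in ("trial_id", "label")]].to_numpy()
y = frame["label"].to_numpy(dtype=object)

print(f"feature matrix: {x.shape[0]} trials x {x.shape[1]} channels "
      f"({stats['n_flagged']} flagged); min reconstruction energy "
      f"{stats['min_energy_pct']:.2f}%")
reports = evaluate_subject(x, y, seed=0)
for name, rep in reports.items():
    print(f"{name:>4}: ACC {rep.acc:6.2f}%  SEN {rep.sen:6.2f}%  "
          f"SPC {rep.spc:6.2f}%  PRC {rep.prc:6.2f}%  AUC {rep.auc:.3f}")
print("Each trial is predicted by a model that never saw it (135 folds); "
      "chance accuracy under the 40/95 imbalance is 70.4%.")
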