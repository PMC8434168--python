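"""Three-class diagnosis classification from in-game trend features.

CFS subset selection (best-first search) feeds a one-hidden-layer
feedforward network, evaluated by stratified tenfold cross-validation with
fold-internal selection and imputation (no test-fold leakage).
"""

import numpy as np

import exerscreen as ex

study = ex.run_study(ex.CohortConfig(seed=1))
feats = study.features
X = feats.drop(columns=["participant_id", "label"])
y = feats["label"].to_numpy()

report = ex.cross_validate(X, y, k=10, seed=1, selection="nested")

print(f"overall accuracy: {report.overall_accuracy:.2f}% "
      f"(majority-class baseline {100 * 64 / 116:.1f}%)")
print("confusion matrix (rows = clinical diagnosis, cols = predicted):")
print("       " + "  ".join(f"{c:>4}" for c in report.classes))
for i, c in enumerate(report.classes):
    print(f"{c:>5}  " + "  ".join(f"{v:>4d}" for v in report.confusion[i]))
print("\nper-class rates (sensitivity = TP rate, specificity = 1 - FP rate):")
for c in report.classes:
    print(f"  {c:>3}: sens {report.sensitivity[c]:.3f}  spec {report.specificity[c]:.3f}"
          f"  ROC area {report.roc_area[c]:.3f}")

sel = report.selected_features[0]
print(f"\nfeatures selected in fold 1 ({len(sel)}): {sel[:6]}{' ...' if len(sel) > 6 else ''}")
print("ROC areas are one-vs-rest AUCs of the pooled out-of-fold probabilities.")
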