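"""ROC screening of MCI against cognitively normal participants.

Compares the discriminative ability of the HRMG mean-total game score with
the MMSE and MoCA clinical screens (lower score = positive/impaired), and
reports confusion counts at the conventional clinical cut-offs.
"""

import exerscreen as ex

study = ex.run_study(ex.CohortConfig(seed=1))
f = study.features.merge(
    study.participants[["id", "mmse", "moca"]], left_on="participant_id", right_on="id"
)
sub = f[f.label.isin(["CN", "MCI"])]
y = (sub.label == "MCI").astype(int).to_numpy()
print(f"MCI (n={y.sum()}) vs CN (n={(1 - y).sum()})\n")

for name, col in [("HRMG", "HRMG MeanTotal"), ("MMSE", "mmse"), ("MoCA", "moca")]:
    roc = ex.roc_curve(sub[col].to_numpy(), y, "lower_is_positive", score_name=name)
    print(f"  {name:<5} AUC = {roc.auc:.3f}")
print("AUC is the probability a random MCI participant scores below a random CN one.\n")

clf_roc = ex.classifier_screen(study.features, positive="MCI", negative="CN", seed=1)
print(f"  classifier P(MCI) from in-game features: AUC = {clf_roc.auc:.3f}\n")

for name, col in [("MMSE < 27", "mmse"), ("MoCA < 26", "moca")]:
    res = ex.screen_at_cutoff(sub[col].to_numpy(), y, ex.DEFAULT_CUTOFFS[col])
    print(f"  {name}: sens {res.sensitivity:.3f}, spec {res.specificity:.3f}, "
          f"accuracy {100 * res.accuracy:.2f}%  (TP {res.tp}, TN {res.tn}, "
          f"FP {res.fp}, FN {res.fn})")
print("Sensitivity = flagged MCI fraction; specificity = CN correctly passed.")
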