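"""DeLong AUC machinery on a hand-checkable example.

The 4-score example has AUC 0.75 by exhaustive pair counting; the paired
test compares two score vectors on the same 8 cases and prints the AUC
difference with its nonparametric z and p.
"""

from lnradiomics import delong_paired_test, roc_auc

res = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
print(f"4-score example: AUC = {res.auc:.2f} "
      f"(3 of 4 positive-negative pairs ranked correctly)")
print(f"95% CI [{res.ci95[0]:.3f}, {res.ci95[1]:.3f}] from the DeLong variance\n")

labels = [0, 0, 0, 0, 1, 1, 1, 1]
model_a = [0.2, 0.3, 0.6, 0.4, 0.7, 0.8, 0.5, 0.9]
model_b = [0.6, 0.4, 0.7, 0.5, 0.3, 0.8, 0.2, 0.9]
cmp_ = delong_paired_test(model_a, model_b, labels)
auc_a = roc_auc(model_a, labels).auc
auc_b = roc_auc(model_b, labels).auc
print(f"model A AUC {auc_a:.3f}, model B AUC {auc_b:.3f}")
print(f"paired DeLong: dAUC = {cmp_.delta_auc:+.3f}, z = {cmp_.z:.3f}, "
      f"p = {cmp_.p_value:.3f}")
print("The covariance of the paired placement values keeps the test honest")
print("when both models are scored on the same cases.")
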