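"""Run the full study replica on a small cohort and print the metrics table.

Simulates 50+50 nodes, splits 80/20 with class stratification, fits the
clinical > 10 mm rule, the exhaustive-search demographic SVM and the
LASSO-selected radiomic SVM, and prints accuracy / sensitivity /
specificity / AUC per model and cohort plus the paired DeLong comparison
of the radiomic and clinical models.
"""

import warnings

warnings.filterwarnings("ignore")

from lnradiomics import CohortConfig, generate_cohort
from lnradiomics.pipeline import RunConfig, extract_features, run_study

cases = generate_cohort(CohortConfig(50, 50, seed=9))
data = extract_features(cases)
report = run_study(data, RunConfig(split_seed=9, cv_seed=9, n_folds=10))

print(f"radiomic signature: {report['lasso']['used_features']}")
print(f"demographic subset: {report['demographic_search']['selected']}\n")
print(f"{'model':<12s} {'cohort':<6s} {'acc%':>7s} {'sens%':>7s} {'spec%':>7s} {'AUC':>6s}")
for model in ("clinical", "demographic", "radiomic"):
    for cohort in ("train", "test"):
        m = report["metrics"][model][cohort]
        print(f"{model:<12s} {cohort:<6s} {m['accuracy']:>7.2f} "
              f"{m['sensitivity']:>7.2f} {m['specificity']:>7.2f} {m['auc']:>6.3f}")

cmp_ = report["comparisons"]["radiomic_vs_clinical"]["test"]
print(f"\nDeLong radiomic vs clinical (test): dAUC = {cmp_['delta_auc']:+.3f}, "
      f"p = {cmp_['p']:.4f}")
print("A small p says the texture signature genuinely out-ranks the size rule.")
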