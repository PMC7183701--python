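"""Generate a synthetic lymph-node cohort and inspect its size structure.

Builds a 60+60 cohort with the default class parameters (normal long-axis
12.12 +/- 5.74 mm, metastatic 17.37 +/- 8.48 mm, truncated at 4 mm) and
prints the recovered per-class size statistics, the rank-sum p-value and
the 0.25 mm histogram overlap — the quantities that make the clinical size
rule weak.
"""

import numpy as np

from lnradiomics import CohortConfig, diameter_histogram_overlap, generate_cohort
from lnradiomics.evaluation import cohort_stats
from lnradiomics.pipeline import demographics_of

cases = generate_cohort(CohortConfig(n_normal=60, n_metastatic=60, seed=7))
long_axes = np.array([c.long_axis for c in cases])
labels = np.array([c.label for c in cases])

stats = cohort_stats([demographics_of(c) for c in cases])
row = stats["long_axis"]
print(f"normal long axis      {row['class0']['mean']:.2f} +/- {row['class0']['sd']:.2f} mm")
print(f"metastatic long axis  {row['class1']['mean']:.2f} +/- {row['class1']['sd']:.2f} mm")
print(f"rank-sum p            {row['p']:.2e}")

overlap = diameter_histogram_overlap(long_axes, labels, bin_width=0.25)
print(f"0.25 mm histogram overlap: {overlap:.2f}% of nodes share bins")
print("-> the size distributions separate in the mean but overlap heavily,")
print("   which is why a pure >10 mm threshold misclassifies many nodes.")
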