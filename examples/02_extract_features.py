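"""Extract the 146-feature texture panel for a single lymph node.

Generates one metastatic-class lesion, assembles the full ordered feature
vector and prints the five landmark features by their published aliases
together with their 1-based panel indices.
"""

from lnradiomics import assemble_feature_vector, generate_lesion
from lnradiomics.features import FEATURE_ALIASES, feature_index
from lnradiomics.synthetic import METASTATIC_PARAMS

case = generate_lesion(METASTATIC_PARAMS, seed=11)
print(f"case {case.case_id}: long axis {case.long_axis:.1f} mm, "
      f"{int(case.mask.sum())} ROI pixels")

features = assemble_feature_vector(case)
print(f"panel size: {len(features)} features\n")
for alias, name in FEATURE_ALIASES.items():
    print(f"F^{feature_index(alias):<3d} {alias:<55s} = {features[name]:.4f}")
print("\nEach value is a texture descriptor of the quantized (8-level) ROI")
print("in the intensity, wavelet or gradient domain.")
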