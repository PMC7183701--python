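# lnradiomics

Preoperative CT assessment of lymph-node (LN) metastasis in colon cancer is
usually a size call: a node with long-axis diameter > 10 mm is read as
metastatic. Size alone is weak — normal and metastatic size distributions
overlap heavily — and the texture of the node on CT carries additional
information about its histology. `lnradiomics` implements, as a tested
Python library, the full radiomics pipeline that quantifies that claim:

1. **Synthetic cohorts** of elliptical LN ROIs whose long-axis diameters
   follow the reported class laws (normal 12.12 ± 5.74 mm, metastatic
   17.37 ± 8.48 mm, truncated at 4 mm) with class-dependent internal
   texture (a Gaussian random field) — the generator stands in for the
   undeposited patient data and makes every stage testable.
2. **A 146-feature texture panel** per node: first-order statistics,
   gray-level co-occurrence (GLCM) and run-length (GLRLM) matrices averaged
   over four directions, rotation-invariant uniform local binary patterns,
   box-counting fractal dimension and shape descriptors, plus the FoS/GLCM/
   GLRLM panels recomputed in the four first-level Daubechies-2 wavelet
   subbands and on the Sobel gradient magnitude.
3. **Model building**: an 80/20 class-stratified split; the clinical
   > 10 mm rule; a demographic kernel SVM on the covariate subset chosen by
   exhaustive search over all 63 subsets of {age, gender, grade, location,
   short axis, long axis}; and a radiomic kernel SVM on the features with
   nonzero weight in a LASSO regression of the 0/1 label at the penalty λ*
   minimizing the 10-fold cross-validation MSE,

   min_β ‖y − Xβ‖² / 2n + λ‖β‖₁.

4. **Evaluation**: accuracy / sensitivity / specificity in %, AUC with the
   DeLong nonparametric variance and 95% CI, and the paired DeLong z-test
   z = ΔAUC / √(var A + var B − 2 cov) for comparing models scored on the
   same cases.

It is intended for methodologists who want a fully reproducible,
oracle-tested reference implementation of this study design — not for
clinical use.

## Worked example

`examples/04_train_and_evaluate.py` simulates 50 + 50 nodes, runs the whole
protocol and prints:

```
radiomic signature: ['glcm_correlation', 'glrlm_lre', 'lbp_5', 'wavelet_ll_variance',
                     'wavelet_ll_kurtosis', 'wavelet_lh_log_energy', 'wavelet_hl_log_energy']
demographic subset: ['gender', 'short_axis']

model        cohort    acc%   sens%   spec%    AUC
clinical     train    68.75   90.00   47.50  0.744
clinical     test     50.00   90.00   10.00  0.570
demographic  train    72.50   55.00   90.00  0.736
demographic  test     65.00   50.00   80.00  0.620
radiomic     train    77.50   80.00   75.00  0.851
radiomic     test     65.00   80.00   50.00  0.710

DeLong radiomic vs clinical (test): dAUC = +0.140, p = 0.1246
```

The LASSO kept 7 of 146 texture features; the radiomic SVM out-ranks the
size rule by 0.14 AUC on the held-out nodes, although at n = 20 test cases
the paired DeLong test does not reach significance — at the full study
size (312/78) the same pipeline yields radiomic test AUCs around
0.83–0.89 against ≈ 0.65–0.75 for the clinical rule, with p well below
0.05. The other examples cover cohort simulation (`01`), single-node
feature extraction with the published landmark features F⁸, F¹⁶, F¹²⁶,
F¹²⁹ (`02`), LASSO path inspection (`03`) and the DeLong machinery on a
hand-checkable 8-case example (`05`).

A thin CLI mirrors the pipeline stages on file artifacts
(NIfTI images + CSV tables + JSON models):

```bash
lnradiomics simulate --seed 1 --out cohort/
lnradiomics extract --cohort cohort/ --out features.csv
lnradiomics select --features features.csv --out lasso.json
lnradiomics evaluate --cohort cohort/ --features features.csv --out study/
lnradiomics report --metrics study/metrics.json --out table2.csv
lnradiomics run --seed 1 --out results/run   # everything at once
```

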