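# dwigrade

Noninvasive preoperative grading of rectal cancer from diffusion-weighted
MRI (DWI), as a tested, reusable analysis pipeline.

Histopathological grade (WHO G1–G3) strongly conditions prognosis and
treatment of rectal cancer, but biopsy-based grading is invasive and prone
to sampling bias. Quantitative DWI offers noninvasive surrogates: three
scalar signal models read out complementary tissue properties, and their
parameters can feed a machine-learning classifier that separates low-grade
(G1/G2) from high-grade (G3) tumors. Because clinical DICOM data of this
kind cannot be shared, the package includes a first-class synthetic phantom
generator that emulates the statistical structure of such a cohort, so the
entire analysis is exercisable and testable end to end.

## Models

For diffusion weighting *b* (s/mm²) and signal *S(b)*:

* **Mono-exponential**: S(b)/S₀ = exp(−b·ADC). The apparent diffusion
  coefficient ADC indexes cellular density; it is computed from the
  two-point closed form over b = 0 and 800 s/mm².
* **IVIM** (intravoxel incoherent motion):
  S(b)/S₀ = (1−f)·exp(−b·D) + f·exp(−b·D_p), fitted over twelve b-values
  from 0 to 800 s/mm². D is the true tissue diffusivity (cellularity),
  D_p the perfusion-driven pseudo-diffusion, f the perfusion fraction
  (vascularity).
* **DKI** (diffusion kurtosis imaging):
  ln S(b) = ln S₀ − b·D_app + (1/6)·b²·D_app²·K_app, fitted in log-signal
  space over b = 0, 800, 1500, 2000 s/mm². K_app measures deviation from
  Gaussian diffusion (micro-structural heterogeneity).

Voxel-wise estimates come from bounded nonlinear least squares with
segmented initialisation; bounds are 0–5.0×10⁻³ mm²/s for ADC, D and D_app,
0–80×10⁻³ mm²/s for D_p, 0–0.8 for f and 0–2.5 for K_app. Lesions are
measured by whole-lesion averaging over per-observer VOIs, averaged across
three observers, with inter-observer agreement quantified by the two-way
random-effects absolute-agreement ICC. Grading uses the (D, f, K_app)
feature triple under four classifiers (logistic regression, KNN, RBF-SVM,
random forest) with stratified 5-fold cross-validation, empirical ROC/AUC,
Youden-optimal operating points and DeLong AUC comparisons.

## Worked example

```python
import numpy as np
from dwigrade import BScheme, IvimParams, ivim_signal, fit_ivim
from dwigrade.synthetic_data import GroupDistributionSpec, sample_cohort_parameters
from dwigrade.group_analysis import compare_groups
from dwigrade.classification import assemble_features, cross_validate

# 1. voxel-level: render an IVIM decay and invert it
scheme = BScheme()                       # b = 0 ... 2000 s/mm²
truth = IvimParams(s0=1000, f=0.239, d=1.339e-3, dp=45.952e-3)
signals = ivim_signal(truth, scheme.b(scheme.ivim_subset))
fit = fit_ivim(signals, scheme)
print(f"f = {fit.params.f:.3f}, D = {fit.params.d*1e3:.3f}e-3 mm2/s, "
      f"D_p = {fit.params.dp*1e3:.3f}e-3 mm2/s")

# 2. cohort-level: synthetic 53 low / 32 high cohort, group test, CV grading
cohort = sample_cohort_parameters(GroupDistributionSpec(),
                                  n_low=53, n_high=32, seed=7)
low, high = cohort[cohort.grade == "low"], cohort[cohort.grade == "high"]
res = compare_groups(low["d"], high["d"], parameter="d")
print(f"D: {res.test_used} test, p = {res.p_value:.2e}")

cv = cross_validate(assemble_features(cohort), "LG", k=5, seed=7)
print(f"LG mean AUC = {cv.mean_auc:.3f} [{cv.ci_low:.3f}, {cv.ci_high:.3f}]")
```

Output:

```
f = 0.239, D = 1.339e-3 mm2/s, D_p = 45.952e-3 mm2/s
D: t test, p = 8.45e-05
LG mean AUC = 0.676 [0.550, 0.802]
```

The noise-free fit recovers the generating parameters exactly (forward and
inverse share one set of signal models). At the cohort level, D separates
the grades decisively; the cross-validated AUC of the combined logistic
model varies cohort to cohort around ~0.78 at this sample size (the seed-7
draw above is on the low side).

## Command line

```bash
dwigrade run-all --seed 1 --outdir runs/demo          # full pipeline
dwigrade simulate --seed 1 --outdir runs/demo         # or stage by stage
dwigrade cohort-flow --enrolled 105 --exclude neoadjuvant 7
```

Stages (`simulate`, `fit`, `measure`, `analyze`, `classify`, `report`)
exchange NIfTI/CSV/JSON artifacts inside the run directory; re-running with
the same config and seed reproduces every CSV byte for byte.

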