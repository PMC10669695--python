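# Methods

## Signal models and units

Three orientation-averaged scalar models describe the magnitude DWI signal
of a voxel. All b-values are carried in s/mm² and diffusivities in mm²/s
internally; the conventional ×10⁻³ mm²/s reporting scale appears only at
I/O boundaries (cohort CSVs, reports). The acquisition scheme is the
14-point b-table 0, 10, 20, 30, 50, 80, 100, 150, 200, 400, 600, 800, 1500,
2000 s/mm², with fitting subsets {0, 800} (ADC), all b ≤ 800 (IVIM) and
{0, 800, 1500, 2000} (DKI). The forward models are the single source of
truth: the fitting engine evaluates its residuals and the phantom generator
renders its signals through the same functions, which is what makes the
noise-free forward–inverse identity exact.

## Voxel-wise fitting

* **ADC** uses the two-point closed form ln(S₀/S₈₀₀)/800, clipped to
  [0, 5×10⁻³] mm²/s. No regression is involved — with two observations the
  mono-exponential model is exactly identified.
* **IVIM** fixes S₀ to the measured b = 0 signal (the model is a normalised
  ratio) and fits (f, D, D_p) by bounded trust-region nonlinear least
  squares in signal space. Initialisation is segmented: a log-linear fit
  over b ≥ 200 s/mm² — where the perfusion compartment has decayed —
  provides D and, through its intercept ln(1−f), the perfusion fraction;
  D_p starts at 10×10⁻³ mm²/s. The segmented start matters because D_p is
  notoriously ill-conditioned; a joint refinement from a poor start can
  stall in flat regions of the objective.
* **DKI** fixes ln S₀ and fits (D_app, K_app) by bounded least squares on
  log-signal residuals (the model is stated in log space; under noise this
  weights high-b points more than a signal-space fit would — a deliberate,
  recorded choice). Initialisation comes from an unconstrained quadratic
  fit of ln S in b.

Bounds (ADC, D, D_app: 0–5×10⁻³ mm²/s; D_p: 0–80×10⁻³ mm²/s; f: 0–0.8;
K_app: 0–2.5) are enforced by the solver; because trust-region iterates
stay strictly interior, a boundary optimum is returned a hair inside the
box, so estimates within 10⁻³ of a bound's range are snapped exactly onto
the bound whenever that does not worsen the residual. A snapped coordinate
is flagged (`at_bound`) and the voxel marked non-converged, which is how
"truth outside the box → estimate exactly at the bound" is realised. When
f reaches 0 the pseudo-diffusion term vanishes from the model, so D_p is
flagged unidentifiable but retained numerically. Voxels with non-positive
signal anywhere in a fitted subset are invalid (log transforms are
undefined there). Tolerances are 10⁻¹⁵ on step, gradient and cost change;
with noise-free data all fits recover interior truths to better than 10⁻⁶
relative error. There is no internal randomness: identical inputs give
bit-identical maps.

## Synthetic cohorts

The generator emulates a two-class rectal-cancer cohort at the lesion
level. Per class, the six parameters (ADC, D, D_p, f, D_app, K_app) are
drawn from a multivariate Gaussian with the published group means and SDs
(low grade n = 53: ADC 1.471 ± 0.202, D 1.339 ± 0.201, D_p 45.952 ± 12.376
(all ×10⁻³ mm²/s), f 0.239 ± 0.068, D_app 1.499 ± 0.231, K_app
0.678 ± 0.133; high grade n = 32: 1.321 ± 0.143, 1.129 ± 0.146,
48.165 ± 12.368, 0.197 ± 0.055, 1.297 ± 0.224, 0.819 ± 0.130) and the
twelve published pairwise correlations as a Gaussian copula (the three
unpublished D_p pairs default to 0; the matrix is repaired to its nearest
positive semi-definite correlation by eigenvalue clipping). Sampling is
rejection-truncated at the fitting bounds so generated and fitted supports
coincide; with these means the rejection rate is negligible.

Each lesion is rendered as a sphere (default radius 3 voxels in a
16×16×8 grid, S₀ = 1000) in a homogeneous background of healthy-tissue-like
parameters. Signals at b ≤ 800 come from the IVIM model and at b = 1500,
2000 from the DKI model — one stitched 14-point series per voxel, exactly
as a real acquisition would measure one decay curve and fit both models to
it. A consequence worth knowing: the DKI fit sees a b = 800 point generated
by the IVIM curve, so the sampled D_app/K_app round-trip only approximately
through the stitched series (the IVIM triple and ADC relation round-trip
exactly); model-consistent recovery is verified on per-model rendered
signals.

Rician noise replaces each sample s by sqrt((s+g₁)² + g₂²) with independent
zero-mean Gaussians of SD σ = S₀/SNR; the default b = 0 SNR is 50, a
realistic value for 3 T single-shot EPI (the source acquisition's SNR is
not reported). Three simulated radiologists are emulated by thresholding
the true VOI's signed Euclidean distance plus a smooth unit-variance
Gaussian random field scaled by a perturbation amplitude (default 1 voxel);
zero perturbation reproduces the truth, and each observer uses a distinct
deterministic sub-seed. Everything — parameter draws, noise, observer
jitter, fold splits — derives from one master seed.

What the phantoms do **not** emulate: anatomically realistic geometry,
partial-volume and rim effects, within-lesion parameter heterogeneity
(available as an option, off by default), scanner artifacts, distortion or
motion. Passing tests therefore demonstrate the correctness of the
estimation and evaluation machinery under the assumed statistical
structure, not clinical performance on real images.

## Lesion measurement and agreement

VOIs drawn on one map are propagated to co-registered maps as identity
copies after a grid/affine check (the maps share the source volume's grid
by construction). Lesion values are arithmetic means over valid voxels;
three observers are averaged. Inter-observer agreement uses the two-way
random-effects, absolute-agreement, single-rater ICC — the standard choice
when raters are interchangeable — computed from the ANOVA mean squares with
the F-based 95% interval; a consistency-type ICC is available by switch.
Interpretation bands are poor < 0.2 ≤ fair < 0.4 ≤ moderate < 0.6 ≤
substantial < 0.8 ≤ excellent, with boundary values assigned to the higher
band. Zero between-subject variance leaves the coefficient undefined (NaN).

## Group statistics

Each parameter's low-vs-high comparison is gated on normality: Welch
t-test when both groups pass Shapiro–Wilk at α = 0.05, otherwise a
two-sided Mann–Whitney U (exact null for combined n ≤ 20 without ties,
normal approximation with tie correction otherwise; constant or tiny
groups fall back to the rank test with a warning flag). Pairwise
correlations use Pearson when both variables pass Shapiro–Wilk, Spearman
otherwise. The output records which branch was taken. No multiple-testing
correction is applied by default, matching the single-parameter reporting
convention; a Holm adjustment is available.

## Classification and ROC evaluation

Features are the (D, f, K_app) triple — the three significant parameters
carrying distinct biology (cellularity, vascularity, heterogeneity); ADC
and D_app duplicate D's insight and D_p does not separate the classes.
Classifiers: unpenalised logistic regression; KNN with k = 5 (unweighted);
RBF-SVM with unit cost and median-heuristic bandwidth computed on the
training fold; random forest with 500 seeded trees. Features are
standardised with training-fold statistics only (no leakage). Stratified
5-fold CV yields per-fold test AUCs; the reported AUC is their arithmetic
mean with a mean ± 1.96·SD interval clipped to [0, 1], while the operating
point (sensitivity, specificity, Youden index = sens + spec − 1) comes
from pooled out-of-fold scores — fold-wise AUCs but a single pooled
cutpoint, since per-fold cutpoints on ~17 patients are too unstable to
report. The empirical ROC is computed over unique score thresholds
(positive when score ≥ threshold); AUC equals the Mann–Whitney concordance
probability with ties counted ½, and Youden ties break toward higher
specificity. The DeLong test compares correlated AUCs via placement-value
(structural-component) variances with a two-sided normal p-value; the
pipeline pairs pooled out-of-fold logistic scores against each raw
parameter over all patients. Single-parameter ROCs are computed on the
full cohort (no training is involved), with automatic sign orientation for
parameters that decrease with grade.

## Problem sizes and numerical choices

Default pipeline runs use 20 low + 12 high phantoms; the acceptance script
scales to the full 53/32 cohort on the default 16×16×8 grid, fitting only
inside the dilated union of observer VOIs (the measurements never leave
that region, and it keeps a full-cohort run to a few minutes). Monte-Carlo
checks use 1000 voxels per noise condition and 100 cohort replicates for
the group-test power property. CV seeds, per-fold classifier seeds,
per-patient noise and observer seeds are all spawned deterministically from
the master seed.

## Known limitations

* The within-class copula reuses the published cohort-level (pooled)
  correlations. Pooling two shifted classes inflates correlations relative
  to the within-class ones, so this choice over-correlates D, f and K_app
  inside each class and makes the combined classifier's margin over the
  best single parameter (D) small — the population-level combined AUC is
  ≈ 0.81 vs ≈ 0.80 for D alone under these conditions, so the combined
  model's advantage is not reliably resolvable at n = 85. An alternative
  generator that decomposes pooled correlations into within- and
  between-class parts would widen that margin; it is not the default
  because it requires assumptions beyond the published numbers.
* ADC and D_app measured from the stitched phantom series are shifted
  relative to their sampled values (the b = 800 point carries perfusion
  signal); group orderings are preserved.
* The DeLong pairing of cross-validated scores with raw parameter values
  mixes out-of-sample and in-sample quantities; it is reported for
  completeness, not as a calibrated hypothesis test.
* D_p is reported but unidentifiable whenever f fits to 0.
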