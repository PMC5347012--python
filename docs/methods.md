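# Methods

## The model

`dsindex` implements a disease severity index for preclinical dementia
built from regional brain morphometry. An orthogonal projections to
latent structures (OPLS) discriminant model is trained to separate
Alzheimer's disease (AD) patients from healthy controls (HC) using a
subject-by-feature table of FreeSurfer-style measures — by default 68
cortical thickness values, 68 cortical gray-matter volumes and 51
subcortical volumes (187 features). Subjects with subjective memory
decline (SMD), who are cognitively normal on objective testing, are
then projected onto the fitted model as unseen data. The predicted
coded response is the severity index: near 0 means an HC-like pattern
of brain structure, near 1 an AD-like pattern. SMD subjects with index
≥ 0.5 are subtyped AD-like, and the subtypes are validated against
longitudinal follow-up (progression to MCI/dementia/death, survival
curves, log-rank tests).

### OPLS decomposition

With X the standardized n×p feature matrix and y the coded class
labels (control = 0, disease = 1, centered by the training mean ȳ),
the fit removes `n_orth` orthogonal components by deflation and then
fits one predictive component:

repeat `n_orth` times:

    w* = Xᵀy / ‖Xᵀy‖            candidate predictive weight
    t* = X w*,  p* = Xᵀt*/(t*ᵀt*)
    w_o ∝ p* − (w*ᵀp*) w*        orthogonal weight, unit norm
    t_o = X w_o,  p_o = Xᵀt_o/(t_oᵀt_o)
    X ← X − t_o p_oᵀ             deflate

then

    w = Xᵀy / ‖Xᵀy‖,  t = X w,  p = Xᵀt/(tᵀt),  c = yᵀt/(tᵀt)

Prediction for a new (preprocessed) row x removes the stored
orthogonal variation sequentially (t_o = xᵀw_o; x ← x − t_o·p_o) and
returns ŷ = c·(xᵀw) + ȳ. Two consequences define the method and are
enforced as tests: every orthogonal score has zero covariance with y
on the training data, and the index is invariant to adding any linear
combination of stored orthogonal loadings to a subject. With
`n_orth = 0` the model reduces exactly to single-component PLS1
(w ∝ Xᵀy). For a single response, every step is closed-form; no NIPALS
iteration is needed.

### Cross-validation

Model quality is the cross-validated goodness of prediction

    Q²(Y) = 1 − PRESS / SS,  PRESS = Σᵢ (yᵢ − ŷᵢᶜᵛ)²,  SS = Σᵢ (yᵢ − ȳ)²,

from a seeded, stratified 7-fold split in which *the entire
preprocessing chain* (ICV adjustment, standardization) and the OPLS
fit are re-estimated inside each training fold — held-out subjects are
transformed with stored parameters only, so no statistic leaks across
the fold boundary. By the field's convention Q² > 0.05 is significant
and Q² > 0.5 a good model. Sensitivity and specificity are computed
from the cross-validated predictions thresholded at 0.5 (disease class
positive). The number of orthogonal components is chosen automatically
as the smallest n at which Q²(n+1) − Q²(n) < 0.01 (cap 5, same fold
split at every n); the count is recorded in the model file.

### Preprocessing

Total intracranial volume (ICV) is a nuisance covariate for volumetric
measures. Two adjustment modes are provided, selected by
`icv_mode`:

* `residualize` (default): each volume column is replaced by its
  residual from a straight-line fit on ICV estimated on training rows;
  thickness columns are untouched. This is the most common practice in
  morphometry and makes adjusted volumes exactly uncorrelated with ICV
  on the training rows.
* `append`: ICV enters as one extra standardizable input variable —
  the other defensible reading of "including ICV as a covariate" in a
  projection model.

Columns are then mean-centered and scaled to unit variance (n−1
denominator), the default of the commercial OPLS tooling this class of
analysis historically used; zero-variance columns are dropped and
recorded. All constants live in `ScalingParams`, serialized inside the
model JSON, so projection of unseen subjects replays the exact
training transform.

### Variable importance

Features are ranked by |covariance| between the orthogonality-filtered
standardized column and the predictive score t, with correlation
reported alongside. The sign is oriented so that positive covariance
means "larger in controls": atrophied regions (hippocampus, entorhinal,
inferior parietal, amygdala, precuneus) rank positive and enlarged
inferior lateral ventricles negative.

## Follow-up validation

A subject's final outcome is the first follow-up visit whose diagnosis
falls in a worse severity category than baseline (HC = SMD < MCI <
dementia), or death, whichever comes first; the event time is that
visit's month (no interval-midpoint imputation). Moves between HC and
SMD are not events; stable subjects are censored at their last attended
visit, and a record with no post-baseline visits is a missing outcome.
Progression proportions use MCI + any dementia + death in the numerator
and subjects with a recorded outcome in the denominator; percentages
and ratios are printed to 1 decimal, rounding half away from zero.
Because a plain proportion ratio ignores differential follow-up time,
the report also carries a person-time incidence-rate ratio, labelled as
such. Kaplan–Meier curves and the two-group log-rank test are computed
via lifelines, and Benjamini–Hochberg FDR correction (step-up, level
q = 0.05) via statsmodels, behind the `outcomes` module interface;
hand-computed product-limit tables, an observed-minus-expected log-rank
table and a direct step-up enumeration serve as independent oracles in
the tests. Threshold rules: MMSE ≥ 24 is normal global cognition;
amyloid-PET SUVR ≥ 1.5 is positive.

## The synthetic cohort generator

No subject-level data ship with the package; every analysis is
exercised on seeded synthetic cohorts that emulate the structure the
method assumes.

* **Groups and sizes.** HC 69, SMD 86, MCI 45, AD 38 — the baseline
  composition of the memory-clinic style cohort the pipeline targets.
  Eleven of the 86 SMD subjects are planted carriers of the full AD
  pattern (the hidden `truth_ad_like` column records them and never
  enters feature matrices); MCI carries the pattern at half strength.
* **Features.** Each subject draws a latent standard-normal vector z
  with single-parameter exchangeable correlation (ρ = 0.3) within
  three blocks — cortical thickness, cortical volume, subcortical —
  shifted by the configured effect vector for pattern carriers.
  Thickness values are `2.5 mm + 0.15·z`; volumes are
  `base · (ICV/ICV̄)^1 · (1 + 0.12·z)` with ICV ~ N(1.5·10⁶, 1.5·10⁵) mm³,
  so volumes are multiplicatively coupled to head size and the
  residualization step has a real signal to remove. Baseline volumes
  use anatomically plausible magnitudes for well-known structures
  (hippocampus ≈ 4000 mm³, amygdala ≈ 1700 mm³, …) and a mid-range
  default elsewhere; since every feature is standardized before
  modelling, only the planted standardized shifts matter downstream.
* **Effect sizes.** The default pattern puts d = −2.5 (in within-group
  standard deviations) on hippocampus, amygdala, entorhinal,
  inferior-parietal and precuneus measures and d = +2.0 on the inferior
  lateral ventricles — 18 non-zero features. The magnitude is a
  calibration choice: it makes the AD/HC contrast cleanly separable so
  that a correctly implemented model attains Q² well above 0.5 with
  near-perfect cross-validated specificity, mirroring the separability
  regime the index was designed for. It is not an empirical estimate
  of real-world atrophy.
* **Follow-up.** Each subject samples one final outcome from its
  (group × truth) stratum: the default probabilities are the published
  outcome frequencies of the reference cohort (for planted AD-like SMD
  the expected progressed fraction is 8/11), with the probability mass
  left over becoming missing follow-up. Events occur at a visit drawn
  uniformly from the post-baseline grid {18, 36, 54, 72, 90} months;
  MMSE and CDR-SOB follow linear group trajectories with noise; death
  terminates the visit sequence. SUVR is drawn per stratum around the
  1.5 positivity threshold (AD-like strata mostly above it).

**What the generator does not emulate:** measurement noise of real
segmentation pipelines, site/scanner effects, realistic ROI-specific
covariance (one exchangeable ρ per block is deliberately simple),
age/sex structure in the features, informative missingness, or
time-varying hazards. Passing tests therefore demonstrate correctness
of the algorithms and recoverability of planted structure under clean
conditions — not expected performance on clinical data.

## Numerical choices and degenerate inputs

* Norm guards at 1e-12: a single-class y or a numerically zero Xᵀy is
  an explicit error, and an orthogonal weight with vanishing norm ends
  the deflation early (no systematic variation left).
* sd uses the n−1 denominator everywhere; zero-variance columns are
  dropped with a record, constant ICV under residualization is a
  degenerate-covariate error.
* Ties at the 0.5 cutoff classify as AD-like (closed upper category);
  indices are never clipped to [0, 1], preserving monotonicity
  diagnostics.
* Stratified folds refuse a class with fewer members than folds.
* One master seed drives a run; stage sub-seeds are derived by hashing
  (seed, stage-name), so identical configuration and seed give
  byte-identical artifacts.

## Problem sizes

The bundled analyses and tests run the full 238-subject, 187-feature
cohort for single fits and cross-validations, and 20-seed replicates
for the recovery-rate checks; null-behaviour checks use 60×187 noise
matrices over 10 seeds. These sizes give stable estimates of the
properties being checked while keeping a complete run in the order of
seconds.

## Known limitations

Two-class discrimination with a single predictive component only;
multi-class OPLS, O2-PLS and kernel variants are out of scope, as are
FreeSurfer-native file parsing, image-level processing, and the routine
inferential statistics around the index (ANOVA/MANCOVA/mixed models) —
only their multiple-comparison correction and the count/proportion/
survival computations are provided. Whether the reference analysis
derived SMD indices from the refit full model or the cross-validated
submodels is not documented; this package projects onto the full model
(the "unseen data" reading) and exposes the choice in code.
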