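# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the tests do and do not establish.

## The brain-age model

Brain age is estimated from gray-matter (GM) probability maps by a
three-step chain: smooth with a 3-mm FWHM Gaussian, resample to 3 mm
(trilinear), flatten over the brain mask, center, and reduce by PCA (at most
n−1 components); then regress age on the reduced features with a
linear-kernel relevance vector regression (RVR). The RVR design matrix is
`[1 | K]` with `K(x_i, x_j) = x_i · x_j`; each column carries its own
precision hyperparameter `α_i` and the noise carries a precision `β`. The
type-II maximum-likelihood fixed point is iterated:

```
S = (β ΦᵀΦ + diag(α))⁻¹        m = β S Φᵀ y
γ_i = 1 − α_i S_ii             α_i ← γ_i / m_i²
β ← (n − Σ γ) / ‖y − Φ m‖²
```

with `α = 1/n²`, `β = 10/var(y)` at start, pruning of columns with
`α > 10⁶`, convergence on a 10⁻⁴ relative change of the log marginal
likelihood, and at most 500 iterations. The procedure is deterministic (no
random initialization) and needs no tuning. With hyperparameters frozen and
pruning disabled, the posterior mean is exactly a generalized kernel ridge
solution — the degenerate-limit equivalence the tests check against an
explicit linear solve.

Leave-one-out cross-validation refits the *entire* reduction (centering and
PCA) and the RVR on each fold's n−1 training subjects; the held-out map
never touches any training statistic. The per-subject smoothing/resampling
step is deterministic per map and is precomputed once — this does not leak
information across subjects. A `refit_reduction_per_fold=False` flag instead
fits one global PCA, which is faster but slightly optimistic.

BrainAGE score, MAE and Pearson r are defined in the README; the score
identity `score ≡ BA − CA` is enforced structurally in the result object.
The baboon→human age conversion is a fixed factor of 3.5 (consistent with
the anchor pairs 4→14, 22→77 and 5→17.5 years).

## Synthetic study conditions

No image data for such cohorts is publicly deposited, so the generator *is*
the study definition. Its defaults encode:

- **Lifespan cohort:** 15 females + 14 males, ages uniform on 4–22 y, total
  intracranial volume (TIV) drawn per sex from N(186.7, 14.4²) ml (females)
  and N(210.4, 14.0²) ml (males).
- **Fractional trajectories** (per-sex polynomials of age; CSF is the
  complement): females lose GM linearly (−0.0065/y, anchored at
  GM/TIV = 0.47 at the female mean age 9.43 y) and gain WM (+0.002/y,
  anchored at 0.32); CSF therefore rises linearly (+0.0045/y, 0.21 at
  anchor). Males decline mostly quadratically
  (GM = 0.4816 − 0.000323·a − 0.0002·a², 0.46 at the male mean age 9.62 y),
  with WM mirroring the GM age terms so male fractional CSF stays flat at
  0.22. These coefficients are configuration, calibrated once so cohort
  means and SDs approximate the target cohort table; they are not claims
  about measured trajectories.
- **MNR effect:** MNR females lose `mnr_gm_offset = 2.7 × 0.0065 ≈ 0.0176`
  of fractional GM, rebalanced into CSF — an atrophy offset equivalent to
  +2.7 brain-years on the female trajectory, matching the direction of the
  experimental contrast (fractional GM down, absolute CSF up). Males carry
  no programmed effect.
- **Experimental cohort:** 5/5 female CTR/MNR and 7/6 male CTR/MNR, ages
  uniform on 4–7 y, with birth weights and scan weights drawn from the
  published per-cell summaries.
- **Phantom geometry:** three concentric compartments (WM core, GM ribbon,
  CSF shell) under a seeded volume-preserving anisotropic metric; voxels are
  assigned by sorting the deformed radius, so class voxel counts match the
  requested fractions to ±1 voxel. Default grid 48³ at 2.0 mm synthetic
  voxels — 8 mm³ voxels let a 187–210 ml brain fit the grid with margin
  while keeping every stage desk-fast; a 1-mm grid of this size could hold
  at most ~110 ml and would break the TIV-recovery invariant.
- **Artifacts:** T1-like class means (CSF 0.3 < GM 0.6 < WM 0.9 on a 0–1
  scale), additive Gaussian noise (SD 0.02), a smooth multiplicative bias
  field (±5%, from a seeded 3³ lattice upsampled cubically), and per-slice
  gains (SD 3%) along the third axis.

**What the phantoms do not emulate:** cortical folding and gyral geometry,
MR physics (relaxometry, k-space artifacts, partial-volume mixtures beyond
trilinear interpolation), skull and extracerebral tissue, and nonlinear
anatomical variability. Passing tests therefore demonstrate that the
algorithms recover *programmed* effects through this imaging chain at
realistic noise levels — not that the pipeline's accuracy numbers transfer
to real scans.

### Model-layer GM maps and the SNR calibration

The model layer consumes "preprocessed" GM maps directly:
`noisy_gm_maps` takes each subject's ground-truth GM probability map,
affinely size-normalizes it to a common 200-ml template volume (the
synthetic analogue of registration into template space — unmodulated, so
values are preserved and only geometry is normalized), and adds voxelwise
Gaussian noise. Without the normalization, raw head-size variation (≈15×
the age-signal variance in feature space) acts as a nuisance that both
degrades the age model and attenuates group contrasts; the real pipeline
removes it by registration, so the emulation must too.

The noise SD (default 0.045) is calibrated so the **feature-space age SNR**
of a default lifespan cohort is ≈2. SNR is defined as the RMS ratio of
per-subject age-attributable clean feature energy to per-subject map-noise
energy after the deterministic reduction steps (`feature_age_snr`). Two
tempting alternatives fail: correlating PC1 with age measures the head-size
axis, not aging; and projecting onto a single fixed direction averages iid
noise to near zero, yielding SNRs in the hundreds that predict nothing
about estimation error.

At SNR ≈ 2 a regression-based predictor necessarily *shrinks*: the
recoverable fraction of an injected effect is roughly SNR²/(1+SNR²) ≈ 0.8,
compounded mildly by the Bayesian shrinkage of the RVR. The recovered MNR
group difference therefore concentrates near 2.2–2.5 years rather than the
injected 2.7 — within two standard errors of the 5-vs-5 group-difference
estimator, which is the scale on which a single experiment can measure it.
The acceptance script also reports an age-bias-corrected difference
(dividing by the slope of BA on CA from training LOOCV), which removes the
attenuation on average.

## Preprocessing

**Slice-gain correction.** One multiplicative gain per slice along the
acquisition axis. The anatomy profile is estimated voxelwise by a running
median over 5 neighbouring slices; each slice's gain is the median over
foreground voxels of the slice-to-profile ratio — insensitive to the
slice's tissue composition, unlike a plain slice-median profile, which
misreads composition jumps (e.g. pole slices of a brain) as gain. Because
the running median mixes neighbouring gains, three fixed-point passes are
run (residual gain amplitude roughly halves per pass). Foreground is
`> 0.25 × P99`; empty slices keep gain 1; the output is rescaled to the
input mean. On a uniform volume with periodic gains the correction is exact
away from the two outermost slices; gain recovery at 2% noise is ≈1.9% RMS
on supported slices.

**Denoising** wraps scikit-image's fast non-local means. `h="auto"` sets
the filter strength to 0.8 of a global robust noise estimate from
first-difference pseudo-residuals (median absolute difference × 1.4826/√2).
A single data-driven `h` is used rather than a voxelwise-local one, which
the patchwise backend does not support; on phantoms this preserves ≥90% of
between-class contrast while cutting flat-region noise SD by ≳10×. The main
known cost: structures ≈1 voxel thick (the outer CSF shell at 2-mm
resolution) lose some definition, which is why volumetry quality is
dominated by the segmentation, not the denoiser.

**Affine registration** minimizes the mean squared difference of
z-normalized, 2-mm-smoothed images over 1 (scale-only), 6 (rigid) or 12
(full-affine) parameters: a coarse grid over translations (or scale),
Powell refinement (xtol 10⁻³) on a 2×-decimated grid, final resampling at
full resolution. Transforms map fixed-image world coordinates to
moving-image world coordinates about the image centers. Non-convergence is
flagged on the result, never swallowed. Typical accuracy on phantoms:
translation within 0.05 voxel, scale within 0.3%.

**Segmentation** is a four-class (GM/WM/CSF/background) Gaussian-mixture EM
with the TPM as per-voxel spatial prior: posterior ∝ prior × likelihood,
renormalized per voxel; class means/SDs re-estimated from posterior
weights; convergence on a 10⁻⁴ relative log-likelihood change. One Gaussian
per class suffices for the phantom intensity model. Numerical choices: a
SD floor of 10⁻³ of the intensity range; priors clipped at 10⁻⁶ before
renormalization; classes with ~zero prior mass dropped with a warning; and
a symmetry-breaking initialization (class means spread over intensity
quantiles in the T1 order background < CSF < GM < WM) when the prior is
spatially flat — otherwise all classes would start identical and EM would
sit in a symmetric fixed point. Volumes are posterior mass × voxel volume
(mm³)/1000; TIV = GM+WM+CSF; fractional volumes divide by TIV and sum to 1
by construction. Segmentation — and therefore all volumetry — happens in
**native space** (the TPM is pulled back through the inverse affine);
template space is used only for feature maps, since size normalization
before volumetry would erase the very volumes being measured.

## Template building

The species template starts from a generic reference prior (shipped as a
synthetic three-compartment, heavily smoothed stand-in for a human-scale
atlas) scaled isotropically so its non-background mass matches the target
brain volume (cube-root rule plus one corrective re-estimation; ≤1% error)
and resampled to the working resolution. Each iteration: register every
subject's T1 to the current T1 average (full-affine), segment the subject
natively against the pulled-back TPM, push the posteriors into template
space, take the voxel-wise **median** across subjects per class (robust to
corrupted scans — one inverted-intensity subject among ten leaves the
template unchanged where the majority agrees), smooth with FWHM 2 mm,
rebuild background as `1 − (GM+WM+CSF)` (guaranteeing normalization), and
recompute the T1 average (median) and brain mask (non-background prior
> 0.5). The change metric is the mean absolute voxel-wise TPM difference
over the previous mask (tissue classes averaged); iteration stops below
10⁻³ (default) or after 6 iterations.

Re-registration uses each subject's previous parameters as a warm start and
keeps them unless re-optimization improves the cost by more than 10%. This
deadband is load-bearing: without it, optimizer-tolerance jitter feeds the
register→median→register loop and the template never settles; with it, a
clean single-subject cohort reaches its exact fixed point at iteration 2.

## Statistics

- **Trajectory fits:** OLS of volume on age and age², with adjusted
  R² = 1 − (1−R²)(n−1)/(n−p−1) and the overall F per order. Two selection
  rules are provided. The default picks the significant order with the
  higher adjusted R² (ties → lower order). The `nested_f` rule keeps the
  quadratic only when its quadratic term is significant (α = 0.05). The
  adjusted-R² comparison is equivalent to a partial-F threshold of 1, so
  under a true linear model it elects the quadratic ~33% of the time — a
  property of the rule, not of the data. Where reliable order selection is
  the goal (the selection-accuracy checks and the analysis scripts), the
  nested-F rule is used, because it controls the order error at α.
- **Summary-statistic ANOVA:** pooled variance
  `s² = [(n_a−1)s_a² + (n_b−1)s_b²]/(n_a+n_b−2)`,
  `F = (x̄_a−x̄_b)²/[s²(1/n_a+1/n_b)]` on (1, n_a+n_b−2) df — identical to
  the squared two-sample t and exactly reproducible from published
  mean ± SD tables. Zero pooled variance with unequal means reports an
  infinite-F sentinel with a warning.
- **ANCOVA:** `value ~ group + age`, Type-II sums of squares, partial
  η² = SS_group/(SS_group+SS_residual). p-values are two-sided from the F
  distribution; no multiple-testing correction is applied (none is part of
  the analysis design).
- **Group contrast:** mean(score | MNR) − mean(score | CTR) plus the
  ANCOVA on the scores.

## Problem sizes used by tests and the acceptance script

Tests run on 48³ grids at 2 mm with cohorts of 29 (lifespan) and 10
(5-vs-5 female experiment): 20 seeds for LOOCV recovery, 50 seeds for
MNR-effect recovery, 100 fresh null cohorts (one trained model) for the
ANCOVA size check, 200 simulations for order selection, and 1000 for the
ANCOVA power-vs-noncentral-F comparison. The acceptance script uses 5 LOOCV
seeds (median) and 12 recovery seeds. These sizes were chosen so each
check's Monte-Carlo error is small against its acceptance margin while the
whole suite stays desk-fast.

## Known limitations

- Phantom geometry is smooth and three-compartment; segmentation Dice and
  registration accuracy on real folded anatomy will be lower.
- The affine-only registration cannot express local shape differences; the
  template is correspondingly blurry at compartment boundaries.
- The published cohort-level accuracy of the original study (r, MAE,
  adjusted R² of real trajectories, the covariate-adjusted experimental F)
  depends on the real images and per-subject data, which are not deposited;
  this package's corresponding numbers quantify recovery of *programmed*
  synthetic effects instead.
- The slice-gain estimator cannot separate gain from anatomy on slices
  whose tissue composition changes abruptly (outermost brain slices); its
  errors there are bounded by the foreground-support weighting but not
  eliminated.
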