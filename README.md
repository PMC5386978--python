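# primage

Brain age gap estimation (**BrainAGE**) for nonhuman-primate structural MRI,
built as a fully testable pipeline: seeded synthetic brain cohorts with
programmed age-, sex- and group-dependent tissue changes are preprocessed,
segmented against an iteratively built species template, reduced by PCA, and
fed to a relevance vector regression that estimates each individual's brain
age.

## The scientific problem

Moderate maternal nutrient restriction (MNR, a 70%-of-control diet during
pregnancy) programs lifelong changes in offspring physiology. In the baboon —
the closest widely available model of human developmental programming — the
question is whether fetal undernutrition leaves a measurable mark on *brain
aging* in young adulthood. The BrainAGE approach answers it with a single
per-subject number: train a machine-learning model to predict chronological
age from structural gray-matter maps of healthy controls spanning the adult
lifespan (4–22 baboon years ≈ 14–77 human years), apply it to new subjects,
and read the gap

```
BrainAGE score_i = BA_i − CA_i
```

between estimated brain age `BA_i` and chronological age `CA_i` as
accelerated (+) or decelerated (−) structural aging. Model accuracy is
summarized by the mean absolute error over a test sample,

```
MAE = (1/n) Σ_i |BA_i − CA_i| ,
```

and by Pearson's r between `BA` and `CA`, pooled over leave-one-out
cross-validation folds.

The pipeline has four stages (plus a synthetic-cohort generator that stands
in for the unavailable scan data):

1. **Preprocessing** — per-slice gain correction, spatially adaptive
   non-local-means denoising, affine registration, and tissue segmentation
   (GM/WM/CSF) by an EM-fitted Gaussian intensity mixture with a species
   tissue probability map (TPM) as spatial prior.
2. **Template building** — the species TPM, T1 average and brain mask are
   created by scaling a generic reference prior to the expected brain size
   (~200 ml) and iterating segment → register → voxel-wise *median* →
   2-mm smoothing until the template stops changing.
3. **Data reduction** — GM maps are smoothed (FWHM 3 mm), resampled to 3 mm,
   masked and reduced by PCA.
4. **Age regression** — a linear-kernel relevance vector regression (sparse
   Bayesian regression; hyperparameters estimated from the marginal
   likelihood, so no tuning is needed) maps the reduced features to age.

A statistics layer reproduces the study's analysis: sex-specific
linear/quadratic volume-trajectory fits with order selection, two-group
ANOVA recomputed from published summary statistics, age-adjusted ANCOVA with
partial η², and the MNR-vs-CTR BrainAGE contrast.

## Worked example

```python
import numpy as np
import primage as pm

params = pm.AgingModelParams()          # the programmed study conditions
mask = np.ones(params.grid_shape, bool)
vs = (params.voxel_size_mm,) * 3

# lifespan cohort: 29 subjects (15 female), ages 4-22 y
lifespan = pm.generate_cohort(params, n_per_sex=(15, 14), master_seed=1)
maps = pm.noisy_gm_maps(lifespan, seed=1)      # template-space GM maps

loocv = pm.loocv_brainage(maps, lifespan.metadata, mask, vs)
print(f"r = {loocv.r:.2f}, MAE = {loocv.mae:.2f} years")
# r = 0.97, MAE = 0.91 years

# young-adult experiment: 5 CTR / 5 MNR females (programmed GM deficit)
exp = pm.generate_experiment_cohort(params, n_per_cell=(5, 5, 0, 0),
                                    master_seed=2)
res, _ = pm.apply_trained_model(maps, lifespan.metadata,
                                pm.noisy_gm_maps(exp, seed=2),
                                exp.metadata, mask, vs)
t = res.table
diff, anc = pm.brainage_group_difference(t["score"].to_numpy(),
                                         t["group"].to_numpy(),
                                         t["age"].to_numpy())
print(f"MNR - CTR BrainAGE = {diff:+.2f} y, "
      f"ANCOVA F = {anc.f_stat:.1f}, p = {anc.p_value:.3f}")
```

The LOOCV line says the model explains the programmed aging signal almost
completely under the calibrated noise level; the contrast line recovers the
injected MNR effect — the MNR females' brains look about two and a half
years older than the controls', and the age-adjusted ANCOVA flags the
difference. The numbered scripts in `analysis/` run the same steps as a
narrative (simulate → template → preprocess → brain age → statistics),
writing their tables under `results/`.

A `primage` command-line interface wraps the stages
(`simulate | build-template | preprocess | brainage | stats | run`).

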