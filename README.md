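# survmixer

Pathway-patch gene expression images, a ConvMixer-style survival
classifier, and Grad-CAM based key-pathway discovery.

## The problem

Predicting whether a cancer patient will survive beyond a clinical
horizon (1, 3 or 5 years) from bulk gene expression is hard to do
robustly, and harder still to do interpretably: a classifier over
thousands of genes rarely tells the clinician *which biology* drove a
prediction. `survmixer` approaches both problems by structuralizing
expression into **pathway images**: each curated pathway becomes one
square patch of pixels (its genes in pathway order, zero-padded), patches
tile a small grid, and a compact convolutional network learns one spatial
position per pathway. Because pathways stay spatially localized,
gradient-based attribution maps read out directly as per-pathway
importances.

The package is aimed at computational biologists who have a samples ×
genes expression table, overall-survival follow-up, and a gene-set
collection (GMT), and who want survival classification plus a ranked,
statistically tested list of survival-associated pathways.

## The method

1. **Imaging.** Expression is min-max scaled per gene,
   `x' = (x − x_min)/(x_max − x_min)`. Each pathway's gene vector is
   zero-padded to `s²` values and reshaped row-major into an `s×s` patch;
   patches tile a `g×g` grid row-major (defaults `s = g = 7`, giving
   49×49 images). Grid slots beyond the last pathway are *blank patches*,
   held at zero and masked out of the model.
2. **Labeling.** A sample is labeled 0 if it survived strictly beyond the
   horizon, 1 if death occurred within it; samples censored before the
   horizon are unlabelable and dropped.
3. **Model.** A patch-embedding convolution (kernel = stride = `s`) maps
   each patch to one position of a `C×g×g` feature map; `B` mixer blocks
   follow (depthwise 3×3 convolution with residual connection, then
   pointwise 1×1 convolution, each with GELU + batch norm); blank
   positions are re-zeroed after every stage; global average pooling, a
   linear unit and a sigmoid produce `P(death within horizon)`. Training
   minimizes binary cross-entropy with Adam. The network is implemented
   directly in NumPy with a hand-written backward pass.
4. **Validation.** Repeated stratified k-fold cross-validation (default
   5×10) reporting AUC per fold, plus scoring of an untouched external
   cohort in every fold.
5. **Interpretation.** Grad-CAM at the final block: channel importances
   `α_n = (1/Z) Σ_ij ∂y/∂A^n_ij` (`y` the pre-sigmoid score, `Z = g²`),
   activation map `ReLU(Σ_n α_n A^n)`. Per pathway, a two-sided Wilcoxon
   rank-sum test compares activations between label groups with
   Bonferroni correction; key pathways are then validated by GSVA
   scoring, median split, Kaplan–Meier curves and a log-rank test.

A synthetic-data generator produces cohorts with known pathway-level
hazard signal (latent pathway activities → member-gene expression;
exponential survival times with log-hazard linear in the designated
effect pathways' mean activity; calibrated uniform censoring), so the
whole chain is testable end to end without any data download.

## Worked example

```python
import numpy as np
import survmixer as sm

# generate a cohort with a planted two-pathway survival signal
spec = sm.SyntheticSpec(n_samples=400, seed=1)
collection = sm.generate_collection(spec)
cohort = sm.generate_cohort(spec, collection)

# images + labels for the 3-year horizon
images = sm.build_images(cohort.expression, collection)
labeled = sm.label_samples(cohort.records, horizon=3.0)
idx = {s: i for i, s in enumerate(images.sample_ids)}
rows = [idx[s] for s in labeled.sample_ids]
x, y = images.images[rows], np.array(labeled.labels)
print(f"image tensor: {x.shape}, kept {labeled.n_kept} of {spec.n_samples} "
      f"samples ({len(labeled.dropped)} unlabelable), {y.mean():.0%} died within 3y")

# cross-validated discrimination
cfg = sm.ModelConfig(channels=16, epochs=12, learning_rate=3e-3)
result = sm.repeated_cv(x, y, images.layout, sm.default_model_factory(cfg),
                        k=5, repeats=1, seed=1)
print(f"5-fold internal AUC: {result.internal_mean:.3f} +/- {result.internal_sd:.3f}")

# train a final model and interrogate it
model, _ = sm.train_model(x, y, cfg, images.layout)
report = sm.find_key_pathways(model, x, y, labeled.sample_ids,
                              cohort.expression, collection, cohort.records, seed=1)
planted = cohort.truth()["effect_pathway_names"]
print(f"planted pathways: {planted}")
for p in planted:
    row = report.tests.loc[p]
    print(f"  {p}: corrected p = {row.corrected_p:.2e}, "
          f"median-split log-rank p = {report.km[p]['logrank_p']:.2e}")
```

Output:

```
image tensor: (375, 49, 49), kept 375 of 400 samples (25 unlabelable), 50% died within 3y
5-fold internal AUC: 0.825 +/- 0.059
planted pathways: ['PW000', 'PW001']
  PW000: corrected p = 9.40e-32, median-split log-rank p = 1.86e-20
  PW001: corrected p = 2.12e-36, median-split log-rank p = 2.09e-11
```

The 49×49 tensor holds one pathway image per labeled sample (25 of 400
were censored before 3 years and dropped). Cross-validated AUC 0.825
approaches this generator's irreducible ceiling (survival times are
drawn from an exponential around the latent hazard, so even the true
latent score only reaches ≈0.87 here). Both planted pathways are
recovered by the interpretation chain with overwhelming significance,
and their GSVA median splits separate survival sharply.

A command-line interface mirrors the same workflow
(`survmixer simulate | build-images | label | validate | train |
interpret | run`); see `survmixer --help`.

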