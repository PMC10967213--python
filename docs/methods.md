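# Methods

This note records the modeling choices, conventions and numerical
decisions behind `survmixer`, and what the synthetic experiments do and
do not demonstrate.

## Pathway images

Expression is renormalized per gene over samples with min-max scaling.
A gene constant across samples has zero range; it maps to all-zeros
rather than being dropped, so the image geometry never depends on the
data. Normalization is idempotent, and each dataset (training, external)
is normalized independently by default — cohorts from different
platforms arrive differently preprocessed, and per-dataset scaling is
what makes them comparable at all. `build_images(..., normalize=True)`
applies scaling in place for callers that skip the explicit step.

Patch fill and patch placement are both **row-major**; this scan order
is a convention (any fixed order works), pinned by an inverse-lookup
oracle in the tests: reading a patch back out of the image must
reproduce the padded pathway vector bit-exactly. Genes listed in a
pathway but absent from the matrix contribute zero at their position —
inside-patch zeros are real pixels that participate in training, unlike
blank patches. Genes in the matrix but in no pathway are ignored.
Geometry is parameterized (`patch_side`, `grid_side`, defaults 7/7) so
tests can run tiny layouts; sizing violations raise with the minimum
geometry that would fit.

## Labeling

The three-way rule — survived strictly beyond the horizon → 0, death
within it → 1, censored within it → dropped — treats the boundary
`os_time == horizon` as *not* beyond: an observed death at exactly the
horizon is a positive, a censoring there is unlabelable. The strictness
is configurable (`survive_strictly`). Horizon presets short/mid/long map
to 365/1095/1825 days; times and horizon must share a unit, and a
heuristic warns when the median observed time is more than 20× below
the horizon (a years-vs-days tell).

## Network

The depthwise convolution uses **stride 1 with same padding**. A strided
depthwise convolution cannot simultaneously keep the `g×g` feature-map
shape that the blank-slot mask and the per-slot Grad-CAM readout
require, so shape preservation wins; the stride remains configurable and
the residual connection is skipped automatically if a non-default
stride changes the shape.

Blank slots are re-zeroed **after the embedding and after every block**,
not only before the head. Same-padding depthwise convolutions mix
neighboring grid positions, so masking only at the head would let blank
content leak into neighbors' features. Re-masking at every stage makes
the output provably independent of anything written inside blank
patches (the tests assert invariance to 1e-6; measured deltas are
exactly 0 because blank content is annihilated before any spatial
mixing).

Remaining choices, unconstrained by the architecture itself and
recorded in `ModelConfig`: GELU activations with conv → activation →
norm ordering (the ConvMixer convention); no second residual around the
pointwise convolution; global average pooling divides by all `g²`
positions (zeros included), with `pool_nonblank_only` to average over
pathway slots only; a single linear unit between pooling and the
sigmoid (pooling straight into a sigmoid has no trainable class
boundary); binary cross-entropy, Adam at lr 1e-3, batch size 32,
50 epochs as training defaults. Batches of size 1 are skipped (batch
norm needs ≥2 samples).

After the optimization loop, batch-norm running statistics are
**re-estimated on the full training set with the final weights**
(one training-mode pass with momentum 1). Momentum-averaged statistics
collected during short training runs lag the fast-moving weights, which
systematically distorted eval-mode predictions in cross-validation; the
recalibration pass makes eval statistics self-consistent and is
deterministic.

Everything is NumPy with a hand-written backward pass; the same
backward machinery supplies Grad-CAM's gradients, cross-checked against
central finite differences in the tests.

## Validation

Folds are **stratified** (an unstratified fold can lack a class, making
AUC undefined) and the model is re-initialized and retrained per fold.
One master seed spawns per-repeat shuffle seeds and per-fold init seeds
via `numpy.random.SeedSequence`; all are recorded in the result, so a
run is exactly reproducible. External cohorts are scored inside every
fold but never touched by training.

## Interpretation

Grad-CAM is computed at the **masked output of the final block** by
default (configurable by stage name). Maps target the death class for
every sample and are grouped by ground-truth label afterward; the
survival class simply flips the gradient sign. After the
non-overlapping embedding, one grid position is one pathway, so the
per-pathway statistic is the map value at the pathway's slot; blank
slots are excluded.

The rank test is the two-sided Wilcoxon rank-sum (Mann–Whitney): exact
enumeration when both groups have ≤10 tie-free values, otherwise the
normal approximation with continuity and tie correction. Bonferroni
multiplies raw p-values by the number of tested pathways (capped at 1);
the significance flag uses the corrected value at α = 0.05, and both
raw and corrected values are always reported.

GSVA scores come from `gseapy.gsva` (the rank-based per-sample
enrichment method itself); the package pins its contract — rank-extreme
samples score maximal, random gene sets center near zero, duplicated
samples duplicate columns — rather than its kernel internals. Member
genes missing from the matrix are dropped with a warning; a pathway
with no matched genes gets NaN scores and is flagged. Median splits put
ties in the low group; a degenerate split (constant scores) is an
error. Kaplan–Meier curves and the log-rank test use `lifelines`,
cross-checked in the tests against a hand-written risk-set oracle.

## Synthetic cohorts

The generator emulates what the pipeline assumes of real data: pathway-
structured co-expression (per-sample latent activity `a_p ~ N(0,1)`
driving member genes with Gaussian noise, then min-max scaling),
survival `T ~ Exponential(λ)` with
`log λ = log λ₀ + β · mean(a_p over effect pathways)`, and independent
uniform censoring whose upper bound is bisected to hit the requested
rate. Defaults: 400 samples, 40 pathways of 3–46 genes, two effect
pathways, β = 2, noise sd 0.3, λ₀ = 0.2/year, 20% censoring, 3-year
horizon (≈50% positives). Pathways are gene-disjoint by default for
clean ground truth; `overlap_fraction` emulates curated-collection
overlap.

What passing tests show: the geometry, gradients and statistics are
exactly right, and a genuine pathway-level hazard signal is recovered
end to end. What they do not show: robustness to platform batch
effects, non-exponential hazards, or correlated pathway activities —
the generator has none of these.

**An irreducible ceiling.** With exponential survival noise the binary
label is stochastic even given the true latent score: at the default
conditions the Bayes-optimal AUC (the true latent score against the
realized labels, measured by Monte-Carlo) is ≈0.87, and no classifier
can beat it. Measured 5-fold AUC of ≈0.81–0.83 should be read against
that ceiling, not against 1.0. Pushing the ceiling to 0.9+ requires
severely imbalanced conditions (≳74% deaths), which we do not consider
a realistic default.

**Experiment sizes.** The synthetic recovery experiments in the tests
and `scripts/acceptance.py` use a 16-channel, 12-epoch model
(lr 3e-3) rather than the 256-channel default: at 400 samples the wider
model only overfits, and the narrow one trains in ~2 s while reaching
the same discrimination. The data conditions — not the model width —
are what the experiments pin down.

## Known limitations

- Results depend on the gene order serialized in the GMT; no canonical
  KEGG order is assumed or recovered.
- No gene-identifier mapping: symbols are matched case-sensitively
  after whitespace stripping.
- The classifier is a fixed-horizon binary model, not a time-to-event
  regressor; competing risks are out of scope.
- Training is CPU-bound NumPy: fine for hundreds of samples and ≤256
  channels, not for GPU-scale sweeps.
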