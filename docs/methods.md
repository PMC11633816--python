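# Methods

## The procedure

`segsense` implements a four-stage sensitivity-analysis loop for
segmentation-model development under small-data constraints:

1. **Declare** a hyperparameter space: a base grid of candidate-value lists
   plus, per loss function, a conditional sub-grid of loss-specific
   parameters that only expands under its parent loss. Expansion is the
   Cartesian product in declared order, so the trial count is
   `prod(|base_i|) * sum_losses prod(|cond_lj|)` and two expansions of the
   same declaration enumerate identically. Trial ids are content hashes of
   the configuration, so ledgers from resumed or merged sweeps join stably.
2. **Train** every combination under leave-one-out cross-validation: per
   fold, overlap-constrained patches are sampled fresh from the training
   patients, optionally augmented, and a learner is refined for a fixed
   epoch budget. Early stopping and learning-rate decay are deliberately
   absent: they would make per-epoch trajectories incomparable across the
   grid and multiply the searched space.
3. **Log** the full metric suite after every epoch, for the training patches
   and for the held-out patients' complete slices, into an append-only
   long-format ledger keyed by (trial, fold, epoch, split, metric).
   Validation is always evaluated on whole slices, not patches, because that
   is what the held-out patient contributes in deployment. A learner failure
   becomes a flagged row (`diverged = 1`, metrics NaN), not a crash —
   divergence is data.
4. **Condense** the ledger per target metric into relative hyperparameter
   importance via repeated random-forest regression, and epoch curves with
   bootstrap bands.

## Synthetic phantom cohort

The generator emulates the statistical structure of a multi-scanner
abdominal CT cohort with organ masks, at desk scale:

- **Geometry per slice.** Class 2 ("liver"-like) is a single smooth blob
  (union of two jittered ellipses, semi-axes 0.18–0.24 of the slice side);
  class 1 ("bone"-like) is a thin annulus (ring radius 0.28–0.33 of the
  side, 1.6 px thick) plus 2–4 small discs. Every slice therefore satisfies
  `count(background) > count(liver) > count(bone)`, the class-imbalance
  ordering that makes background-aware metric aggregation meaningful, and
  background always exceeds half the pixels. Positions and sizes jitter per
  slice and per patient.
- **Intensities.** Class-conditional Gaussians in arbitrary HU-like units
  (background −50, liver-like 80, bone-like 400), a per-patient global
  offset with SD 40 (the scanner/protocol-drift analog), and additive
  acquisition noise: the per-pixel SD is `noise_sd` (default 15) scaled by a
  per-class factor (1.0 / 2.0 / 1.33), so `noise_sd = 0` is an exact
  noiseless limit. The means are well separated relative to the noise —
  separable but non-trivial for a small learner — while the patient offset
  is large enough that ignoring it measurably degrades held-out
  performance.
- **Scale.** Default 10 patients, 4–8 slices each, 64×64 px. This keeps the
  full 16-trial LOO sweep in CPU minutes while preserving the 10-patient
  LOO fold structure of a realistic small study.
- **Determinism.** `(seed, patient_index)` keys a dedicated RNG stream per
  patient, so cohorts are bit-identical across reruns and patients are
  independent of cohort size.

What the phantoms do **not** emulate: anatomical shape realism, 3D organ
continuity across slices, tumors or lesions, partial-volume effects, and
non-Gaussian CT noise. Passing tests on phantoms therefore demonstrate that
the *harness and analysis* behave correctly on data with the right
imbalance, drift and noise structure — not that any particular model will
segment real CT well.

DICOM export writes one signed 16-bit image series plus one 0/1 mask series
per foreground class per patient (`image/`, `mask_<class>/`), with a JSON
manifest; ingest merges binary masks into a mutually exclusive label volume.
When two masks claim a pixel, the class listed later in `class_order` wins —
declare small structures after large ones so they are not swallowed. Any
nonzero mask value counts as foreground, which tolerates both 0/1 and 0/max
mask encodings in the wild.

## Patch sampling and augmentation

Patches (default eight per slice at case-study scale, four 32 px patches at
desk scale) are drawn uniformly from the offsets whose window overlaps at
least one foreground pixel: rejection sampling with a 100-try cap, then
exact enumeration of the feasible offset set via a summed-area table. No
minimum foreground fraction is enforced — a patch may contain a single
foreground pixel — and offsets are drawn with replacement. All-background
slices are skipped.

The augmentation policy applies four transforms, each independently with
probability 0.25 (one per patch in expectation), in fixed order for
reproducibility: 10% downscale (resample to 0.9× linear scale and back,
quality-degradation semantics), motion blur (3–7 px line kernel at 0/45/90/
135°), Gaussian blur (σ matched to the same kernel span), and rotation drawn
uniformly in ±10°. Geometric transforms move image and labels together with
nearest-neighbour label interpolation (no interpolation-created classes);
blurs touch the image only. Rotation fills with the configured background
value.

## The reference learner

The framework-free learner is a per-pixel Gaussian class-conditional
intensity classifier: running per-class mean/variance and priors, refined
once per epoch toward the empirical statistics of the training pixels, with
Bayes-rule prediction normalized by a SoftMax. It exists so the entire
pipeline — and its sensitivity analysis — runs with no deep-learning
dependency, and its hyperparameter semantics are designed to be mechanistic
rather than cosmetic:

- **learning rate × optimizer** set the per-epoch step
  `η = clip(lr · 100 · gain, 0.05, 1)` toward the empirical statistics
  (gain 1.0 for Adam-family, 0.9 RMSprop, 0.7 Adagrad, 0.5 SGD), so low
  rates genuinely under-converge within a short epoch budget;
- **batch normalization** toggles per-patient intensity standardization
  (training features are z-scored against their source patient's pooled
  patch statistics; prediction z-scores the held-out stack against its own).
  Because the phantoms carry per-patient scanner drift, this normalization
  is load-bearing: without it the held-out patient's offset shifts every
  class relative to the learned means;
- **dropout** discards that fraction of training pixels each epoch — a
  regularization analog with a deliberately small effect, mirroring its
  marginal role in small-data segmentation;
- **augmentation** is applied upstream by the harness.

Initialization perturbs the global intensity statistics with a small seeded
0.1-SD random offset (a random-init analog); keeping the perturbation small
keeps initialization a minor axis rather than an accidental driver of the
sensitivity analysis.

## The planted-effect demonstration grid

`desk_scale_grid()` (16 trials) is constructed the way a method-validation
experiment should be: one axis — batch normalization — has a known,
mechanistically planted effect (the scanner-drift standardization above),
while the other axes are deliberately placed in the learner's inert regimes
(both learning rates reach the clipped full step, both optimizers share gain
1.0, dropout only subsamples an abundant pixel pool). The sensitivity
analysis therefore has a ground truth to recover, and recovering it —
batch normalization top-ranked for foreground DSC — is the package's
end-to-end correctness check. `paper_scale_grid()` separately ships the
case-study axis values (3 learning rates × 3 dropouts × 2 optimizers ×
2 batch-norm × 2 augmentation = 72 generic combinations, plus combo-loss
weights 0.05/0.20); at those values learning rate is *not* inert for the
reference learner, which is expected — axis importance is a joint property
of learner and grid, which is the method's own point.

## Losses and metrics: numerical choices

- Losses use soft (probabilistic) confusion sums for differentiability, an
  additive smoothing constant ε = 1e−6 by default, and an unweighted mean
  over all classes including background (configurable). The family
  identities — F-beta(β=1) ≡ Dice, Tversky(0.5, 0.5, γ=1) ≡ Dice,
  J = D/(2−D) — hold to 1e−12 and are enforced by tests.
- Hard metrics are computed on the argmax of the SoftMax output; ties break
  toward the lowest class index (numpy argmax semantics), deterministically.
  Accuracy and categorical accuracy coincide after hard argmax and are both
  logged for schema completeness.
- 0/0 metric cells (e.g. precision with no declared positives) are reported
  as NaN and excluded from means by default; a strict mode scores them 0.
  Silent zeros would mask the conservative-model pathology the dual
  background means exist to expose.
- The per-epoch metric vocabulary is fixed and versioned
  (`segsense.metrics.metric_schema`): accuracy, categorical accuracy, and
  per-class + both-mean variants of Dice, Jaccard, precision and recall,
  plus any requested loss values — 36 names for three classes before loss
  columns, documented rather than forced to any particular count.

## Importance analysis

One response per (trial, fold): by default the target metric's value at the
final recorded epoch of the validation split (per-epoch pooling is available
behind a flag). Categorical and boolean hyperparameters are ordinally
encoded in order of first appearance — the grid's declared order, since
expansion is deterministic; a missing conditional parameter encodes as −1;
constant columns are dropped with a warning. Importances are the forest's
normalized impurity importances (non-negative, sum to 1); permutation
importance is available as a cross-check method. The settings sweep (depth
{5, 10, 50} × trees {100, 1000, 5000}, nine seeded fits) yields the
mean ± SD shown in reports. Known caveats, flagged in the report output:
ordinal encoding makes tree importances encoding-dependent, and coupled
metrics (Dice/Jaccard are monotone transforms of each other) necessarily
yield near-identical rankings, so conclusions should rest on independent
metrics.

## Bootstrap intervals

Epoch-curve bands are percentile bootstraps of the fold-mean (default 2000
resamples, 95% level), resampling folds with replacement — the appropriate
design when each fold contributes exactly one series. A known limitation of
the percentile method is anti-conservative coverage at very small fold
counts such as the 10 folds of a 10-patient LOO; the package's coverage
validation therefore runs in the many-fold regime where the method's
asymptotics apply, and interval widths at LOO scale should be read as
indicative rather than exact. With a single fold the interval is degenerate
and flagged.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at desk
scale: 10 phantom patients of 4–8 slices at 64×64 px, 16 trials, LOO-CV,
5 epochs, 4 patches of 32×32 px per slice — about 30 seconds of CPU for the
sweep — plus a 500-replicate coverage simulation at 100 folds and the
case-study planning arithmetic (658 trials × 20 patients; 6571 realized
folds × 10 epochs). These sizes were chosen so a full verification pass
stays in the minutes range on one core while exercising every stage at the
fold structure of the real study.

## Known limitations

- The reference learner is intensity-only; it cannot represent spatial
  context, so hyperparameters whose benefit is spatial (e.g. augmentation)
  have intrinsically small effects on phantoms with class-separable
  intensities. Use the U-net backend for spatially realistic studies.
- Impurity-based importance attributes *variance explained*, not causal
  effect, and inert axes still receive a noise floor of importance when the
  planted effect is moderate.
- LOO-CV fold counts make bootstrap bands approximate (see above).
- Phantom realism limits are listed in the phantom section; none of the
  shipped numbers are claims about real CT cohorts.
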