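# segsense

Grid-search hyperparameter sensitivity analysis for dataset-constrained
multiclass semantic segmentation.

## Who this is for

Small clinical and research groups routinely build organ-segmentation models
from cohorts of a few dozen patients. At that scale the choice of training
hyperparameters — learning rate, dropout, optimizer, batch normalization,
augmentation, loss function — can matter as much as the architecture, and
fully automated optimizers (Bayesian, evolutionary, self-configuring
networks) are usually out of computational reach. `segsense` operationalizes
the pragmatic alternative: declare a hyperparameter grid, train every
combination under leave-one-out cross-validation (LOO-CV), log every metric
every epoch into a long-format ledger, and condense the resulting mass of
numbers into *relative hyperparameter importance* per target metric with a
repeated random-forest regression.

Everything is testable on a laptop CPU: the package ships a synthetic
CT-phantom generator that reproduces the statistical structure of real
abdominal CT cohorts (background-dominated slices, a large soft-tissue organ
vs. sparse bright bone, per-patient scanner drift, heterogeneous stack
lengths) and a framework-free reference learner, so the whole pipeline runs
end to end in minutes with no data download and no deep-learning dependency.
A small U-net backend (`segsense.unet`, optional `torch` extra) honours the
same learner contract for real training runs.

## The statistics at the core

All segmentation losses are soft (probabilistic) members of one family.
With per-class probabilistic counts TP, FP, FN and smoothing ε:

- **Dice loss** `1 − mean_c (2·TP + ε)/(2·TP + FP + FN + ε)`
- **Jaccard loss** `1 − mean_c (TP + ε)/(TP + FP + FN + ε)`, with
  `J = D/(2 − D)` per class
- **Tversky / focal Tversky** `mean_c (1 − TI_c)^γ`,
  `TI = (TP + ε)/(TP + α·FP + β·FN + ε)`; α = β = 0.5, γ = 1 recovers Dice
- **F-beta ("recall-favored") loss**
  `1 − mean_c ((1+β²)·TP + ε)/((1+β²)·TP + β²·FN + FP + ε)`; β = 1 is
  Dice/F1, β = 0 is precision, β → ∞ approaches recall
- **combo loss** `w·CCE + (1 − w)·Dice` mixing categorical cross-entropy
  with Dice

The evaluation suite logs accuracy, categorical accuracy, and per-class
Dice, Jaccard, precision and recall, each aggregated **including and
excluding background**. The dual means are the point: in background-heavy
images a model that predicts background everywhere posts a high mean
precision *with* background while its foreground-only precision is
undefined (it declares no positives) — the conservative-model pathology the
analysis is designed to expose.

Hyperparameter importance is the normalized impurity importance of a seeded
random-forest regressor fitted to (encoded hyperparameters → one metric's
per-fold response), repeated over a 3×3 grid of forest settings
(depth ∈ {5, 10, 50} × trees ∈ {100, 1000, 5000}) to attach a mean ± SD per
hyperparameter. Epoch curves get percentile-bootstrap 95% bands over folds.

## Worked example

Sixteen trials (2 learning rates × 2 dropouts × 2 optimizers × batch norm
on/off) over a 10-patient phantom cohort, LOO-CV, 5 epochs each, with the
reference learner:

```python
from segsense import (PhantomSpec, generate_cohort, StaticSettings,
                      expand_grid, run_sweep, build_design, importance_sweep)
from segsense.search import desk_scale_grid

cohort = generate_cohort(PhantomSpec(seed=1))
configs = expand_grid(desk_scale_grid(), StaticSettings.desk_scale(epochs=5), seed=1)
ledger = run_sweep(configs, cohort, seed=1, losses_to_log=[])
df = ledger.to_frame()

final = df[(df.metric == "dice_mean_nobg") & (df.split == "validation") & (df.epoch == 5)]
print(final.groupby("batch_normalization").value.mean().round(3))
rep = importance_sweep(build_design(df, "dice_mean_nobg"), seed=1)
for hp in rep.ranking:
    print(f"{hp:20s} {rep.mean[hp]:.3f} +/- {rep.sd[hp]:.3f}")
```

prints

```
batch_normalization
False    0.911
True     0.942

batch_normalization  0.349 +/- 0.008
learning_rate        0.220 +/- 0.011
optimizer            0.218 +/- 0.013
dropout              0.213 +/- 0.008
```

Batch normalization — which in this cohort standardizes away the per-patient
scanner-drift offsets the phantoms deliberately carry — both lifts held-out
foreground DSC (0.942 vs 0.911) and is correctly ranked the most important
hyperparameter, with the deliberately inert axes splitting the remainder.

The same loop is available from the shell:

```bash
segsense synth --n-patients 10 --seed 1 --out cohort/     # DICOM phantom cohort
segsense plan  --grid examples/desk_grid.yaml             # sweep arithmetic only
segsense run   --grid examples/desk_grid.yaml --seed 1 --out ledger.csv
segsense analyze --ledger ledger.csv --metric dice_mean_nobg --out importance.csv
segsense report  --ledger ledger.csv --out report/
```

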