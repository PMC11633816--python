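"""Grid expansion, experiment planning, cross-validation folds, and the
trial-running harness that feeds the results ledger.

The declared hyperparameter space is a dictionary of candidate-value lists
(the base grid) plus, per loss function, a conditional sub-grid of
loss-specific parameters that only expands under its parent loss.  The full
sweep is the Cartesian product of the base axes crossed with each loss's
conditional sub-grid, enumerated in declared order so two expansions of the
same grid are identical.

Every trial x fold trains for a fixed number of epochs with no early
stopping and no learning-rate decay — both are deliberately absent so that
the per-epoch metric trajectories stay comparable across the whole grid —
and appends one long-format row per (epoch, split, metric) to the ledger.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from segsense.ingest import AugmentPolicy, augment_patch, sample_patches
from segsense.learners import GaussianPixelLearner
from segsense.losses import LossParams
from segsense.metrics import epoch_suite, metric_schema
from segsense.phantoms import LabeledVolume

__all__ = [
    "HyperGrid",
    "StaticSettings",
    "TrialConfig",
    "FoldPlan",
    "PlanSummary",
    "ResultsLedger",
    "expand_grid",
    "plan_counts",
    "make_folds",
    "run_trial",
    "run_sweep",
]

logger = logging.getLogger(__name__)

#: ledger columns that are not hyperparameters
LEDGER_INDEX_COLUMNS = ("trial_id", "fold_id", "epoch", "split")

LOSS_AXIS = "loss_function"


@dataclasses.dataclass(frozen=True)
class HyperGrid:
    """Declared hyperparameter space.

    ``base`` maps each varied hyperparameter to its candidate list (the loss
    axis, if present, is named ``loss_function``); ``conditional`` maps a
    loss name to its loss-specific sub-grid.
    """

    base: dict[str, list]
    conditional: dict[str, dict[str, list]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, values in self.base.items():
            if not values:
                raise ValueError(f"empty candidate list for {name!r}")
        for loss, sub in self.conditional.items():
            for name, values in sub.items():
                if not values:
                    raise ValueError(f"empty candidate list for {loss}.{name}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HyperGrid":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(base=doc.get("base", {}), conditional=doc.get("conditional", {}))


@dataclasses.dataclass(frozen=True)
class StaticSettings:
    """Hyperparameters held static across the whole sweep."""

    epochs: int = 10
    patch_size: int = 128
    patches_per_slice: int = 8
    initial_filters: int = 32
    unet_depth: int = 4
    activation: str = "relu"
    kernel_initializer: str = "he_normal"
    kernel_size: int = 3
    batch_size: int = 16
    cv_scheme: str = "loo"

    def __post_init__(self) -> None:
        if self.batch_size not in (16, 32):
            raise ValueError("batch_size must be 16 or 32")

    @classmethod
    def desk_scale(cls, epochs: int = 5) -> "StaticSettings":
        """Settings sized for the 64 px phantom cohort (CPU minutes, not GPU weeks)."""
        return cls(epochs=epochs, patch_size=32, patches_per_slice=4)


@dataclasses.dataclass(frozen=True)
class TrialConfig:
    """One concrete hyperparameter combination drawn from the grid."""

    values: dict
    static: StaticSettings
    trial_id: str
    seed: int

    @property
    def loss_name(self) -> str | None:
        return self.values.get(LOSS_AXIS)

    def loss_params(self) -> LossParams:
        keys = ("beta", "alpha_tversky", "beta_tversky", "gamma", "w_cce", "epsilon")
        return LossParams(**{k: self.values[k] for k in keys if k in self.values})


def _content_hash(values: dict, static: StaticSettings) -> str:
    payload = json.dumps({"values": values, "static": dataclasses.asdict(static)},
                         sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def expand_grid(grid: HyperGrid, static: StaticSettings | None = None,
                seed: int = 0) -> list[TrialConfig]:
    """Expand the declared grid into concrete trial configurations.

    Full Cartesian product over base axes, crossed with the conditional
    sub-grid of each loss value; enumeration is lexicographic in declared
    name/value order, so the count is
    ``prod(|base_i|) * sum_losses prod(|cond_lj|)`` when a loss axis is
    present, and expansion order is a stable function of the declaration.
    """
    static = static or StaticSettings()
    names = list(grid.base)
    configs: list[TrialConfig] = []
    for combo in itertools.product(*(grid.base[n] for n in names)):
        values = dict(zip(names, combo))
        sub = grid.conditional.get(values.get(LOSS_AXIS), {})
        sub_names = list(sub)
        for sub_combo in itertools.product(*(sub[n] for n in sub_names)):
            full = {**values, **dict(zip(sub_names, sub_combo))}
            configs.append(TrialConfig(values=full, static=static,
                                       trial_id=_content_hash(full, static),
                                       seed=seed))
    return configs


def paper_scale_grid() -> HyperGrid:
    """The case-study grid: five generic axes plus loss-specific sub-grids.

    The base axes (3 learning rates x 3 dropouts x 2 optimizers x 2
    batch-norm x 2 augmentation = 72 combinations) are crossed with each
    loss's conditional parameters; only the combo-loss weights visible in the
    study captions are shipped, other loss-specific lists are user-supplied.
    """
    return HyperGrid(
        base={
            "learning_rate": [0.001, 0.005, 0.01],
            "dropout": [0.1, 0.3, 0.5],
            "optimizer": ["adam", "rmsprop"],
            "batch_normalization": [True, False],
            "augmentation": [True, False],
        },
        conditional={"ComboLoss": {"w_cce": [0.05, 0.20]}},
    )


def desk_scale_grid() -> HyperGrid:
    """16-trial planted-effect demonstration grid for the phantom cohort.

    Batch normalization is the planted dominant axis (it standardizes away
    the phantoms' per-patient scanner drift); the other axes are deliberately
    chosen in their inert regimes — both learning rates reach the full
    per-epoch step, both optimizers have identical gain, dropout only
    subsamples training pixels — so the sensitivity analysis has a known
    ground truth to recover.
    """
    return HyperGrid(base={
        "learning_rate": [0.01, 0.02],
        "dropout": [0.0, 0.3],
        "optimizer": ["adam", "weighted_adam"],
        "batch_normalization": [True, False],
    })


@dataclasses.dataclass(frozen=True)
class PlanSummary:
    """Closed-form experiment size: no I/O, just the sweep arithmetic."""

    n_trials: int
    n_patients: int
    folds_total: int
    epochs_total: int
    effective_patients: int


def plan_counts(n_trials: int, n_patients: int, cv_scheme: str = "loo",
                epochs_per_fold: int = 10, folds_total: int | None = None) -> PlanSummary:
    """Plan the sweep size before running anything.

    ``effective_patients = n_trials * n_patients`` (every patient is
    re-trained on once per trial) and ``epochs_total = folds_total *
    epochs_per_fold``.  ``folds_total`` defaults to the scheme arithmetic
    (LOO: one fold per patient per trial; ``kfold(k)``: k per trial) but can
    be given directly, e.g. when quoting a realized sweep in which some folds
    were skipped.
    """
    if n_trials <= 0 or n_patients <= 0 or epochs_per_fold <= 0:
        raise ValueError("counts must be positive")
    if folds_total is None:
        if cv_scheme == "loo":
            folds_per_trial = n_patients
        elif cv_scheme.startswith("kfold"):
            folds_per_trial = int(cv_scheme.split("(")[1].rstrip(")"))
        else:
            raise ValueError(f"unknown cv scheme {cv_scheme!r}")
        folds_total = n_trials * folds_per_trial
    return PlanSummary(
        n_trials=n_trials,
        n_patients=n_patients,
        folds_total=folds_total,
        epochs_total=folds_total * epochs_per_fold,
        effective_patients=n_trials * n_patients,
    )


@dataclasses.dataclass(frozen=True)
class FoldPlan:
    """Ordered (train, validation) patient-id partitions."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    scheme: str
    seed: int

    def __iter__(self):
        return iter(self.folds)

    def __len__(self) -> int:
        return len(self.folds)


def make_folds(patient_ids: Sequence[str], scheme: str = "loo", seed: int = 0) -> FoldPlan:
    """Build a cross-validation fold plan.

    LOO: one fold per patient, training on all others.  ``kfold(k)``: a
    seeded shuffle split into k near-equal validation groups.  Validation
    sets partition the cohort in both schemes.
    """
    ids = list(patient_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 patients")
    if scheme == "loo":
        folds = tuple(
            (tuple(p for p in ids if p != held), (held,)) for held in ids
        )
    elif scheme.startswith("kfold"):
        k = int(scheme.split("(")[1].rstrip(")"))
        if k > len(ids):
            raise ValueError(f"k={k} exceeds {len(ids)} patients")
        order = list(np.random.default_rng(seed).permutation(ids))
        groups = [tuple(order[i::k]) for i in range(k)]
        folds = tuple(
            (tuple(p for p in ids if p not in g), g) for g in groups
        )
    else:
        raise ValueError(f"unknown cv scheme {scheme!r}")
    return FoldPlan(folds=folds, scheme=scheme, seed=seed)


class ResultsLedger:
    """Append-only long-format per-epoch metrics table.

    One row per (trial, fold, epoch, split, metric); hyperparameter columns
    repeat on every row of a trial so the table is self-describing and feeds
    the importance analysis directly.
    """

    def __init__(self, hyperparameter_names: Sequence[str]) -> None:
        self.hyperparameter_names = list(hyperparameter_names)
        self._rows: list[dict] = []
        self._seen: set[tuple] = set()

    def append_epoch(self, trial: TrialConfig, fold_id: int, epoch: int, split: str,
                     metrics: dict[str, float]) -> None:
        hp = {name: trial.values.get(name) for name in self.hyperparameter_names}
        for metric, value in metrics.items():
            key = (trial.trial_id, fold_id, epoch, split, metric)
            if key in self._seen:
                raise ValueError(f"duplicate ledger row {key}")
            self._seen.add(key)
            self._rows.append({
                "trial_id": trial.trial_id,
                "fold_id": fold_id,
                "epoch": epoch,
                "split": split,
                **hp,
                "metric": metric,
                "value": value,
            })

    def to_frame(self) -> pd.DataFrame:
        cols = [*LEDGER_INDEX_COLUMNS, *self.hyperparameter_names, "metric", "value"]
        return pd.DataFrame(self._rows, columns=cols)

    def validate(self) -> None:
        """Check row uniqueness and hyperparameter-column constancy per trial."""
        df = self.to_frame()
        if df.duplicated(subset=[*LEDGER_INDEX_COLUMNS, "metric"]).any():
            raise ValueError("duplicate (trial, fold, epoch, split, metric) rows")
        for hp in self.hyperparameter_names:
            if (df.groupby("trial_id")[hp].nunique(dropna=False) > 1).any():
                raise ValueError(f"hyperparameter column {hp!r} varies within a trial")

    def to_csv(self, path: str | Path) -> None:
        """Crash-safe persist: write to a temp file, then atomic rename."""
        path = Path(path)
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".csv.tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                self.to_frame().to_csv(fh, index=False)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise

    @classmethod
    def from_csv(cls, path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path)


def _fold_rng(config: TrialConfig, fold_id: int) -> np.random.Generator:
    key = int(config.trial_id[:8], 16)
    return np.random.default_rng(np.random.SeedSequence((config.seed, key, fold_id)))


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes)[labels]


def run_trial(config: TrialConfig, cohort: Iterable[LabeledVolume], folds: FoldPlan,
              learner_factory: Callable | None = None,
              ledger: ResultsLedger | None = None,
              losses_to_log: Sequence[str] | None = None) -> ResultsLedger:
    """Train one trial over all folds, appending per-epoch rows to the ledger.

    Per fold: patches are sampled fresh from the training patients (and
    augmented iff the trial's ``augmentation`` flag is set), the learner is
    refined for the static epoch budget, and after every epoch the full
    metric suite is evaluated on the training patches and on the held-out
    patients' complete slices.  All randomness derives from
    ``(config.seed, trial_id, fold_id)`` so reruns are bit-identical.

    A learner failure is recorded as a flagged epoch row (all metrics NaN,
    ``diverged`` = 1) rather than raised: divergence is data.
    """
    cohort = list(cohort)
    by_id = {v.patient_id: v for v in cohort}
    n_classes = cohort[0].n_classes
    if ledger is None:
        ledger = ResultsLedger(sorted(config.values))
    static = config.static
    losses_to_log = list(losses_to_log if losses_to_log is not None
                         else ([config.loss_name] if config.loss_name else []))
    factory = learner_factory or (lambda cfg, k, seed: GaussianPixelLearner(cfg, k, seed))
    schema = metric_schema(n_classes, losses_to_log)

    for fold_id, (train_ids, val_ids) in enumerate(folds):
        rng = _fold_rng(config, fold_id)
        fold_seed = int(rng.integers(0, 2**31))
        patches = []
        for pid in train_ids:
            patches.extend(sample_patches(by_id[pid], static.patches_per_slice,
                                          static.patch_size, rng))
        if config.values.get("augmentation"):
            policy = AugmentPolicy(seed=fold_seed)
            patches = [augment_patch(p, policy, rng) for p in patches]
        learner = factory(config, n_classes, fold_seed)

        for epoch in range(1, static.epochs + 1):
            try:
                learner.fit_epoch(patches)
                train_imgs = np.stack([p.image_window for p in patches])
                train_truth = _one_hot(
                    np.stack([p.label_window for p in patches]), n_classes)
                train_probs = learner.predict(train_imgs)
                val_probs, val_truth = [], []
                for pid in val_ids:
                    vol = by_id[pid]
                    val_probs.append(learner.predict(vol.image).reshape(-1, n_classes))
                    val_truth.append(_one_hot(vol.labels.ravel(), n_classes))
                params = config.loss_params()
                train_metrics = epoch_suite(train_probs, train_truth,
                                            losses_to_log, params)
                val_metrics = epoch_suite(np.concatenate(val_probs),
                                          np.concatenate(val_truth),
                                          losses_to_log, params)
                train_metrics["diverged"] = 0.0
                val_metrics["diverged"] = 0.0
            except Exception:
                logger.exception("trial %s fold %d epoch %d failed; flagged as diverged",
                                 config.trial_id, fold_id, epoch)
                flagged = {name: float("nan") for name in schema}
                flagged["diverged"] = 1.0
                train_metrics = dict(flagged)
                val_metrics = dict(flagged)
            ledger.append_epoch(config, fold_id, epoch, "train", train_metrics)
            ledger.append_epoch(config, fold_id, epoch, "validation", val_metrics)
    return ledger


def run_sweep(configs: Sequence[TrialConfig], cohort: Iterable[LabeledVolume],
              scheme: str = "loo", seed: int = 0,
              learner_factory: Callable | None = None,
              losses_to_log: Sequence[str] | None = None) -> ResultsLedger:
    """Run every trial of an expanded grid under a shared fold plan."""
    cohort = list(cohort)
    folds = make_folds([v.patient_id for v in cohort], scheme, seed)
    hp_names = sorted({name for c in configs for name in c.values})
    ledger = ResultsLedger(hp_names)
    for config in configs:
        run_trial(config, cohort, folds, learner_factory, ledger, losses_to_log)
    return ledger
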