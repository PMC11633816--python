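"""Random-forest sensitivity analysis of the results ledger.

The ledger is condensed per target metric into a design matrix — one row per
(trial, fold) with numerically encoded hyperparameters and that metric's
response value — and a seeded random-forest regressor attributes the
response variance across hyperparameters via normalized impurity-based
importances.  Repeating the fit over a grid of forest settings (tree depth x
estimator count) turns single-fit importances into a mean +/- SD per
hyperparameter, which is what the reports show as uncertainty.  Epoch
trajectories get percentile-bootstrap confidence bands over folds, the
appropriate choice when each fold contributes exactly one series.

Caveats stated up front: ordinal encoding of categoricals means tree
importances depend on the encoding; impurity importances are the headline
number, with permutation importance available as an optional cross-check;
and mathematically coupled metrics (Dice and Jaccard are monotone
transforms of each other) necessarily produce near-identical rankings, so
conclusions should rest on independent metrics.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

__all__ = [
    "DesignMatrix",
    "ImportanceReport",
    "build_design",
    "fit_importance",
    "importance_sweep",
    "bootstrap_ci",
    "report",
]

DEFAULT_DEPTHS = (5, 10, 50)
DEFAULT_ESTIMATOR_COUNTS = (100, 1000, 5000)


@dataclasses.dataclass
class DesignMatrix:
    """Numerically encoded (trial x fold) hyperparameters plus one response."""

    X: pd.DataFrame
    y: pd.Series
    target_metric: str
    encoding: dict[str, dict]
    dropped_constant: list[str]


def build_design(ledger: pd.DataFrame, target_metric: str,
                 response_epoch_policy: str = "final",
                 split: str = "validation") -> DesignMatrix:
    """Extract a design matrix from a long-format ledger.

    One response per (trial, fold): the target metric at the final recorded
    epoch of the requested split (``response_epoch_policy="final"``, the
    default) or pooled over all epochs (``"all"``).  Categorical and boolean
    hyperparameters are encoded by deterministic ordinal codes in order of
    first appearance (the grid's declared order, since expansion is
    deterministic); a missing conditional value encodes as -1.  Constant
    columns are dropped with a warning.
    """
    if ledger.empty:
        raise ValueError("empty ledger")
    sub = ledger[(ledger["metric"] == target_metric) & (ledger["split"] == split)]
    if sub.empty:
        raise ValueError(f"metric {target_metric!r} absent from split {split!r}")
    if response_epoch_policy == "final":
        last = sub.groupby(["trial_id", "fold_id"])["epoch"].transform("max")
        sub = sub[sub["epoch"] == last]
    elif response_epoch_policy != "all":
        raise ValueError("response_epoch_policy must be 'final' or 'all'")

    incomplete = sub["value"].isna()
    if incomplete.any():
        warnings.warn(f"excluding {int(incomplete.sum())} rows with missing responses "
                      "(diverged or incomplete trials)", stacklevel=2)
        sub = sub[~incomplete]

    reserved = {"trial_id", "fold_id", "epoch", "split", "metric", "value"}
    hp_cols = [c for c in ledger.columns if c not in reserved]
    X = sub[hp_cols].reset_index(drop=True)
    y = sub["value"].reset_index(drop=True).rename(target_metric)

    encoding: dict[str, dict] = {}
    for col in hp_cols:
        series = X[col]
        if series.dtype == object or series.dtype == bool or series.isna().any():
            codes: dict = {}
            for v in series:
                if (v is None or (isinstance(v, float) and np.isnan(v))):
                    continue
                if v not in codes:
                    codes[v] = len(codes)
            encoding[col] = codes
            X[col] = series.map(lambda v, c=codes: c.get(v, -1)
                                if not (v is None or (isinstance(v, float) and np.isnan(v)))
                                else -1).astype(np.int64)
    dropped = [c for c in hp_cols if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant hyperparameter columns {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    return DesignMatrix(X=X, y=y, target_metric=target_metric,
                        encoding=encoding, dropped_constant=dropped)


def fit_importance(design: DesignMatrix, depth: int, n_estimators: int,
                   seed: int = 0, method: str = "impurity") -> pd.Series:
    """Normalized hyperparameter importances from one seeded forest fit.

    ``method="impurity"`` (default) uses the forest's impurity importances;
    ``method="permutation"`` is an optional cross-check that scores columns
    by response degradation under shuffling (renormalized to sum to 1).
    """
    if design.y.nunique() < 2:
        raise ValueError("degenerate response: fewer than 2 distinct values")
    rf = RandomForestRegressor(max_depth=depth, n_estimators=n_estimators,
                               random_state=seed)
    rf.fit(design.X.to_numpy(), design.y.to_numpy())
    if method == "impurity":
        imp = rf.feature_importances_
    elif method == "permutation":
        res = permutation_importance(rf, design.X.to_numpy(), design.y.to_numpy(),
                                     n_repeats=10, random_state=seed)
        imp = np.clip(res.importances_mean, 0.0, None)
    else:
        raise ValueError("method must be 'impurity' or 'permutation'")
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    return pd.Series(imp, index=design.X.columns, name=design.target_metric)


@dataclasses.dataclass
class ImportanceReport:
    """Mean +/- SD importance per hyperparameter over the settings sweep."""

    target_metric: str
    mean: pd.Series
    sd: pd.Series
    ranking: list[str]
    depths: tuple[int, ...]
    estimator_counts: tuple[int, ...]
    n_fits: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "hyperparameter": self.mean.index,
            "mean_importance": self.mean.to_numpy(),
            "sd_importance": self.sd.to_numpy(),
        })


def importance_sweep(design: DesignMatrix,
                     depths: Sequence[int] = DEFAULT_DEPTHS,
                     estimator_counts: Sequence[int] = DEFAULT_ESTIMATOR_COUNTS,
                     seed: int = 0) -> ImportanceReport:
    """Repeat the forest fit over depth x estimator-count settings.

    The default 3 x 3 settings grid yields 9 fits; the spread across them is
    the SD reported per hyperparameter, and the ranking orders the means.
    """
    fits = []
    for i, depth in enumerate(depths):
        for j, n_est in enumerate(estimator_counts):
            fits.append(fit_importance(design, depth, n_est,
                                       seed=seed + i * len(estimator_counts) + j))
    mat = pd.concat(fits, axis=1)
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1) if len(fits) > 1 else mat.iloc[:, 0] * 0.0
    ranking = list(mean.sort_values(ascending=False).index)
    return ImportanceReport(target_metric=design.target_metric, mean=mean, sd=sd,
                            ranking=ranking, depths=tuple(depths),
                            estimator_counts=tuple(estimator_counts),
                            n_fits=len(fits))


def bootstrap_ci(values: np.ndarray, n_boot: int = 2000, level: float = 0.95,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Percentile-bootstrap CI of the fold-mean, per epoch.

    ``values`` is a ``(n_folds, n_epochs)`` array (a 1-D input is read as one
    value per fold at a single epoch); folds are resampled with replacement
    and the interval taken from the percentiles of the resampled means.
    With a single fold the interval is degenerate and a warning is issued.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    n_folds = values.shape[0]
    if n_folds < 2:
        warnings.warn("single fold: degenerate (zero-width) interval", stacklevel=2)
        return values[0].copy(), values[0].copy()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_folds, size=(n_boot, n_folds))
    boot_means = values[idx].mean(axis=1)  # (n_boot, n_epochs)
    alpha = (1.0 - level) / 2.0
    low = np.quantile(boot_means, alpha, axis=0)
    high = np.quantile(boot_means, 1.0 - alpha, axis=0)
    return low, high


#: metric pairs that are monotone transforms of each other; rankings from
#: either member carry the same information
COUPLED_METRIC_STEMS = (("dice", "jaccard"),)


def _coupled_note(metric: str) -> str:
    for a, b in COUPLED_METRIC_STEMS:
        if a in metric or b in metric:
            return f"coupled: {a}/{b} are monotone transforms; prefer independent metrics"
    return ""


def report(importances: dict[str, ImportanceReport], ledger: pd.DataFrame,
           outdir: str | Path, metrics_for_curves: Sequence[str] = (),
           n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Write per-metric importance charts, epoch curves, and a summary table.

    Produces one bar chart (mean importance with SD error bars) per target
    metric, optional per-trial validation epoch curves with bootstrap bands,
    and a machine-readable CSV of means/SDs with a coupling note for
    mathematically interdependent metrics.  Returns the summary table.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for metric, rep in importances.items():
        fig, ax = plt.subplots(figsize=(6, 3.2))
        order = rep.ranking
        ax.bar(range(len(order)), rep.mean[order], yerr=rep.sd[order], capsize=3)
        ax.set_xticks(range(len(order)))
        ax.set_xticklabels(order, rotation=30, ha="right")
        ax.set_ylabel("relative importance")
        ax.set_title(f"hyperparameter importance — {metric}")
        fig.tight_layout()
        fig.savefig(outdir / f"importance_{metric}.svg")
        plt.close(fig)
        for hp in rep.mean.index:
            rows.append({"target_metric": metric, "hyperparameter": hp,
                         "mean_importance": rep.mean[hp], "sd_importance": rep.sd[hp],
                         "note": _coupled_note(metric)})
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "importance_summary.csv", index=False)

    for metric in metrics_for_curves:
        sub = ledger[(ledger["metric"] == metric) & (ledger["split"] == "validation")]
        fig, ax = plt.subplots(figsize=(6, 3.2))
        for trial_id, grp in sub.groupby("trial_id"):
            wide = grp.pivot_table(index="fold_id", columns="epoch", values="value")
            epochs = wide.columns.to_numpy()
            low, high = bootstrap_ci(wide.to_numpy(), n_boot=n_boot, seed=seed)
            mean = wide.to_numpy().mean(axis=0)
            ax.plot(epochs, mean, label=str(trial_id)[:8])
            ax.fill_between(epochs, low, high, alpha=0.2)
        ax.set_xlabel("epoch")
        ax.set_ylabel(metric)
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(outdir / f"curves_{metric}.svg")
        plt.close(fig)
    return table
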