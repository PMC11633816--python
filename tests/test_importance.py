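import numpy as np
import pandas as pd
import pytest

from segsense.importance import (
    bootstrap_ci,
    build_design,
    fit_importance,
    importance_sweep,
    report,
)


def make_ledger(hyper_rows, metric="dice_mean_nobg", n_folds=3, epochs=2,
                response=None, rng=None):
    """Long-format ledger fixture: one trial per hyper_rows entry."""
    rows = []
    for t, hp in enumerate(hyper_rows):
        for fold in range(n_folds):
            for epoch in range(1, epochs + 1):
                for split in ("train", "validation"):
                    value = 0.5
                    if response is not None:
                        value = response(hp, fold, epoch, split, rng)
                    rows.append({"trial_id": f"t{t}", "fold_id": fold, "epoch": epoch,
                                 "split": split, **hp, "metric": metric, "value": value})
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_one_row_per_trial_fold(self):
        ledger = make_ledger([{"lr": v} for v in (0.1, 0.2, 0.3, 0.4)], n_folds=3)
        design = build_design(ledger, "dice_mean_nobg")
        assert len(design.X) == 12 and len(design.y) == 12

    def test_final_epoch_policy_selects_last_epoch(self):
        ledger = make_ledger(
            [{"lr": v} for v in (0.1, 0.2)], epochs=3,
            response=lambda hp, fold, epoch, split, rng: epoch / 10.0)
        design = build_design(ledger, "dice_mean_nobg")
        assert (design.y == 0.3).all()

    def test_categorical_encoding_in_declared_order(self):
        ledger = make_ledger([{"optimizer": "Adam", "x": 0.0},
                              {"optimizer": "RMSProp", "x": 1.0}])
        design = build_design(ledger, "dice_mean_nobg")
        assert design.encoding["optimizer"] == {"Adam": 0, "RMSProp": 1}
        assert set(design.X["optimizer"]) == {0, 1}

    def test_constant_column_dropped_with_warning(self):
        ledger = make_ledger([{"lr": 0.1, "opt": "adam"}, {"lr": 0.2, "opt": "adam"}])
        with pytest.warns(UserWarning, match="constant"):
            design = build_design(ledger, "dice_mean_nobg")
        assert "opt" in design.dropped_constant
        assert list(design.X.columns) == ["lr"]

    def test_absent_metric_raises(self):
        ledger = make_ledger([{"lr": 0.1}])
        with pytest.raises(ValueError, match="absent"):
            build_design(ledger, "hausdorff")

    def test_missing_responses_excluded_with_warning(self):
        ledger = make_ledger([{"lr": 0.1}, {"lr": 0.2}], n_folds=2)
        ledger.loc[(ledger.trial_id == "t0") & (ledger.fold_id == 0) &
                   (ledger.split == "validation"), "value"] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            design = build_design(ledger, "dice_mean_nobg")
        assert len(design.y) == 3


class TestFitImportance:
    def _design(self, response, n=60, seed=0):
        rng = np.random.default_rng(seed)
        hypers = [{"a": float(rng.integers(0, 2)), "b": float(rng.integers(0, 3))}
                  for _ in range(n)]
        ledger = make_ledger(hypers, n_folds=1, epochs=1,
                             response=response, rng=rng)
        return build_design(ledger, "dice_mean_nobg")

    def test_single_driving_column_gets_nearly_all_importance(self):
        design = self._design(lambda hp, f, e, s, rng: hp["a"])
        imp = fit_importance(design, depth=5, n_estimators=200, seed=0)
        assert imp["a"] > 0.95

    def test_pure_noise_splits_importance(self):
        for seed in range(3):
            design = self._design(lambda hp, f, e, s, rng: float(rng.normal()), seed=seed)
            imp = fit_importance(design, depth=5, n_estimators=200, seed=seed)
            assert 0.2 <= imp["a"] <= 0.8

    def test_importances_sum_to_one(self):
        design = self._design(lambda hp, f, e, s, rng: hp["a"] + float(rng.normal(0, 0.1)))
        imp = fit_importance(design, depth=10, n_estimators=100, seed=1)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_response_rejected(self):
        design = self._design(lambda hp, f, e, s, rng: 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            fit_importance(design, depth=5, n_estimators=10)

    def test_permutation_cross_check_agrees_on_planted_axis(self):
        design = self._design(lambda hp, f, e, s, rng: hp["a"])
        imp = fit_importance(design, depth=5, n_estimators=100, seed=0,
                             method="permutation")
        assert imp.idxmax() == "a"


class TestImportanceSweep:
    def test_default_settings_grid_is_nine_fits(self):
        rng = np.random.default_rng(0)
        ledger = make_ledger(
            [{"a": float(i % 2), "b": float(i % 3)} for i in range(12)],
            response=lambda hp, f, e, s, rng_: hp["a"] + np.random.default_rng(
                int(hp["b"] * 7 + f)).normal(0, 0.05), rng=rng)
        design = build_design(ledger, "dice_mean_nobg")
        rep = importance_sweep(design, depths=(2, 3, 4), estimator_counts=(10, 20, 30))
        assert rep.n_fits == 9
        assert rep.mean.sum() == pytest.approx(1.0, abs=1e-9)

    def test_singleton_sweep_has_zero_sd(self):
        ledger = make_ledger(
            [{"a": float(i % 2), "b": float(i)} for i in range(8)],
            response=lambda hp, f, e, s, rng: hp["a"] + hp["b"] / 100)
        design = build_design(ledger, "dice_mean_nobg")
        rep = importance_sweep(design, depths=(5,), estimator_counts=(50,))
        assert (rep.sd == 0).all()
        assert rep.n_fits == 1

    def test_planted_effect_recovery(self):
        # one axis drives the response (effect 0.4 vs noise 0.01)
        rng = np.random.default_rng(7)
        hypers = [{"batch_norm": float(b), "lr": lr, "opt": o}
                  for b in (0, 1) for lr in (0.001, 0.01) for o in ("adam", "rmsprop")]
        ledger = make_ledger(
            hypers, n_folds=5,
            response=lambda hp, f, e, s, r: 0.5 + 0.4 * hp["batch_norm"]
            + float(r.normal(0, 0.01)), rng=rng)
        design = build_design(ledger, "dice_mean_nobg")
        rep = importance_sweep(design, depths=(5, 10), estimator_counts=(50, 100))
        assert rep.ranking[0] == "batch_norm"
        assert rep.mean["batch_norm"] > 0.8


class TestBootstrapCI:
    def test_constant_series_zero_width(self):
        low, high = bootstrap_ci(np.full((6, 4), 0.7), seed=0)
        np.testing.assert_allclose(low, 0.7)
        np.testing.assert_allclose(high, 0.7)

    def test_interval_contains_sample_mean(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (10, 3))
        low, high = bootstrap_ci(x, n_boot=2000, seed=3)
        mean = x.mean(axis=0)
        assert (low <= mean).all() and (mean <= high).all()

    def test_single_fold_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="single fold"):
            low, high = bootstrap_ci(np.array([[1.0, 2.0]]), seed=0)
        np.testing.assert_array_equal(low, high)

    def test_seeded_determinism(self):
        x = np.random.default_rng(0).normal(size=(8, 5))
        assert np.array_equal(bootstrap_ci(x, seed=5)[0], bootstrap_ci(x, seed=5)[0])


class TestReport:
    def test_one_chart_per_metric_and_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        hypers = [{"a": float(i % 2), "b": float(i % 4)} for i in range(8)]
        ledger = make_ledger(hypers, n_folds=3,
                             response=lambda hp, f, e, s, r: hp["a"] + float(r.normal(0, 0.05)),
                             rng=rng)
        reps = {}
        for metric in ("dice_mean_nobg",):
            design = build_design(ledger, metric)
            reps[metric] = importance_sweep(design, depths=(3,), estimator_counts=(25,))
        ledger2 = ledger.copy()
        ledger2["metric"] = "precision_mean_bg"
        both = pd.concat([ledger, ledger2])
        reps["precision_mean_bg"] = importance_sweep(
            build_design(both, "precision_mean_bg"), depths=(3,), estimator_counts=(25,))
        table = report(reps, both, tmp_path, metrics_for_curves=["dice_mean_nobg"])
        assert (tmp_path / "importance_dice_mean_nobg.svg").exists()
        assert (tmp_path / "importance_precision_mean_bg.svg").exists()
        assert (tmp_path / "curves_dice_mean_nobg.svg").exists()
        back = pd.read_csv(tmp_path / "importance_summary.csv")
        pd.testing.assert_frame_equal(
            back[["target_metric", "hyperparameter"]],
            table[["target_metric", "hyperparameter"]].reset_index(drop=True))

    def test_background_variants_can_rank_differently(self, tmp_path):
        # construct a ledger where precision-with-background responds to one
        # axis and precision-without-background to another
        rng = np.random.default_rng(4)
        hypers = [{"a": float(i % 2), "b": float((i // 2) % 2)} for i in range(8)]
        with_bg = make_ledger(hypers, n_folds=4, metric="precision_mean_bg",
                              response=lambda hp, f, e, s, r: 0.9 + 0.05 * hp["a"]
                              + float(r.normal(0, 0.005)), rng=rng)
        no_bg = make_ledger(hypers, n_folds=4, metric="precision_mean_nobg",
                            response=lambda hp, f, e, s, r: 0.4 + 0.3 * hp["b"]
                            + float(r.normal(0, 0.005)), rng=rng)
        ledger = pd.concat([with_bg, no_bg])
        rep_bg = importance_sweep(build_design(ledger, "precision_mean_bg"),
                                  depths=(5,), estimator_counts=(100,))
        rep_nobg = importance_sweep(build_design(ledger, "precision_mean_nobg"),
                                    depths=(5,), estimator_counts=(100,))
        assert rep_bg.ranking[0] == "a"
        assert rep_nobg.ranking[0] == "b"
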