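import itertools

import numpy as np
import pandas as pd
import pytest

from segsense.metrics import metric_schema
from segsense.search import (
    HyperGrid,
    ResultsLedger,
    StaticSettings,
    TrialConfig,
    desk_scale_grid,
    expand_grid,
    make_folds,
    paper_scale_grid,
    plan_counts,
    run_trial,
)


@pytest.fixture
def base_grid():
    return HyperGrid(base={
        "learning_rate": [0.001, 0.005, 0.01],
        "dropout": [0.1, 0.3, 0.5],
        "optimizer": ["adam", "rmsprop"],
        "batch_normalization": [True, False],
        "augmentation": [True, False],
    })


class TestExpandGrid:
    def test_case_study_base_axes_yield_72(self, base_grid):
        assert len(expand_grid(base_grid)) == 3 * 3 * 2 * 2 * 2 == 72

    def test_conditional_subgrids_sum_product_rule(self, base_grid):
        grid = HyperGrid(
            base={**base_grid.base, "loss_function": ["ComboLoss", "RFLoss"]},
            conditional={"ComboLoss": {"w_cce": [0.05, 0.20]},
                         "RFLoss": {"beta": [0.5, 1.0, 2.0]}},
        )
        assert len(expand_grid(grid)) == 72 * (2 + 3)

    def test_expansion_order_is_deterministic(self, base_grid):
        a = [c.trial_id for c in expand_grid(base_grid)]
        b = [c.trial_id for c in expand_grid(base_grid)]
        assert a == b
        assert len(set(a)) == len(a)

    def test_count_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_axes = int(rng.integers(1, 4))
            base = {f"h{i}": list(range(int(rng.integers(1, 4))))
                    for i in range(n_axes)}
            losses = [f"L{i}" for i in range(int(rng.integers(1, 3)))]
            base["loss_function"] = losses
            cond = {L: {f"p{j}": list(range(int(rng.integers(1, 3))))
                        for j in range(int(rng.integers(0, 3)))}
                    for L in losses}
            grid = HyperGrid(base=base, conditional=cond)
            # oracle: explicit nested enumeration
            base_sz = int(np.prod([len(v) for k, v in base.items()
                                   if k != "loss_function"]))
            cond_sz = sum(int(np.prod([len(v) for v in cond[L].values()] or [1]))
                          for L in losses)
            assert len(expand_grid(grid)) == base_sz * cond_sz

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            HyperGrid(base={"learning_rate": []})

    def test_loss_parameters_only_under_parent_loss(self):
        grid = HyperGrid(base={"loss_function": ["Dice", "ComboLoss"]},
                         conditional={"ComboLoss": {"w_cce": [0.05]}})
        configs = expand_grid(grid)
        by_loss = {c.values["loss_function"]: c for c in configs}
        assert "w_cce" in by_loss["ComboLoss"].values
        assert "w_cce" not in by_loss["Dice"].values

    def test_yaml_round_trip(self, base_grid, tmp_path):
        import yaml

        path = tmp_path / "grid.yaml"
        path.write_text(yaml.safe_dump({"base": base_grid.base, "conditional": {}}))
        assert len(expand_grid(HyperGrid.from_yaml(path))) == 72


class TestPlanCounts:
    def test_effective_dataset_of_case_study(self):
        assert plan_counts(658, 20).effective_patients == 13_160

    def test_epoch_total_from_realized_folds(self):
        assert plan_counts(658, 20, epochs_per_fold=10, folds_total=6571).epochs_total == 65_710

    def test_single_trial_loo_arithmetic(self):
        s = plan_counts(1, 10, "loo", 10)
        assert (s.folds_total, s.epochs_total) == (10, 100)

    def test_kfold_scheme(self):
        assert plan_counts(2, 10, "kfold(5)", 3).folds_total == 10

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            plan_counts(0, 10)


class TestMakeFolds:
    def test_loo_over_ten_patients(self):
        ids = [f"p{i}" for i in range(10)]
        plan = make_folds(ids, "loo")
        assert len(plan) == 10
        assert all(len(tr) == 9 and len(va) == 1 for tr, va in plan)

    def test_validation_sets_partition_cohort(self):
        ids = [f"p{i}" for i in range(10)]
        for scheme in ("loo", "kfold(10)", "kfold(3)"):
            plan = make_folds(ids, scheme, seed=4)
            val_all = list(itertools.chain.from_iterable(va for _, va in plan))
            assert sorted(val_all) == sorted(ids)
            for tr, va in plan:
                assert not set(tr) & set(va)

    def test_kfold_ten_matches_loo_sizes(self):
        ids = [f"p{i}" for i in range(10)]
        loo = make_folds(ids, "loo")
        kf = make_folds(ids, "kfold(10)", seed=0)
        assert sorted(len(va) for _, va in kf) == sorted(len(va) for _, va in loo)

    def test_seeded_determinism(self):
        ids = [f"p{i}" for i in range(6)]
        assert make_folds(ids, "kfold(3)", seed=9) == make_folds(ids, "kfold(3)", seed=9)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], "kfold(3)")


class TestResultsLedger:
    def _config(self):
        return expand_grid(HyperGrid(base={"dropout": [0.1]}),
                           StaticSettings.desk_scale())[0]

    def test_duplicate_rows_rejected(self):
        config = self._config()
        ledger = ResultsLedger(["dropout"])
        ledger.append_epoch(config, 0, 1, "train", {"accuracy": 0.5})
        with pytest.raises(ValueError, match="duplicate"):
            ledger.append_epoch(config, 0, 1, "train", {"accuracy": 0.6})

    def test_hyperparameter_constancy_validation(self):
        config = self._config()
        ledger = ResultsLedger(["dropout"])
        ledger.append_epoch(config, 0, 1, "train", {"accuracy": 0.5})
        ledger.validate()
        # corrupt a row to simulate a broken merge
        ledger._rows[0]["dropout"] = 0.9
        ledger.append_epoch(config, 1, 1, "train", {"accuracy": 0.5})
        with pytest.raises(ValueError, match="varies"):
            ledger.validate()

    def test_csv_round_trip(self, tmp_path):
        config = self._config()
        ledger = ResultsLedger(["dropout"])
        ledger.append_epoch(config, 0, 1, "validation", {"accuracy": 0.75})
        path = tmp_path / "ledger.csv"
        ledger.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["trial_id", "fold_id", "epoch", "split",
                                    "dropout", "metric", "value"]
        assert df.loc[0, "value"] == 0.75


class TestRunTrial:
    @pytest.fixture
    def tiny_setup(self, small_cohort):
        grid = HyperGrid(base={"learning_rate": [0.01],
                               "batch_normalization": [True]})
        static = StaticSettings(epochs=2, patch_size=24, patches_per_slice=2)
        config = expand_grid(grid, static, seed=5)[0]
        folds = make_folds([v.patient_id for v in small_cohort], "loo")
        return config, folds

    def test_row_cardinality(self, small_cohort, tiny_setup):
        config, folds = tiny_setup
        ledger = run_trial(config, small_cohort, folds, losses_to_log=["Dice"])
        df = ledger.to_frame()
        n_metrics = len(metric_schema(3, ["Dice"])) + 1  # + diverged flag
        assert len(df) == 3 * 2 * 2 * n_metrics  # folds x epochs x splits x metrics

    def test_loo_validation_coverage(self, small_cohort, tiny_setup):
        config, folds = tiny_setup
        val_patients = [va[0] for _, va in folds]
        assert sorted(val_patients) == sorted(v.patient_id for v in small_cohort)

    def test_rerun_is_bit_identical(self, small_cohort, tiny_setup):
        config, folds = tiny_setup
        a = run_trial(config, small_cohort, folds).to_frame()
        b = run_trial(config, small_cohort, folds).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_learner_failure_recorded_not_raised(self, small_cohort, tiny_setup):
        config, folds = tiny_setup

        class ExplodingLearner:
            def __init__(self, *a, **k): ...
            def fit_epoch(self, patches):
                raise FloatingPointError("diverged")
            def predict(self, images): ...

        ledger = run_trial(config, small_cohort, folds,
                           learner_factory=lambda c, k, s: ExplodingLearner())
        df = ledger.to_frame()
        flags = df[df.metric == "diverged"]
        assert (flags.value == 1.0).all()
        others = df[df.metric != "diverged"]
        assert others.value.isna().all()

    def test_phantom_learner_separates_classes(self, small_cohort, tiny_setup):
        config, folds = tiny_setup
        df = run_trial(config, small_cohort, folds).to_frame()
        final = df[(df.metric == "dice_mean_nobg") & (df.split == "validation")
                   & (df.epoch == 2)]
        assert final.value.mean() > 0.8


def test_preset_grids_expand():
    assert len(expand_grid(desk_scale_grid())) == 16
    paper = paper_scale_grid()
    base_only = HyperGrid(base=paper.base)
    assert len(expand_grid(base_only)) == 72


def test_static_settings_batch_size_restricted():
    with pytest.raises(ValueError):
        StaticSettings(batch_size=64)
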