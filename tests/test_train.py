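"""Training harness: balancing, folds, early stopping, metrics, CV protocol."""

import numpy as np
import pandas as pd
import pytest

from slicemap import ModelSpec, TrainConfig, build_model
from slicemap.train import (EarlyStopper, cross_validate, downsample_balance, evaluate,
                            kfold_split, standardize_feature_maps, train_model)


def brute_metrics(y, p, thr=0.5):
    """Independent oracle: confusion-matrix metrics + pairwise-rank AUC."""
    y = np.asarray(y)
    p = np.asarray(p)
    yhat = (p >= thr).astype(int)
    tp = int(((y == 1) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    acc = (tp + tn) / len(y)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    pos, neg = p[y == 1], p[y == 0]
    auc = None
    if len(pos) and len(neg):
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        auc = wins / (len(pos) * len(neg))
    return acc, prec, rec, f1, auc


class _FixedModel:
    """Stub classifier returning preset probabilities (for metric tests)."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def forward(self, X, covariates=None, train=False):
        return self.probs


class TestDownsample:
    def test_minority_count_rule(self):
        labels = np.array([0] * 10 + [1] * 4)
        idx = downsample_balance(labels, seed=0)
        assert len(idx) == 8
        assert (labels[idx] == 1).sum() == 4 and (labels[idx] == 0).sum() == 4
        assert set(np.flatnonzero(labels == 1)) <= set(idx)   # minority fully kept

    def test_already_balanced_is_identity(self):
        labels = np.array([0, 1, 0, 1])
        assert np.array_equal(downsample_balance(labels, 3), np.arange(4))

    def test_seed_determinism(self):
        labels = np.array([0] * 50 + [1] * 20)
        assert np.array_equal(downsample_balance(labels, 9), downsample_balance(labels, 9))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            downsample_balance(np.zeros(5), 0)


class TestKFold:
    def test_equal_partition_for_20_by_10(self):
        labels = np.tile([0, 1], 10)
        folds = kfold_split(20, 10, labels, seed=0)
        assert all(len(te) == 2 for _, te in folds)

    def test_partition_covers_every_index_once(self):
        labels = np.tile([0, 1], 17)
        folds = kfold_split(34, 5, labels, seed=1)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(34))

    def test_fold_sizes_for_344_subjects(self):
        labels = np.tile([0, 1], 172)
        sizes = sorted(len(te) for _, te in kfold_split(344, 10, labels, seed=2))
        assert sizes == [34] * 6 + [35] * 4

    def test_stratification_balances_classes_per_fold(self):
        labels = np.tile([0, 1], 15)
        for _, te in kfold_split(30, 10, labels, seed=3):
            cnt = np.bincount(labels[te], minlength=2)
            assert abs(cnt[0] - cnt[1]) <= 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(5, 10, np.tile([0, 1], 3)[:5], 0)


class TestEarlyStopping:
    def test_monotonic_worsening_stops_after_patience_epochs(self):
        stopper = EarlyStopper(patience=10)
        stopped_at = None
        for epoch, acc in enumerate([0.9] + [0.9 - 0.01 * i for i in range(1, 30)], start=1):
            if stopper.update(epoch, acc):
                stopped_at = epoch
                break
        assert stopped_at == 11
        assert stopper.best_epoch == 1

    def test_improvement_resets_the_stall_counter(self):
        stopper = EarlyStopper(patience=3)
        values = [0.5, 0.4, 0.4, 0.6, 0.5, 0.5, 0.5]
        stops = [stopper.update(e, v) for e, v in enumerate(values, 1)]
        assert stops == [False, False, False, False, False, False, True]
        assert stopper.best_epoch == 4


class TestTrainModel:
    def make_data(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        y = np.tile([0, 1], n // 2).astype(float)
        X = rng.normal(size=(n, 12, 6)) + y[:, None, None] * 1.5
        return X, y

    def config(self, **kw):
        base = dict(max_epochs=5, patience=3, batch_size=4, k_folds=2)
        base.update(kw)
        return TrainConfig(**base)

    def model(self, seed=0):
        return build_model(ModelSpec("cnn1d", hidden_sizes=(4, 6), dense_units=8,
                                     init_seed=seed), (12, 6), 0)

    def test_max_epochs_one_runs_exactly_one_epoch(self):
        X, y = self.make_data()
        history = train_model(self.model(), X, None, y, self.config(max_epochs=1, patience=0))
        assert len(history["train_loss"]) == 1
        assert history["best_epoch"] == 1

    def test_fixed_seeds_give_identical_final_weights(self):
        X, y = self.make_data()
        m1, m2 = self.model(), self.model()
        train_model(m1, X, None, y, self.config())
        train_model(m2, X, None, y, self.config())
        for p1, p2 in zip(m1.params(), m2.params()):
            assert np.array_equal(p1.value, p2.value)

    def test_training_reduces_loss_on_separable_data(self):
        X, y = self.make_data()
        history = train_model(self.model(), X, None, y, self.config(max_epochs=20, patience=19))
        assert history["train_loss"][-1] < history["train_loss"][0]

    def test_single_class_training_set_rejected(self):
        X, _ = self.make_data()
        with pytest.raises(ValueError, match="both classes"):
            train_model(self.model(), X, None, np.zeros(len(X)), self.config())

    def test_restores_best_epoch_weights(self):
        X, y = self.make_data()
        model = self.model()
        history = train_model(model, X, None, y, self.config(max_epochs=8, patience=7))
        best = history["best_epoch"]
        assert 1 <= best <= 8
        assert history["val_acc"][best - 1] == max(history["val_acc"])


class TestEvaluate:
    def test_worked_confusion_matrix_example(self):
        # TP=3, FP=1, FN=1, TN=5
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        p = np.array([.9, .8, .7, .2, .6, .1, .1, .1, .2, .3])
        m = evaluate(_FixedModel(p), None, None, y)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)

    def test_perfect_separation_gives_auc_one(self):
        y = np.array([0, 0, 1, 1])
        m = evaluate(_FixedModel([.1, .2, .8, .9]), None, None, y)
        assert m["auc"] == 1.0

    def test_constant_scores_give_auc_half_under_tie_correction(self):
        y = np.array([0, 1, 0, 1])
        m = evaluate(_FixedModel([.5] * 4), None, None, y)
        assert m["auc"] == pytest.approx(0.5)

    def test_single_class_test_set_records_auc_missing(self):
        m = evaluate(_FixedModel([.4, .6]), None, None, np.array([1, 1]))
        assert m["auc"] is None

    def test_degenerate_denominators_yield_zero(self):
        m = evaluate(_FixedModel([.1, .2]), None, None, np.array([1, 1]))
        assert m["precision"] == 0.0 and m["recall"] == 0.0 and m["f1"] == 0.0

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_FixedModel([]), None, None, np.array([]))

    def test_agrees_with_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(2, 15)
            y = rng.integers(0, 2, n)
            p = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)   # ties likely
            m = evaluate(_FixedModel(p), None, None, y)
            acc, prec, rec, f1, auc = brute_metrics(y, p)
            assert m["accuracy"] == pytest.approx(acc)
            assert m["precision"] == pytest.approx(prec)
            assert m["recall"] == pytest.approx(rec)
            assert m["f1"] == pytest.approx(f1)
            if auc is None:
                assert m["auc"] is None
            else:
                assert m["auc"] == pytest.approx(auc)


class TestStandardisation:
    def test_training_columns_are_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        tr, te = rng.normal(2, 3, (6, 10, 4)), rng.normal(2, 3, (3, 10, 4))
        ztr, zte = standardize_feature_maps(tr, te)
        assert np.allclose(ztr.mean(axis=(0, 1)), 0, atol=1e-12)
        assert np.allclose(ztr.std(axis=(0, 1)), 1, atol=1e-12)
        # held-out data transformed with training statistics, not its own
        assert not np.allclose(zte.mean(axis=(0, 1)), 0, atol=1e-3)

    def test_identical_padded_rows_stay_identical(self):
        tr = np.random.default_rng(1).normal(size=(4, 6, 3))
        tr[:, :2] = tr[:, :1]                       # rows 0,1 identical per subject
        (z,) = standardize_feature_maps(tr)
        assert np.array_equal(z[:, 0], z[:, 1])


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(5)
    n = 24
    y = np.tile([0, 1], n // 2)
    X = rng.normal(size=(n, 12, 6)) + y[:, None, None] * 2.0
    attrs = pd.DataFrame(dict(
        age=rng.uniform(8, 16, n), gender=rng.integers(0, 2, n).astype(float),
        handedness=rng.choice([0.0, 1.0, 2.0], n), full4_iq=rng.normal(105, 10, n),
        ld_or_odd=rng.integers(0, 2, n).astype(float)))
    return X, attrs, y


class TestCrossValidate:
    def config(self):
        return TrainConfig(max_epochs=4, patience=3, batch_size=4, k_folds=4)

    def spec(self, use_cov=False):
        return ModelSpec("cnn1d", use_covariates=use_cov, hidden_sizes=(4, 6),
                         dense_units=8)

    def test_fold_counts_and_partition(self, cohort):
        X, attrs, y = cohort
        table = cross_validate(X, attrs, y, [self.spec()], self.config())
        assert len(table.folds) == 4
        assert table.folds["n_test"].sum() == len(y)          # each subject tested once
        assert (table.folds["n_train"] + table.folds["n_test"] == len(y)).all()

    def test_mean_equals_arithmetic_mean_of_folds(self, cohort):
        X, attrs, y = cohort
        table = cross_validate(X, attrs, y, [self.spec()], self.config())
        assert table.mean("cnn1d", False, "accuracy") == pytest.approx(
            table.folds["accuracy"].mean())

    def test_covariate_and_plain_modes_both_run(self, cohort):
        X, attrs, y = cohort
        table = cross_validate(X, attrs, y, [self.spec(), self.spec(use_cov=True)],
                               self.config())
        assert set(map(tuple, table.folds[["model", "covariates"]].drop_duplicates()
                       .itertuples(index=False))) == {("cnn1d", False), ("cnn1d", True)}

    def test_artifacts_written(self, cohort, tmp_path):
        X, attrs, y = cohort
        cross_validate(X, attrs, y, [self.spec()], self.config(), out_dir=tmp_path)
        for name in ("folds.csv", "summary.csv", "heatmap.png", "auc_per_fold.png",
                     "run_manifest.json"):
            assert (tmp_path / name).exists(), name

    def test_unbalanced_cohort_is_downsampled_before_splitting(self):
        rng = np.random.default_rng(6)
        y = np.array([0] * 16 + [1] * 8)
        X = rng.normal(size=(24, 12, 6)) + y[:, None, None]
        attrs = pd.DataFrame(dict(age=rng.uniform(8, 16, 24), gender=np.ones(24),
                                  handedness=np.ones(24), full4_iq=rng.normal(100, 9, 24),
                                  ld_or_odd=np.zeros(24)))
        table = cross_validate(X, attrs, y, [self.spec()], self.config())
        assert table.folds["n_test"].sum() == 16              # 8 per class retained
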