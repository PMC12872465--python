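"""Cross-validation bookkeeping and the scoring machinery."""

import numpy as np
import pandas as pd
import pytest

import enzyres as ez
from enzyres.evaluation import (
    Protocol,
    confusion,
    sensor_rmse,
)
from enzyres.table import FeatureTable
from enzyres.tasks import make_task


class TestSplits:
    def test_score_count_bookkeeping(self):
        plan = ez.make_splits(60, repeats=10, seed=0)
        assert len(plan) == 120  # 10 repeats x 12 batches

    def test_test_sets_partition_each_repeat(self):
        plan = ez.make_splits(23, repeats=3, seed=1)
        per_repeat = np.ceil(23 / 5).astype(int)
        for r in range(3):
            chunk = plan.splits[r * per_repeat:(r + 1) * per_repeat]
            ids = np.concatenate([test for _, test in chunk])
            assert sorted(ids) == list(range(23))
            sizes = sorted(len(test) for _, test in chunk)
            assert sizes == [3, 5, 5, 5, 5]

    def test_train_and_test_disjoint_and_complete(self):
        plan = ez.make_splits(30, repeats=2, seed=2)
        for train, test in plan:
            assert np.intersect1d(train, test).size == 0
            assert len(train) + len(test) == 30

    def test_stratified_batches_hold_both_classes(self):
        labels = np.repeat([0, 1], 30)
        plan = ez.make_splits(60, labels=labels, repeats=5, seed=3)
        for _, test in plan:
            assert set(labels[test]) == {0, 1}
            assert len(test) == 5

    def test_deterministic_given_seed(self):
        a = ez.make_splits(40, repeats=4, seed=9)
        b = ez.make_splits(40, repeats=4, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_tiny_class_warns(self):
        labels = np.array([0] * 57 + [1] * 3)
        with pytest.warns(UserWarning, match="best-effort"):
            ez.make_splits(60, labels=labels, repeats=1, seed=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ez.make_splits(8, batch_size=5)


class TestPhi:
    @pytest.mark.parametrize("tp,tn,fp,fn,expected", [
        (3, 2, 0, 0, 1.0),    # perfect predictions
        (0, 0, 2, 3, -1.0),   # completely wrong predictions
        (1, 1, 1, 1, 0.0),    # no association
        (5, 0, 0, 0, 0.0),    # zero denominator factor -> defined as 0
    ])
    def test_printed_formula_cases(self, tp, tn, fp, fn, expected):
        assert ez.phi_score(tp, tn, fp, fn) == pytest.approx(expected)

    def test_transform_maps_to_unit_interval(self):
        assert ez.transform_phi(1.0) == 1.0
        assert ez.transform_phi(-1.0) == 0.0
        assert ez.transform_phi(0.0) == 0.5

    def test_empty_confusion_matrix_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            ez.phi_score(0, 0, 0, 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ez.phi_score(-1, 0, 0, 0)

    def test_confusion_counting(self):
        y = np.array([1, 1, 0, 0, 1])
        p = np.array([1, 0, 0, 1, 1])
        assert confusion(y, p) == (2, 1, 1, 1)


class TestRegressionScores:
    def test_r2_perfect_and_mean_estimator(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert ez.r2_pooled(t, t) == 1.0
        assert ez.r2_pooled(np.full(4, t.mean()), t) == 0.0

    def test_r2_hand_example(self):
        truths = np.array([1.0, 2.0, 3.0, 4.0])
        preds = np.array([1.5, 1.5, 3.5, 3.5])
        # SS_res = 4 * 0.25 = 1.0, SS_tot = 5.0
        assert ez.r2_pooled(preds, truths) == pytest.approx(1.0 - 1.0 / 5.0)

    def test_sensor_error_perfect_is_zero(self):
        pairs = [(np.array([30.0, 40.0]), np.array([30.0, 40.0]))]
        assert ez.sensor_error(pairs) == 0.0

    def test_sensor_error_ignores_constant_bias(self):
        pairs = [(np.array([32.0, 42.0, 52.0]), np.array([30.0, 40.0, 50.0]))]
        assert ez.sensor_error(pairs) == pytest.approx(0.0, abs=1e-12)
        assert sensor_rmse(pairs) == pytest.approx(2.0)

    def test_sensor_error_hand_two_splits(self):
        a = (np.array([1.0, 3.0]), np.array([0.0, 0.0]))  # residuals 1,3 -> sd sqrt(2)
        b = (np.array([2.0, 2.0]), np.array([1.0, 3.0]))  # residuals 1,-1 -> sd sqrt(2)
        assert ez.sensor_error([a, b]) == pytest.approx(np.sqrt(2.0))


def _toy_table(n=40, seed=0, informative=True):
    """Small synthetic table whose features encode the XOR answer."""
    rng = np.random.default_rng(seed)
    s1 = rng.uniform(40, 100, size=n)
    s2 = rng.uniform(15, 75, size=n)
    u1, u2 = (s1 - 40) / 60, (s2 - 15) / 60
    feats = {}
    if informative:
        feats["fA"] = (u1 - 0.5) * (u2 - 0.5) + 0.01 * rng.normal(size=n)
        feats["fB"] = u1 + u2 + 0.01 * rng.normal(size=n)
    for j in range(3):
        feats[f"noise{j}"] = rng.normal(size=n)
    data = pd.DataFrame({"meta_s1_uM": s1, "meta_s2_uM": s2, **feats})
    return FeatureTable(data)


class TestEvaluateTask:
    def test_informative_features_solve_xor(self):
        rep = ez.evaluate_task(_toy_table(), make_task("xor"),
                               protocol=Protocol(repeats=5, seed=0))
        assert rep.mean > 0.9
        assert rep.n_splits == 5 * 8

    def test_reports_are_bit_for_bit_deterministic(self):
        kw = dict(protocol=Protocol(repeats=3, seed=4))
        a = ez.evaluate_task(_toy_table(), make_task("xor"), **kw)
        b = ez.evaluate_task(_toy_table(), make_task("xor"), **kw)
        assert np.array_equal(a.scores, b.scores)
        assert a.predictions.equals(b.predictions)

    def test_shuffled_labels_score_at_chance(self):
        """Held-out transformed Phi is centred at 0.5 under the null."""
        table = _toy_table(n=40, informative=False)
        rng = np.random.default_rng(5)
        meta = table.data.copy()
        # random labels via a metadata column the task never saw
        meta["meta_s1_uM"] = rng.permutation(meta["meta_s1_uM"].to_numpy())
        rep = ez.evaluate_task(FeatureTable(meta), make_task("xor"),
                               protocol=Protocol(repeats=25, seed=6))
        repeat_means = rep.scores.reshape(25, -1).mean(axis=1)
        se = repeat_means.std(ddof=1) / np.sqrt(len(repeat_means))
        assert abs(rep.mean - 0.5) < max(3 * se, 0.05)

    def test_duplicated_features_equivalent_under_scaled_penalty(self):
        table = _toy_table()
        dup = table.data.copy()
        for f in table.feature_names:
            dup[f + "_copy"] = dup[f]
        prot = Protocol(repeats=3, seed=7)
        orig = ez.evaluate_task(table, make_task("xor"), protocol=prot, C=1.0)
        twice = ez.evaluate_task(FeatureTable(dup), make_task("xor"),
                                 protocol=prot, C=0.5)
        assert twice.mean == pytest.approx(orig.mean, abs=0.02)

    def test_regression_pipeline_reports_pooled_r2(self):
        rng = np.random.default_rng(8)
        t = np.repeat(np.linspace(25, 55, 8), 4)
        data = pd.DataFrame({
            "meta_T_C": t,
            "f0": 2.0 * t + rng.normal(scale=0.5, size=t.size),
            "f1": rng.normal(size=t.size),
        })
        rep = ez.evaluate_task(FeatureTable(data), make_task("sensing"),
                               protocol=Protocol(repeats=10, stratified=False, seed=9))
        assert rep.pooled_r2 > 0.95
        assert rep.sensor_sd < 2.0
        assert rep.sensor_rmse >= rep.sensor_sd - 1e-9

    def test_single_class_dataset_rejected(self):
        data = _toy_table().data.copy()
        data["meta_T_C"] = 30.0  # every sample below the decision boundary
        with pytest.raises(ValueError, match="single class"):
            ez.evaluate_task(FeatureTable(data), make_task("threshold", t0=1000.0),
                             protocol=Protocol(repeats=2, seed=0))

    def test_missing_task_metadata_errors(self):
        table = _toy_table()
        with pytest.raises(KeyError):
            ez.evaluate_task(table, make_task("sensing"),
                             protocol=Protocol(repeats=2, stratified=False, seed=0))

    def test_per_input_accuracy_covers_all_samples(self):
        rep = ez.evaluate_task(_toy_table(), make_task("xor"),
                               protocol=Protocol(repeats=4, seed=1))
        assert rep.per_input.shape == (40,)
        assert np.all(rep.per_input >= 0) and np.all(rep.per_input <= 1)
        assert not np.any(np.isnan(rep.per_input))

    def test_feature_count_ablation_monotone_bookkeeping(self):
        table = _toy_table()
        df = ez.evaluation.feature_count_ablation(
            table, make_task("xor"), counts=[1, 5],
            protocol=Protocol(repeats=2, seed=0), seed=3)
        assert list(df["n_features"]) == [1, 5]
        assert df["score"].between(0, 1).all()
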