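"""Split protocol, metrics, training loop and the ablation sweeps."""

import numpy as np
import pytest

from msgcn import ConnectomeClassifier, TrainConfig, make_splits
from msgcn.errors import DataError
from msgcn.evaluation import (auc_score, canonical_method, compare_methods, evaluate,
                              fusion_ratio_sweep, metrics_from_counts, roc_points,
                              run_protocol, sparsity_sweep, train)
from msgcn.nn import FeedForwardNet


class TestSplits:
    def test_sizes_follow_floor_floor_remainder(self):
        labels = np.tile([0, 1], 92)  # 184 subjects
        sp = make_splits(labels, reps=3, seed=0)[0]
        assert (len(sp.train), len(sp.val), len(sp.test)) == (147, 18, 19)

    def test_same_seed_reproduces_index_sets(self):
        labels = np.tile([0, 1], 30)
        a = make_splits(labels, reps=5, seed=9)
        b = make_splits(labels, reps=5, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.train, y.train)
            np.testing.assert_array_equal(x.val, y.val)
            np.testing.assert_array_equal(x.test, y.test)

    def test_partition_is_disjoint_and_complete(self):
        labels = np.tile([0, 1], 25)
        for sp in make_splits(labels, reps=10, seed=4):
            joined = np.concatenate([sp.train, sp.val, sp.test])
            assert len(set(joined)) == len(joined) == 50

    def test_every_part_contains_both_classes(self):
        labels = np.array([1] * 5 + [0] * 45)  # heavily imbalanced forces redraws
        for sp in make_splits(labels, reps=20, seed=1):
            for part in (sp.train, sp.val, sp.test):
                assert set(np.unique(labels[part])) == {0, 1}

    def test_too_few_subjects_rejected(self):
        with pytest.raises(DataError):
            make_splits(np.array([0, 1] * 3), reps=1, seed=0)


class TestMetrics:
    def test_printed_formula_example(self):
        m = metrics_from_counts(tp=8, fn=2, fp=3, tn=7)
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(8 / 11)
        assert m["f1"] == pytest.approx(2 * (8 / 11) * 0.8 / (8 / 11 + 0.8))

    def test_perfect_predictions_score_one(self):
        class _Oracle:
            def predict_proba(self, x):
                p1 = (x[:, 0] > 0).astype(float)
                return np.column_stack([1.0 - p1, p1])

        y = np.repeat([0, 1], 10)
        x = np.where(y == 1, 5.0, -5.0)[:, None]
        res = evaluate(_Oracle(), x, y, np.arange(20))
        for k in ("accuracy", "recall", "precision", "f1", "auc"):
            assert res[k] == pytest.approx(1.0)

    def test_auc_midrank_with_all_tied_scores(self):
        y = np.repeat([0, 1], 6)
        assert auc_score(y, np.full(12, 0.3)) == pytest.approx(0.5)

    def test_auc_matches_all_pairs_oracle(self, rng):
        for _ in range(30):
            y = rng.integers(0, 2, size=25)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(25), 1)  # coarse scores force ties
            pos, neg = s[y == 1], s[y == 0]
            pairs = (pos[:, None] > neg[None, :]).mean() \
                + 0.5 * (pos[:, None] == neg[None, :]).mean()
            assert auc_score(y, s) == pytest.approx(pairs, abs=1e-12)

    def test_auc_none_for_single_class(self):
        assert auc_score(np.ones(5, dtype=int), np.random.rand(5)) is None

    def test_roc_endpoints(self, rng):
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]
        fpr, tpr = roc_points(y, rng.random(20))
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


class TestTraining:
    def test_zero_learning_rate_keeps_parameters(self, rng):
        x = rng.normal(size=(30, 6))
        y = np.tile([0, 1], 15)
        net = FeedForwardNet(6, seed=2)
        before = [p.copy() for p in net.params]
        train(net, x, y, np.arange(24), np.arange(24, 30),
              TrainConfig(lr=0.0, epochs=10, seed=0))
        for p, q in zip(net.params, before):
            np.testing.assert_array_equal(p, q)

    def test_fixed_seed_gives_identical_loss_trace(self, rng):
        x = rng.normal(size=(40, 5))
        y = np.tile([0, 1], 20)
        traces = []
        for _ in range(2):
            net = FeedForwardNet(5, seed=11)
            rec = train(net, x, y, np.arange(32), np.arange(32, 40),
                        TrainConfig(epochs=20, seed=11))
            traces.append(rec.loss_trace)
        np.testing.assert_array_equal(traces[0], traces[1])

    def test_best_epoch_checkpoint_recorded(self, rng):
        x = rng.normal(size=(40, 5)) + 2.0 * np.tile([0, 1], 20)[:, None]
        y = np.tile([0, 1], 20)
        net = FeedForwardNet(5, seed=1)
        rec = train(net, x, y, np.arange(32), np.arange(32, 40), TrainConfig(seed=1))
        assert 0 <= rec.best_epoch < 50
        assert rec.best_val_accuracy == max(rec.val_accuracy_trace)

    def test_non_finite_loss_aborts_with_diagnostics(self, rng):
        x = rng.normal(size=(20, 4))
        y = np.tile([0, 1], 10)
        net = FeedForwardNet(4, seed=0)
        net.head.W[0][0, 0] = np.nan
        with pytest.raises(DataError, match="non-finite"):
            train(net, x, y, np.arange(16), np.arange(16, 20), TrainConfig(seed=0))


class TestProtocol:
    def test_strong_effect_cohort_trains_to_high_accuracy(self, tiny_samples):
        from msgcn import prepare_batch
        from msgcn.nn import MultiScaleGCNNet

        batch, labels = prepare_batch(tiny_samples)
        net = MultiScaleGCNNet({"coarse": 10, "fine": 20}, seed=0)
        idx = np.arange(len(labels))
        rec = train(net, batch, labels, idx[:-4], idx[-4:], TrainConfig(seed=0))
        assert rec.loss_trace[0] > rec.loss_trace[-10:].mean()  # loss decreases
        train_res = evaluate(net, batch, labels, idx[:-4])
        assert train_res["accuracy"] >= 0.95
        # held-out accuracy over repeated splits stays well above chance
        res = ConnectomeClassifier(tiny_samples, method="multiscale_gcn").fit(
            reps=5, seed=0)
        assert res.accuracy >= 0.7

    def test_single_repetition_has_zero_sd(self, tiny_samples):
        res = ConnectomeClassifier(tiny_samples, method="dc").fit(reps=1, seed=0)
        assert res.report.sd("accuracy") == 0.0

    def test_methods_share_bit_identical_splits(self, tiny_samples):
        reports = compare_methods(tiny_samples, ["dc", "gcn_coarse"], reps=2, seed=7)
        assert set(reports) == {"dc", "gcn_coarse"}
        # identical split seeds imply identical confusion-table denominators
        for r1, r2 in zip(reports["dc"].records, reports["gcn_coarse"].records):
            assert r1["tp"] + r1["fn"] + r1["fp"] + r1["tn"] \
                == r2["tp"] + r2["fn"] + r2["fp"] + r2["tn"]

    def test_alias_names_resolve(self):
        assert canonical_method("MGRL") == "multiscale_gcn"
        assert canonical_method("GCNA") == "gcn_coarse"
        assert canonical_method("dcf") == "dc"
        with pytest.raises(DataError):
            canonical_method("svm")

    def test_multiscale_not_worse_than_single_scales(self, tiny_samples):
        reports = compare_methods(tiny_samples,
                                  ["multiscale_gcn", "gcn_coarse", "gcn_fine"],
                                  reps=4, seed=2)
        multi = reports["multiscale_gcn"].mean("accuracy")
        singles = max(reports["gcn_coarse"].mean("accuracy"),
                      reports["gcn_fine"].mean("accuracy"))
        assert multi >= singles - 1e-9


class TestSweeps:
    def test_sparsity_sweep_rows_and_full_retention_match(self, tiny_cohort):
        table = sparsity_sweep(tiny_cohort, retains=(1.0, 0.8), reps=2, seed=3)
        assert set(table) == {1.0, 0.8}
        base = run_protocol(__import__("msgcn").graphs_from_cohort(tiny_cohort),
                            "multiscale_gcn", reps=2, seed=3)
        assert table[1.0].mean("accuracy") == pytest.approx(base.mean("accuracy"))
        for rep in table.values():
            assert set(rep.records[0]) >= {"accuracy", "recall", "precision",
                                           "f1", "auc"}

    def test_fusion_ratio_sweep_table(self, tiny_samples):
        df = fusion_ratio_sweep(tiny_samples, ratios=(0.2, 0.5, 0.8), reps=2, seed=5)
        assert list(df["ratio"]) == [0.2, 0.5, 0.8]
        assert df["accuracy_mean"].between(0, 1).all()

    def test_equal_ratio_equals_default_run(self, tiny_samples):
        df = fusion_ratio_sweep(tiny_samples, ratios=(0.5,), reps=2, seed=5)
        base = run_protocol(tiny_samples, "multiscale_gcn", reps=2, seed=5)
        assert df["accuracy_mean"][0] == pytest.approx(base.mean("accuracy"))

    def test_summary_output_contains_all_metrics(self, tiny_samples):
        res = ConnectomeClassifier(tiny_samples, method="lcc").fit(reps=2, seed=1)
        text = res.summary()
        for word in ("accuracy", "recall", "precision", "f1", "auc"):
            assert word in text
        frame = res.metrics
        assert set(frame.columns) == {"mean", "sd"}
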