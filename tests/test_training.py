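import numpy as np
import pytest

from oncograph.interactome import LabeledDataset, MoleculeSignal
from oncograph.layers import init_model
from oncograph.metrics import summary_metrics
from oncograph.training import (
    DEFAULT_GRID,
    TrainingConfig,
    _grid_combinations,
    anticancer_likeness,
    class_weights,
    grid_search,
    stratified_splits,
    train_model,
    weighted_cross_entropy,
)


class TestClassWeights:
    def test_study_class_counts(self):
        labels = np.array([1] * 209 + [0] * 1839)
        w = class_weights(labels)
        assert w[1] / w[0] == pytest.approx(1839 / 209)
        assert w[1] / w[0] == pytest.approx(8.799, abs=1e-3)

    def test_balanced_gives_unit_weights(self):
        assert np.allclose(class_weights(np.array([0, 1, 0, 1])), [1.0, 1.0])

    def test_extreme_imbalance(self):
        labels = np.array([1] + [0] * 99)
        w = class_weights(labels)
        assert w[1] == pytest.approx(50.0)
        assert w[0] == pytest.approx(100 / 198)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            class_weights(np.zeros(10))


class TestWeightedCrossEntropy:
    def test_perfect_predictions_vanish(self):
        p = np.array([[1e-15, 1 - 1e-15], [1 - 1e-15, 1e-15]])
        assert weighted_cross_entropy(p, np.array([1, 0]), np.ones(2)) < 1e-10

    def test_uniform_prediction_is_log2(self):
        p = np.array([[0.5, 0.5]])
        loss = weighted_cross_entropy(p, np.array([1]), np.ones(2))
        assert loss == pytest.approx(np.log(2))

    def test_weighted_two_sample_average(self):
        p = np.array([[0.8, 0.2], [0.3, 0.7]])
        w = np.array([2.0, 1.0])
        expected = (2.0 * -np.log(0.8) + 1.0 * -np.log(0.7)) / 2
        assert weighted_cross_entropy(p, np.array([0, 1]), w) == pytest.approx(expected)


class TestStratifiedSplits:
    def test_fold_positive_counts(self):
        labels = np.array([1] * 10 + [0] * 90)
        plan = stratified_splits(labels, k=5, seed=0)
        for fold in plan.folds:
            assert labels[fold.test].sum() == 2

    def test_test_folds_partition_indices(self):
        labels = np.array([1] * 13 + [0] * 87)
        plan = stratified_splits(labels, k=5, seed=1)
        all_test = np.concatenate([f.test for f in plan.folds])
        assert sorted(all_test.tolist()) == list(range(100))
        for fold in plan.folds:
            parts = np.concatenate([fold.train, fold.val, fold.test])
            assert sorted(parts.tolist()) == list(range(100))

    def test_validation_fraction(self):
        labels = np.array([1] * 20 + [0] * 180)
        plan = stratified_splits(labels, k=5, val_frac=0.1, seed=2)
        for fold in plan.folds:
            n_rest = 200 - len(fold.test)
            assert len(fold.val) == pytest.approx(0.1 * n_rest, abs=2)
            assert labels[fold.val].sum() >= 1  # stratified validation

    def test_deterministic_under_seed(self):
        labels = np.array([1] * 10 + [0] * 40)
        p1 = stratified_splits(labels, seed=3)
        p2 = stratified_splits(labels, seed=3)
        for f1, f2 in zip(p1.folds, p2.folds):
            assert np.array_equal(f1.train, f2.train)
            assert np.array_equal(f1.val, f2.val)
            assert np.array_equal(f1.test, f2.test)

    def test_small_class_raises(self):
        with pytest.raises(ValueError):
            stratified_splits(np.array([1, 0, 0, 0, 0, 0]), k=5)


def _separable_dataset(n=60, n_genes=10):
    """Positives target gene 0, negatives target gene 9: linearly separable."""
    signals, labels = [], []
    for i in range(n):
        x = np.zeros(n_genes, dtype=np.int8)
        y = 1 if i < n // 2 else 0
        x[0 if y else n_genes - 1] = 1
        signals.append(MoleculeSignal(f"m{i}", "drug", x))
        labels.append(y)
    return LabeledDataset(signals=signals, labels=np.array(labels))


class TestTrainModel:
    def test_separable_set_learned_perfectly(self, toy_graph):
        g, ops = toy_graph
        data = _separable_dataset()
        plan = stratified_splits(data.labels, seed=4)
        fold = plan.folds[0]
        arch = init_model(n_nodes=10, kind="gcn", n_conv_layers=1, seed=5,
                          dropout_rate=0.0)
        cfg = TrainingConfig(seed=5, max_epochs=60)
        res = train_model(data, ops, arch, cfg, fold)
        assert all(np.diff(res.train_loss[:5]) < 0)
        from oncograph.layers import forward_batch
        probs, _ = forward_batch(res.model, data.feature_matrix()[fold.train], ops)
        rep = summary_metrics(data.labels[fold.train], probs[:, 1])
        assert rep.balanced_accuracy == 100.0

    def test_constant_validation_loss_stops_at_21(self, toy_graph):
        g, ops = toy_graph
        data = _separable_dataset()
        plan = stratified_splits(data.labels, seed=6)
        arch = init_model(n_nodes=10, kind="gcn", n_conv_layers=1, seed=6)
        cfg = TrainingConfig(seed=6, learning_rate=0.0)  # weights frozen
        res = train_model(data, ops, arch, cfg, plan.folds[0])
        assert res.stop_epoch == 21
        assert res.best_epoch == 1

    def test_max_epochs_bound(self, toy_graph):
        _g, ops = toy_graph
        data = _separable_dataset()
        plan = stratified_splits(data.labels, seed=7)
        arch = init_model(n_nodes=10, kind="gcn", n_conv_layers=1, seed=7)
        res = train_model(data, ops, arch, TrainingConfig(seed=7, max_epochs=1),
                          plan.folds[0])
        assert res.stop_epoch == 1 and len(res.train_loss) == 1

    def test_early_stop_restores_best_weights(self, small_synthetic, trained_toy):
        _g, ops, _pa, data, _f, _m, plan = small_synthetic
        res = trained_toy
        from oncograph.layers import forward_batch
        from oncograph.training import class_weights as cw
        fold = plan.folds[0]
        w = cw(data.labels[fold.train])
        probs, _ = forward_batch(res.model, data.feature_matrix()[fold.val], ops)
        final_val = weighted_cross_entropy(probs, data.labels[fold.val], w)
        assert final_val <= res.val_loss[res.stop_epoch - 1] + 1e-9
        assert final_val == pytest.approx(min(res.val_loss), abs=1e-9)

    def test_class_weighting_improves_positive_recall(self, toy_graph):
        # 10:1 imbalance with a weak signal: unweighted training collapses to
        # the majority class more often (seed-averaged trend over 3 seeds)
        g, ops = toy_graph
        rng = np.random.default_rng(8)
        recalls = {True: [], False: []}
        for seed in range(3):
            signals, labels = [], []
            for i in range(110):
                y = 1 if i < 10 else 0
                x = np.zeros(10, dtype=np.int8)
                k = rng.integers(1, 3)
                pool = [0, 1, 2] if y else list(range(10))
                x[rng.choice(pool, size=min(k, len(pool)), replace=False)] = 1
                signals.append(MoleculeSignal(f"m{i}", "drug", x))
                labels.append(y)
            data = LabeledDataset(signals=signals, labels=np.array(labels))
            plan = stratified_splits(data.labels, seed=seed)
            for weighted in (True, False):
                arch = init_model(n_nodes=10, kind="gcn", n_conv_layers=1,
                                  seed=seed + 20)
                cfg = TrainingConfig(seed=seed + 20, max_epochs=30,
                                     class_weighting=weighted)
                res = train_model(data, ops, arch, cfg, plan.folds[0])
                recalls[weighted].append(res.metrics.recall_pos)
        assert np.mean(recalls[True]) >= np.mean(recalls[False])


class TestGridSearch:
    def test_table1_combination_counts(self):
        assert len(_grid_combinations(DEFAULT_GRID, "cheb")) == 432
        assert len(_grid_combinations(DEFAULT_GRID, "gcn")) == 144

    def test_single_combination_returned(self, small_synthetic):
        g, ops, _pa, data, _f, _m, plan = small_synthetic
        grid = {"learning_rate": [5e-3]}
        combo, result, table = grid_search(
            data, ops, plan.folds[0], kind="gcn", grid=grid, seed=0,
            training_kwargs={"max_epochs": 3})
        assert combo == {"learning_rate": 5e-3}
        assert len(table) == 1

    def test_selects_lower_validation_loss(self, toy_graph):
        _g, ops = toy_graph
        data = _separable_dataset()
        plan = stratified_splits(data.labels, seed=8)
        grid = {"learning_rate": [0.0, 5e-3]}  # lr=0 cannot learn anything
        combo, _result, table = grid_search(
            data, ops, plan.folds[0], kind="gcn", grid=grid, seed=1,
            training_kwargs={"max_epochs": 40})
        assert combo["learning_rate"] == 5e-3
        assert table.loc[table["learning_rate"] == 5e-3, "val_loss"].iloc[0] < \
            table.loc[table["learning_rate"] == 0.0, "val_loss"].iloc[0]


class TestAnticancerLikeness:
    def test_identical_models_equal_single_forward(self, small_synthetic):
        g, ops, _pa, data, foods, _m, _p = small_synthetic
        model = init_model(n_nodes=g.n_genes, kind="gcn", seed=9,
                           gene_ids=g.gene_ids)
        from oncograph.layers import forward
        table = anticancer_likeness([model] * 5, foods[:10], ops)
        for _, row in table.iterrows():
            sig = next(f for f in foods if f.molecule_id == row.molecule_id)
            assert row.score == pytest.approx(forward(model, sig.x, ops)[1])

    def test_flagging_threshold(self, small_synthetic):
        g, ops, _pa, _d, foods, _m, _p = small_synthetic
        model = init_model(n_nodes=g.n_genes, kind="gcn", seed=10,
                           gene_ids=g.gene_ids)
        table = anticancer_likeness([model], foods[:10], ops, threshold=0.9)
        assert (table.flagged == (table.score >= 0.9)).all()
        assert table.score.is_monotonic_decreasing

    def test_node_order_mismatch_raises(self, small_synthetic):
        g, ops, _pa, _d, foods, _m, _p = small_synthetic
        m1 = init_model(n_nodes=g.n_genes, kind="gcn", seed=11,
                        gene_ids=g.gene_ids)
        m2 = init_model(n_nodes=g.n_genes, kind="gcn", seed=11,
                        gene_ids=list(reversed(g.gene_ids)))
        with pytest.raises(ValueError, match="node order"):
            anticancer_likeness([m1, m2], foods[:5], ops)
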