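"""Module partitioning, stratified splitting, training and prediction."""

import numpy as np
import pytest

from modcast.annotation_io import FeatureMatrix, GenomeAnnotation, LabelMatrix
from modcast.classifier import (
    ClassifierConfig,
    ModelPair,
    ModulePartition,
    partition_modules,
    predict_modules,
    stratified_multilabel_split,
    train_model_pair,
)
from modcast.nn import MultiLabelMLP


def _labels_with_prevalence(prevs, n=200, seed=0):
    rng = np.random.default_rng(seed)
    cols = []
    for p in prevs:
        k = max(1, min(n - 1, round(p * n)))
        col = np.zeros(n, dtype=np.uint8)
        col[rng.choice(n, size=k, replace=False)] = 1
        cols.append(col)
    return LabelMatrix(
        [f"g{i}" for i in range(n)],
        [f"M{j}" for j in range(len(prevs))],
        np.stack(cols, axis=1),
    )


class TestPartition:
    def test_threshold_comparison(self):
        lm = _labels_with_prevalence([0.5, 0.05, 0.95])
        part = partition_modules(lm, low=0.1, high=0.9)
        assert part.balanced_modules == ["M0"]
        assert set(part.imbalanced_modules) == {"M1", "M2"}

    def test_boundary_prevalence_is_balanced(self):
        lm = _labels_with_prevalence([0.10, 0.90])
        part = partition_modules(lm, low=0.1, high=0.9)
        assert set(part.balanced_modules) == {"M0", "M1"}

    def test_inclusion_floor_excludes(self):
        lm = _labels_with_prevalence([0.01, 0.5], n=200)  # 2 positives for M0
        part = partition_modules(lm, min_positive_count=3)
        assert part.excluded_modules == ["M0"]
        assert part.retained_modules == ["M1"]

    def test_all_dropped_is_error(self):
        lm = _labels_with_prevalence([0.01, 0.01], n=100)
        with pytest.raises(ValueError, match="inclusion"):
            partition_modules(lm, min_positive_count=50)

    def test_partition_exhaustive_and_disjoint(self):
        lm = _labels_with_prevalence([0.05, 0.2, 0.5, 0.8, 0.95, 0.98])
        part = partition_modules(lm)
        retained = part.retained_modules
        assert sorted(retained + part.excluded_modules) == sorted(lm.module_ids)
        assert not (set(part.balanced_modules) & set(part.imbalanced_modules))


class TestSplit:
    def test_exact_test_row_count(self):
        lm = _labels_with_prevalence([0.3, 0.6], n=1000)
        train, test = stratified_multilabel_split(None, lm, 0.25, seed=0)
        assert len(test) == 250
        assert len(train) == 750
        assert sorted(np.concatenate([train, test]).tolist()) == list(range(1000))

    def test_deterministic(self):
        lm = _labels_with_prevalence([0.3, 0.05], n=500)
        a = stratified_multilabel_split(None, lm, 0.25, seed=9)
        b = stratified_multilabel_split(None, lm, 0.25, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_prevalence_preserved_single_label(self):
        lm = _labels_with_prevalence([0.3], n=1000)
        train, test = stratified_multilabel_split(None, lm, 0.25, seed=2)
        p_train = lm.labels[train, 0].mean()
        p_test = lm.labels[test, 0].mean()
        assert abs(p_train - 0.3) <= 0.05 and abs(p_test - 0.3) <= 0.05

    def test_all_zero_label_column_handled(self):
        lm = _labels_with_prevalence([0.4], n=100)
        lm.labels = np.concatenate(
            [lm.labels, np.zeros((100, 1), dtype=np.uint8)], axis=1
        )
        lm.module_ids = ["M0", "Mzero"]
        train, test = stratified_multilabel_split(None, lm, 0.2, seed=0)
        assert len(test) == 20

    def test_invalid_fraction(self):
        lm = _labels_with_prevalence([0.5], n=10)
        with pytest.raises(ValueError):
            stratified_multilabel_split(None, lm, 1.5, seed=0)


class TestTraining:
    def test_recovers_deterministic_labels(self, small_world, trained_pair):
        """Labels are a boolean function of features; a fitted pair should
        classify held-out complete genomes nearly perfectly."""
        from modcast.annotation_io import build_feature_matrix

        world = small_world
        feats = build_feature_matrix(world.genomes, trained_pair.ko_universe)
        proba = trained_pair.predict_proba(feats.bits.astype(np.float32))
        col = {m: j for j, m in enumerate(world.labels.module_ids)}
        accs = []
        for mid in trained_pair.partition.retained_modules:
            pred = (proba[mid] >= 0.5).astype(int)
            accs.append((pred == world.labels.labels[:, col[mid]]).mean())
        assert np.mean(accs) >= 0.9

    def test_probabilities_in_unit_interval(self, trained_pair, small_world):
        from modcast.annotation_io import build_feature_matrix

        feats = build_feature_matrix(small_world.genomes, trained_pair.ko_universe)
        for p in trained_pair.predict_proba(feats.bits.astype(np.float32)).values():
            assert ((p >= 0) & (p <= 1)).all()

    def test_outputs_cover_retained_modules_exactly_once(self, trained_pair):
        part = trained_pair.partition
        combined = list(part.balanced_modules) + list(part.imbalanced_modules)
        assert len(combined) == len(set(combined))
        assert trained_pair.balanced_model.n_outputs == len(part.balanced_modules)
        assert trained_pair.imbalanced_model.n_outputs == len(part.imbalanced_modules)

    def test_zero_hidden_layers_trains(self):
        rng = np.random.default_rng(0)
        X = (rng.random((120, 10)) < 0.5).astype(np.float32)
        Y = X[:, :2]  # labels copy two features
        feats = FeatureMatrix([f"g{i}" for i in range(120)], [f"K{j}" for j in range(10)], X.astype(np.uint8))
        labels = LabelMatrix([f"g{i}" for i in range(120)], ["M0", "M1"], Y.astype(np.uint8))
        part = partition_modules(labels)
        cfg = ClassifierConfig(
            hidden_layers=0, hidden_units=1, epochs=300, batch_size=32,
            learning_rate=0.05, patience=30, seed=0,
        )
        pair = train_model_pair(feats, labels, part, cfg)
        proba = pair.predict_proba(X)
        for j, mid in enumerate(labels.module_ids):
            if mid in proba:
                assert ((proba[mid] >= 0.5) == (Y[:, j] > 0.5)).mean() > 0.9

    def test_same_seed_reproduces_training(self):
        rng = np.random.default_rng(1)
        X = (rng.random((100, 12)) < 0.4).astype(np.float32)
        Y = X[:, :3].astype(np.float32)

        def train_once():
            m = MultiLabelMLP(12, 3, hidden_layers=1, hidden_units=16, seed=42)
            m.fit(X[:80], Y[:80], X[80:], Y[80:], epochs=5, batch_size=16)
            return m

        m1, m2 = train_once(), train_once()
        assert m1.history["val_loss"] == m2.history["val_loss"]
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)

    def test_row_count_mismatch_rejected(self):
        feats = FeatureMatrix(["a"], ["K1"], np.zeros((1, 1), dtype=np.uint8))
        labels = _labels_with_prevalence([0.5], n=10)
        part = partition_modules(labels)
        with pytest.raises(ValueError):
            train_model_pair(feats, labels, part, ClassifierConfig())


class TestPredict:
    def test_complete_module_bypasses_model(self, small_world, trained_pair):
        world = small_world
        # pick a genome completing at least one module
        i, j = np.argwhere(world.labels.labels == 1)[0]
        genome = world.genomes[i]
        mid = world.labels.module_ids[j]
        recs = predict_modules(trained_pair, genome, world.catalog)
        rec = next(r for r in recs if r.module_id == mid)
        assert rec.status == "complete"
        assert rec.probability == 1.0
        assert rec.gap_fill_kos == frozenset()

    def test_complete_modules_never_predicted_absent(self, small_world, trained_pair):
        from modcast.grammar import evaluate_module

        for genome in small_world.genomes[:20]:
            for rec in predict_modules(trained_pair, genome, small_world.catalog):
                ast = next(a for a in small_world.catalog if a.module_id == rec.module_id)
                if evaluate_module(ast, genome.kos).status == "complete":
                    assert rec.status == "complete"

    def test_threshold_boundary_inclusive(self, small_world):
        """sigmoid(0) = 0.5 exactly: with all-zero weights every incomplete
        module sits on the threshold and must be called present."""
        universe = small_world.ko_universe
        part = partition_modules(small_world.labels)
        n_b, n_i = len(part.balanced_modules), len(part.imbalanced_modules)
        zero_b = MultiLabelMLP(len(universe), n_b, hidden_layers=0, seed=0)
        zero_i = MultiLabelMLP(len(universe), n_i, hidden_layers=0, seed=0)
        for m in (zero_b, zero_i):
            m.weights = [np.zeros_like(w) for w in m.weights]
            m.biases = [np.zeros_like(b) for b in m.biases]
        pair = ModelPair(zero_b, zero_i, universe, part, ClassifierConfig(threshold=0.5))
        genome = GenomeAnnotation("empty", set())
        recs = predict_modules(pair, genome, small_world.catalog)
        for rec in recs:
            if rec.module_id in part.retained_modules:
                assert rec.probability == 0.5
                assert rec.status == "predicted_present"
                # gap filling attached to predicted-present incomplete modules
                assert rec.gap_fill_kos

    def test_requested_subset_and_unknown_module(self, small_world, trained_pair):
        mid = small_world.catalog[0].module_id
        recs = predict_modules(
            trained_pair, small_world.genomes[0], small_world.catalog, requested=[mid]
        )
        assert [r.module_id for r in recs] == [mid]
        with pytest.raises(KeyError, match="M_unknown"):
            predict_modules(
                trained_pair,
                small_world.genomes[0],
                small_world.catalog,
                requested=["M_unknown"],
            )

    def test_gap_fill_completes_the_module(self, small_world, trained_pair):
        from modcast.grammar import evaluate_module

        for genome in small_world.genomes[:10]:
            for rec in predict_modules(trained_pair, genome, small_world.catalog):
                if rec.status == "predicted_present":
                    ast = next(
                        a for a in small_world.catalog if a.module_id == rec.module_id
                    )
                    assert (
                        evaluate_module(ast, genome.kos | rec.gap_fill_kos).status
                        == "complete"
                    )


def test_model_archive_round_trip(tmp_path, small_world, trained_pair):
    from modcast.annotation_io import build_feature_matrix

    path = tmp_path / "pair.modcast.zip"
    trained_pair.save(path)
    back = ModelPair.load(path)
    feats = build_feature_matrix(small_world.genomes[:5], trained_pair.ko_universe)
    X = feats.bits.astype(np.float32)
    p1 = trained_pair.predict_proba(X)
    p2 = back.predict_proba(X)
    assert p1.keys() == p2.keys()
    for k in p1:
        assert np.allclose(p1[k], p2[k])
    assert back.ko_universe == trained_pair.ko_universe
    assert back.partition.balanced_modules == trained_pair.partition.balanced_modules
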