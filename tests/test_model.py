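import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from acetylsite import encode, mdd, model
from acetylsite.model import compute_metrics
from acetylsite.seqio import ProteinRecord

from conftest import make_fragment


def _blobs(n=50, separation=6.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n, 2))
    b = rng.normal(separation, 1.0, size=(n, 2))
    X = np.vstack([a, b])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "counts,mcc",
        [((50, 0, 50, 0), 1.0), ((25, 25, 25, 25), 0.0), ((0, 50, 0, 50), -1.0)],
    )
    def test_mcc_identities(self, counts, mcc):
        assert compute_metrics(*counts).mcc == pytest.approx(mcc)

    def test_worked_example(self):
        report = compute_metrics(3, 1, 4, 1)
        assert report.sn == pytest.approx(0.75)
        assert report.sp == pytest.approx(0.8)
        assert report.acc == pytest.approx(7 / 9)

    def test_matches_direct_arithmetic_on_random_matrices(self):
        """All formula identities vs an independent in-test oracle."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 40, size=4))
            if tp + fp + tn + fn == 0:
                continue
            r = compute_metrics(tp, fp, tn, fn)
            if tp + fn:
                assert r.sn == tp / (tp + fn)
            if tn + fp:
                assert r.sp == tn / (tn + fp)
            if tp + fp:
                assert r.pre == tp / (tp + fp)
            assert r.acc == (tp + tn) / (tp + fp + tn + fn)
            denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
            if denom:
                assert r.mcc == pytest.approx(
                    (tp * tn - fn * fp) / math.sqrt(denom)
                )
                assert -1.0 <= r.mcc <= 1.0

    def test_mcc_against_sklearn(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 30, size=4))
            y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
            y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
            assert compute_metrics(tp, fp, tn, fn).mcc == pytest.approx(
                matthews_corrcoef(y_true, y_pred)
            )

    def test_zero_denominators_flagged(self):
        report = compute_metrics(0, 0, 5, 0)
        assert report.sn is None
        assert report.pre is None
        assert report.mcc == 0.0
        assert not report.mcc_defined

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 1, 0)


class TestTrainClassifier:
    def test_separable_blobs_fit_perfectly(self):
        X, y = _blobs()
        m = model.train_classifier(X, y, gamma=0.5, cost=10.0)
        assert (m.predict(X) == y).mean() == 1.0

    def test_no_signal_gives_majority_rate(self):
        X = np.zeros((40, 2))
        y = np.array([0] * 30 + [1] * 10)
        m = model.train_classifier(X, y, gamma=0.5, cost=1.0)
        assert (m.predict(X) == y).mean() == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            model.train_classifier(np.zeros((5, 2)), [1] * 5, gamma=1.0, cost=1.0)

    def test_deterministic(self):
        X, y = _blobs(seed=3)
        a = model.train_classifier(X, y, gamma=0.5, cost=10.0, seed=1)
        b = model.train_classifier(X, y, gamma=0.5, cost=10.0, seed=1)
        assert np.array_equal(a.predict(X), b.predict(X))


class TestGridSearch:
    def test_single_point_grid(self):
        X, y = _blobs(n=20)
        gamma, cost, _ = model.grid_search(X, y, [0.5], [2.0], k=2)
        assert (gamma, cost) == (0.5, 2.0)

    def test_reported_accuracy_is_reproducible(self):
        X, y = _blobs(n=30, separation=2.0, seed=5)
        gamma, cost, acc = model.grid_search(X, y, [0.1, 1.0], [1.0, 10.0], k=3, seed=2)
        _, _, again = model.grid_search(X, y, [gamma], [cost], k=3, seed=2)
        assert acc == pytest.approx(again)

    def test_separable_data_reaches_high_accuracy(self):
        X, y = _blobs(n=40)
        _, _, acc = model.grid_search(X, y, k=5, seed=1)
        assert acc >= 0.95


class TestCrossValidate:
    def test_each_sample_tested_exactly_once_per_run(self):
        X, y = _blobs(n=25, separation=1.0, seed=2)
        reports, _ = model.cross_validate(X, y, gamma=0.5, cost=1.0, k=5, runs=3)
        for r in reports:
            assert r.tp + r.fp + r.tn + r.fn == len(y)

    def test_single_run_reduces_to_plain_cv(self):
        X, y = _blobs(n=25, seed=4)
        reports, summary = model.cross_validate(X, y, 0.5, 10.0, k=5, runs=1, seed=9)
        assert len(reports) == 1
        assert summary["mean"]["Acc"] == pytest.approx(reports[0].acc)
        assert summary["sd"]["Acc"] == pytest.approx(0.0)

    def test_separable_data_perfect_confusion(self):
        X, y = _blobs(n=25)
        reports, _ = model.cross_validate(X, y, gamma=0.5, cost=10.0, k=5, runs=2)
        for r in reports:
            assert (r.tp, r.fp, r.tn, r.fn) == (25, 0, 25, 0)

    def test_shuffled_labels_are_chance_level(self, default_benchmark):
        """Balanced training on label-shuffled data sits at Acc 0.5 ± 0.05."""
        pos = default_benchmark["positives"]
        neg = default_benchmark["negatives"]
        X = encode.encode_fragments(pos + neg, "AAPC")
        rng = np.random.default_rng(11)
        y = rng.permutation([1] * len(pos) + [0] * len(neg))
        _, summary = model.cross_validate(X, y, gamma=8.0, cost=8.0, k=5, runs=2, seed=1)
        assert summary["mean"]["Acc"] == pytest.approx(0.5, abs=0.05)


@pytest.fixture(scope="module")
def tree_and_sets(default_benchmark):
    pos = default_benchmark["positives"]
    neg = default_benchmark["negatives"]
    tree = mdd.mdd_cluster(pos, max_cluster_size=100)
    return tree, pos, neg


class TestMddModels:
    def test_leaf_positives_disjoint_and_balanced(self, tree_and_sets):
        tree, pos, neg = tree_and_sets
        sets = model.leaf_training_sets(tree, neg, seed=1)
        seen = set()
        for leaf_id, (leaf_pos, leaf_neg) in sets.items():
            assert len(leaf_neg) == len(leaf_pos)
            ids = {(f.protein_id, f.center) for f in leaf_pos}
            assert not ids & seen
            seen |= ids

    def test_deterministic_given_seed(self, tree_and_sets):
        tree, pos, neg = tree_and_sets
        a = model.leaf_training_sets(tree, neg, seed=5)
        b = model.leaf_training_sets(tree, neg, seed=5)
        assert a == b

    def test_tiny_leaf_rejected(self):
        leaf = mdd.MddLeaf(0, [make_fragment("AAAKAAA")])
        tree = mdd.MddTree(leaf, 3, 2, 34.3)
        with pytest.raises(ValueError, match="max_cluster_size"):
            model.leaf_training_sets(tree, [make_fragment("CCCKCCC")], seed=1)

    def test_trained_models_score_their_own_positives(self, tree_and_sets):
        tree, pos, neg = tree_and_sets
        models = model.train_mdd_models(tree, neg, "AAPC", gamma=8.0, cost=8.0, seed=1)
        assert set(models) == {leaf.id for leaf in tree.leaves()}
        leaf = tree.leaves()[0]
        X = encode.encode_fragments(leaf.members[:20], "AAPC")
        assert models[leaf.id].predict(X).mean() >= 0.9


class TestPredictSites:
    def test_no_lysine_empty(self):
        X, y = _blobs(n=10)
        # Model trained on 2D toys is irrelevant: no K means no fragments.
        m = model.train_classifier(X, y, gamma=0.5, cost=1.0)
        m.scheme = "AAC"
        table = model.predict_sites(m, ProteinRecord("P1", "AAAA"), n=3)
        assert table.empty

    def test_resubstitution_and_determinism(self, default_benchmark):
        pos = default_benchmark["positives"]
        neg = default_benchmark["negatives"]
        X = encode.encode_fragments(pos + neg, "AAPC")
        y = [1] * len(pos) + [0] * len(neg)
        m = model.train_classifier(X, y, gamma=8.0, cost=8.0)
        m.scheme = "AAPC"
        by_id = {p.id: p for p in default_benchmark["proteins"]}
        protein = by_id[pos[0].protein_id]
        first = model.predict_sites(m, protein, n=7)
        second = model.predict_sites(m, protein, n=7)
        assert first.equals(second)
        row = first[first.position == pos[0].center].iloc[0]
        assert row.call == "positive"

    def test_bundle_roundtrip(self, default_benchmark, tmp_path):
        pos = default_benchmark["positives"]
        neg = default_benchmark["negatives"]
        tree = mdd.mdd_cluster(pos, max_cluster_size=100)
        models = model.train_mdd_models(tree, neg, "AAPC", gamma=8.0, cost=8.0, seed=1)
        model.save_bundle(tmp_path, "AAPC", 7, tree=tree, leaf_models=models)
        manifest, loaded, loaded_tree = model.load_bundle(tmp_path)
        assert manifest["scheme"] == "AAPC"
        by_id = {p.id: p for p in default_benchmark["proteins"]}
        protein = by_id[pos[0].protein_id]
        original = model.predict_sites(models, protein, n=7, tree=tree)
        reloaded = model.predict_sites(loaded, protein, n=7, tree=loaded_tree)
        assert original.equals(reloaded)
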