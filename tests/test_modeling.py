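import copy

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from ksphos import dataset, modeling, synthetic
from ksphos.modeling import (
    ConfusionMatrix,
    ModelSpec,
    PhosphositeModel,
    auc,
    compute_metrics,
    cross_validate,
    cluster_features,
    load_registry,
    predict_sites,
    save_registry,
    train,
    weighted_metrics,
)
from ksphos.windowing import ResidueClass


def brute_force_auc(y, scores):
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_symmetric_confusion_matrix(self):
        m = compute_metrics(ConfusionMatrix(tp=40, tn=40, fp=10, fn=10))
        assert m == {
            "accuracy": 0.8,
            "recall": 0.8,
            "precision": 0.8,
            "f1": pytest.approx(0.8),
        }

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(tp=10, tn=10, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_degenerate_denominators_zero_convention(self):
        m = compute_metrics(ConfusionMatrix(tp=0, tn=10, fp=0, fn=5))
        assert m["recall"] == 0.0
        assert m["precision"] == 0.0
        assert m["f1"] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(0, 0, 0, 0))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_counting(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 2, size=100)
        y_pred = rng.integers(0, 2, size=100)
        cm = ConfusionMatrix.from_labels(y_true, y_pred)
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
        tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)
        m = compute_metrics(cm)
        assert m["accuracy"] == pytest.approx((tp + tn) / 100, abs=1e-12)


class TestWeightedMetrics:
    def test_perfect_balanced(self):
        y = [0, 1] * 10
        m = weighted_metrics(y, y)
        assert all(v == pytest.approx(1.0) for v in m.values())

    def test_perfect_imbalanced_recall_is_one(self):
        y = [1] * 90 + [0] * 10
        assert weighted_metrics(y, y)["weighted_recall"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_weighted_recall_equals_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 2, size=200)
        y_pred = rng.integers(0, 2, size=200)
        m = weighted_metrics(y_true, y_pred)
        accuracy = (y_true == y_pred).mean()
        assert m["weighted_recall"] == pytest.approx(accuracy, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_weighted_precision_f1_match_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 2, size=200)
        y_pred = rng.integers(0, 2, size=200)
        m = weighted_metrics(y_true, y_pred)
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0
        )
        assert m["weighted_precision"] == pytest.approx(p, abs=1e-12)
        assert m["weighted_recall"] == pytest.approx(r, abs=1e-12)
        assert m["weighted_f1"] == pytest.approx(f1, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_metrics([], [])


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1, 1], [0.1, 0.2, 0.3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=30)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        scores = np.round(rng.random(30), 1)  # coarse grid forces ties
        assert auc(y, scores) == pytest.approx(
            brute_force_auc(y, scores), abs=1e-12
        )


class TestTraining:
    def test_resubstitution_accuracy_on_separable_motif(self, trained_gbtree, motif_cluster):
        cluster, _, _ = motif_cluster
        X, y = cluster_features(cluster)
        y_pred = (trained_gbtree.predict_proba(X) >= 0.5).astype(int)
        assert (y_pred == y).mean() >= 0.95

    def test_deterministic_for_fixed_seed(self, motif_cluster):
        cluster, _, _ = motif_cluster
        X, _ = cluster_features(cluster)
        probe = X[:25]
        a = train(cluster, ModelSpec(seed=3)).predict_proba(probe)
        b = train(cluster, ModelSpec(seed=3)).predict_proba(probe)
        assert np.array_equal(a, b)

    def test_single_class_cluster_rejected(self, motif_cluster):
        cluster, _, _ = motif_cluster
        broken = copy.copy(cluster)
        broken.negatives = []
        with pytest.raises(ValueError, match="single class"):
            train(broken)


class TestCrossValidation:
    def test_k_below_two_rejected(self, motif_cluster):
        cluster, _, _ = motif_cluster
        with pytest.raises(ValueError, match="k >= 2"):
            cross_validate(cluster, k=1)

    def test_class_too_small_to_stratify_rejected(self):
        motif = synthetic.make_motif([-2], ResidueClass.ST, 1.0, seed=0)
        frag = synthetic.plant_sites(motif, 15, 40, 1, seed=0)
        cluster = dataset.assemble_cluster(
            frag.sites, frag.proteins, "K", "kinase", ResidueClass.ST
        )
        with pytest.raises(ValueError, match="stratify"):
            cross_validate(cluster, k=40)

    def test_folds_partition_data_and_report_is_deterministic(self, motif_cluster):
        cluster, _, _ = motif_cluster
        r1 = cross_validate(cluster, k=5, seed=2)
        r2 = cross_validate(cluster, k=5, seed=2)
        assert r1.as_dict() == r2.as_dict()
        assert r1.folds.shape[0] == 5
        assert all(0 <= v <= 1 for v in r1.as_dict().values())


class TestPrediction:
    def test_no_candidates_gives_empty_output(self, trained_gbtree):
        from ksphos.seqio import ProteinRecord

        protein = ProteinRecord(id="q", sequence="MKLAGGIL")
        assert predict_sites([protein], [trained_gbtree], include_all=True) == []

    def test_empty_model_list_rejected(self, motif_cluster):
        _, frag, _ = motif_cluster
        with pytest.raises(ValueError, match="no models"):
            predict_sites(frag.proteins[:1], [])

    def test_planted_site_is_top_scoring_candidate(self, trained_gbtree, motif_cluster):
        _, frag, _ = motif_cluster
        protein = frag.proteins[0]
        planted = set(frag.truth["planted_positions"][protein.id])
        preds = predict_sites([protein], [trained_gbtree], include_all=True)
        best = max(preds, key=lambda p: p.score)
        assert best.position in planted

    def test_known_sites_flagged_experimental(self, trained_gbtree, motif_cluster):
        _, frag, _ = motif_cluster
        protein = frag.proteins[0]
        known = [s for s in frag.sites if s.substrate_id == protein.id]
        preds = predict_sites(
            [protein], [trained_gbtree], known_sites=known, include_all=True
        )
        by_pos = {p.position: p for p in preds}
        for site in known:
            assert by_pos[site.position].source == "Exp."
        others = [p for p in preds if p.position not in {s.position for s in known}]
        assert all(p.source == "Pred." for p in others)

    def test_call_consistent_with_threshold(self, trained_gbtree, motif_cluster):
        _, frag, _ = motif_cluster
        preds = predict_sites(frag.proteins[:3], [trained_gbtree], include_all=True)
        for p in preds:
            assert (p.call == "phospho") == (p.score >= 0.5)


class TestRegistry:
    def test_roundtrip_preserves_predictions(self, trained_gbtree, motif_cluster, tmp_path):
        cluster, _, _ = motif_cluster
        svm = train(cluster, ModelSpec(algorithm="svm", seed=1))
        X, _ = cluster_features(cluster)
        probe = X[:30]
        save_registry([trained_gbtree, svm], tmp_path / "reg")
        loaded = load_registry(tmp_path / "reg")
        assert len(loaded) == 2
        for before, after in zip([trained_gbtree, svm], loaded):
            assert after.model_id == before.model_id
            assert np.array_equal(
                before.predict_proba(probe), after.predict_proba(probe)
            )

    def test_corrupted_index_rejected(self, tmp_path):
        reg = tmp_path / "reg"
        reg.mkdir()
        (reg / "index.json").write_text("{not json")
        with pytest.raises(ValueError, match="registry"):
            load_registry(reg)

    def test_version_mismatch_rejected(self, tmp_path):
        reg = tmp_path / "reg"
        reg.mkdir()
        (reg / "index.json").write_text('{"version": 99, "models": []}')
        with pytest.raises(ValueError, match="version"):
            load_registry(reg)


class TestModelResultsApi:
    def test_fit_summary_and_predict(self, motif_cluster):
        cluster, frag, _ = motif_cluster
        res = PhosphositeModel(cluster, ModelSpec(seed=1)).fit()
        res.cross_validate(k=4, seed=1)
        text = res.summary()
        assert "PLANTED" in text and "cross-validation" in text
        frame = res.predict(frag.proteins[:1], include_all=True)
        assert set(frame.columns) >= {"protein_id", "position", "score", "call"}
        assert len(frame) > 0

    def test_from_tables_rejects_small_cluster(self):
        motif = synthetic.make_motif([-2], ResidueClass.ST, 1.0, seed=0)
        frag = synthetic.plant_sites(motif, 10, 40, 1, seed=0)
        with pytest.raises(ValueError, match="rejected"):
            PhosphositeModel.from_tables(
                frag.sites, frag.proteins, "K", level="kinase"
            )
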