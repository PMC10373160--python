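import math

import numpy as np
import pytest
import xgboost

from ksphos import explain, modeling
from ksphos.explain import (
    differential_logo,
    exact_shapley,
    explain_instances,
    group_by_position,
    permutation_shapley,
    sequence_logo,
    tree_shap_interventional,
)
from ksphos.modeling import ModelSpec, cluster_features, train
from ksphos.windowing import Window


class TestExactShapley:
    def test_linear_model_gives_coefficient_times_deviation(self):
        f = lambda pts: 3.0 * pts[:, 0]
        exp = exact_shapley(f, np.array([2.0, 5.0]), np.array([0.0, 1.0]))
        assert exp.values[0] == pytest.approx(6.0)
        assert exp.values[1] == pytest.approx(0.0)

    def test_symmetry_axiom(self):
        f = lambda pts: pts[:, 0] + pts[:, 1]
        exp = exact_shapley(f, np.array([1.0, 1.0]), np.array([0.0, 0.0]))
        assert exp.values[0] == pytest.approx(exp.values[1])

    def test_dummy_axiom(self):
        f = lambda pts: pts[:, 0] * pts[:, 2]
        exp = exact_shapley(
            f, np.array([1.0, 9.0, 2.0]), np.array([0.0, -3.0, 0.0])
        )
        assert exp.values[1] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_additivity_for_nonlinear_scorers(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.normal(size=6)

        def f(pts):
            return np.tanh(pts @ w) + 0.5 * pts[:, 0] * pts[:, 3]

        x, bg = rng.normal(size=6), rng.normal(size=6)
        exp = exact_shapley(f, x, bg)
        assert exp.additivity_gap < 1e-10

    def test_refuses_large_m(self):
        f = lambda pts: pts.sum(axis=1)
        with pytest.raises(ValueError, match="intractable"):
            exact_shapley(f, np.zeros(20), np.zeros(20))


def _tiny_booster(n_features=8, depth=3, n_trees=15, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(300, n_features))
    y = (X[:, 1] + X[:, 3] * X[:, 5] + 0.3 * rng.normal(size=300) > 0).astype(int)
    clf = xgboost.XGBClassifier(
        n_estimators=n_trees, max_depth=depth, learning_rate=0.3,
        random_state=seed, n_jobs=1,
    )
    clf.fit(X, y)
    return clf.get_booster(), X


class TestTreeAttribution:
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exact_enumeration_oracle(self, seed):
        booster, X = _tiny_booster(seed=seed)
        rng = np.random.default_rng(100 + seed)
        bg = rng.normal(size=(1, 8))
        instances = X[:3]
        phi, base, margins = tree_shap_interventional(booster, instances, bg)

        def margin_fn(pts):
            return booster.predict(xgboost.DMatrix(pts), output_margin=True)

        for i in range(3):
            oracle = exact_shapley(margin_fn, instances[i], bg[0])
            # booster predictions are float32; agreement is to that precision
            assert np.abs(oracle.values - phi[i]).max() < 1e-5
            assert abs(base + phi[i].sum() - margins[i]) < 1e-6

    def test_multi_background_additivity(self):
        booster, X = _tiny_booster()
        bg = X[50:60]
        phi, base, margins = tree_shap_interventional(booster, X[:5], bg)
        np.testing.assert_allclose(base + phi.sum(axis=1), margins, atol=1e-9)

    def test_constant_model_attributes_nothing(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        y = np.ones(50, dtype=int)
        y[0] = 0  # keep two classes but no signal in features
        X[0] = X[1]  # identical features, different labels: no split possible
        clf = xgboost.XGBClassifier(
            n_estimators=5, max_depth=1, min_child_weight=100, random_state=0, n_jobs=1
        )
        clf.fit(X, y)
        phi, base, margins = tree_shap_interventional(clf.get_booster(), X[:4], X[5:9])
        assert np.abs(phi).max() < 1e-12
        np.testing.assert_allclose(margins, base, atol=1e-9)


class TestPermutationShapley:
    def test_additivity_exact_by_construction(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=10)
        f = lambda pts: np.tanh(pts @ w)
        X = rng.normal(size=(4, 10))
        bg = rng.normal(size=(3, 10))
        phi, base, outputs = permutation_shapley(f, X, bg, n_permutations=5, seed=0)
        np.testing.assert_allclose(base + phi.sum(axis=1), outputs, atol=1e-12)

    def test_converges_to_exact_values_on_linear_model(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=6)
        f = lambda pts: pts @ w
        x = rng.normal(size=(1, 6))
        bg = rng.normal(size=(1, 6))
        phi, _, _ = permutation_shapley(f, x, bg, n_permutations=10, seed=0)
        # linear model: Shapley value is w_i * (x_i - bg_i) for any ordering
        np.testing.assert_allclose(phi[0], w * (x[0] - bg[0]), atol=1e-10)


class TestExplainInstances:
    def test_gbtree_explanations_additive_and_ordered(self, trained_gbtree, motif_cluster):
        cluster, _, _ = motif_cluster
        X, _ = cluster_features(cluster)
        exps = explain_instances(trained_gbtree, X[:20], X[200:], seed=0)
        assert len(exps) == 20
        assert [e.instance_index for e in exps] == list(range(20))
        assert max(e.additivity_gap for e in exps) < 1e-6

    def test_svm_explanations_additive(self, motif_cluster):
        cluster, _, _ = motif_cluster
        svm = train(cluster, ModelSpec(algorithm="svm", seed=1))
        X, _ = cluster_features(cluster)
        exps = explain_instances(
            svm, X[:2], X[200:], max_background=2, n_permutations=3, seed=0
        )
        assert max(e.additivity_gap for e in exps) < 1e-3

    def test_layout_mismatch_rejected(self, trained_gbtree):
        with pytest.raises(ValueError, match="features"):
            explain_instances(trained_gbtree, np.zeros((1, 40)), np.zeros((1, 300)))


class TestGrouping:
    def test_exactly_one_group_per_window_position(self, trained_gbtree, motif_cluster):
        cluster, _, _ = motif_cluster
        X, _ = cluster_features(cluster)
        exps = explain_instances(trained_gbtree, X[:10], X[200:], seed=0)
        att = group_by_position(exps, trained_gbtree.layout)
        assert len(att.positions) == 15
        assert att.positions == list(range(-7, 8))

    def test_group_values_conserve_total_attribution(self, trained_gbtree, motif_cluster):
        cluster, _, _ = motif_cluster
        X, _ = cluster_features(cluster)
        exps = explain_instances(trained_gbtree, X[:10], X[200:], seed=0)
        att = group_by_position(exps, trained_gbtree.layout)
        for i, e in enumerate(exps):
            assert att.group_values[i].sum() == pytest.approx(e.values.sum(), abs=1e-9)

    def test_planted_positions_rank_top_two(self, trained_gbtree, motif_cluster):
        cluster, _, motif = motif_cluster
        X, _ = cluster_features(cluster)
        exps = explain_instances(trained_gbtree, X[:100], X[200:], seed=0)
        att = group_by_position(exps, trained_gbtree.layout)
        assert set(att.ranking()[:2]) == set(motif.informative_positions)

    def test_indivisible_width_rejected(self):
        exp = explain.ShapExplanation(0.0, np.zeros(30), 0.0)
        with pytest.raises(ValueError, match="divisible"):
            group_by_position([exp], [(-1, "A")] * 30)


def _windows(seqs):
    return [Window("p", 8, s) for s in seqs]


class TestSequenceLogo:
    def test_conserved_column_has_full_information(self):
        logo = sequence_logo(_windows(["AAAAAAASAAAAAAA"] * 10))
        assert logo.information.loc[-7] == pytest.approx(math.log2(20))

    def test_uniform_column_has_zero_information(self):
        seqs = [aa + "AAAAAA" + "S" + "AAAAAAA" for aa in "ARNDCQEGHILKMFPSTWYV"]
        logo = sequence_logo(_windows(seqs))
        assert logo.information.loc[-7] == pytest.approx(0.0, abs=1e-12)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        seqs = [
            "".join(rng.choice(list("ACDEFG"), 7)) + "S" + "".join(rng.choice(list("ACDEFG"), 7))
            for _ in range(30)
        ]
        logo = sequence_logo(_windows(seqs))
        sums = logo.frequencies.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)

    def test_all_pad_position_flagged(self):
        logo = sequence_logo(_windows(["-AAAAAASAAAAAAA"] * 5))
        assert logo.all_pad_positions == [-7]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sequence_logo([])


class TestDifferentialLogo:
    def test_identical_sets_give_zero_scores(self):
        wins = _windows(["ACDEFGHSKLMNPQR", "MMMMMMMSMMMMMMM"])
        diff = differential_logo(wins, list(wins))
        assert np.abs(diff.scores.to_numpy()).max() == 0.0

    def test_fully_enriched_residue_strongly_positive(self):
        pos = _windows(["W" + "AAAAAA" + "S" + "AAAAAAA"] * 100)
        neg = _windows(["M" + "AAAAAA" + "S" + "AAAAAAA"] * 100)
        diff = differential_logo(pos, neg)
        assert diff.scores.loc[-7, "W"] > 6

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(1)
        mk = lambda: _windows(
            [
                "".join(rng.choice(list("ACDEFGH"), 7)) + "S" + "".join(rng.choice(list("ACDEFGH"), 7))
                for _ in range(40)
            ]
        )
        a, b = mk(), mk()
        d1 = differential_logo(a, b).scores.to_numpy()
        d2 = differential_logo(b, a).scores.to_numpy()
        np.testing.assert_allclose(d1, -d2, atol=1e-12)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            differential_logo(_windows(["A" * 15]), [])
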