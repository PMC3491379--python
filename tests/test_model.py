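"""Bagged ensemble: bootstrap, OOB discipline, prediction, evaluation."""

import numpy as np
import pandas as pd
import pytest

from girewire import (
    DegreeTable,
    GIDegreeModel,
    OrthologyMap,
    Parameters,
    ablation_variants,
    bootstrap_sample,
    degree_percentiles,
    feature_degree_correlations,
    fit_ensemble,
    ortholog_baseline,
    read_ensemble,
    write_ensemble,
)
from girewire.model import (
    GIDegreeResults,
    PredictionTable,
    TreeEnsemble,
    evaluate,
)
from girewire.tree import RegressionTree, TreeNode

from conftest import make_feature_table


def constant_tree(value, n):
    return RegressionTree([TreeNode(-1, np.nan, -1, -1, float(value), n)], ["f0"])


def toy_ensemble(leaf_values, in_bag, genes):
    """Ensemble of single-leaf (constant) trees with hand-set in-bag counts."""
    trees = [constant_tree(v, len(genes)) for v in leaf_values]
    return TreeEnsemble(
        trees=trees,
        in_bag=np.asarray(in_bag, dtype=int),
        gene_ids=list(genes),
        species="species1",
        seed=0,
        feature_names=["f0"],
    )


def toy_results(ens):
    ft = make_feature_table(ens.gene_ids)
    dt = DegreeTable(
        species="species1",
        degrees=pd.Series(np.arange(len(ens.gene_ids)), index=ens.gene_ids),
    )

    class _Shim:
        pass

    model = _Shim()
    model._X = ft.data[ens.feature_names].to_numpy() if set(ens.feature_names) <= set(
        ft.data.columns
    ) else np.zeros((len(ens.gene_ids), 1))
    model.gene_ids = ens.gene_ids
    return GIDegreeResults(model, ens)


class TestBootstrap:
    def test_n_one(self):
        rng = np.random.default_rng(0)
        counts, oob = bootstrap_sample(1, rng)
        assert counts.tolist() == [1] and len(oob) == 0

    def test_n_zero_error(self):
        with pytest.raises(ValueError):
            bootstrap_sample(0, np.random.default_rng(0))

    def test_distinct_fraction_small_n(self):
        # analytic: expected distinct fraction = 1 - (1 - 1/n)^n
        rng = np.random.default_rng(5)
        fracs = [
            np.count_nonzero(bootstrap_sample(10, rng)[0]) / 10 for _ in range(4000)
        ]
        assert np.mean(fracs) == pytest.approx(1 - 0.9**10, abs=0.005)

    def test_distinct_fraction_large_n(self):
        # each tree trains on ~63.2% of genes
        rng = np.random.default_rng(6)
        fracs = [
            np.count_nonzero(bootstrap_sample(5000, rng)[0]) / 5000 for _ in range(20)
        ]
        assert np.mean(fracs) == pytest.approx(0.632, abs=0.005)


class TestFitEnsemble:
    def test_determinism(self, small_pair, tmp_path):
        params = Parameters(n_trees=5)
        m = GIDegreeModel(small_pair.features1, small_pair.degrees1, params=params)
        a, b = m.fit(seed=7), m.fit(seed=7)
        write_ensemble(a.ensemble, tmp_path / "a.txt")
        write_ensemble(b.ensemble, tmp_path / "b.txt")
        assert (tmp_path / "a.txt").read_text() == (tmp_path / "b.txt").read_text()

    def test_overlap_too_small(self):
        ft = make_feature_table([f"g{i}" for i in range(30)])
        dt = DegreeTable(
            species="species1", degrees=pd.Series([1] * 5, index=[f"g{i}" for i in range(5)])
        )
        with pytest.raises(ValueError, match="overlap"):
            GIDegreeModel(ft, dt)

    def test_oob_rate_near_368(self, small_pair):
        params = Parameters(n_trees=100)
        res = GIDegreeModel(
            small_pair.features1, small_pair.degrees1, params=params
        ).fit(0)
        oob_frac = (res.ensemble.in_bag == 0).mean()
        assert oob_frac == pytest.approx((1 - 1 / 300) ** 300, abs=0.02)

    def test_single_tree_equals_grow_tree(self, small_pair):
        from girewire.tree import grow_tree

        params = Parameters(n_trees=1)
        m = GIDegreeModel(small_pair.features1, small_pair.degrees1, params=params)
        res = m.fit(seed=3)
        counts = res.ensemble.in_bag[0]
        idx = np.repeat(np.arange(len(m.gene_ids)), counts)
        ref = grow_tree(m._X[idx], m._y[idx], min_split=params.min_split,
                        feature_names=m.feature_names)
        X = m._X
        np.testing.assert_allclose(res.ensemble.trees[0].predict(X), ref.predict(X))

    def test_serialization_round_trip(self, small_pair, tmp_path):
        params = Parameters(n_trees=3)
        res = GIDegreeModel(
            small_pair.features1, small_pair.degrees1, params=params
        ).fit(1)
        write_ensemble(res.ensemble, tmp_path / "ens.txt")
        back = read_ensemble(tmp_path / "ens.txt")
        assert back.gene_ids == res.ensemble.gene_ids
        np.testing.assert_array_equal(back.in_bag, res.ensemble.in_bag)
        X = small_pair.features1.data[back.feature_names].to_numpy()
        for t0, t1 in zip(res.ensemble.trees, back.trees):
            np.testing.assert_allclose(t0.predict(X), t1.predict(X))


class TestPredictions:
    def test_oob_median_odd(self):
        ens = toy_ensemble([3, 5, 7, 100], [[0], [0], [0], [2]], ["g"])
        pred = toy_results(ens).predict_within()
        assert pred.predictions["g"] == 5  # tree 4 in-bag -> excluded
        assert pred.n_trees_used["g"] == 3

    def test_in_bag_everywhere_missing(self):
        ens = toy_ensemble([1, 2], [[1], [1]], ["g"])
        pred = toy_results(ens).predict_within()
        assert np.isnan(pred.predictions["g"])
        assert pred.n_trees_used["g"] == 0

    def test_oob_median_even_mean_of_middle(self):
        ens = toy_ensemble([1, 2, 8, 9], [[0], [0], [0], [0]], ["g"])
        pred = toy_results(ens).predict_within()
        assert pred.predictions["g"] == 5.0

    def test_cross_all_constant(self):
        ens = toy_ensemble([4.0] * 10, [[1]] * 10, ["g"])
        ft = make_feature_table(["x", "y"], species="species2")
        ens.feature_names = list(ft.data.columns)
        pred = toy_results(ens).predict_cross(ft)
        assert (pred.predictions == 4.0).all()
        assert (pred.n_trees_used == 10).all()

    def test_cross_toy_hand_median(self):
        ens = toy_ensemble([2.0, 6.0, 10.0], [[1]] * 3, ["g"])
        ft = make_feature_table(["x"], species="species2")
        ens.feature_names = list(ft.data.columns)
        pred = toy_results(ens).predict_cross(ft)
        assert pred.predictions["x"] == 6.0

    def test_tree_order_permutation_invariance(self, small_pair, rng):
        params = Parameters(n_trees=8)
        res = GIDegreeModel(
            small_pair.features1, small_pair.degrees1, params=params
        ).fit(2)
        base = res.predict_within().predictions
        order = rng.permutation(8)
        ens = res.ensemble
        permuted = TreeEnsemble(
            trees=[ens.trees[i] for i in order],
            in_bag=ens.in_bag[order],
            gene_ids=ens.gene_ids,
            species=ens.species,
            seed=ens.seed,
            feature_names=ens.feature_names,
        )
        res2 = GIDegreeResults(res.model, permuted)
        pd.testing.assert_series_equal(base, res2.predict_within().predictions)

    def test_oob_discipline_instrumented(self, small_pair):
        """Within-species predictions use exactly the trees excluding each gene."""
        params = Parameters(n_trees=12)
        res = GIDegreeModel(
            small_pair.features1, small_pair.degrees1, params=params
        ).fit(4)
        ens = res.ensemble
        pred = res.predict_within()
        X = res.model._X
        all_preds = np.vstack([t.predict(X) for t in ens.trees])
        for col in range(0, len(ens.gene_ids), 17):
            gene = ens.gene_ids[col]
            oob_trees = np.flatnonzero(ens.in_bag[:, col] == 0)
            assert pred.n_trees_used[gene] == len(oob_trees)
            if len(oob_trees):
                assert pred.predictions[gene] == pytest.approx(
                    np.median(all_preds[oob_trees, col])
                )

    def test_within_wrong_species_rejected(self, small_pair):
        params = Parameters(n_trees=2)
        res = GIDegreeModel(
            small_pair.features1, small_pair.degrees1, params=params
        ).fit(0)
        with pytest.raises(ValueError, match="species"):
            res.predict_within(small_pair.features2)


class TestEvaluate:
    def _const_refit(self, preds):
        def refit(seed):
            return PredictionTable(
                species="s",
                predictions=pd.Series(preds, dtype=float),
                n_trees_used=pd.Series(1, index=preds.keys()),
            )

        return refit

    def test_perfect_correlation(self):
        actual = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        res = evaluate(self._const_refit(actual.to_dict()), actual, n_repeats=2)
        assert res.mean_r == pytest.approx(1.0)
        assert res.sd_r == 0.0

    def test_anticorrelation(self):
        actual = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        preds = {"a": 3.0, "b": 2.0, "c": 1.0}
        res = evaluate(self._const_refit(preds), actual, n_repeats=1)
        assert res.mean_r == pytest.approx(-1.0)

    def test_closed_form_example(self):
        # hand computation: cov = 8/5, sd_x = sd_y = sqrt(2), r = 8/10
        actual = pd.Series([1, 2, 3, 4, 5], index=list("abcde"), dtype=float)
        preds = dict(zip("abcde", [2.0, 1.0, 4.0, 3.0, 5.0]))
        res = evaluate(self._const_refit(preds), actual, n_repeats=1)
        assert res.mean_r == pytest.approx(0.8)

    def test_zero_variance_error(self):
        actual = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        with pytest.raises(ValueError, match="variance"):
            evaluate(self._const_refit({"a": 1.0, "b": 2.0, "c": 3.0}), actual, 1)


class TestCorrelationsTable:
    def test_feature_equal_to_degree(self, rng):
        genes = [f"g{i}" for i in range(40)]
        deg = rng.integers(0, 60, size=40)
        ft = make_feature_table(genes, sm_fitness_defect=deg.astype(float), rng=rng)
        dt = DegreeTable(species="species1", degrees=pd.Series(deg, index=genes))
        tab = feature_degree_correlations(ft, dt).set_index("feature")
        assert tab.loc["sm_fitness_defect", "r"] == pytest.approx(1.0)
        assert tab.loc["sm_fitness_defect", "ci_high"] == pytest.approx(1.0)
        assert tab.index[0] == "sm_fitness_defect"  # ordered by |r|

    def test_independent_feature_ci_covers_zero(self, rng):
        genes = [f"g{i}" for i in range(500)]
        ft = make_feature_table(genes, rng=rng)
        dt = DegreeTable(
            species="species1",
            degrees=pd.Series(rng.integers(0, 50, size=500), index=genes),
        )
        tab = feature_degree_correlations(ft, dt).set_index("feature")
        covers = (tab["ci_low"] <= 0) & (tab["ci_high"] >= 0)
        assert covers.sum() >= 12  # most of 16 independent features

    def test_fisher_z_closed_form(self, rng):
        genes = [f"g{i}" for i in range(50)]
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        deg = np.abs(np.round(10 * y + 30)).astype(int)
        ft = make_feature_table(genes, disorder=x, rng=rng)
        dt = DegreeTable(species="species1", degrees=pd.Series(deg, index=genes))
        tab = feature_degree_correlations(ft, dt).set_index("feature")
        r = tab.loc["disorder", "r"]
        lo = np.tanh(np.arctanh(r) - 1.96 / np.sqrt(50 - 3))
        hi = np.tanh(np.arctanh(r) + 1.96 / np.sqrt(50 - 3))
        assert tab.loc["disorder", "ci_low"] == pytest.approx(lo, abs=1e-4)
        assert tab.loc["disorder", "ci_high"] == pytest.approx(hi, abs=1e-4)


class TestOrthologBaseline:
    def _orth(self):
        return OrthologyMap(
            pairs=pd.DataFrame(
                {"gene_species1": ["a", "b"], "gene_species2": ["x", "y"],
                 "relation": ["one_to_one", "one_to_one"]}
            )
        )

    def test_maps_degree(self):
        dt = DegreeTable(species="species1", degrees=pd.Series({"a": 12, "b": 3}))
        pred = ortholog_baseline(dt, self._orth(), target_side=2)
        assert pred.predictions["x"] == 12

    def test_unmapped_gene_missing(self):
        dt = DegreeTable(species="species1", degrees=pd.Series({"a": 12}))
        pred = ortholog_baseline(dt, self._orth(), target_side=2)
        assert "y" not in pred.predictions.index

    def test_coverage_counting(self, rng):
        n = 30
        g1 = [f"a{i}" for i in range(n)]
        g2 = [f"b{i}" for i in range(n)]
        orth = OrthologyMap(
            pairs=pd.DataFrame(
                {"gene_species1": g1, "gene_species2": g2,
                 "relation": ["one_to_one"] * 20 + ["other"] * 10}
            )
        )
        known = g1[:15]
        dt = DegreeTable(
            species="species1",
            degrees=pd.Series(rng.integers(0, 9, size=15), index=known),
        )
        pred = ortholog_baseline(dt, orth, target_side=2)
        # one-to-one pairs with known source degree: first 15 of the 20
        assert len(pred) == 15


class TestAblation:
    def test_no_fitness_ignores_fitness_column(self, small_pair, rng):
        params = Parameters(n_trees=5)
        out = ablation_variants(small_pair.features1, small_pair.degrees1,
                                params=params, seed=9)
        base = out["no_fitness"].predict_within().predictions
        shuffled = small_pair.features1.data.copy()
        shuffled["sm_fitness_defect"] = rng.permutation(
            shuffled["sm_fitness_defect"].to_numpy()
        )
        ft_perm = type(small_pair.features1)(species="species1", data=shuffled)
        out2 = ablation_variants(ft_perm, small_pair.degrees1, params=params, seed=9)
        pd.testing.assert_series_equal(
            base, out2["no_fitness"].predict_within().predictions
        )

    def test_residual_model_recovers_secondary_signal(self, rng):
        # degree = f(fitness) + g(disorder): the residual model must find g
        n = 400
        genes = [f"g{i}" for i in range(n)]
        fit = rng.uniform(size=n)
        dis = rng.uniform(size=n)
        deg = np.round(40 * fit + 20 * dis + rng.normal(0, 1, n)).clip(0).astype(int)
        ft = make_feature_table(genes, sm_fitness_defect=fit, disorder=dis, rng=rng)
        dt = DegreeTable(species="species1", degrees=pd.Series(deg, index=genes))
        out = ablation_variants(ft, dt, params=Parameters(n_trees=30), seed=1)
        resid_pred = out["residual"].predict_within().predictions
        target = out["residual_target"]
        both = pd.concat([resid_pred, target], axis=1).dropna()
        r = np.corrcoef(both.iloc[:, 0], both.iloc[:, 1])[0, 1]
        assert r > 0.3

    def test_pure_fitness_degree_leaves_no_residual_signal(self, rng):
        n = 300
        genes = [f"g{i}" for i in range(n)]
        fit = rng.uniform(size=n)
        deg = np.round(50 * fit).astype(int)
        ft = make_feature_table(genes, sm_fitness_defect=fit, rng=rng)
        dt = DegreeTable(species="species1", degrees=pd.Series(deg, index=genes))
        out = ablation_variants(ft, dt, params=Parameters(n_trees=20), seed=2)
        pred = out["no_fitness"].predict_within().predictions
        both = pd.concat([pred, dt.degrees], axis=1).dropna()
        r = np.corrcoef(both.iloc[:, 0], both.iloc[:, 1])[0, 1]
        assert abs(r) < 0.25


class TestPercentiles:
    def test_midrank_distinct(self):
        out = degree_percentiles(pd.Series({"a": 10.0, "b": 20.0, "c": 30.0}))
        assert out.tolist() == pytest.approx([1 / 6, 3 / 6, 5 / 6])

    def test_full_tie(self):
        out = degree_percentiles(pd.Series([7.0, 7.0, 7.0, 7.0]))
        assert (out == 0.5).all()

    def test_max_is_largest(self, rng):
        v = pd.Series(rng.choice(100, size=20, replace=False).astype(float))
        out = degree_percentiles(v)
        assert out[v.idxmax()] == pytest.approx((20 - 0.5) / 20)


class TestSpeciesSpecificSubset:
    def test_restricted_evaluation_drops_all_ortholog_genes(self, small_pair):
        """Genes with any ortholog (one-to-one or curated 'other') are removed
        when evaluating on the species-specific subset."""
        orth = small_pair.orthology
        with_orth = orth.genes_with_any_ortholog(side=2)
        specific = [g for g in small_pair.features2.genes if g not in with_orth]
        assert len(specific) > 50
        model = GIDegreeModel(
            small_pair.features1, small_pair.degrees1, params=Parameters(n_trees=10)
        )
        res = model.evaluate(
            actual=small_pair.degrees2, mode="cross",
            test_features=small_pair.features2, n_repeats=2, seed=0,
            restrict_to=specific,
        )
        assert res.n_pairs <= len(specific)
        assert -1 <= res.mean_r <= 1
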