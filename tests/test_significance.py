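import numpy as np
import pandas as pd
import pytest

from tftrans.evaluation import brute_force_bh
from tftrans.significance import (
    RobustnessResult,
    apply_background_filters,
    background_random_tf_sets,
    background_shuffled_residuals,
    bh_adjust,
    empirical_p,
    robustness_test,
)
from tftrans.tf_models import PredictorSet, fit_all, fit_lasso


class TestEmpiricalP:
    def test_observed_above_all_nulls(self):
        assert empirical_p(0.5, np.zeros(100)) == pytest.approx(1 / 101)

    def test_four_of_hundred_at_or_above(self):
        nulls = np.concatenate([np.full(4, 0.6), np.full(96, 0.1)])
        assert empirical_p(0.5, nulls) == pytest.approx(5 / 101)

    def test_all_ties_saturate_to_one(self):
        assert empirical_p(0.0, np.zeros(50)) == 1.0

    def test_values_on_exact_grid_never_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 50))
            p = empirical_p(rng.uniform(), rng.uniform(size=n))
            assert p > 0
            k = round(p * (n + 1))
            assert p == pytest.approx(k / (n + 1))


class TestBH:
    def test_hand_computed_step_up(self):
        adj, flags = bh_adjust(np.array([0.01, 0.02, 0.04]))
        assert np.allclose(adj, [0.03, 0.03, 0.04])
        assert flags.all()

    def test_single_p_identity(self):
        adj, _ = bh_adjust(np.array([0.04]))
        assert adj[0] == pytest.approx(0.04)

    def test_all_equal_unchanged(self):
        adj, flags = bh_adjust(np.full(5, 0.05))
        assert np.allclose(adj, 0.05)
        assert not flags.any()  # strict '<' at alpha=0.05

    def test_empty_vector(self):
        adj, flags = bh_adjust(np.array([]))
        assert adj.size == 0 and flags.size == 0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.0, 0.5]))

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            m = int(rng.integers(1, 30))
            p = rng.uniform(1e-4, 1, size=m)
            adj, _ = bh_adjust(p)
            assert np.allclose(adj, brute_force_bh(p), rtol=1e-12)


def _signal_fit(n=100, p=5, r2=0.6, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X[:, 0] * np.sqrt(r2) + rng.normal(size=n) * np.sqrt(1 - r2)
    pset = PredictorSet("g1", "tf_expression", [f"TF{j}" for j in range(p)],
                        pd.DataFrame(X, columns=[f"TF{j}" for j in range(p)]))
    return fit_lasso(y, pset, folds=5, seed=seed), y, pset


class TestShuffledBackground:
    def test_strong_signal_beats_every_permutation(self):
        fit, y, pset = _signal_fit()
        res = background_shuffled_residuals(fit, y, pset, n_null=30, seed=1, folds=5)
        assert res.p_empirical == pytest.approx(1 / 31)
        assert res.null_r2.shape == (30,)

    def test_null_response_gets_large_p(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 5))
        y = rng.normal(size=100)
        pset = PredictorSet("g1", "tf_expression", [f"TF{j}" for j in range(5)],
                            pd.DataFrame(X, columns=[f"TF{j}" for j in range(5)]))
        fit = fit_lasso(y, pset, folds=5, seed=2)
        res = background_shuffled_residuals(fit, y, pset, n_null=30, seed=3, folds=5)
        assert res.p_empirical > 0.1

    def test_deterministic_given_seed(self):
        fit, y, pset = _signal_fit()
        a = background_shuffled_residuals(fit, y, pset, n_null=10, seed=7, folds=5)
        b = background_shuffled_residuals(fit, y, pset, n_null=10, seed=7, folds=5)
        assert np.array_equal(a.null_r2, b.null_r2)


class TestRandomTFSetBackground:
    def test_untestable_when_pool_smaller_than_true_set(self, small_dataset, small_prep):
        ds = small_dataset
        norm, _, residuals = small_prep
        gene = next(g for g in ds.truth.genes.index if ds.regulatory_map.tfs_of(g))
        fit, y, _ = _signal_fit()
        fit.gene_id = gene
        res = background_random_tf_sets(
            fit, residuals.data[gene].to_numpy(), ds.regulatory_map, ds.annotations,
            norm, ds.genotypes, n_null=5, seed=1, folds=5,
            tf_pool=ds.regulatory_map.tfs_of(gene),  # pool == true set -> empty
        )
        assert res.untestable
        assert res.p_empirical == 1.0

    def test_null_genes_have_calibrated_p_values(self):
        # on trans-null data the fraction of genes with p < 0.05 under the
        # size-matched random-TF null stays near the nominal level
        from tftrans.preprocessing import compute_cis_residuals, fit_cis_models, normalize_expression
        from tftrans.synthetic_data import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(n_samples=80, n_genes=200, n_tfs=120, trans_expr_r2=0.0,
                               trans_bind_r2=0.0, fraction_null_genes=1.0,
                               fraction_genes_with_tf=1.0, seed=77)
        ds = simulate_dataset(cfg)
        norm = normalize_expression(ds.expression, ds.covariates)
        cis = fit_cis_models(ds.genotypes, norm, ds.gene_bounds, folds=5, seed=1)
        resid = compute_cis_residuals(norm, cis)
        fits, _ = fit_all(resid, ds.regulatory_map, ds.annotations, norm, ds.genotypes,
                          "tf_expression", folds=5, seed=2)
        ps = []
        for i, (g, f) in enumerate(sorted(fits.items())):
            res = background_random_tf_sets(
                f, resid.data[g].to_numpy(), ds.regulatory_map, ds.annotations,
                norm, ds.genotypes, n_null=20, seed=1000 + i, folds=5,
            )
            if not res.untestable:
                ps.append(res.p_empirical)
        frac = np.mean(np.asarray(ps) < 0.05)
        assert len(ps) >= 150
        assert 0.01 <= frac <= 0.10


class TestApplyFilters:
    def test_pass_requires_both_null_kinds(self, small_dataset, small_prep):
        ds = small_dataset
        norm, _, residuals = small_prep
        genes = [g for g in residuals.gene_ids if ds.regulatory_map.tfs_of(g)][:6]
        fits, _ = fit_all(residuals, ds.regulatory_map, ds.annotations, norm,
                          ds.genotypes, "tf_expression", folds=5, seed=4, gene_ids=genes)
        rows, passed = apply_background_filters(
            fits, residuals, ds.regulatory_map, ds.annotations, norm, ds.genotypes,
            n_null=25, alpha=0.05, folds=5, seed=5,
        )
        per_gene = rows.groupby("gene_id")["passed_null"].all()
        assert passed == sorted(per_gene.index[per_gene])
        # every result row is on the empirical-p grid and adjusted >= raw
        assert (rows["p_adjusted"] >= rows["p_empirical"] - 1e-12).all()

    def test_empty_candidate_set(self, small_dataset, small_prep):
        ds = small_dataset
        norm, _, residuals = small_prep
        rows, passed = apply_background_filters(
            {}, residuals, ds.regulatory_map, ds.annotations, norm, ds.genotypes,
            n_null=10, folds=5, seed=1,
        )
        assert passed == []
        assert rows.empty


class TestRobustness:
    @pytest.mark.parametrize(
        "n_discovered,expected", [(4, False), (5, True), (10, True)]
    )
    def test_half_of_ten_rule(self, n_discovered, expected):
        assert RobustnessResult("g", "tf_expression", 10, n_discovered).is_hit is expected

    def test_threshold_generalizes_to_ceil_half(self):
        assert not RobustnessResult("g", "m", 3, 1).is_hit
        assert RobustnessResult("g", "m", 3, 2).is_hit

    def test_subsample_runs_count_discoveries(self, small_dataset, small_prep):
        ds = small_dataset
        norm, _, residuals = small_prep
        genes = [g for g in residuals.gene_ids if ds.regulatory_map.tfs_of(g)][:5]
        results = robustness_test(
            residuals, ds.regulatory_map, ds.annotations, norm, ds.genotypes,
            "tf_expression", n_runs=3, drop_fraction=0.1, n_null=10, folds=5,
            seed=6, candidate_genes=genes,
        )
        assert sorted(results) == sorted(genes)
        for r in results.values():
            assert 0 <= r.n_discovered <= 3
        again = robustness_test(
            residuals, ds.regulatory_map, ds.annotations, norm, ds.genotypes,
            "tf_expression", n_runs=3, drop_fraction=0.1, n_null=10, folds=5,
            seed=6, candidate_genes=genes,
        )
        assert {g: r.n_discovered for g, r in results.items()} == {
            g: r.n_discovered for g, r in again.items()
        }
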