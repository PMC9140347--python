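import numpy as np
import pandas as pd
import pytest

from tftrans.errors import ValidationError
from tftrans.io_formats import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeDosageMatrix,
    ResidualMatrix,
)
from tftrans.preprocessing import (
    compute_cis_residuals,
    fit_cis_model,
    fit_cis_models,
    normalize_expression,
    read_imputed_expression,
)
from tftrans.synthetic_data import SimulationConfig, simulate_dataset


def _expr(values, samples, genes):
    return ExpressionMatrix(pd.DataFrame(values, index=samples, columns=genes))


class TestNormalizeExpression:
    def test_exact_linear_relation_leaves_zero_residuals(self):
        samples = list("abcd")
        expr = _expr([[1.0], [3.0], [1.0], [3.0]], samples, ["G1"])
        cov = CovariateTable(pd.DataFrame({"c": [0.0, 1.0, 0.0, 1.0]}, index=samples))
        res = normalize_expression(expr, cov)
        assert np.allclose(res.data["G1"], 0.0, atol=1e-12)
        assert res.stage == "post_covariate"

    def test_empty_covariate_table_centers_only(self):
        samples = list("abcd")
        expr = _expr([[1.0], [2.0], [3.0], [6.0]], samples, ["G1"])
        cov = CovariateTable(pd.DataFrame(index=pd.Index(samples), dtype=float))
        res = normalize_expression(expr, cov)
        assert np.allclose(res.data["G1"], [1, 2, 3, 6] - np.mean([1, 2, 3, 6]))

    def test_full_covariate_stack_regressed_out(self, small_dataset):
        # 20 columns standing in for sex + platform + 3 PCs + 15 PEER factors
        ds = small_dataset
        assert len(ds.covariates.covariate_names) == 20
        res = normalize_expression(ds.expression, ds.covariates)
        C = ds.covariates.data.loc[res.sample_ids].to_numpy()
        R = res.data.to_numpy()
        for j in range(C.shape[1]):
            corr = np.corrcoef(C[:, j], R.T)[0, 1:]
            assert np.abs(corr).max() < 1e-8

    def test_idempotent_on_own_output(self, small_dataset):
        ds = small_dataset
        res = normalize_expression(ds.expression, ds.covariates)
        res2 = normalize_expression(ExpressionMatrix(res.data), ds.covariates)
        assert np.allclose(res.data.to_numpy(), res2.data.to_numpy(), atol=1e-10)

    def test_collinear_covariates_listed_in_error(self):
        samples = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        c1 = rng.normal(size=10)
        cov = CovariateTable(pd.DataFrame({"c1": c1, "c2": 2 * c1}, index=samples))
        expr = _expr(rng.normal(size=(10, 2)), samples, ["G1", "G2"])
        with pytest.raises(ValidationError, match="collinear"):
            normalize_expression(expr, cov)

    def test_too_few_samples_rejected(self):
        samples = list("abc")
        rng = np.random.default_rng(0)
        cov = CovariateTable(pd.DataFrame(rng.normal(size=(3, 2)), index=samples,
                                          columns=["c1", "c2"]))
        expr = _expr(rng.normal(size=(3, 1)), samples, ["G1"])
        with pytest.raises(ValidationError, match="samples"):
            normalize_expression(expr, cov)


def _single_variant_setup(effect=0.9, n=200, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    d = rng.binomial(2, 0.3, size=n).astype(float)
    dosages = GenotypeDosageMatrix(
        pd.DataFrame({"v1": d}, index=samples),
        pd.DataFrame({"chrom": ["chr1"], "pos": [500_000], "ref": ["A"], "alt": ["G"]},
                     index=pd.Index(["v1"], name="variant_id")),
    )
    bounds = pd.DataFrame({"chrom": ["chr1"], "start": [600_000], "end": [620_000]},
                          index=pd.Index(["G1"], name="gene_id"))
    y = effect * d
    norm = ResidualMatrix(pd.DataFrame({"G1": y - y.mean()}, index=samples),
                          stage="post_covariate")
    return dosages, bounds, norm


class TestCisModel:
    def test_near_noiseless_single_variant_recovered(self):
        dosages, bounds, norm = _single_variant_setup()
        fit = fit_cis_model("G1", dosages, norm, bounds, seed=1)
        assert fit.r2_cis > 0.95
        assert fit.n_variants_used == 1

    def test_null_gene_has_near_zero_cv_r2(self):
        rng = np.random.default_rng(3)
        n, p = 500, 50
        samples = [f"s{i}" for i in range(n)]
        vids = [f"v{j}" for j in range(p)]
        dosages = GenotypeDosageMatrix(
            pd.DataFrame(rng.binomial(2, 0.3, size=(n, p)).astype(float),
                         index=samples, columns=vids),
            pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, p + 1) * 1000,
                          "ref": "A", "alt": "G"}, index=pd.Index(vids, name="variant_id")),
        )
        bounds = pd.DataFrame({"chrom": ["chr1"], "start": [25_000], "end": [30_000]},
                              index=pd.Index(["G1"], name="gene_id"))
        norm = ResidualMatrix(pd.DataFrame({"G1": rng.normal(size=n)}, index=samples),
                              stage="post_covariate")
        fit = fit_cis_model("G1", dosages, norm, bounds, seed=2)
        assert fit.r2_cis < 0.05

    def test_no_cis_variants_yields_zero_baseline(self):
        dosages, bounds, norm = _single_variant_setup()
        far = bounds.assign(chrom=["chr9"])
        fit = fit_cis_model("G1", dosages, norm, far, seed=1)
        assert fit.r2_cis == 0.0
        assert fit.n_variants_used == 0
        assert (fit.predicted == 0).all()

    def test_median_recovery_at_planted_cis_fraction(self):
        # planted cis fraction 0.3 at n=700: cross-validated R2 centers on it
        cfg = SimulationConfig(n_samples=700, n_genes=15, n_tfs=12, tf_per_gene_mean=5,
                               tf_per_gene_sd=2, cis_r2=0.3, trans_expr_r2=0.0,
                               fraction_genes_with_tf=0.0, seed=5)
        ds = simulate_dataset(cfg)
        norm = normalize_expression(ds.expression, ds.covariates)
        fits = fit_cis_models(ds.genotypes, norm, ds.gene_bounds, seed=3,
                              gene_ids=[g for g in norm.gene_ids if g.startswith("G")])
        med = np.median([f.r2_cis for f in fits.values()])
        assert 0.2 <= med <= 0.4


class TestImputedAndResiduals:
    def test_perfect_predictions_score_one(self, tmp_path):
        dosages, bounds, norm = _single_variant_setup()
        norm.data.to_csv(tmp_path / "p.tsv", sep="\t", index_label="sample_id")
        fits = read_imputed_expression(tmp_path / "p.tsv", norm)
        assert fits["G1"].r2_cis == pytest.approx(1.0)

    def test_constant_prediction_scores_zero(self, tmp_path):
        dosages, bounds, norm = _single_variant_setup()
        const = norm.data.copy()
        const["G1"] = 5.0
        const.to_csv(tmp_path / "p.tsv", sep="\t", index_label="sample_id")
        fits = read_imputed_expression(tmp_path / "p.tsv", norm)
        assert fits["G1"].r2_cis == 0.0

    def test_round_trip_reproduces_trained_r2(self, tmp_path):
        dosages, bounds, norm = _single_variant_setup()
        fit = fit_cis_model("G1", dosages, norm, bounds, seed=1)
        pd.DataFrame({"G1": fit.predicted}).to_csv(
            tmp_path / "p.tsv", sep="\t", index_label="sample_id"
        )
        fits = read_imputed_expression(tmp_path / "p.tsv", norm)
        assert fits["G1"].r2_cis == pytest.approx(fit.r2_cis)

    def test_zero_prediction_leaves_residuals_unchanged(self):
        dosages, bounds, norm = _single_variant_setup()
        res = compute_cis_residuals(norm, {})
        pd.testing.assert_frame_equal(res.data, norm.data)
        assert res.stage == "post_cis"

    def test_perfect_prediction_zeroes_residuals(self):
        dosages, bounds, norm = _single_variant_setup()
        from tftrans.preprocessing import CisModelFit

        fit = CisModelFit("G1", norm.data["G1"].copy(), 1.0, 1.0, 1,
                          pd.Series(dtype=float))
        res = compute_cis_residuals(norm, {"G1": fit})
        assert np.allclose(res.data["G1"], 0.0)

    def test_cis_stage_shrinks_variance_on_planted_cis_genes(self, small_dataset, small_prep):
        norm, cis_fits, residuals = small_prep
        genes = [g for g in small_dataset.truth.genes.index]
        var_before = norm.data[genes].var().mean()
        var_after = residuals.data[genes].var().mean()
        assert var_after <= var_before + 1e-9
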