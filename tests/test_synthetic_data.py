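import numpy as np
import pandas as pd
import pytest

from tftrans.errors import ConfigError
from tftrans.synthetic_data import (
    SimulationConfig,
    simulate_annotations,
    simulate_dataset,
    simulate_genotypes,
    simulate_regulatory_map,
)


def _cfg(**kw):
    base = dict(n_samples=50, n_genes=10, n_tfs=15, tf_per_gene_mean=4, tf_per_gene_sd=2, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_variance_fractions_must_sum_below_one(self):
        with pytest.raises(ConfigError, match="exceed 1"):
            _cfg(cis_r2=0.5, trans_expr_r2=0.4, trans_bind_r2=0.2)

    def test_tf_mean_larger_than_pool_rejected(self):
        with pytest.raises(ConfigError, match="n_tfs"):
            _cfg(tf_per_gene_mean=3, n_tfs=2)

    def test_maf_range_must_be_ordered_within_half(self):
        with pytest.raises(ConfigError, match="maf_range"):
            _cfg(maf_range=(0.3, 0.6))

    def test_yaml_round_trip(self, tmp_path):
        cfg = _cfg(trans_expr_r2=0.25)
        cfg.to_yaml(tmp_path / "sim.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "sim.yaml") == cfg

    def test_unknown_yaml_key_rejected(self, tmp_path):
        (tmp_path / "sim.yaml").write_text("n_samples: 10\nbogus_knob: 3\n")
        with pytest.raises(ConfigError, match="bogus_knob"):
            SimulationConfig.from_yaml(tmp_path / "sim.yaml")


class TestGenotypes:
    def test_fixed_half_maf_mean_dosage_near_one(self):
        cfg = _cfg(n_samples=10000, n_genes=2, n_tfs=2, tf_per_gene_mean=1,
                   tf_per_gene_sd=1, maf_range=(0.5, 0.5))
        g = simulate_genotypes(cfg)
        means = g.data.mean(axis=0)
        assert np.all(np.abs(means - 1.0) < 0.03)

    def test_zero_maf_gives_all_reference(self):
        cfg = _cfg(maf_range=(0.0, 0.0))
        g = simulate_genotypes(cfg)
        assert (g.data.to_numpy() == 0).all()

    def test_same_seed_bit_identical(self):
        cfg = _cfg()
        a, b = simulate_genotypes(cfg), simulate_genotypes(cfg)
        assert a.data.equals(b.data)
        assert a.variant_meta.equals(b.variant_meta)

    def test_cis_variants_fall_in_window_and_nssnps_in_tf_body(self):
        cfg = _cfg()
        rmap = simulate_regulatory_map(cfg)
        ann = simulate_annotations(cfg, rmap)
        g = simulate_genotypes(cfg, rmap, ann)
        bounds = rmap.tf_bounds
        for vid, tf in zip(ann.data["variant_id"], ann.data["gene_id"]):
            pos = g.variant_meta.loc[vid, "pos"]
            assert bounds.loc[tf, "start"] <= pos <= bounds.loc[tf, "end"]


class TestRegulatoryMapGeneration:
    def test_tfs_per_gene_matches_tissue_statistics(self):
        cfg = SimulationConfig(n_samples=10, n_genes=2000, n_tfs=500,
                               fraction_genes_with_tf=1.0, seed=3)
        rmap = simulate_regulatory_map(cfg)
        counts = rmap.pairs.groupby("target_gene_id").size()
        assert 9.8 <= counts.mean() <= 11.8
        assert counts.min() >= 1  # zero-truncation contract

    def test_fraction_of_genes_with_tf(self):
        cfg = SimulationConfig(n_samples=10, n_genes=1000, n_tfs=200, seed=4)
        rmap = simulate_regulatory_map(cfg)
        frac = len(set(rmap.pairs["target_gene_id"])) / cfg.n_genes
        assert abs(frac - 0.52) < 0.01


class TestAnnotationsGeneration:
    def test_nssnp_per_tf_mean_matches_tissue_statistics(self):
        cfg = SimulationConfig(n_samples=10, n_genes=20, n_tfs=500, seed=6)
        rmap = simulate_regulatory_map(cfg)
        ann = simulate_annotations(cfg, rmap)
        ns = ann.data[ann.data["consequence"] == "nonsynonymous"]
        per_tf = ns.groupby("gene_id").size().reindex(rmap.tf_bounds.index, fill_value=0)
        assert abs(per_tf.mean() - 1.55) < 0.3

    def test_deleterious_fraction_one_puts_all_sift_below_threshold(self):
        cfg = _cfg(deleterious_fraction=1.0)
        rmap = simulate_regulatory_map(cfg)
        ann = simulate_annotations(cfg, rmap)
        ns = ann.data[ann.data["consequence"] == "nonsynonymous"]
        assert (ns["sift_score"] < 0.05).all()


class TestExpression:
    def test_all_trans_zero_marks_every_gene_null(self):
        cfg = _cfg(trans_expr_r2=0.0, trans_bind_r2=0.0)
        ds = simulate_dataset(cfg)
        assert ds.truth.genes["is_null"].all()

    def test_noiseless_expression_is_exact_linear_combination(self):
        cfg = _cfg(n_samples=100, noise_sd=0.0, trans_expr_r2=0.4, cis_r2=0.3,
                   covariate_r2=0.2, fraction_null_genes=0.0, n_causal_tfs=1)
        ds = simulate_dataset(cfg)
        sig = ds.truth.signal_genes
        assert sig
        for gene in sig[:3]:
            row = ds.truth.genes.loc[gene]
            cols = []
            cols.append(ds.genotypes.data[row["cis_variants"].split(";")].to_numpy())
            cols.append(ds.expression.data[ds.truth.causal_tfs(gene)].to_numpy())
            cols.append(ds.covariates.data.to_numpy())
            X = np.column_stack([np.ones(cfg.n_samples)] + cols)
            y = ds.expression.data[gene].to_numpy()
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            assert np.abs(y - X @ beta).max() < 1e-8

    def test_ledger_references_only_linked_tfs_and_deleterious_snps(self, small_dataset):
        ds = small_dataset
        ann = ds.annotations.data
        for gene in ds.truth.signal_genes:
            linked = set(ds.regulatory_map.tfs_of(gene))
            assert set(ds.truth.causal_tfs(gene)) <= linked
            for snp in ds.truth.causal_snps(gene):
                row = ann[ann["variant_id"] == snp].iloc[0]
                assert row["gene_id"] in linked
                assert row["consequence"] == "nonsynonymous"
                assert row["sift_score"] < 0.05

    def test_realized_fractions_match_targets_in_ledger(self, small_dataset):
        truth = small_dataset.truth.genes
        sig = truth[~truth["is_null"]]
        assert np.allclose(sig["frac_trans_expr"], 0.3)
        assert np.allclose(sig["frac_cis"], 0.15)

    def test_realized_trans_r2_by_regression_oracle(self, small_dataset):
        # cross-component projection noise scales as 1/sqrt(n); at n=300 the
        # per-gene oracle R2 scatters ~0.025 SD around the target (the
        # tighter +-0.05 guarantee holds from n=1000, see the acceptance
        # calibration test)
        ds = small_dataset
        for gene in ds.truth.signal_genes[:10]:
            ctfs = ds.truth.causal_tfs(gene)
            y = ds.expression.data[gene].to_numpy()
            X = np.column_stack([np.ones(len(y)), ds.expression.data[ctfs].to_numpy()])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r2 = 1 - (y - X @ beta).var() / y.var()
            assert abs(r2 - 0.3) < 0.1

    def test_dataset_fully_deterministic(self):
        cfg = _cfg(trans_expr_r2=0.2, trans_bind_r2=0.1)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        assert a.expression.data.equals(b.expression.data)
        assert a.covariates.data.equals(b.covariates.data)
        assert a.annotations.data.equals(b.annotations.data)
        assert a.regulatory_map.pairs.equals(b.regulatory_map.pairs)
        pd.testing.assert_frame_equal(a.truth.genes, b.truth.genes)
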