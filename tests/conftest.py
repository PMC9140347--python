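import logging

import pytest

from tftrans.preprocessing import (
    compute_cis_residuals,
    fit_cis_models,
    normalize_expression,
)
from tftrans.synthetic_data import SimulationConfig, simulate_dataset

logging.getLogger("tftrans").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """Mixed signal/null dataset shared by module tests (n=300, 40 genes)."""
    cfg = SimulationConfig(
        n_samples=300,
        n_genes=40,
        n_tfs=50,
        trans_expr_r2=0.3,
        trans_bind_r2=0.1,
        fraction_null_genes=0.5,
        seed=123,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_prep(small_dataset):
    """Normalized expression, cis fits and post-cis residuals for it."""
    ds = small_dataset
    norm = normalize_expression(ds.expression, ds.covariates)
    target_genes = [g for g in norm.gene_ids if g.startswith("G")]
    cis_fits = fit_cis_models(
        ds.genotypes, norm, ds.gene_bounds, gene_ids=target_genes, folds=5, seed=11
    )
    residuals = compute_cis_residuals(norm, cis_fits)
    return norm, cis_fits, residuals
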