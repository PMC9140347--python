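"""Expression normalization and the cis-imputation baseline.

Two stages precede the TF models:

1. *Covariate residualization* — per-gene ordinary least squares of observed
   expression on the full covariate table (sex, platform, genotype PCs,
   PEER-style factors, all consumed as pre-encoded numeric columns). The
   residuals are the "normalized" expression used everywhere downstream.

2. *Cis baseline* — a trainable elastic-net model (mixing 0.5, +-1 Mb
   window, 10-fold CV) predicting each gene's normalized expression from
   nearby variant dosages, standing in for externally trained
   transcriptome-imputation weights; a reader for externally produced
   predictions is provided as an alternative entry point. The per-gene
   baseline quality ``r2_cis`` is the squared Pearson correlation between
   cross-validated predictions and normalized expression, floored at 0 (the
   in-sample value is also reported for transparency).

The TF models consume the *post-cis* residuals: normalized expression minus
the cis prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError
from .io_formats import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeDosageMatrix,
    ResidualMatrix,
    align_samples,
)
from .penalized import CVPathEngine, floored_cv_r2, standardize_columns
from .seeding import derive_seed

logger = logging.getLogger(__name__)

__all__ = [
    "CisModelFit",
    "normalize_expression",
    "fit_cis_model",
    "fit_cis_models",
    "read_imputed_expression",
    "compute_cis_residuals",
]

DEFAULT_CIS_WINDOW = 1_000_000
DEFAULT_MIXING = 0.5
DEFAULT_FOLDS = 10


@dataclass
class CisModelFit:
    """Per-gene cis baseline: cross-validated predictions and their quality."""

    gene_id: str
    predicted: pd.Series  # per aligned sample
    r2_cis: float
    r2_cis_insample: float
    n_variants_used: int
    weights: pd.Series  # per-variant coefficients (standardized-dosage scale)


def normalize_expression(expr: ExpressionMatrix, cov: CovariateTable) -> ResidualMatrix:
    """Residualize every gene on intercept + all covariates (OLS)."""
    samples = align_samples(expr.sample_ids, cov.sample_ids)
    Y = expr.data.loc[samples].to_numpy(dtype=np.float64)
    C = cov.data.loc[samples].to_numpy(dtype=np.float64)
    n, k = C.shape
    if n < k + 2:
        raise ValidationError(
            f"need at least covariates+2 samples ({k + 2}), have {n} after alignment"
        )
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j, name in enumerate(cov.data.columns):
            reduced = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(name)
        raise ValidationError(f"rank-deficient covariate matrix; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return ResidualMatrix(
        pd.DataFrame(resid, index=samples, columns=expr.gene_ids), stage="post_covariate"
    )


def _cis_variant_ids(
    gene_id: str,
    dosages: GenotypeDosageMatrix,
    gene_bounds: pd.DataFrame,
    cis_window: int,
) -> list[str]:
    if gene_id not in gene_bounds.index:
        raise ValidationError(f"gene {gene_id!r} has no genomic bounds")
    chrom, start, end = gene_bounds.loc[gene_id, ["chrom", "start", "end"]]
    meta = dosages.variant_meta
    mask = (
        (meta["chrom"] == chrom)
        & (meta["pos"] >= max(1, int(start) - cis_window))
        & (meta["pos"] <= int(end) + cis_window)
    )
    return sorted(meta.index[mask])


def _zero_fit(gene_id: str, samples: list[str]) -> CisModelFit:
    return CisModelFit(
        gene_id=gene_id,
        predicted=pd.Series(0.0, index=samples),
        r2_cis=0.0,
        r2_cis_insample=0.0,
        n_variants_used=0,
        weights=pd.Series(dtype=np.float64),
    )


def fit_cis_model(
    gene_id: str,
    dosages: GenotypeDosageMatrix,
    norm: ResidualMatrix,
    gene_bounds: pd.DataFrame,
    cis_window: int = DEFAULT_CIS_WINDOW,
    mixing: float = DEFAULT_MIXING,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> CisModelFit:
    """Elastic-net cis model for one gene on its +-``cis_window`` variants.

    A gene with no cis variants (or only zero-variance ones) gets a zero
    prediction and ``r2_cis = 0`` — retained, never excluded.
    """
    if norm.stage != "post_covariate":
        raise ValidationError("cis models are fitted on post_covariate residuals")
    samples = align_samples(norm.sample_ids, dosages.sample_ids)
    y = norm.data.loc[samples, gene_id].to_numpy(dtype=np.float64)
    cis_ids = _cis_variant_ids(gene_id, dosages, gene_bounds, cis_window)
    if not cis_ids:
        logger.info("gene %s: no cis variants in window; zero baseline", gene_id)
        return _zero_fit(gene_id, samples)
    X = dosages.data.loc[samples, cis_ids].to_numpy(dtype=np.float64)
    Z, keep = standardize_columns(X)
    if not keep.any():
        return _zero_fit(gene_id, samples)
    fit = CVPathEngine(
        Z[:, keep],
        l1_ratio=mixing,
        folds=folds,
        seed=derive_seed(seed, "cis_cv", gene_id),
    ).fit(y)
    kept_ids = [v for v, k in zip(cis_ids, keep) if k]
    weights = pd.Series(fit.coef, index=kept_ids)
    weights = weights[weights != 0]
    return CisModelFit(
        gene_id=gene_id,
        predicted=pd.Series(fit.cv_pred, index=samples),
        r2_cis=floored_cv_r2(fit.cv_pred, y),
        r2_cis_insample=floored_cv_r2(fit.insample_pred, y),
        n_variants_used=int(keep.sum()),
        weights=weights,
    )


def fit_cis_models(
    dosages: GenotypeDosageMatrix,
    norm: ResidualMatrix,
    gene_bounds: pd.DataFrame,
    gene_ids: list[str] | None = None,
    cis_window: int = DEFAULT_CIS_WINDOW,
    mixing: float = DEFAULT_MIXING,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> dict[str, CisModelFit]:
    """Batch driver: one cis fit per gene (all normalized genes by default,
    restricted to those with genomic bounds)."""
    if gene_ids is None:
        gene_ids = [g for g in norm.gene_ids if g in gene_bounds.index]
    fits = {}
    for gene in gene_ids:
        fits[gene] = fit_cis_model(
            gene, dosages, norm, gene_bounds, cis_window, mixing, folds, seed
        )
    logger.info("fitted cis baselines for %d genes", len(fits))
    return fits


def read_imputed_expression(path, norm: ResidualMatrix) -> dict[str, CisModelFit]:
    """Wrap externally computed cis predictions (samples x genes table) as
    cis fits, scoring them against the supplied normalized expression."""
    from .io_formats import read_expression

    pred = read_expression(path)
    common = set(pred.sample_ids) & set(norm.sample_ids)
    if len(common) != len(norm.sample_ids):
        raise AlignmentError(
            "imputed expression samples do not cover the normalized expression samples"
        )
    samples = norm.sample_ids
    fits = {}
    for gene in pred.gene_ids:
        if gene not in norm.data.columns:
            continue
        p = pred.data.loc[samples, gene].to_numpy(dtype=np.float64)
        y = norm.data.loc[samples, gene].to_numpy(dtype=np.float64)
        r2 = floored_cv_r2(p, y)
        fits[gene] = CisModelFit(
            gene_id=gene,
            predicted=pd.Series(p, index=samples),
            r2_cis=r2,
            r2_cis_insample=r2,
            n_variants_used=-1,  # unknown for external predictions
            weights=pd.Series(dtype=np.float64),
        )
    return fits


def compute_cis_residuals(
    norm: ResidualMatrix, fits: dict[str, CisModelFit]
) -> ResidualMatrix:
    """Post-cis residuals: normalized expression minus the cis prediction.

    Genes absent from ``fits`` are treated as a zero prediction (logged)."""
    if norm.stage != "post_covariate":
        raise ValidationError("cis residuals are computed from post_covariate input")
    out = norm.data.copy()
    missing = []
    for gene in out.columns:
        fit = fits.get(gene)
        if fit is None:
            missing.append(gene)
            continue
        out[gene] = out[gene] - fit.predicted.reindex(out.index).to_numpy()
    if missing:
        logger.info("%d gene(s) without a cis fit kept with zero prediction", len(missing))
    return ResidualMatrix(out, stage="post_cis")
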