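"""TF-expression and TF-binding LASSO models on post-cis residuals.

For each candidate gene (a gene with at least one annotated TF) two
mechanistic models are available:

* ``tf_expression`` — predictors are the normalized expression values of the
  TFs annotated as regulating the gene;
* ``tf_binding`` — predictors are the dosages of nonsynonymous,
  SIFT-deleterious (score strictly below 0.05) variants located in those
  TFs, proxying altered binding affinity.

Both are L1-penalized linear models with the penalty chosen by k-fold CV;
model quality ``r2_tf`` is the squared Pearson correlation between
cross-validated predictions and the residual response, floored at 0, the
same estimator used for the cis baseline so the two are comparable.
Weights are reported on the standardized-predictor scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    GenotypeDosageMatrix,
    RegulatoryMap,
    ResidualMatrix,
    VariantAnnotationTable,
)
from .penalized import CVPathEngine, PenalizedFit, floored_cv_r2, standardize_columns
from .seeding import derive_seed

logger = logging.getLogger(__name__)

__all__ = [
    "MECHANISMS",
    "SIFT_DELETERIOUS_THRESHOLD",
    "PredictorSet",
    "TFModelFit",
    "GeneSkipped",
    "build_predictor_set",
    "fit_lasso",
    "fit_all",
]

MECHANISMS = ("tf_expression", "tf_binding")
SIFT_DELETERIOUS_THRESHOLD = 0.05  # strict '<' per the deleteriousness call
MIN_SAMPLES = 10


class GeneSkipped(Exception):
    """Signal (not an error) that a gene is ineligible for a mechanism."""

    def __init__(self, gene_id: str, reason: str) -> None:
        super().__init__(f"{gene_id}: {reason}")
        self.gene_id = gene_id
        self.reason = reason


@dataclass
class PredictorSet:
    """The design matrix for one gene under one mechanism."""

    gene_id: str
    mechanism: str
    predictor_ids: list[str]  # TF ids (tf_expression) or variant ids (tf_binding)
    matrix: pd.DataFrame  # samples x predictors

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_ids)


@dataclass
class TFModelFit:
    gene_id: str
    mechanism: str
    r2_tf: float
    weights: pd.Series  # nonzero coefficients, standardized-predictor scale
    alpha: float  # selected L1 penalty
    n_predictors: int
    n_nonzero: int
    predictor_ids: list[str]

    @property
    def top_predictor(self) -> str | None:
        if self.weights.empty:
            return None
        return self.weights.abs().sort_values(ascending=False, kind="stable").index[0]


def build_predictor_set(
    gene_id: str,
    mechanism: str,
    rmap: RegulatoryMap,
    ann: VariantAnnotationTable,
    expr_norm: ResidualMatrix,
    dosages: GenotypeDosageMatrix,
) -> PredictorSet:
    """Assemble the predictor matrix for one gene.

    Raises :class:`GeneSkipped` when the gene has no TF in the map; an empty
    predictor set after filtering is returned as such (the caller records a
    skip with its reason).
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    tfs = rmap.tfs_of(gene_id)
    if not tfs:
        raise GeneSkipped(gene_id, "no TF associated in the regulatory map")
    if mechanism == "tf_expression":
        present = [t for t in tfs if t in expr_norm.data.columns and t != gene_id]
        matrix = expr_norm.data[present]
        return PredictorSet(gene_id, mechanism, present, matrix)
    # tf_binding: deleterious nsSNPs within TFs that have genomic bounds
    bounded_tfs = [t for t in tfs if t not in rmap.boundless_tfs]
    snps = ann.deleterious_nonsynonymous(bounded_tfs)
    snps = [s for s in snps if s in dosages.data.columns]
    matrix = dosages.data[snps]
    return PredictorSet(gene_id, mechanism, snps, matrix)


def fit_lasso(
    response: np.ndarray | pd.Series,
    predictors: PredictorSet,
    folds: int = 10,
    seed: int = 0,
    n_alphas: int = 25,
    _engine: CVPathEngine | None = None,
) -> TFModelFit:
    """Cross-validated LASSO of the residual response on the predictor set.

    Predictors are standardized to unit variance first; all-constant
    predictor sets yield an all-zero fit with ``r2_tf = 0`` rather than an
    error.
    """
    y = np.asarray(response, dtype=np.float64)
    if y.shape[0] < MIN_SAMPLES:
        raise ValidationError(f"need at least {MIN_SAMPLES} samples, have {y.shape[0]}")
    if predictors.n_predictors == 0:
        raise ValidationError("empty predictor set; gene should have been skipped")
    if _engine is None:
        Z, _ = standardize_columns(predictors.matrix.to_numpy(dtype=np.float64))
        _engine = CVPathEngine(Z, l1_ratio=1.0, folds=folds, seed=seed, n_alphas=n_alphas)
    fit: PenalizedFit = _engine.fit(y)
    weights = pd.Series(fit.coef[: predictors.n_predictors], index=predictors.predictor_ids)
    weights = weights[weights != 0]
    return TFModelFit(
        gene_id=predictors.gene_id,
        mechanism=predictors.mechanism,
        r2_tf=floored_cv_r2(fit.cv_pred, y),
        weights=weights,
        alpha=fit.alpha,
        n_predictors=predictors.n_predictors,
        n_nonzero=fit.n_nonzero,
        predictor_ids=predictors.predictor_ids,
    )


def fit_all(
    residuals: ResidualMatrix,
    rmap: RegulatoryMap,
    ann: VariantAnnotationTable,
    expr_norm: ResidualMatrix,
    dosages: GenotypeDosageMatrix,
    mechanism: str,
    folds: int = 10,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    n_jobs: int = 1,
) -> tuple[dict[str, TFModelFit], pd.DataFrame]:
    """Fit one model per eligible gene; returns (fits, skip table).

    Genes are eligible when they appear in the residual matrix and have at
    least one TF; genes whose predictor set is empty after filtering are
    recorded in the skip table with a reason, never as non-hits. Per-gene
    seeds are derived from ``seed``, so results are identical for any
    ``n_jobs`` or gene ordering.
    """
    if gene_ids is None:
        gene_ids = [g for g in residuals.gene_ids if rmap.tfs_of(g)]

    def _one(gene: str):
        try:
            pset = build_predictor_set(gene, mechanism, rmap, ann, expr_norm, dosages)
        except GeneSkipped as sk:
            return gene, None, sk.reason
        if pset.n_predictors == 0:
            reason = (
                "no deleterious nonsynonymous SNP in associated TFs"
                if mechanism == "tf_binding"
                else "no associated TF present in expression matrix"
            )
            return gene, None, reason
        y = residuals.data[gene].to_numpy(dtype=np.float64)
        fit = fit_lasso(
            y, pset, folds=folds, seed=derive_seed(seed, f"fit_{mechanism}", gene)
        )
        return gene, fit, None

    if n_jobs != 1:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=n_jobs)(delayed(_one)(g) for g in gene_ids)
    else:
        outcomes = [_one(g) for g in gene_ids]
    fits = {g: fit for g, fit, _ in outcomes if fit is not None}
    skips = [(g, reason) for g, fit, reason in outcomes if fit is None]
    skip_table = pd.DataFrame(skips, columns=["gene_id", "reason"])
    logger.info(
        "%s: fitted %d gene(s), skipped %d", mechanism, len(fits), len(skip_table)
    )
    return fits, skip_table
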