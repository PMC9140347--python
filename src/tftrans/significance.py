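"""Background null models, BH FDR filtering and subsample robustness.

A candidate gene's TF model must survive two permutation backgrounds:

* *shuffled residuals* — the response vector is permuted across samples and
  the full model (including CV penalty selection) retrained ``n_null``
  times;
* *random TF sets* — ``n_null`` TF sets of the same cardinality as the
  gene's true TF set are drawn without replacement from the non-associated
  TF pool, the matching predictor matrix rebuilt and the model retrained.

Empirical p-values use the add-one estimator ``(1 + #{null R2 >= observed
R2}) / (n_null + 1)`` (ties count against the observed model). p-values are
Benjamini-Hochberg adjusted within each (mechanism, null kind) family across
all candidate genes, and a gene passes only if both adjusted p-values fall
strictly below alpha.

The robustness stage repeats model fitting plus both backgrounds on
subsamples retaining ``1 - drop_fraction`` of the samples; a gene is
robust when discovered in at least ``ceil(n_runs / 2)`` runs (five of ten
at the defaults).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .io_formats import (
    GenotypeDosageMatrix,
    RegulatoryMap,
    ResidualMatrix,
    VariantAnnotationTable,
)
from .penalized import CVPathEngine, floored_cv_r2, standardize_columns
from .seeding import derive_seed
from .tf_models import PredictorSet, TFModelFit, build_predictor_set, fit_all

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundResult",
    "RobustnessResult",
    "empirical_p",
    "background_shuffled_residuals",
    "background_random_tf_sets",
    "bh_adjust",
    "apply_background_filters",
    "robustness_test",
]

NULL_KINDS = ("shuffled_residuals", "random_tf_sets")
DEFAULT_N_NULL = 100
DEFAULT_ALPHA = 0.05
DEFAULT_N_RUNS = 10
DEFAULT_DROP_FRACTION = 0.1


@dataclass
class BackgroundResult:
    gene_id: str
    mechanism: str
    null_kind: str
    n_null: int
    null_r2: np.ndarray
    p_empirical: float
    p_adjusted: float = float("nan")  # filled in by the BH pass
    untestable: bool = False


@dataclass
class RobustnessResult:
    gene_id: str
    mechanism: str
    n_runs: int
    n_discovered: int

    @property
    def is_hit(self) -> bool:
        return self.n_discovered >= math.ceil(self.n_runs / 2)


def empirical_p(observed_r2: float, null_r2: np.ndarray) -> float:
    """Add-one permutation p-value; ties count toward the null."""
    null_r2 = np.asarray(null_r2, dtype=np.float64)
    return float(1 + np.count_nonzero(null_r2 >= observed_r2)) / (null_r2.size + 1)


def _null_fit_r2(engine: CVPathEngine, y: np.ndarray) -> float:
    fit = engine.fit(y)
    return floored_cv_r2(fit.cv_pred, y)


def background_shuffled_residuals(
    fit: TFModelFit,
    response: np.ndarray,
    predictors: PredictorSet,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    folds: int = 10,
) -> BackgroundResult:
    """Permutation null: shuffle the response, retrain the full model."""
    y = np.asarray(response, dtype=np.float64)
    Z, _ = standardize_columns(predictors.matrix.to_numpy(dtype=np.float64))
    engine = CVPathEngine(Z, l1_ratio=1.0, folds=folds, seed=seed)
    rng = np.random.default_rng(seed)
    null_r2 = np.array([_null_fit_r2(engine, rng.permutation(y)) for _ in range(n_null)])
    return BackgroundResult(
        gene_id=fit.gene_id,
        mechanism=fit.mechanism,
        null_kind="shuffled_residuals",
        n_null=n_null,
        null_r2=null_r2,
        p_empirical=empirical_p(fit.r2_tf, null_r2),
    )


def _random_set_matrix(
    mechanism: str,
    tf_set: list[str],
    ann: VariantAnnotationTable,
    expr_norm: ResidualMatrix,
    dosages: GenotypeDosageMatrix,
) -> np.ndarray:
    if mechanism == "tf_expression":
        cols = [t for t in tf_set if t in expr_norm.data.columns]
        return expr_norm.data[cols].to_numpy(dtype=np.float64)
    snps = ann.deleterious_nonsynonymous(tf_set)
    snps = [s for s in snps if s in dosages.data.columns]
    return dosages.data[snps].to_numpy(dtype=np.float64)


def background_random_tf_sets(
    fit: TFModelFit,
    response: np.ndarray,
    rmap: RegulatoryMap,
    ann: VariantAnnotationTable,
    expr_norm: ResidualMatrix,
    dosages: GenotypeDosageMatrix,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    folds: int = 10,
    tf_pool: list[str] | None = None,
) -> BackgroundResult:
    """Size-matched random-TF-set null.

    Each null draw samples, without replacement, as many TFs as the gene
    truly has from the non-associated pool, rebuilds the mechanism's
    predictor matrix and retrains. A draw whose predictor matrix is empty
    (e.g. random TFs carrying no deleterious nsSNP) scores R2 = 0. If the
    pool is smaller than the true set the gene is flagged untestable (and
    cannot pass this null).
    """
    y = np.asarray(response, dtype=np.float64)
    true_tfs = rmap.tfs_of(fit.gene_id)
    if tf_pool is None:
        tf_pool = rmap.tf_ids
    pool = sorted(set(tf_pool) - set(true_tfs))
    if len(pool) < len(true_tfs):
        logger.info(
            "gene %s untestable for random-TF null (pool %d < true set %d)",
            fit.gene_id,
            len(pool),
            len(true_tfs),
        )
        return BackgroundResult(
            gene_id=fit.gene_id,
            mechanism=fit.mechanism,
            null_kind="random_tf_sets",
            n_null=n_null,
            null_r2=np.array([]),
            p_empirical=1.0,
            untestable=True,
        )
    rng = np.random.default_rng(seed)
    null_r2 = np.empty(n_null)
    for i in range(n_null):
        tf_set = sorted(rng.choice(pool, size=len(true_tfs), replace=False))
        X = _random_set_matrix(fit.mechanism, tf_set, ann, expr_norm, dosages)
        if X.shape[1] == 0:
            null_r2[i] = 0.0
            continue
        Z, keep = standardize_columns(X)
        if not keep.any():
            null_r2[i] = 0.0
            continue
        engine = CVPathEngine(
            Z[:, keep], l1_ratio=1.0, folds=folds, seed=derive_seed(seed, "rnd_set", i)
        )
        null_r2[i] = _null_fit_r2(engine, y)
    return BackgroundResult(
        gene_id=fit.gene_id,
        mechanism=fit.mechanism,
        null_kind="random_tf_sets",
        n_null=n_null,
        null_r2=null_r2,
        p_empirical=empirical_p(fit.r2_tf, null_r2),
    )


def bh_adjust(p_values: np.ndarray, alpha: float = DEFAULT_ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and strict-alpha flags."""
    p_values = np.asarray(p_values, dtype=np.float64)
    if p_values.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p_values <= 0).any() or (p_values > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj < alpha


def apply_background_filters(
    fits: dict[str, TFModelFit],
    residuals: ResidualMatrix,
    rmap: RegulatoryMap,
    ann: VariantAnnotationTable,
    expr_norm: ResidualMatrix,
    dosages: GenotypeDosageMatrix,
    n_null: int = DEFAULT_N_NULL,
    alpha: float = DEFAULT_ALPHA,
    folds: int = 10,
    seed: int = 0,
    n_jobs: int = 1,
) -> tuple[pd.DataFrame, list[str]]:
    """Run both backgrounds for every fitted gene and BH-filter the results.

    Returns a long-format table (gene x null kind) and the list of genes
    whose adjusted p-values pass strictly below alpha for *both* null kinds.
    Per-gene null seeds derive from ``seed``, so output is independent of
    ``n_jobs`` and iteration order.
    """
    if n_null < 20:
        logger.warning("n_null=%d gives coarse empirical p-value resolution", n_null)

    def _one(gene: str) -> list[BackgroundResult]:
        fit = fits[gene]
        y = residuals.data[gene].to_numpy(dtype=np.float64)
        pset = build_predictor_set(gene, fit.mechanism, rmap, ann, expr_norm, dosages)
        return [
            background_shuffled_residuals(
                fit, y, pset, n_null=n_null, folds=folds,
                seed=derive_seed(seed, "bg_shuffle", f"{fit.mechanism}:{gene}"),
            ),
            background_random_tf_sets(
                fit, y, rmap, ann, expr_norm, dosages, n_null=n_null, folds=folds,
                seed=derive_seed(seed, "bg_tfset", f"{fit.mechanism}:{gene}"),
            ),
        ]

    genes = sorted(fits)
    if n_jobs != 1:
        from joblib import Parallel, delayed

        nested = Parallel(n_jobs=n_jobs)(delayed(_one)(g) for g in genes)
    else:
        nested = [_one(g) for g in genes]
    results: list[BackgroundResult] = [r for pair in nested for r in pair]

    rows = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "mechanism": [r.mechanism for r in results],
            "null_kind": [r.null_kind for r in results],
            "n_null": [r.n_null for r in results],
            "p_empirical": [r.p_empirical for r in results],
            "untestable": [r.untestable for r in results],
            "observed_r2": [fits[r.gene_id].r2_tf for r in results],
        }
    )
    rows["p_adjusted"] = np.nan
    rows["passed_null"] = False
    for (_, _), idx in rows.groupby(["mechanism", "null_kind"]).groups.items():
        p_adj, flags = bh_adjust(rows.loc[idx, "p_empirical"].to_numpy(), alpha=alpha)
        rows.loc[idx, "p_adjusted"] = p_adj
        rows.loc[idx, "passed_null"] = flags
    rows.loc[rows["untestable"], "passed_null"] = False

    per_gene = rows.groupby("gene_id")["passed_null"].all()
    passed = sorted(per_gene.index[per_gene])
    logger.info(
        "background filters: %d of %d candidate gene(s) passed both nulls",
        len(passed),
        len(fits),
    )
    return rows, passed


def robustness_test(
    residuals: ResidualMatrix,
    rmap: RegulatoryMap,
    ann: VariantAnnotationTable,
    expr_norm: ResidualMatrix,
    dosages: GenotypeDosageMatrix,
    mechanism: str,
    n_runs: int = DEFAULT_N_RUNS,
    drop_fraction: float = DEFAULT_DROP_FRACTION,
    n_null: int = DEFAULT_N_NULL,
    alpha: float = DEFAULT_ALPHA,
    folds: int = 10,
    seed: int = 0,
    candidate_genes: list[str] | None = None,
    n_jobs: int = 1,
) -> dict[str, RobustnessResult]:
    """Re-run model fitting + both backgrounds on ``n_runs`` subsamples.

    Each run independently retains ``ceil((1 - drop_fraction) * n)`` samples
    (so a sample may be dropped in several runs); a gene's discovery count
    is the number of runs in which it passed both background filters.
    """
    if candidate_genes is None:
        candidate_genes = [g for g in residuals.gene_ids if rmap.tfs_of(g)]
    samples = residuals.sample_ids
    n = len(samples)
    n_keep = math.ceil((1.0 - drop_fraction) * n)
    if n_keep < 2 * 10:
        raise ConfigError(f"subsample size {n_keep} too small for model fitting")

    counts = {g: 0 for g in candidate_genes}
    for run in range(n_runs):
        run_seed = derive_seed(seed, "robust_run", run)
        rng = np.random.default_rng(run_seed)
        kept = sorted(rng.choice(samples, size=n_keep, replace=False))
        sub_resid = ResidualMatrix(residuals.data.loc[kept], stage=residuals.stage)
        sub_norm = ResidualMatrix(expr_norm.data.loc[kept], stage=expr_norm.stage)
        sub_dos = GenotypeDosageMatrix(dosages.data.loc[kept], dosages.variant_meta)
        fits, _ = fit_all(
            sub_resid, rmap, ann, sub_norm, sub_dos, mechanism,
            folds=folds, seed=run_seed, gene_ids=candidate_genes, n_jobs=n_jobs,
        )
        _, discovered = apply_background_filters(
            fits, sub_resid, rmap, ann, sub_norm, sub_dos,
            n_null=n_null, alpha=alpha, folds=folds, seed=run_seed, n_jobs=n_jobs,
        )
        for g in discovered:
            counts[g] += 1
        logger.info("robustness run %d/%d: %d discoveries", run + 1, n_runs, len(discovered))

    return {
        g: RobustnessResult(gene_id=g, mechanism=mechanism, n_runs=n_runs, n_discovered=c)
        for g, c in counts.items()
    }
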