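"""Method-validation studies: oracle equivalence, error control, power,
generator calibration and determinism.

These are the package's standard self-checks, run by the test suite and by
``scripts/acceptance.py``. Each study builds its own synthetic dataset (the
ground-truth ledger scores the pipeline's output), runs the *public*
pipeline entry points, and returns plain numbers.

The brute-force reference implementations here (step-up FDR by definition,
direct permutation-count p-values, hypergeometric tail by explicit
summation) are deliberately naive and independent of the library code they
check.
"""

from __future__ import annotations

import filecmp
import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import comb

from .io_formats import (
    GenotypeDosageMatrix,
    RegulatoryMap,
    ResidualMatrix,
    VariantAnnotationTable,
)
from .pipeline import PipelineConfig, run_pipeline
from .reporting import hypergeometric_overlap
from .seeding import derive_seed
from .significance import RobustnessResult, bh_adjust, empirical_p
from .synthetic_data import SimulationConfig, simulate_dataset
from .tf_models import build_predictor_set

__all__ = [
    "brute_force_bh",
    "brute_force_hypergeom_tail",
    "oracle_agreement",
    "typei_study",
    "power_study",
    "calibration_study",
    "sift_filter_check",
    "robustness_rule_check",
    "determinism_check",
]


# ---------------------------------------------------------------------------
# brute-force references
# ---------------------------------------------------------------------------


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up FDR-adjusted p-values computed directly from the definition:
    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1."""
    p = np.asarray(p, dtype=np.float64)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    q = np.empty(m)
    running = np.inf
    for j in range(m - 1, -1, -1):
        running = min(running, sorted_p[j] * m / (j + 1))
        q[j] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def brute_force_hypergeom_tail(k: int, universe: int, n_a: int, n_b: int) -> float:
    """P(X >= k) for X ~ Hypergeom by explicit term-by-term summation."""
    total = comb(universe, n_b, exact=True)
    acc = 0
    for x in range(k, min(n_a, n_b) + 1):
        acc += comb(n_a, x, exact=True) * comb(universe - n_a, n_b - x, exact=True)
    return acc / total


def oracle_agreement(n_instances: int = 1000, seed: int = 0) -> dict[str, float]:
    """Fraction of random instances on which the pipeline's BH adjustment,
    add-one empirical p-value and hypergeometric tail agree with the
    brute-force references (to 1e-12 relative)."""
    rng = np.random.default_rng(derive_seed(seed, "oracle"))

    bh_ok = 0
    for _ in range(n_instances):
        m = int(rng.integers(1, 40))
        p = rng.uniform(1e-6, 1.0, size=m)
        if rng.random() < 0.3:  # inject ties
            p[: m // 2 + 1] = p[0]
        adj, _ = bh_adjust(p)
        bh_ok += int(np.allclose(adj, brute_force_bh(p), rtol=1e-12, atol=1e-15))

    emp_ok = 0
    for _ in range(n_instances):
        n_null = int(rng.integers(5, 200))
        nulls = np.round(rng.uniform(0, 0.5, size=n_null), 2)
        obs = float(np.round(rng.uniform(0, 0.5), 2))
        direct = (1 + int(sum(1 for v in nulls if v >= obs))) / (n_null + 1)
        emp_ok += int(abs(empirical_p(obs, nulls) - direct) < 1e-15)

    hyp_ok = 0
    for _ in range(n_instances):
        universe = int(rng.integers(2, 40))
        n_a = int(rng.integers(0, universe + 1))
        n_b = int(rng.integers(0, universe + 1))
        ids = [f"g{i}" for i in range(universe)]
        set_a = set(rng.choice(ids, size=n_a, replace=False))
        set_b = set(rng.choice(ids, size=n_b, replace=False))
        k, p_val = hypergeometric_overlap(set_a, set_b, set(ids))
        ref = brute_force_hypergeom_tail(k, universe, n_a, n_b)
        hyp_ok += int(math.isclose(p_val, ref, rel_tol=1e-9))

    return {
        "bh": bh_ok / n_instances,
        "empirical_p": emp_ok / n_instances,
        "hypergeom": hyp_ok / n_instances,
    }


# ---------------------------------------------------------------------------
# simulation studies
# ---------------------------------------------------------------------------


def _study_sim(seed: int, **overrides) -> SimulationConfig:
    base = dict(
        n_samples=500,
        n_genes=50,
        n_tfs=120,
        fraction_genes_with_tf=1.0,
        cis_r2=0.15,
        covariate_r2=0.1,
        n_covariates=20,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def typei_study(
    n_genes: int = 50,
    n_samples: int = 500,
    n_null: int = 20,
    n_runs: int = 10,
    seed: int = 0,
    mechanisms: tuple[str, ...] = ("tf_expression", "tf_binding"),
) -> dict[str, float]:
    """End-to-end false-positive rate on a dataset with zero trans effects."""
    sim = _study_sim(
        derive_seed(seed, "typei_sim"),
        n_genes=n_genes,
        n_samples=n_samples,
        trans_expr_r2=0.0,
        trans_bind_r2=0.0,
        fraction_null_genes=1.0,
    )
    cfg = PipelineConfig(
        simulation=sim,
        mechanisms=mechanisms,
        n_null=n_null,
        n_runs=n_runs,
        seed=derive_seed(seed, "typei_run"),
    )
    res = run_pipeline(cfg)
    rep = res.hit_report
    n_candidates = len(rep)
    n_hits = int(rep["is_hit"].sum())
    return {
        "hit_fraction": n_hits / n_candidates if n_candidates else 0.0,
        "n_hits": float(n_hits),
        "n_candidates": float(n_candidates),
    }


def power_study(
    mechanism: str = "tf_expression",
    n_genes: int = 100,
    n_samples: int = 500,
    trans_r2: float = 0.3,
    n_null: int = 20,
    n_runs: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Hit rate and top-predictor recovery on all-signal synthetic data.

    Genes are scored only if the generator could actually plant the effect
    (for TF-binding a gene needs at least one deleterious nsSNP among its
    TFs). Recovery asks whether the largest-|weight| predictor of a hit is
    one of the planted causal TFs / variants.
    """
    overrides = dict(
        n_genes=n_genes,
        n_samples=n_samples,
        fraction_null_genes=0.0,
        trans_expr_r2=trans_r2 if mechanism == "tf_expression" else 0.0,
        trans_bind_r2=trans_r2 if mechanism == "tf_binding" else 0.0,
    )
    if mechanism == "tf_binding":
        overrides["deleterious_fraction"] = 0.35
    sim = _study_sim(derive_seed(seed, f"power_sim_{mechanism}"), **overrides)
    ds = simulate_dataset(sim)
    truth = ds.truth.genes
    planted_col = "causal_tfs" if mechanism == "tf_expression" else "causal_snps"
    planted = set(truth.index[(truth[planted_col] != "") & truth["has_tf"]])

    cfg = PipelineConfig(
        simulation=sim,
        mechanisms=(mechanism,),
        n_null=n_null,
        n_runs=n_runs,
        seed=derive_seed(seed, f"power_run_{mechanism}"),
    )
    res = run_pipeline(cfg)
    rep = res.hit_report.set_index("gene_id")
    scored = sorted(planted & set(rep.index))
    hits = [g for g in scored if rep.loc[g, "is_hit"]]

    recovered = 0
    for g in hits:
        fit = res.tf_fits[mechanism][g]
        top = fit.top_predictor
        causal = set(ds.truth.causal_tfs(g) if mechanism == "tf_expression" else ds.truth.causal_snps(g))
        recovered += int(top in causal)
    return {
        "hit_fraction": len(hits) / len(scored) if scored else 0.0,
        "top_recovery_fraction": recovered / len(hits) if hits else 0.0,
        "n_scored": float(len(scored)),
        "n_hits": float(len(hits)),
    }


def calibration_study(
    n_samples: int = 1000, n_genes: int = 60, seed: int = 0
) -> dict[str, float]:
    """Per-gene realized variance fractions versus configured targets.

    For each non-null gene, regress the simulated expression on the true
    causal TF expressions (trans), on the gene's cis variant dosages (cis),
    and on the covariates, and compare each OLS R-squared with its target.
    Returns the worst absolute deviation per component across genes.
    """
    sim = _study_sim(
        derive_seed(seed, "calib_sim"),
        n_samples=n_samples,
        n_genes=n_genes,
        trans_expr_r2=0.3,
        fraction_null_genes=0.0,
        noise_sd=1.0,
    )
    ds = simulate_dataset(sim)

    def ols_r2(X: np.ndarray, y: np.ndarray) -> float:
        # adjusted R2: corrects the p/n inflation of the raw coefficient of
        # determination (matters for the 20-column covariate block)
        n, p = X.shape
        X1 = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
        resid = y - X1 @ beta
        r2 = 1.0 - resid.var() / y.var()
        return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

    errs = {"trans_expr": [], "cis": [], "cov": []}
    truth = ds.truth
    for gene in truth.signal_genes:
        row = truth.genes.loc[gene]
        y = ds.expression.data[gene].to_numpy()
        ctfs = truth.causal_tfs(gene)
        if ctfs and row["frac_trans_expr"] > 0:
            r2 = ols_r2(ds.expression.data[ctfs].to_numpy(), y)
            errs["trans_expr"].append(abs(r2 - sim.trans_expr_r2))
        cis_vars = row["cis_variants"].split(";")
        if row["frac_cis"] > 0:
            r2 = ols_r2(ds.genotypes.data[cis_vars].to_numpy(), y)
            errs["cis"].append(abs(r2 - sim.cis_r2))
        if row["frac_cov"] > 0:
            r2 = ols_r2(ds.covariates.data.to_numpy(), y)
            errs["cov"].append(abs(r2 - sim.covariate_r2))
    return {k: float(max(v)) if v else float("nan") for k, v in errs.items()}


# ---------------------------------------------------------------------------
# constructed-fixture checks
# ---------------------------------------------------------------------------


def sift_fixture() -> tuple[RegulatoryMap, VariantAnnotationTable, ResidualMatrix, GenotypeDosageMatrix]:
    """Hand-built fixture exercising every branch of the TF-binding filter."""
    samples = [f"S{i}" for i in range(6)]
    pairs = pd.DataFrame(
        {"tf_id": ["TFA", "TFB", "TFC"], "target_gene_id": ["GENE1", "GENE1", "GENE2"]}
    )
    bounds = pd.DataFrame(
        {"chrom": ["chr1"] * 2, "start": [100, 5000], "end": [200, 5100]},
        index=pd.Index(["TFA", "TFC"], name="tf_id"),
    )  # TFB deliberately boundless
    rmap = RegulatoryMap(pairs, bounds, boundless_tfs={"TFB"})
    ann = VariantAnnotationTable(
        pd.DataFrame(
            {
                "variant_id": ["v_in", "v_border", "v_syn", "v_nosift", "v_otherTF", "v_boundless"],
                "gene_id": ["TFA", "TFA", "TFA", "TFA", "TFC", "TFB"],
                "consequence": [
                    "nonsynonymous",
                    "nonsynonymous",
                    "synonymous",
                    "nonsynonymous",
                    "nonsynonymous",
                    "nonsynonymous",
                ],
                "sift_score": [0.03, 0.05, 0.01, np.nan, 0.04, 0.02],
            }
        )
    )
    dosage = pd.DataFrame(
        {v: [0.0, 1.0, 2.0, 1.0, 0.0, 1.0] for v in ann.data["variant_id"]}, index=samples
    )
    meta = pd.DataFrame(
        {
            "chrom": ["chr1"] * 6,
            "pos": [150, 160, 170, 180, 5050, 300],
            "ref": ["A"] * 6,
            "alt": ["G"] * 6,
        },
        index=pd.Index(ann.data["variant_id"], name="variant_id"),
    )
    dosages = GenotypeDosageMatrix(dosage, meta)
    expr = ResidualMatrix(
        pd.DataFrame(0.0, index=samples, columns=["GENE1", "GENE2", "TFA", "TFB", "TFC"]),
        stage="post_covariate",
    )
    return rmap, ann, expr, dosages


def sift_filter_check() -> bool:
    """TF-binding predictors must be exactly the nonsynonymous SIFT<0.05
    variants of the gene's bounded TFs (strict inequality; synonymous,
    SIFT-absent, borderline, unlinked and boundless-TF variants excluded)."""
    rmap, ann, expr, dosages = sift_fixture()
    pset = build_predictor_set("GENE1", "tf_binding", rmap, ann, expr, dosages)
    return pset.predictor_ids == ["v_in"]


def robustness_rule_check() -> bool:
    """Discovery patterns 4/10, 5/10, 10/10 -> not-hit, hit, hit."""
    patterns = {4: False, 5: True, 10: True}
    return all(
        RobustnessResult("g", "tf_expression", 10, k).is_hit == expected
        for k, expected in patterns.items()
    )


def determinism_check(seed: int = 0, workdir: str | None = None) -> bool:
    """Three pipeline runs with the same config + master seed (two serial,
    one with two workers) must produce byte-identical output files."""
    sim = _study_sim(
        derive_seed(seed, "det_sim"),
        n_samples=120,
        n_genes=20,
        n_tfs=30,
        trans_expr_r2=0.3,
        trans_bind_r2=0.1,
        fraction_null_genes=0.5,
    )

    def make_cfg(n_jobs: int) -> PipelineConfig:
        return PipelineConfig(
            simulation=sim,
            mechanisms=("tf_expression", "tf_binding"),
            n_null=5,
            n_runs=2,
            folds=5,
            seed=derive_seed(seed, "det_run"),
            n_jobs=n_jobs,
            robustness_when_empty=True,
        )

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        dirs = [Path(tmp) / name for name in ("a", "b", "c")]
        for d, n_jobs in zip(dirs, (1, 1, 2)):
            run_pipeline(make_cfg(n_jobs), out_dir=d)
        names = sorted(p.name for p in dirs[0].iterdir())
        for other in dirs[1:]:
            if sorted(p.name for p in other.iterdir()) != names:
                return False
            match, mismatch, errors = filecmp.cmpfiles(dirs[0], other, names, shallow=False)
            if mismatch or errors:
                return False
    return True
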