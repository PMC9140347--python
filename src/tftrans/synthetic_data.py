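"""Synthetic genotype/expression datasets with a ground-truth ledger.

The generator emulates the statistical shape of a GTEx-style tissue dataset
as consumed by the pipeline:

* Hardy-Weinberg genotypes (dosage ~ Binomial(2, MAF), variants independent —
  no linkage disequilibrium);
* a TF -> target regulatory map whose TFs-per-gene counts follow an
  overdispersed (negative-binomial, zero-truncated) distribution with mean
  10.8 and SD 8.4, and about half the genes having at least one TF;
* nonsynonymous SNP counts per TF (mean 1.55, SD 1.77) with SIFT scores, a
  configurable fraction deleterious (SIFT < 0.05), plus synonymous decoys;
* gene expression assembled from cis-variant effects, trans effects mediated
  by TF expression and by deleterious nsSNP dosages, covariate effects, and
  Gaussian noise, with each component standardized and scaled so its realized
  variance fraction matches the configured target.

Every planted effect is recorded in a :class:`GroundTruth` ledger so that
recovery, calibration and type-I studies can score the pipeline's output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .io_formats import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeDosageMatrix,
    RegulatoryMap,
    VariantAnnotationTable,
)
from .seeding import derive_seed

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_regulatory_map",
    "simulate_annotations",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_dataset",
]

_CHROM_SLOTS = 20  # units per synthetic chromosome
_SLOT_SPACING = 3_000_000  # > 2x the 1 Mb cis window, so windows never overlap
_FIRST_CENTER = 2_000_000
_GENE_BODY = 20_000


@dataclass(frozen=True)
class SimulationConfig:
    """Defaults mirror the whole-blood / skeletal-muscle summary statistics
    (TFs per gene, nsSNPs per TF, fraction of genes with a TF) at a
    desk-scale gene count."""

    n_samples: int = 500
    n_genes: int = 200
    n_tfs: int = 120
    fraction_genes_with_tf: float = 0.52
    tf_per_gene_mean: float = 10.8
    tf_per_gene_sd: float = 8.4
    nsnp_per_tf_mean: float = 1.55
    nsnp_per_tf_sd: float = 1.77
    deleterious_fraction: float = 0.35
    n_synonymous_per_tf: int = 1
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_cis_variants_per_gene: int = 5
    n_cis_variants_per_tf: int = 3
    cis_r2: float = 0.15
    trans_expr_r2: float = 0.2
    trans_bind_r2: float = 0.0
    covariate_r2: float = 0.1
    noise_sd: float = 1.0
    n_covariates: int = 20
    n_causal_tfs: int = 2
    n_causal_snps: int = 2
    fraction_null_genes: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_tfs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        fracs = {
            "cis_r2": self.cis_r2,
            "trans_expr_r2": self.trans_expr_r2,
            "trans_bind_r2": self.trans_bind_r2,
            "covariate_r2": self.covariate_r2,
            "fraction_null_genes": self.fraction_null_genes,
            "fraction_genes_with_tf": self.fraction_genes_with_tf,
            "deleterious_fraction": self.deleterious_fraction,
        }
        for name, val in fracs.items():
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name}={val} outside [0, 1]")
        total = self.cis_r2 + self.trans_expr_r2 + self.trans_bind_r2
        if total > 1.0 + 1e-12:
            raise ConfigError(f"cis + trans variance fractions exceed 1 ({total})")
        if total + self.covariate_r2 > 1.0 + 1e-12:
            raise ConfigError("variance fractions (incl. covariates) exceed 1")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ConfigError(f"maf_range {self.maf_range} not within [0, 0.5]")
        if self.tf_per_gene_mean > self.n_tfs:
            raise ConfigError(
                f"tf_per_gene_mean={self.tf_per_gene_mean} exceeds n_tfs={self.n_tfs}"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown simulation config key(s): {sorted(unknown)}")
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["maf_range"] = list(d["maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted-effect ledger: one row per gene plus per-TF cis effects and
    per-variant minor-allele frequencies."""

    genes: pd.DataFrame  # index gene_id
    tfs: pd.DataFrame  # index tf_id
    variant_maf: pd.Series  # index variant_id

    def causal_tfs(self, gene_id: str) -> list[str]:
        raw = self.genes.loc[gene_id, "causal_tfs"]
        return raw.split(";") if raw else []

    def causal_snps(self, gene_id: str) -> list[str]:
        raw = self.genes.loc[gene_id, "causal_snps"]
        return raw.split(";") if raw else []

    @property
    def null_genes(self) -> list[str]:
        return sorted(self.genes.index[self.genes["is_null"]])

    @property
    def signal_genes(self) -> list[str]:
        return sorted(self.genes.index[~self.genes["is_null"]])

    def write(self, genes_path, tfs_path, maf_path) -> None:
        self.genes.to_csv(genes_path, sep="\t", index_label="gene_id")
        self.tfs.to_csv(tfs_path, sep="\t", index_label="tf_id")
        self.variant_maf.rename("maf").to_csv(maf_path, sep="\t", index_label="variant_id")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genotypes: GenotypeDosageMatrix
    regulatory_map: RegulatoryMap
    annotations: VariantAnnotationTable
    expression: ExpressionMatrix
    covariates: CovariateTable
    gene_bounds: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# count distributions and layout
# ---------------------------------------------------------------------------


def _overdispersed_counts(
    rng: np.random.Generator, mean: float, sd: float, size: int, truncate_at_one: bool
) -> np.ndarray:
    """Counts matched to (mean, sd): negative binomial when sd^2 > mean,
    Poisson otherwise; optionally zero-truncated by resampling."""
    var = sd * sd

    def draw(k: int) -> np.ndarray:
        if var > mean > 0:
            shape = mean * mean / (var - mean)
            p = shape / (shape + mean)
            return rng.negative_binomial(shape, p, size=k)
        return rng.poisson(mean, size=k)

    counts = draw(size)
    if truncate_at_one:
        for _ in range(1000):
            zeros = counts == 0
            if not zeros.any():
                break
            counts[zeros] = draw(int(zeros.sum()))
        counts = np.maximum(counts, 1)
    return counts


def _unit_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    width_g = max(4, len(str(config.n_genes)))
    width_t = max(3, len(str(config.n_tfs)))
    genes = [f"G{i:0{width_g}d}" for i in range(1, config.n_genes + 1)]
    tfs = [f"TF{i:0{width_t}d}" for i in range(1, config.n_tfs + 1)]
    return genes, tfs


def _genomic_layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic placement of genes and TFs on synthetic chromosomes,
    spaced so that 1 Mb cis windows of distinct units never overlap."""
    genes, tfs = _unit_ids(config)
    rows = []
    for i, unit in enumerate(genes + tfs):
        chrom = f"chrS{i // _CHROM_SLOTS + 1}"
        center = _FIRST_CENTER + (i % _CHROM_SLOTS) * _SLOT_SPACING
        rows.append((unit, chrom, center, center + _GENE_BODY))
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end"]).set_index("id")


def gene_bounds(config: SimulationConfig) -> pd.DataFrame:
    layout = _genomic_layout(config)
    genes, _ = _unit_ids(config)
    return layout.loc[genes]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_regulatory_map(config: SimulationConfig) -> RegulatoryMap:
    rng = np.random.default_rng(derive_seed(config.seed, "sim_map"))
    genes, tfs = _unit_ids(config)
    layout = _genomic_layout(config)
    n_with_tf = int(round(config.fraction_genes_with_tf * config.n_genes))
    chosen = sorted(rng.choice(genes, size=n_with_tf, replace=False)) if n_with_tf else []
    counts = _overdispersed_counts(
        rng, config.tf_per_gene_mean, config.tf_per_gene_sd, len(chosen), truncate_at_one=True
    )
    counts = np.minimum(counts, config.n_tfs)
    rows = []
    for gene, k in zip(chosen, counts):
        for tf in sorted(rng.choice(tfs, size=int(k), replace=False)):
            rows.append((tf, gene))
    pairs = pd.DataFrame(rows, columns=["tf_id", "target_gene_id"])
    return RegulatoryMap(pairs, layout.loc[tfs])


def simulate_annotations(
    config: SimulationConfig, rmap: RegulatoryMap
) -> VariantAnnotationTable:
    rng = np.random.default_rng(derive_seed(config.seed, "sim_ann"))
    rows = []
    for tf in list(rmap.tf_bounds.index):
        n_ns = int(
            _overdispersed_counts(
                rng, config.nsnp_per_tf_mean, config.nsnp_per_tf_sd, 1, truncate_at_one=False
            )[0]
        )
        for j in range(n_ns):
            if rng.random() < config.deleterious_fraction:
                sift = rng.uniform(0.0, 0.05)
            else:
                sift = rng.uniform(0.05, 1.0)
            rows.append((f"{tf}_ns{j + 1}", tf, "nonsynonymous", sift))
        for j in range(config.n_synonymous_per_tf):
            rows.append((f"{tf}_syn{j + 1}", tf, "synonymous", rng.uniform(0.0, 1.0)))
    df = pd.DataFrame(rows, columns=["variant_id", "gene_id", "consequence", "sift_score"])
    return VariantAnnotationTable(df)


def simulate_genotypes(
    config: SimulationConfig,
    rmap: RegulatoryMap | None = None,
    annotations: VariantAnnotationTable | None = None,
) -> GenotypeDosageMatrix:
    """HWE dosages for all cis variants, TF nsSNPs and synonymous decoys.

    cis variants are placed within +-1 Mb of their unit; annotated TF
    variants inside the TF's genomic body.
    """
    if rmap is None:
        rmap = simulate_regulatory_map(config)
    if annotations is None:
        annotations = simulate_annotations(config, rmap)
    rng = np.random.default_rng(derive_seed(config.seed, "sim_geno"))
    layout = _genomic_layout(config)
    genes, tfs = _unit_ids(config)

    ids: list[str] = []
    meta_rows: list[tuple] = []
    for unit, n_cis in [(g, config.n_cis_variants_per_gene) for g in genes] + [
        (t, config.n_cis_variants_per_tf) for t in tfs
    ]:
        chrom, start, end = layout.loc[unit, ["chrom", "start", "end"]]
        lo, hi = max(1, start - 1_000_000), end + 1_000_000
        for j in range(n_cis):
            vid = f"{unit}_cis{j + 1}"
            ids.append(vid)
            meta_rows.append((vid, chrom, int(rng.integers(lo, hi + 1)), "A", "G"))
    ann = annotations.data.sort_values("variant_id")
    for vid, tf in zip(ann["variant_id"], ann["gene_id"]):
        chrom, start, end = layout.loc[tf, ["chrom", "start", "end"]]
        ids.append(vid)
        meta_rows.append((vid, chrom, int(rng.integers(start, end + 1)), "C", "T"))

    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=len(ids))
    dosages = rng.binomial(2, mafs[None, :], size=(config.n_samples, len(ids))).astype(
        np.float64
    )
    samples = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]
    meta = pd.DataFrame(meta_rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    meta = meta.set_index("variant_id")
    g = GenotypeDosageMatrix(pd.DataFrame(dosages, index=samples, columns=ids), meta)
    g.data.attrs["maf"] = pd.Series(mafs, index=ids)
    return g


def _standardized(x: np.ndarray) -> np.ndarray | None:
    sd = x.std()
    if sd == 0:
        return None
    return (x - x.mean()) / sd


def simulate_expression(
    config: SimulationConfig,
    genotypes: GenotypeDosageMatrix,
    rmap: RegulatoryMap,
    annotations: VariantAnnotationTable,
) -> tuple[ExpressionMatrix, CovariateTable, GroundTruth]:
    """Assemble TF and gene expression from planted components.

    Each realized component is standardized across samples and scaled by the
    square root of its target variance fraction, so with ``noise_sd = 1`` the
    realized fractions match the configured ``*_r2`` targets up to sampling
    error. A component that cannot be realized (zero variance, or no
    deleterious nsSNP available for a binding effect) forfeits its fraction
    to noise and is recorded as 0 in the ledger. With ``noise_sd = 0`` the
    expression is an exact linear combination of the planted components.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "sim_expr"))
    genes, tfs = _unit_ids(config)
    n = config.n_samples
    samples = genotypes.sample_ids
    dos = genotypes.data

    cov_names = [f"COV{i:02d}" for i in range(1, config.n_covariates + 1)]
    C = rng.normal(size=(n, config.n_covariates))
    covariates = CovariateTable(pd.DataFrame(C, index=samples, columns=cov_names))

    def assemble(parts: list[tuple[str, np.ndarray | None, float]]) -> tuple[np.ndarray, dict]:
        # Components are Gram-Schmidt orthogonalized in order (each against
        # the intercept and all preceding components) before standardizing,
        # so the realized in-sample variance decomposition is exact: each
        # named component is the part of its raw signal orthogonal to what
        # precedes it.
        total = np.zeros(n)
        realized: dict[str, float] = {}
        used = 0.0
        basis = [np.ones(n)]
        for name, arr, frac in parts:
            if arr is None or frac <= 0:
                realized[name] = 0.0
                continue
            B = np.column_stack(basis)
            coef, *_ = np.linalg.lstsq(B, arr, rcond=None)
            resid = arr - B @ coef
            z = _standardized(resid)
            if z is None:
                realized[name] = 0.0
                continue
            total += math.sqrt(frac) * z
            basis.append(z)
            realized[name] = frac
            used += frac
        noise_var = config.noise_sd**2 * max(0.0, 1.0 - used)
        if noise_var > 0:
            raw_noise = rng.normal(size=n)
            B = np.column_stack(basis)
            coef, *_ = np.linalg.lstsq(B, raw_noise, rcond=None)
            z = _standardized(raw_noise - B @ coef)
            if z is not None:
                total += math.sqrt(noise_var) * z
        return total, realized

    # --- TF expression: own cis effects + noise ---------------------------
    # Covariate effects are planted on target genes only: the TF-expression
    # trans signal enters the target model as the realized regulatory input,
    # and keeping it free of the shared covariates makes every planted
    # variance fraction identifiable by a direct regression oracle.
    tf_expr = {}
    tf_rows = []
    for tf in tfs:
        cis_vars = [f"{tf}_cis{j + 1}" for j in range(config.n_cis_variants_per_tf)]
        w_cis = rng.normal(size=len(cis_vars))
        cis_comp = dos[cis_vars].to_numpy() @ w_cis if cis_vars else None
        expr, realized = assemble([("cis", cis_comp, config.cis_r2)])
        tf_expr[tf] = expr
        tf_rows.append(
            {
                "cis_variants": ";".join(cis_vars),
                "cis_weights": ";".join(f"{w:.6g}" for w in w_cis),
                "frac_cis": realized["cis"],
            }
        )
    tf_frame = pd.DataFrame(tf_rows, index=pd.Index(tfs, name="tf_id"))

    # --- gene expression --------------------------------------------------
    genes_with_tf = set(rmap.target_gene_ids)
    eligible = sorted(g for g in genes if g in genes_with_tf)
    n_null = int(round(config.fraction_null_genes * len(eligible)))
    null_set = set(rng.choice(eligible, size=n_null, replace=False)) if n_null else set()

    gene_rows = []
    expr_cols = {}
    for gene in genes:
        my_tfs = rmap.tfs_of(gene)
        is_null = (gene in null_set) or not my_tfs
        cis_vars = [f"{gene}_cis{j + 1}" for j in range(config.n_cis_variants_per_gene)]
        w_cis = rng.normal(size=len(cis_vars))
        w_cov = rng.normal(size=config.n_covariates)
        cis_comp = dos[cis_vars].to_numpy() @ w_cis if cis_vars else None

        causal_tfs: list[str] = []
        betas = np.array([])
        trans_e = None
        if not is_null and config.trans_expr_r2 > 0 and my_tfs:
            k = min(config.n_causal_tfs, len(my_tfs))
            causal_tfs = sorted(rng.choice(my_tfs, size=k, replace=False))
            betas = rng.normal(size=k)
            trans_e = np.column_stack([tf_expr[t] for t in causal_tfs]) @ betas

        causal_snps: list[str] = []
        gammas = np.array([])
        trans_b = None
        if not is_null and config.trans_bind_r2 > 0 and my_tfs:
            pool = annotations.deleterious_nonsynonymous(my_tfs)
            if pool:
                k = min(config.n_causal_snps, len(pool))
                causal_snps = sorted(rng.choice(pool, size=k, replace=False))
                gammas = rng.normal(size=k)
                trans_b = dos[causal_snps].to_numpy() @ gammas

        expr, realized = assemble(
            [
                ("cis", cis_comp, config.cis_r2),
                ("trans_expr", trans_e, config.trans_expr_r2 if not is_null else 0.0),
                ("trans_bind", trans_b, config.trans_bind_r2 if not is_null else 0.0),
                ("cov", C @ w_cov, config.covariate_r2),
            ]
        )
        expr_cols[gene] = expr
        # a gene is trans-null when no trans component was actually realized
        # (designated null, no TFs, zero configured fractions, or no
        # deleterious nsSNP available to carry a binding effect)
        is_null = realized["trans_expr"] == 0.0 and realized["trans_bind"] == 0.0
        gene_rows.append(
            {
                "has_tf": bool(my_tfs),
                "is_null": is_null,
                "causal_tfs": ";".join(causal_tfs),
                "tf_betas": ";".join(f"{b:.6g}" for b in betas),
                "causal_snps": ";".join(causal_snps),
                "snp_gammas": ";".join(f"{v:.6g}" for v in gammas),
                "cis_variants": ";".join(cis_vars),
                "cis_weights": ";".join(f"{w:.6g}" for w in w_cis),
                "frac_cis": realized["cis"],
                "frac_trans_expr": realized["trans_expr"],
                "frac_trans_bind": realized["trans_bind"],
                "frac_cov": realized["cov"],
            }
        )

    for tf in tfs:
        expr_cols[tf] = tf_expr[tf]
    expr_frame = pd.DataFrame(expr_cols, index=samples)[genes + tfs]
    gene_frame = pd.DataFrame(gene_rows, index=pd.Index(genes, name="gene_id"))

    maf = genotypes.data.attrs.get("maf")
    if maf is None:
        p_hat = genotypes.data.mean(axis=0) / 2.0
        maf = p_hat.rename("maf")
    truth = GroundTruth(gene_frame, tf_frame, maf)
    return ExpressionMatrix(expr_frame), covariates, truth


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all four generators with seeds derived from ``config.seed``."""
    rmap = simulate_regulatory_map(config)
    annotations = simulate_annotations(config, rmap)
    genotypes = simulate_genotypes(config, rmap, annotations)
    expression, covariates, truth = simulate_expression(config, genotypes, rmap, annotations)
    return SyntheticDataset(
        config=config,
        genotypes=genotypes,
        regulatory_map=rmap,
        annotations=annotations,
        expression=expression,
        covariates=covariates,
        gene_bounds=gene_bounds(config),
        truth=truth,
    )
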