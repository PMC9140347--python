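"""Typed readers and writers for every table the pipeline touches.

All files are tab-delimited UTF-8 with a single header row; empty fields and
the literal string ``NA`` are treated as missing. Genomic coordinates are
1-based inclusive (GRCh37 convention). Downstream modules never read files
directly — they consume the validated containers defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ValidationError

logger = logging.getLogger(__name__)

_NA_VALUES = ["", "NA"]

#: Map from SnpEff/Sequence Ontology consequence terms to the three classes
#: used by the pipeline. Unknown terms fall through to "other" (counted and
#: logged, never fatal).
CONSEQUENCE_ALIASES: dict[str, str] = {
    "nonsynonymous": "nonsynonymous",
    "missense_variant": "nonsynonymous",
    "missense": "nonsynonymous",
    "non_synonymous_codon": "nonsynonymous",
    "stop_gained": "nonsynonymous",
    "stop_lost": "nonsynonymous",
    "start_lost": "nonsynonymous",
    "synonymous": "synonymous",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Samples x genes matrix of continuous expression values."""

    data: pd.DataFrame  # index: samples, columns: genes

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dup}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dup}")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()[:5]
            raise ValidationError(f"missing expression values (e.g. in {bad})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)


@dataclass
class ResidualMatrix:
    """Expression after removing covariates (post_covariate) or additionally
    the cis prediction (post_cis)."""

    data: pd.DataFrame
    stage: str  # {"post_covariate", "post_cis"}

    def __post_init__(self) -> None:
        if self.stage not in ("post_covariate", "post_cis"):
            raise ValidationError(f"unknown residual stage: {self.stage!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GenotypeDosageMatrix:
    """Samples x variants alternate-allele dosage matrix with variant metadata."""

    data: pd.DataFrame  # index: samples, columns: variant ids
    variant_meta: pd.DataFrame  # index: variant ids; columns chrom, pos, ref, alt

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate variant identifiers: {dup}")
        vals = self.data.to_numpy(dtype=np.float64)
        if np.isnan(vals).any():
            raise ValidationError("missing dosage values")
        if (vals < 0).any() or (vals > 2).any():
            bad = self.data.columns[((vals < 0) | (vals > 2)).any(axis=0)].tolist()
            raise ValidationError(f"dosages outside [0, 2] for variants {bad[:5]}")
        if not self.variant_meta.index.equals(self.data.columns):
            raise ValidationError("variant metadata does not match dosage columns")
        pos = self.variant_meta["pos"]
        if (pos < 1).any():
            bad = self.variant_meta.index[pos < 1].tolist()
            raise ValidationError(f"non-positive (1-based) positions for {bad[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class CovariateTable:
    """Samples x covariates design table (categoricals already indicator-coded)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValidationError("missing covariate values")
        const = self.data.columns[self.data.std(axis=0, ddof=0) == 0].tolist()
        if const:
            logger.warning("dropping %d zero-variance covariate column(s): %s", len(const), const)
            self.data = self.data.drop(columns=const)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class RegulatoryMap:
    """Directed TF -> target-gene pairs plus TF genomic boundaries."""

    pairs: pd.DataFrame  # columns: tf_id, target_gene_id (unique rows)
    tf_bounds: pd.DataFrame  # index tf_id; columns chrom, start, end
    boundless_tfs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.pairs = self.pairs.drop_duplicates(ignore_index=True)
        self_pairs = self.pairs[self.pairs["tf_id"] == self.pairs["target_gene_id"]]
        if len(self_pairs):
            logger.info("regulatory map contains %d self-regulation pair(s)", len(self_pairs))
        if len(self.tf_bounds) and (self.tf_bounds["start"] > self.tf_bounds["end"]).any():
            bad = self.tf_bounds.index[self.tf_bounds["start"] > self.tf_bounds["end"]].tolist()
            raise FormatError(f"TF bounds with start > end: {bad[:5]}")
        self._tfs_of = {
            gene: sorted(sub["tf_id"]) for gene, sub in self.pairs.groupby("target_gene_id")
        }

    @property
    def tf_ids(self) -> list[str]:
        return sorted(self.pairs["tf_id"].unique())

    @property
    def target_gene_ids(self) -> list[str]:
        return sorted(self.pairs["target_gene_id"].unique())

    def tfs_of(self, gene_id: str) -> list[str]:
        return list(self._tfs_of.get(gene_id, []))

    def mean_tfs_per_gene(self) -> float:
        counts = self.pairs.groupby("target_gene_id").size()
        return float(counts.mean()) if len(counts) else 0.0


@dataclass
class VariantAnnotationTable:
    """Variant -> gene assignment with consequence class and SIFT score."""

    data: pd.DataFrame  # columns: variant_id, gene_id, consequence, sift_score

    def __post_init__(self) -> None:
        sift = self.data["sift_score"]
        bad = sift.notna() & ((sift < 0) | (sift > 1))
        if bad.any():
            raise ValidationError(
                f"SIFT scores outside [0, 1] for {self.data.loc[bad, 'variant_id'].tolist()[:5]}"
            )
        if self.data.duplicated(subset=["variant_id", "gene_id"]).any():
            raise ValidationError("duplicate (variant, gene) annotation rows")

    def deleterious_nonsynonymous(self, gene_ids: list[str] | set[str]) -> list[str]:
        """Variant ids that are nonsynonymous, SIFT-annotated and SIFT < 0.05
        (strict), assigned to any of the given genes. Sorted for determinism."""
        d = self.data
        mask = (
            d["gene_id"].isin(set(gene_ids))
            & (d["consequence"] == "nonsynonymous")
            & d["sift_score"].notna()
            & (d["sift_score"] < 0.05)
        )
        return sorted(d.loc[mask, "variant_id"].unique())


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _read_table(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep="\t", na_values=_NA_VALUES, keep_default_na=False, **kwargs
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _as_float_matrix(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        return df.astype(np.float64)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise FormatError(
                    f"{path}: non-numeric value {df[col][bad].iloc[0]!r} "
                    f"in column {col!r}, row {df.index[bad][0]!r}"
                ) from None
        raise


def align_samples(*sample_lists: list[str]) -> list[str]:
    """Sorted intersection of sample id lists; the pipeline's one alignment rule."""
    common = set(sample_lists[0])
    for ids in sample_lists[1:]:
        common &= set(ids)
    if not common:
        raise AlignmentError("no samples shared between tables")
    aligned = sorted(common)
    logger.debug("aligned %d shared samples", len(aligned))
    return aligned


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def read_expression(path, orientation: str = "samples_by_genes") -> ExpressionMatrix:
    """Read an expression table; returns samples x genes regardless of the
    on-disk orientation."""
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated row identifier(s) {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated column identifier(s) {dup}")
    df = _as_float_matrix(df, path)
    if orientation == "genes_by_samples":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix | ResidualMatrix, path) -> None:
    df = matrix.data
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_residuals(path, stage: str) -> ResidualMatrix:
    return ResidualMatrix(read_expression(path).data, stage=stage)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_DOSAGE_META_COLS = ["variant_id", "chrom", "pos", "ref", "alt"]


def read_dosages(path) -> GenotypeDosageMatrix:
    """Read a variant-rows dosage table: variant_id, chrom, pos, ref, alt,
    then one column per sample. Out-of-range dosages are errors, never clipped."""
    df = _read_table(path)
    _require_columns(df, _DOSAGE_META_COLS, path)
    meta = df[_DOSAGE_META_COLS[1:]].copy()
    meta.index = df["variant_id"].astype(str)
    if meta["pos"].isna().any():
        raise FormatError(f"{path}: missing variant positions")
    meta["pos"] = meta["pos"].astype(np.int64)
    sample_cols = [c for c in df.columns if c not in _DOSAGE_META_COLS]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns after metadata")
    dos = _as_float_matrix(df[sample_cols].set_axis(meta.index, axis=0), path).T
    return GenotypeDosageMatrix(dos, meta)


def write_dosages(g: GenotypeDosageMatrix, path) -> None:
    out = g.variant_meta.copy()
    out.insert(0, "variant_id", out.index)
    out = pd.concat([out.reset_index(drop=True), g.data.T.reset_index(drop=True)], axis=1)
    out.columns = _DOSAGE_META_COLS + g.sample_ids
    out.to_csv(path, sep="\t", index=False)


def vcf_to_dosages(path) -> GenotypeDosageMatrix:
    """Convert a VCF (4.x, DS or GT field) into a dosage matrix.

    Dosage is the alternate-allele count (or the DS field when present).
    Variants with any missing genotype, or with more than one ALT allele, are
    dropped with a warning — silent imputation is never performed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_dropped += 1
            continue
        ds = None
        try:
            ds_field = var.format("DS")
        except KeyError:
            ds_field = None
        if ds_field is not None:
            ds = np.asarray(ds_field, dtype=np.float64).reshape(-1)
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            if (gts < 0).any():
                n_dropped += 1
                continue
            ds = gts.sum(axis=1).astype(np.float64)
        if np.isnan(ds).any():
            n_dropped += 1
            continue
        vid = var.ID or f"{var.CHROM}_{var.POS}_{var.REF}_{var.ALT[0]}"
        cols[vid] = ds
        meta_rows.append((vid, var.CHROM, var.POS, var.REF, var.ALT[0]))
    if n_dropped:
        logger.warning("dropped %d variant(s) with missing/multi-allelic genotypes", n_dropped)
    if not meta_rows:
        raise FormatError(f"{path}: no usable variants")
    meta = pd.DataFrame(meta_rows, columns=_DOSAGE_META_COLS).set_index("variant_id")
    data = pd.DataFrame(cols, index=samples)
    return GenotypeDosageMatrix(data, meta)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def read_covariates(path) -> CovariateTable:
    df = _read_table(path, index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicated sample identifiers")
    df = _as_float_matrix(df, path)
    df.index = df.index.astype(str)
    return CovariateTable(df)


def write_covariates(cov: CovariateTable, path) -> None:
    cov.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# regulatory map and bounds
# ---------------------------------------------------------------------------


def read_bounds(path) -> pd.DataFrame:
    """Generic id/chrom/start/end interval table (1-based inclusive)."""
    df = _read_table(path)
    id_col = df.columns[0]
    _require_columns(df, [id_col, "chrom", "start", "end"], path)
    df = df.set_index(df[id_col].astype(str))[["chrom", "start", "end"]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] < 1).any():
        raise ValidationError(f"{path}: non-positive 1-based start coordinate")
    if (df["start"] > df["end"]).any():
        bad = df.index[df["start"] > df["end"]].tolist()
        raise FormatError(f"{path}: start > end for {bad[:5]}")
    return df


def write_bounds(bounds: pd.DataFrame, path, id_label: str = "id") -> None:
    out = bounds.copy()
    out.insert(0, id_label, out.index)
    out.to_csv(path, sep="\t", index=False)


def read_regulatory_map(pairs_path, bounds_path) -> RegulatoryMap:
    pairs = _read_table(pairs_path)
    _require_columns(pairs, ["tf_id", "target_gene_id"], pairs_path)
    pairs = pairs[["tf_id", "target_gene_id"]].astype(str)
    n_raw = len(pairs)
    pairs = pairs.drop_duplicates(ignore_index=True)
    logger.info("regulatory map: %d unique pairs (%d rows read)", len(pairs), n_raw)
    bounds = read_bounds(bounds_path)
    boundless = set(pairs["tf_id"]) - set(bounds.index)
    if boundless:
        logger.warning(
            "%d TF(s) missing genomic bounds (excluded from TF-binding): %s",
            len(boundless),
            sorted(boundless)[:5],
        )
    return RegulatoryMap(pairs, bounds, boundless)


def write_regulatory_map(rmap: RegulatoryMap, pairs_path, bounds_path) -> None:
    rmap.pairs.to_csv(pairs_path, sep="\t", index=False)
    write_bounds(rmap.tf_bounds, bounds_path, id_label="tf_id")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def read_annotations(path) -> VariantAnnotationTable:
    df = _read_table(path)
    _require_columns(df, ["variant_id", "gene_id", "consequence", "sift_score"], path)
    df = df[["variant_id", "gene_id", "consequence", "sift_score"]].copy()
    df["variant_id"] = df["variant_id"].astype(str)
    df["gene_id"] = df["gene_id"].astype(str)
    raw = df["consequence"].astype(str).str.strip().str.lower()
    mapped = raw.map(CONSEQUENCE_ALIASES)
    unknown = mapped.isna() & raw.notna()
    if unknown.any():
        logger.info(
            "%d annotation row(s) with unrecognized consequence mapped to 'other': %s",
            int(unknown.sum()),
            sorted(raw[unknown].unique())[:5],
        )
    df["consequence"] = mapped.fillna("other")
    df["sift_score"] = pd.to_numeric(df["sift_score"], errors="raise")
    return VariantAnnotationTable(df)


def write_annotations(ann: VariantAnnotationTable, path) -> None:
    ann.data.to_csv(path, sep="\t", index=False, na_rep="NA")
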