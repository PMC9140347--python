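"""Hit tables, explanatory-trans classification and overlap statistics.

A *hit* is a candidate gene that passed both background nulls (BH-adjusted,
strictly below alpha) and was discovered in at least half of the robustness
runs. A hit is an *explanatory trans association* when the TF model explains
at least as much variance as the cis baseline (``r2_tf >= r2_cis``; the
strictly-greater count is reported alongside).

Cross-study overlap significance uses the exact hypergeometric upper tail
on a user-chosen gene universe (default: the genes tested in the run).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .preprocessing import CisModelFit
from .significance import RobustnessResult
from .tf_models import TFModelFit

logger = logging.getLogger(__name__)

__all__ = [
    "build_hit_report",
    "classify_explanatory",
    "hypergeometric_overlap",
    "cross_tissue_summary",
    "shared_snp_audit",
    "write_hit_report",
    "read_hit_report",
]

_HIT_COLUMNS = [
    "gene_id",
    "tissue",
    "mechanism",
    "r2_cis",
    "r2_tf",
    "p_adj_shuffled",
    "p_adj_random_tf",
    "n_discovered",
    "n_runs",
    "passed_background",
    "is_hit",
    "is_explanatory",
    "top_weights",
]


def build_hit_report(
    tf_fits: dict[str, TFModelFit],
    cis_fits: dict[str, CisModelFit],
    background: pd.DataFrame,
    robustness: dict[str, RobustnessResult],
    passed_background: list[str],
    tissue: str = "synthetic",
    top_k: int = 5,
) -> pd.DataFrame:
    """Assemble the per-gene final table for one (tissue, mechanism) run."""
    bg = background.set_index(["gene_id", "null_kind"])
    rows = []
    for gene in sorted(tf_fits):
        fit = tf_fits[gene]
        p_sh = bg.loc[(gene, "shuffled_residuals"), "p_adjusted"]
        p_rt = bg.loc[(gene, "random_tf_sets"), "p_adjusted"]
        rob = robustness.get(gene)
        n_disc = rob.n_discovered if rob else 0
        n_runs = rob.n_runs if rob else 0
        passed = gene in passed_background
        is_hit = passed and rob is not None and rob.is_hit
        top = fit.weights.abs().sort_values(ascending=False, kind="stable").head(top_k)
        top_str = ";".join(f"{p}={fit.weights[p]:.4g}" for p in top.index)
        cis = cis_fits.get(gene)
        r2_cis = cis.r2_cis if cis else 0.0
        rows.append(
            (
                gene,
                tissue,
                fit.mechanism,
                r2_cis,
                fit.r2_tf,
                p_sh,
                p_rt,
                n_disc,
                n_runs,
                passed,
                is_hit,
                pd.NA,  # filled by classify_explanatory, defined only for hits
                top_str,
            )
        )
    report = pd.DataFrame(rows, columns=_HIT_COLUMNS)
    return classify_explanatory(report)


def classify_explanatory(report: pd.DataFrame) -> pd.DataFrame:
    """Flag hits whose TF model explains at least the cis baseline's R2.

    ``is_explanatory`` is defined only for hits (NA otherwise). Both the
    inclusive (>=) count and the strictly-greater count are logged."""
    report = report.copy()
    hits = report["is_hit"].astype(bool)
    report["is_explanatory"] = pd.array([pd.NA] * len(report), dtype="boolean")
    report.loc[hits, "is_explanatory"] = (
        report.loc[hits, "r2_tf"] >= report.loc[hits, "r2_cis"]
    )
    n_hits = int(hits.sum())
    n_expl = int((report.loc[hits, "is_explanatory"] == True).sum())  # noqa: E712
    n_strict = int((report.loc[hits, "r2_tf"] > report.loc[hits, "r2_cis"]).sum())
    logger.info(
        "hits: %d; explanatory (r2_tf >= r2_cis): %d; strictly greater: %d",
        n_hits,
        n_expl,
        n_strict,
    )
    return report


def hypergeometric_overlap(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[int, float]:
    """Exact upper-tail overlap test.

    p = P(X >= |A & B|) for X ~ Hypergeom(|universe|, |A|, |B|)."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValidationError("overlap sets must be contained in the universe")
    k = len(set_a & set_b)
    p = float(hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))
    return k, min(p, 1.0)


def cross_tissue_summary(hit_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise intersections and exclusives across (tissue, mechanism) runs."""
    if len(hit_sets) < 2:
        raise ValidationError("need at least two hit sets to summarize")
    names = sorted(hit_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = hit_sets[a] & hit_sets[b]
            rows.append(
                (
                    a,
                    b,
                    len(hit_sets[a]),
                    len(hit_sets[b]),
                    len(inter),
                    len(hit_sets[a] - hit_sets[b]),
                    len(hit_sets[b] - hit_sets[a]),
                    ";".join(sorted(inter)),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "set_a",
            "set_b",
            "n_a",
            "n_b",
            "n_intersection",
            "n_only_a",
            "n_only_b",
            "shared_genes",
        ],
    )


def shared_snp_audit(
    binding_fits: dict[str, TFModelFit], cis_fits: dict[str, CisModelFit]
) -> pd.DataFrame:
    """Per gene, the variants used by both the cis model and the TF-binding
    model (nonzero weights on both sides)."""
    rows = []
    for gene in sorted(binding_fits):
        tf_vars = set(binding_fits[gene].weights.index)
        cis = cis_fits.get(gene)
        cis_vars = set(cis.weights.index) if cis is not None else set()
        shared = sorted(tf_vars & cis_vars)
        rows.append((gene, len(shared), ";".join(shared)))
    return pd.DataFrame(rows, columns=["gene_id", "n_shared", "shared_variants"])


def write_hit_report(report: pd.DataFrame, path) -> None:
    out = report.copy()
    out["is_explanatory"] = out["is_explanatory"].map(
        {True: "True", False: "False", pd.NA: "NA"}
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_hit_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col in ("passed_background", "is_hit"):
        df[col] = df[col].astype(bool)
    df["is_explanatory"] = pd.array(
        [pd.NA if pd.isna(v) else bool(v) for v in df["is_explanatory"]], dtype="boolean"
    )
    df["top_weights"] = df["top_weights"].fillna("")
    return df
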