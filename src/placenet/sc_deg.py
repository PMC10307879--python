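"""Single-cell QC, normalization, and Wilcoxon differential expression.

Preprocessing follows the standard single-cell recipe: cells with a
mitochondrial read percentage at or above the cutoff (default 20%) are
removed, libraries are size-normalized to a common total (default 1e4) and
log1p-transformed. Differential expression between the tumor (T) and normal
(N) groups uses the two-sided Wilcoxon rank-sum test per gene — exact
enumeration when both groups have <= 10 tie-free observations, tie-corrected
normal approximation with continuity correction otherwise — with
Benjamini–Hochberg adjustment across all tested genes. A gene is called a DEG
when p_val_adj < 0.05 and |avg_logFC| > 0.25 (log fold change in base 2 by
default; base e selectable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCMetrics",
    "qc_metrics",
    "qc_filter",
    "normalize",
    "wilcoxon_deg",
    "bh_adjust",
    "write_deg_table",
    "read_deg_table",
]


@dataclass
class QCMetrics:
    """Per-cell QC metrics: total counts, detected genes, mito percentage."""

    n_count: pd.Series
    n_feature: pd.Series
    percent_mt: pd.Series  # 0–100


def qc_metrics(expr: ExpressionMatrix, mt_prefix: str = "MT-") -> QCMetrics:
    """nCount, nFeature and percent.mt per cell, from raw counts.

    Mitochondrial genes are identified by a case-insensitive label prefix.
    """
    if expr.normalized:
        raise ValueError("QC requires raw counts, got a log-normalized matrix")
    v = expr.values
    n_count = v.sum(axis=0)
    n_feature = (v > 0).sum(axis=0)
    is_mt = v.index.str.upper().str.startswith(mt_prefix.upper())
    mt_count = v.loc[is_mt].sum(axis=0) if is_mt.any() else pd.Series(0.0, index=v.columns)
    with np.errstate(invalid="ignore"):
        pct = np.where(n_count > 0, 100.0 * mt_count / n_count, 0.0)
    return QCMetrics(
        n_count=n_count.rename("nCount"),
        n_feature=n_feature.rename("nFeature"),
        percent_mt=pd.Series(pct, index=v.columns, name="percent_mt"),
    )


def qc_filter(
    expr: ExpressionMatrix, max_percent_mt: float = 20.0, mt_prefix: str = "MT-"
) -> ExpressionMatrix:
    """Retain cells with percent.mt strictly below the cutoff (default 20%).

    The gene set is unchanged; group labels are subset accordingly. Removing
    every cell is an error.
    """
    qc = qc_metrics(expr, mt_prefix=mt_prefix)
    keep = qc.percent_mt.index[qc.percent_mt < max_percent_mt]
    if len(keep) == 0:
        raise ValueError(
            f"QC filter removed all {expr.n_cells} cells "
            f"(percent.mt range {qc.percent_mt.min():.1f}–{qc.percent_mt.max():.1f})"
        )
    n_drop = expr.n_cells - len(keep)
    if n_drop:
        logger.info("qc_filter: removed %d/%d cells at percent.mt >= %g",
                    n_drop, expr.n_cells, max_percent_mt)
    return expr.subset_cells(list(keep))


def normalize(expr: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize each cell to ``scale`` total counts, then log1p.

    Mirrors the standard single-cell log-normalization: value ->
    log(1 + scale * value / cell_total), natural log. A zero-total cell is an
    error (it cannot be normalized).
    """
    if expr.normalized:
        raise ValueError("matrix is already log-normalized")
    totals = expr.values.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"cells with zero total counts cannot be normalized: {zero[:5]}")
    out = np.log1p(expr.values * (scale / totals))
    return replace(expr, values=out, normalized=True)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact enumeration when both groups are
    small (<= 10) and tie-free, tie-corrected normal approximation with
    continuity correction otherwise."""
    if len(a) <= 10 and len(b) <= 10 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b):
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _avg_logfc(a: np.ndarray, b: np.ndarray, base: float) -> float:
    """log((mean expm1(a) + 1) / (mean expm1(b) + 1)) in the given base — the
    pseudocount mean-of-expm1 convention of the standard single-cell toolkit."""
    num = np.mean(np.expm1(a)) + 1.0
    den = np.mean(np.expm1(b)) + 1.0
    return float(np.log(num / den) / np.log(base))


def wilcoxon_deg(
    expr: ExpressionMatrix,
    group_a: str = "T",
    group_b: str = "N",
    min_abs_logfc: float = 0.25,
    max_padj: float = 0.05,
    *,
    logfc_base: float = 2.0,
    two_sided_fc: bool = True,
    force: bool = False,
) -> pd.DataFrame:
    """Differential expression of ``group_a`` over ``group_b``.

    Returns a DataFrame with columns gene, p_val, avg_logFC, p_val_adj,
    filtered to p_val_adj < ``max_padj`` and |avg_logFC| > ``min_abs_logfc``
    (one-sided, avg_logFC > threshold, when ``two_sided_fc`` is False),
    sorted by p_val then |avg_logFC| descending, ties alphabetical.
    BH adjustment is computed across all tested genes before filtering.
    """
    if not expr.normalized:
        raise ValueError("wilcoxon_deg expects a log-normalized matrix")
    cells_a = expr.cells_in_group(group_a)
    cells_b = expr.cells_in_group(group_b)
    if min(len(cells_a), len(cells_b)) == 0:
        raise ValueError(f"empty group: {group_a}={len(cells_a)}, {group_b}={len(cells_b)} cells")
    if min(len(cells_a), len(cells_b)) < 3 and not force:
        raise ValueError(
            f"group sizes {len(cells_a)} vs {len(cells_b)} below 3; pass force=True to override"
        )

    va = expr.values[cells_a].to_numpy(dtype=float)
    vb = expr.values[cells_b].to_numpy(dtype=float)
    genes = expr.genes
    pvals = np.empty(len(genes))
    logfc = np.empty(len(genes))
    for i in range(len(genes)):
        a, b = va[i], vb[i]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[i] = 1.0
        else:
            pvals[i] = _rank_sum_p(a, b)
        logfc[i] = _avg_logfc(a, b, logfc_base)

    padj = bh_adjust(pvals)
    df = pd.DataFrame(
        {"gene": genes, "p_val": pvals, "avg_logFC": logfc, "p_val_adj": padj}
    )
    fc_ok = df["avg_logFC"].abs() > min_abs_logfc if two_sided_fc else df["avg_logFC"] > min_abs_logfc
    df = df[(df["p_val_adj"] < max_padj) & fc_ok].copy()
    df["_absfc"] = df["avg_logFC"].abs()
    df = df.sort_values(
        ["p_val", "_absfc", "gene"], ascending=[True, False, True]
    ).drop(columns="_absfc").reset_index(drop=True)
    return df


def write_deg_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "p_val", "avg_logFC", "p_val_adj"}
    missing = required - set(df.columns)
    if missing:
        # tolerate the printed base-2 header
        if "avg_log2FC" in df.columns and "avg_logFC" in missing:
            df = df.rename(columns={"avg_log2FC": "avg_logFC"})
            missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    df["gene"] = df["gene"].astype(str)
    return df
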