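"""Pearson co-expression testing and the retention filter.

The combinatory step keeps a PPI partner only when the candidate-partner pair
is co-expressed: sample Pearson r above a threshold (default r > 0.5) with a
two-sided p-value below a threshold (default p < 0.05). Significance comes
from the exact t-transform t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of
freedom. The filter is positive-only by default; absolute-r and
Benjamini–Hochberg modes are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionEdge",
    "CoexprFilter",
    "ZeroVarianceError",
    "pearson_with_p",
    "coexpression_edges",
    "write_edges",
]


class ZeroVarianceError(ValueError):
    """Correlation is undefined because one vector is constant."""


@dataclass(frozen=True)
class CoexpressionEdge:
    """Unordered co-expression edge: (a, b) == (b, a) with identical r, p."""

    gene_a: str
    gene_b: str
    r: float
    p: float
    n: int

    def __post_init__(self):
        if self.gene_b < self.gene_a:  # canonical orientation, so (a,b) == (b,a)
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)


@dataclass
class CoexprFilter:
    """Retention thresholds: keep a pair iff r > r_min (or |r| > r_min) and
    p < p_max, optionally after BH adjustment across the tested pairs."""

    r_min: float = 0.5
    p_max: float = 0.05
    use_absolute_r: bool = False
    adjust: str = "none"  # or "bh"

    def __post_init__(self):
        if not 0 <= self.r_min <= 1:
            raise ValueError("r_min must be in [0, 1]")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")
        if self.adjust not in ("none", "bh"):
            raise ValueError("adjust must be 'none' or 'bh'")

    def passes(self, r: float, p: float) -> bool:
        rv = abs(r) if self.use_absolute_r else r
        return rv > self.r_min and p < self.p_max


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Sample Pearson r with its two-sided t-test p-value and n.

    Requires n >= 3 and nonzero variance in both vectors; a constant vector
    raises :class:`ZeroVarianceError` (callers may skip such pairs). |r| = 1
    yields p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("undefined correlation: constant input vector")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if 1.0 - abs(r) < 4 * np.finfo(float).eps:  # exact linear dependence
        return (1.0 if r > 0 else -1.0), 0.0, n
    return r, float(res.pvalue), n


def coexpression_edges(
    expr: ExpressionMatrix,
    anchor: str,
    partners,
    filt: CoexprFilter | None = None,
    *,
    cells=None,
) -> set[CoexpressionEdge]:
    """Anchor–partner edges passing the retention filter.

    Partners missing from the matrix are skipped with a warning; the
    anchor–anchor pair is never tested; zero-variance pairs are excluded and
    counted. ``cells`` restricts the observations (e.g. tumor-only mode);
    the default uses every cell in the matrix.
    """
    if filt is None:
        filt = CoexprFilter()
    if anchor not in expr.values.index:
        raise KeyError(f"anchor gene {anchor!r} not in expression matrix")
    sub = expr if cells is None else expr.subset_cells(cells)
    xa = sub.gene_vector(anchor)

    tested: list[tuple[str, float, float, int]] = []
    n_missing = n_zerovar = 0
    for g in partners:
        if g == anchor:
            continue
        if g not in sub.values.index:
            n_missing += 1
            continue
        try:
            r, p, n = pearson_with_p(xa, sub.gene_vector(g))
        except ZeroVarianceError:
            n_zerovar += 1
            continue
        tested.append((g, r, p, n))

    if n_missing:
        logger.warning("coexpression_edges(%s): %d partners missing from matrix", anchor, n_missing)
    if n_zerovar:
        logger.info("coexpression_edges(%s): %d zero-variance pairs excluded", anchor, n_zerovar)

    if filt.adjust == "bh" and tested:
        from statsmodels.stats.multitest import multipletests
        padj = multipletests([t[2] for t in tested], method="fdr_bh")[1]
        tested = [(g, r, float(pa), n) for (g, r, _p, n), pa in zip(tested, padj)]

    return {
        CoexpressionEdge(anchor, g, r, p, n)
        for g, r, p, n in tested
        if filt.passes(r, p)
    }


def write_edges(edges, filt: CoexprFilter, path, *, all_tested=None) -> None:
    """TSV edge-attribute table (gene_a, gene_b, r, p, n, passed_filter),
    consumable by Cytoscape. ``all_tested`` optionally supplies non-passing
    edges so the table records the full tested set."""
    rows = [(e, True) for e in sorted(edges, key=lambda e: (e.gene_a, e.gene_b))]
    if all_tested is not None:
        passed = set(edges)
        rows += [
            (e, False)
            for e in sorted(all_tested, key=lambda e: (e.gene_a, e.gene_b))
            if e not in passed
        ]
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tr\tp\tn\tpassed_filter\n")
        for e, ok in rows:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.r:.6g}\t{e.p:.6g}\t{e.n}\t{ok}\n")
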