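"""The PLACE combinatory step: physical-link levels x co-expression.

For each candidate gene in the DEG universe, its exclusive level-1/2/3 PPI
partners are intersected with the DEG set, and a partner is retained only if
the candidate-partner pair passes the Pearson co-expression filter (r > 0.5,
p < 0.05 by default). Candidates are ranked in descending order by the
retained level counts — by default lexicographically on (n1, n2, n3), direct
partners dominating; a total-count ordering is available since the original
description does not disambiguate. The gene-of-interest network assembles the
retained partners, the physical edges among them, the co-expression
annotations, and the pass-through intermediates on level-2/3 shortest paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .coexpression import CoexprFilter, ZeroVarianceError, pearson_with_p
from .expression import ExpressionMatrix
from .ppi import LevelProfile, PPINetwork, all_level_profiles, level_profile

logger = logging.getLogger(__name__)

__all__ = [
    "PlaceScore",
    "PlaceConfig",
    "GeneNetwork",
    "place_scores",
    "rank_candidates",
    "gene_network",
    "export_network",
    "scores_to_frame",
]


@dataclass
class PlaceScore:
    """Retained partner counts of one candidate at levels 1..3."""

    gene: str
    n1: int = 0
    n2: int = 0
    n3: int = 0
    retained_partners: dict[int, set[str]] = field(default_factory=dict)
    rank: int | None = None

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.n1, self.n2, self.n3)

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3


@dataclass
class PlaceConfig:
    """Knobs of the combinatory step.

    ordering: "lexicographic" ranks by (n1, n2, n3) with level 1 dominating;
    "total" ranks by n1+n2+n3. partner_universe: "degs" restricts partners to
    the DEG set (the default), "all" opens the whole interactome.
    strict_intermediates additionally requires every intermediate protein on a
    level-2/3 shortest path to pass the co-expression filter against the
    candidate (endpoint-only is the default rule).
    """

    max_level: int = 3
    coexpr: CoexprFilter = field(default_factory=CoexprFilter)
    ordering: str = "lexicographic"
    top_k: int = 10
    partner_universe: str = "degs"
    strict_intermediates: bool = False

    def __post_init__(self):
        if self.ordering not in ("lexicographic", "total"):
            raise ValueError("ordering must be 'lexicographic' or 'total'")
        if self.partner_universe not in ("degs", "all"):
            raise ValueError("partner_universe must be 'degs' or 'all'")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def _pair_passes(expr: ExpressionMatrix, a: str, b: str, filt: CoexprFilter) -> bool:
    if a not in expr.values.index or b not in expr.values.index:
        return False
    try:
        r, p, _n = pearson_with_p(expr.gene_vector(a), expr.gene_vector(b))
    except ZeroVarianceError:
        return False
    return filt.passes(r, p)


def _intermediates_ok(
    net: PPINetwork, expr: ExpressionMatrix, source: str, partner: str,
    level: int, filt: CoexprFilter,
) -> bool:
    """Strict mode: some shortest path source->partner must have all its
    interior proteins pass the co-expression filter against the source."""
    if level == 1:
        return True
    for path in nx.all_shortest_paths(net.graph, source, partner):
        if all(_pair_passes(expr, source, x, filt) for x in path[1:-1]):
            return True
    return False


def place_scores(
    degs: pd.DataFrame,
    net: PPINetwork,
    expr: ExpressionMatrix,
    config: PlaceConfig | None = None,
) -> list[PlaceScore]:
    """Score every DEG: level sets intersected with the partner universe,
    each surviving endpoint pair tested against the co-expression filter.

    DEG genes absent from the PPI network score (0, 0, 0); DEG genes absent
    from the expression matrix are skipped with a warning (their pairs cannot
    be tested). Returns one PlaceScore per DEG, unranked.
    """
    if config is None:
        config = PlaceConfig()
    if degs is None or len(degs) == 0:
        raise ValueError("empty DEG table")
    deg_genes = list(dict.fromkeys(degs["gene"].astype(str)))
    missing_expr = [g for g in deg_genes if g not in expr.values.index]
    if missing_expr:
        logger.warning("place_scores: %d DEGs absent from expression matrix, skipped: %s",
                       len(missing_expr), missing_expr[:5])
    candidates = [g for g in deg_genes if g not in missing_expr]
    universe = set(deg_genes) if config.partner_universe == "degs" else net.nodes

    profiles = all_level_profiles(net, candidates, config.max_level)
    scores: list[PlaceScore] = []
    for g in candidates:
        prof = profiles[g]
        retained: dict[int, set[str]] = {}
        for k in range(1, config.max_level + 1):
            kept: set[str] = set()
            for partner in prof.level_sets.get(k, set()) & universe:
                if partner == g:
                    continue
                if not _pair_passes(expr, g, partner, config.coexpr):
                    continue
                if config.strict_intermediates and not _intermediates_ok(
                    net, expr, g, partner, k, config.coexpr
                ):
                    continue
                kept.add(partner)
            retained[k] = kept
        counts = [len(retained.get(k, set())) for k in (1, 2, 3)]
        scores.append(PlaceScore(g, *counts, retained_partners=retained))
    return scores


def rank_candidates(scores, config: PlaceConfig | None = None) -> list[PlaceScore]:
    """Order candidates by descending score key (ties alphabetical) and fill
    in 1-based ranks."""
    if config is None:
        config = PlaceConfig()
    if not scores:
        raise ValueError("no scores to rank")
    if config.ordering == "lexicographic":
        keyfn = lambda s: (-s.n1, -s.n2, -s.n3, s.gene)
    else:
        keyfn = lambda s: (-s.total, s.gene)
    ordered = sorted(scores, key=keyfn)
    for i, s in enumerate(ordered, 1):
        s.rank = i
    return ordered


def scores_to_frame(ranked, degs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Ranked table (gene, n1, n2, n3, n_total, rank), joined with DEG
    statistics when a DEG table is supplied."""
    df = pd.DataFrame(
        [
            {"gene": s.gene, "n1": s.n1, "n2": s.n2, "n3": s.n3,
             "n_total": s.total, "rank": s.rank}
            for s in ranked
        ]
    )
    if degs is not None:
        df = df.merge(degs[["gene", "p_val", "avg_logFC", "p_val_adj"]], on="gene", how="left")
    return df


@dataclass
class GeneNetwork:
    """Gene-of-interest network: the center, its retained partners with level
    attributes, pass-through intermediates, physical edges and co-expression
    annotations. Backed by a networkx graph."""

    center: str
    graph: nx.Graph

    @property
    def partner_nodes(self) -> set[str]:
        return {
            n for n, d in self.graph.nodes(data=True)
            if n != self.center and not d.get("intermediate", False)
        }

    @property
    def intermediate_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("intermediate", False)}


def gene_network(
    gene: str,
    net: PPINetwork,
    degs: pd.DataFrame,
    expr: ExpressionMatrix,
    config: PlaceConfig | None = None,
) -> GeneNetwork:
    """Build the gene-of-interest regulatory network.

    Nodes are the retained partners (level attribute 1..max_level) plus the
    interior proteins of the level-2/3 shortest paths, flagged
    ``intermediate=True``. Edges are the physical PPI edges among all included
    nodes, annotated with ``kind="both"`` plus Pearson r/p when both endpoints
    are DEGs and the pair was testable, else ``kind="physical"``.
    """
    if config is None:
        config = PlaceConfig()
    if gene not in net:
        raise KeyError(f"gene {gene!r} not in PPI network")
    deg_genes = set(degs["gene"].astype(str))
    prof = level_profile(net, gene, config.max_level)
    universe = deg_genes if config.partner_universe == "degs" else net.nodes
    retained: dict[int, set[str]] = {}
    for k in range(1, config.max_level + 1):
        kept = set()
        for partner in prof.level_sets.get(k, set()) & universe:
            if partner != gene and _pair_passes(expr, gene, partner, config.coexpr):
                if config.strict_intermediates and not _intermediates_ok(
                    net, expr, gene, partner, k, config.coexpr
                ):
                    continue
                kept.add(partner)
        retained[k] = kept

    g = nx.Graph()
    g.add_node(gene, center=True)
    all_partners = set()
    for k, members in retained.items():
        for m in members:
            g.add_node(m, level=k, intermediate=False)
            all_partners.add(m)
    # pass-through intermediates on shortest paths to level>=2 partners
    intermediates: set[str] = set()
    for k, members in retained.items():
        if k == 1:
            continue
        for m in members:
            for path in nx.all_shortest_paths(net.graph, gene, m):
                intermediates.update(path[1:-1])
    intermediates -= all_partners | {gene}
    for x in sorted(intermediates):
        g.add_node(x, intermediate=True)

    included = {gene} | all_partners | intermediates
    for u, v in net.graph.edges:
        if u in included and v in included:
            attrs = {"kind": "physical"}
            if u in deg_genes and v in deg_genes:
                try:
                    r, p, _n = pearson_with_p(expr.gene_vector(u), expr.gene_vector(v))
                    attrs = {"kind": "both", "r": r, "p": p}
                except (ZeroVarianceError, KeyError):
                    pass
            g.add_edge(u, v, **attrs)
    if not all_partners:
        logger.warning("gene_network(%s): no retained partners — center-only network", gene)
    return GeneNetwork(gene, g)


_FORMATS = ("graphml", "sif", "edge-tsv")


def export_network(gn: GeneNetwork, path, format: str = "graphml") -> None:
    """Write the gene-of-interest network for Cytoscape.

    graphml: node attributes level/intermediate, edge attributes kind/r/p;
    sif: one line per physical edge with relation token ``pp`` (or ``co``
    when co-expression-annotated); edge-tsv: tabular edge attributes.
    """
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose one of {_FORMATS}")
    edges = sorted(gn.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2])))
    if format == "graphml":
        # write deterministically: rebuild with sorted nodes/edges
        h = nx.Graph()
        for n in sorted(gn.graph.nodes):
            h.add_node(n, **gn.graph.nodes[n])
        for u, v, d in edges:
            a, b = sorted((u, v))
            h.add_edge(a, b, **d)
        nx.write_graphml(h, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, d in edges:
                a, b = sorted((u, v))
                token = "co" if d.get("kind") == "both" else "pp"
                fh.write(f"{a}\t{token}\t{b}\n")
    else:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tkind\tr\tp\n")
            for u, v, d in edges:
                a, b = sorted((u, v))
                r = f"{d['r']:.6g}" if "r" in d else ""
                p = f"{d['p']:.6g}" if "p" in d else ""
                fh.write(f"{a}\t{b}\t{d.get('kind', 'physical')}\t{r}\t{p}\n")
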