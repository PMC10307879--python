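"""Protein–protein interaction graphs and shortest-path level neighborhoods.

A PPI network is an undirected simple graph over gene identifiers. The level-k
partners of a source gene are the genes at shortest-path distance exactly k:
level 1 is a direct physical interaction (A–B), level 2 has one intermediate
protein (A–X–B) and level 3 has two (A–X1–X2–B). Assignment is exclusive — a
protein reachable at distance 1 is never also counted at level 2 or 3, so the
level sets of one source are pairwise disjoint. A non-exclusive "path-exists"
mode is available for sensitivity analysis.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "LevelProfile",
    "load_id_map",
    "load_ppi",
    "write_ppi",
    "level_profile",
    "all_level_profiles",
]


class PPIParseError(ValueError):
    """Raised when an edge-list line cannot be parsed."""


class UnknownGeneError(KeyError):
    """Raised when a requested source gene is not in the network."""


@dataclass
class PPINetwork:
    """Undirected simple graph of physical interactions.

    Invariants: no self-loops, no duplicate (unordered) edges, every edge
    endpoint is a node. Isolated nodes are allowed (e.g. retained self-loop
    endpoints when configured).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop edge rejected: {u!r}")
        self.graph.add_edge(u, v)

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


@dataclass
class LevelProfile:
    """Exclusive level-k partner sets of one source gene.

    ``level_sets[k]`` holds the genes at shortest-path distance exactly k from
    ``source`` (1 <= k <= max_level). Sets are pairwise disjoint and never
    contain the source.
    """

    source: str
    level_sets: dict[int, set[str]]
    max_level: int = 3

    def count(self, level: int) -> int:
        return len(self.level_sets.get(level, set()))

    @property
    def partners(self) -> set[str]:
        out: set[str] = set()
        for s in self.level_sets.values():
            out |= s
        return out

    def level_of(self, gene: str) -> int | None:
        for k, s in self.level_sets.items():
            if gene in s:
                return k
        return None


def load_id_map(path) -> dict[str, str]:
    """Read a two-column identifier-mapping TSV (from, to)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise PPIParseError(f"{path}: line {lineno}: expected 2 columns")
            mapping[parts[0]] = parts[1]
    return mapping


def _looks_like_header(fields: list[str]) -> bool:
    lowered = [f.lower() for f in fields[:2]]
    header_words = {
        "gene", "gene_a", "gene_b", "genea", "geneb", "source", "target",
        "protein", "protein_a", "protein_b", "from", "to", "node1", "node2",
        "ensembl_gene_id_a", "ensembl_gene_id_b", "symbol_a", "symbol_b",
    }
    return any(f in header_words for f in lowered)


def load_ppi(
    path,
    id_map: dict[str, str] | None = None,
    *,
    header: bool | None = None,
    keep_self_loop_nodes: bool = False,
) -> PPINetwork:
    """Parse an edge-list file into a clean undirected :class:`PPINetwork`.

    The file must have >= 2 whitespace- or tab-separated identifier columns;
    extra columns are ignored. Self-loops are dropped (their endpoints are
    retained as isolated nodes only if ``keep_self_loop_nodes``), duplicate
    edges in either orientation collapse, and identifiers are translated
    through ``id_map`` when given (identifiers colliding after mapping merge
    into one node, with a warning). ``header=None`` auto-detects a header
    line by a column-name heuristic.
    """
    g = nx.Graph()
    isolated_candidates: set[str] = set()
    n_self = n_dup = 0
    seen: set[frozenset[str]] = set()
    mapped_from: dict[str, set[str]] = {}

    with open(path) as fh:
        first = True
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            parts = [p.strip() for p in parts]
            if first:
                first = False
                if header is True or (header is None and _looks_like_header(parts)):
                    continue
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise PPIParseError(
                    f"{path}: line {lineno}: expected >=2 identifier columns"
                )
            a, b = parts[0], parts[1]
            if id_map is not None:
                ma, mb = id_map.get(a, a), id_map.get(b, b)
                mapped_from.setdefault(ma, set()).add(a)
                mapped_from.setdefault(mb, set()).add(b)
                a, b = ma, mb
            if a == b:
                n_self += 1
                isolated_candidates.add(a)
                continue
            key = frozenset((a, b))
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            g.add_edge(a, b)

    if keep_self_loop_nodes:
        g.add_nodes_from(isolated_candidates)
    if id_map is not None:
        collisions = {k: v for k, v in mapped_from.items() if len(v) > 1}
        if collisions:
            logger.warning(
                "%d mapped identifiers collide and were merged: %s",
                len(collisions),
                sorted(collisions)[:5],
            )
    if n_self or n_dup:
        logger.info(
            "load_ppi(%s): dropped %d self-loops, %d duplicate edges", path, n_self, n_dup
        )
    return PPINetwork(g)


def write_ppi(net: PPINetwork, path) -> None:
    """Write a canonical two-column TSV: lexicographically smaller id first,
    edges sorted lexicographically. Reloading reproduces the edge set."""
    rows = sorted(tuple(sorted((u, v))) for u, v in net.graph.edges)
    with open(path, "w") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def _suggest(gene: str, pool, k: int = 3) -> list[str]:
    return difflib.get_close_matches(gene, list(pool), n=k, cutoff=0.6)


def level_profile(
    net: PPINetwork,
    source: str,
    max_level: int = 3,
    *,
    exclusive: bool = True,
) -> LevelProfile:
    """Level-k partner sets of ``source`` for k = 1..max_level.

    Default (exclusive) mode assigns each partner to its exact shortest-path
    distance. With ``exclusive=False``, level k holds every gene reachable by
    some simple path of length k (a gene may then appear at several levels);
    this path-exists mode exists only for sensitivity analysis.
    """
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    if source not in net:
        hints = _suggest(source, net.graph.nodes)
        raise UnknownGeneError(
            f"unknown gene {source!r}" + (f"; did you mean {hints}?" if hints else "")
        )
    if exclusive:
        dists = nx.single_source_shortest_path_length(net.graph, source, cutoff=max_level)
        sets: dict[int, set[str]] = {k: set() for k in range(1, max_level + 1)}
        for node, d in dists.items():
            if 1 <= d <= max_level:
                sets[d].add(node)
        return LevelProfile(source, sets, max_level)
    # path-exists mode: BFS frontier expansion without first-visit pruning
    sets = {k: set() for k in range(1, max_level + 1)}
    frontier = {source}
    for k in range(1, max_level + 1):
        nxt: set[str] = set()
        for u in frontier:
            nxt |= set(net.graph.neighbors(u))
        nxt.discard(source)
        sets[k] = nxt
        frontier = nxt
    return LevelProfile(source, sets, max_level)


def all_level_profiles(
    net: PPINetwork,
    sources,
    max_level: int = 3,
    *,
    exclusive: bool = True,
) -> dict[str, LevelProfile]:
    """One :class:`LevelProfile` per source.

    Sources absent from the network yield an empty profile (all level sets
    empty) with a warning rather than an error: a gene outside the
    interactome simply has zero partners at every level.
    """
    out: dict[str, LevelProfile] = {}
    missing = []
    for s in sources:
        if s in net:
            out[s] = level_profile(net, s, max_level, exclusive=exclusive)
        else:
            out[s] = LevelProfile(s, {k: set() for k in range(1, max_level + 1)}, max_level)
            missing.append(s)
    if missing:
        logger.warning(
            "%d of %d sources absent from the PPI network (empty profiles): %s",
            len(missing), len(out), missing[:5],
        )
    return out
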