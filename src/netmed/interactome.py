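"""Undirected protein–protein interaction graphs and distance queries.

The interactome is the backbone of every downstream computation: minimum
shortest-path distances from drug-target proteins to disease modules, and
edge counts between disease gene sets.  Gene identifiers are opaque,
case-sensitive strings; the graph is simple (no self-loops, no parallel
edges) and undirected.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: Sentinel for "no path exists".  Compares larger than every finite hop
#: count and propagates through ``min()`` as the largest element.
UNREACHABLE = float("inf")


class EdgeListParseError(ValueError):
    """Raised when an edge-list line cannot be parsed."""


class NoMappedGenesError(ValueError):
    """Raised when a gene set has no members present in the graph."""


class Interactome:
    """A simple undirected graph over gene identifiers.

    Thin wrapper around :class:`networkx.Graph` that enforces the
    interactome invariants (no self-loops, deduplicated undirected edges)
    and exposes the distance queries the proximity and diseasome analyses
    need.
    """

    def __init__(self, name: str = "interactome") -> None:
        self.graph = nx.Graph()
        self.name = name

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], name: str = "interactome") -> "Interactome":
        g = cls(name=name)
        n_loops = 0
        for u, v in edges:
            if u == v:
                n_loops += 1
                g.graph.add_node(u)
                continue
            g.graph.add_edge(u, v)
        if n_loops:
            logger.warning("%s: dropped %d self-loop edge(s)", name, n_loops)
        return g

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            logger.warning("%s: ignoring self-loop %s-%s", self.name, u, v)
            return
        self.graph.add_edge(u, v)

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def node_list(self) -> list[str]:
        """Nodes in a deterministic (sorted) order, for seeded sampling."""
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def has_node(self, u: str) -> bool:
        return self.graph.has_node(u)

    def degree(self, u: str) -> int:
        return self.graph.degree[u]

    def restrict_genes(self, genes: Iterable[str], label: str = "gene set") -> set[str]:
        """Intersect *genes* with the graph's nodes, logging the dropped count."""
        genes = set(genes)
        kept = genes & set(self.graph.nodes)
        dropped = len(genes) - len(kept)
        if dropped:
            logger.info("%s: %d of %d genes in %s absent from graph, dropped",
                        self.name, dropped, len(genes), label)
        return kept

    def summary(self) -> dict:
        """Graph summary: node/edge counts, components, degree histogram."""
        degrees = [d for _, d in self.graph.degree]
        hist: dict[int, int] = {}
        for d in degrees:
            hist[d] = hist.get(d, 0) + 1
        return {
            "name": self.name,
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "components": nx.number_connected_components(self.graph) if self.n_nodes else 0,
            "degree_histogram": {str(k): v for k, v in sorted(hist.items())},
        }

    # -- persistence -------------------------------------------------------

    def save_edgelist(self, path: str | Path, header: str | None = None) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{u}\t{v}\n")
            # isolated nodes are kept as degenerate single-field comment records
            isolated = sorted(n for n in self.graph.nodes if self.graph.degree[n] == 0)
            for n in isolated:
                fh.write(f"# node\t{n}\n")


def load_interactome(path: str | Path, name: str | None = None) -> Interactome:
    """Load an interactome from a two-column edge-list TSV.

    Lines starting with ``#`` are comments (``# node\\t<id>`` comment
    records re-create isolated nodes written by :meth:`Interactome.save_edgelist`).
    Fields are split on arbitrary whitespace; columns beyond the first two
    are ignored.  Duplicate and reversed-duplicate lines collapse to one
    edge; self-loops are dropped with a warning.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    EdgeListParseError
        If a non-comment line has fewer than two fields (names the line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"interactome edge list not found: {path}")
    g = Interactome(name=name or path.stem)
    n_loops = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "node":
                    g.graph.add_node(parts[1])
                continue
            parts = line.split()
            if len(parts) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected at least 2 fields, got {len(parts)}")
            u, v = parts[0], parts[1]
            if u == v:
                n_loops += 1
                g.graph.add_node(u)
                continue
            g.graph.add_edge(u, v)
    if n_loops:
        logger.warning("%s: dropped %d self-loop line(s)", g.name, n_loops)
    return g


# -- distances -------------------------------------------------------------


def shortest_path_length(g: Interactome, u: str, v: str) -> float:
    """Unweighted hop count between *u* and *v*; ``UNREACHABLE`` if disconnected.

    Symmetric in (u, v); 0 iff ``u == v``.
    """
    for x in (u, v):
        if not g.has_node(x):
            raise KeyError(f"node not in interactome: {x!r}")
    if u == v:
        return 0
    try:
        return nx.shortest_path_length(g.graph, u, v)
    except nx.NetworkXNoPath:
        return UNREACHABLE


def single_source_distances(g: Interactome, source: str) -> dict[str, int]:
    """BFS hop counts from *source* to every reachable node."""
    if not g.has_node(source):
        raise KeyError(f"node not in interactome: {source!r}")
    return dict(nx.single_source_shortest_path_length(g.graph, source))


def distances_to_set(g: Interactome, targets: Iterable[str]) -> dict[str, int]:
    """Multi-source BFS: hop count from each node to the nearest member of *targets*.

    Only nodes that reach the set appear in the result; members of the set
    map to 0.  Targets absent from the graph are dropped (logged).
    """
    retained = g.restrict_genes(targets, "targets")
    if not retained:
        raise NoMappedGenesError("no target genes mapped to the interactome")
    dist: dict[str, int] = {t: 0 for t in retained}
    q = deque(retained)
    adj = g.graph.adj
    while q:
        u = q.popleft()
        du = dist[u]
        for w in adj[u]:
            if w not in dist:
                dist[w] = du + 1
                q.append(w)
    return dist


def min_distance_to_set(g: Interactome, source: str, targets: Iterable[str]) -> float:
    """Minimum hop count from *source* to any member of *targets*.

    0 if *source* is itself a retained target; ``UNREACHABLE`` if no
    retained target can be reached.
    """
    if not g.has_node(source):
        raise KeyError(f"node not in interactome: {source!r}")
    retained = g.restrict_genes(targets, "targets")
    if not retained:
        raise NoMappedGenesError("no target genes mapped to the interactome")
    if source in retained:
        return 0
    best = UNREACHABLE
    dist = nx.single_source_shortest_path_length(g.graph, source)
    for t in retained:
        d = dist.get(t)
        if d is not None and d < best:
            best = d
    return best


# -- degree bins -----------------------------------------------------------


@dataclass
class DegreeBins:
    """Degree-matched sampling pools.

    Nodes are grouped by degree and adjacent degree groups merged (ascending)
    until every bin holds at least ``min_occupancy`` nodes.  Bins partition
    the node set; ``pool(u)`` returns the bin containing *u*.
    """

    boundaries: list[tuple[int, int]]
    members: list[list[str]]
    min_occupancy: int
    _node_to_bin: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._node_to_bin:
            for i, nodes in enumerate(self.members):
                for n in nodes:
                    self._node_to_bin[n] = i

    def bin_index(self, u: str) -> int:
        return self._node_to_bin[u]

    def pool(self, u: str) -> list[str]:
        """Sorted list of nodes sharing u's degree bin (deterministic order)."""
        return self.members[self._node_to_bin[u]]


def build_degree_bins(g: Interactome, min_occupancy: int = 100) -> DegreeBins:
    """Group nodes into degree bins with at least *min_occupancy* members each.

    Degree classes are merged in ascending degree order until the occupancy
    floor is met; a trailing undersized bin is merged into its predecessor.
    Deterministic for a given graph.
    """
    if min_occupancy < 1:
        raise ValueError("min_occupancy must be >= 1")
    if min_occupancy > g.n_nodes:
        logger.warning("min_occupancy %d exceeds node count %d: single bin",
                       min_occupancy, g.n_nodes)
    by_degree: dict[int, list[str]] = {}
    for n in g.node_list():
        by_degree.setdefault(g.degree(n), []).append(n)

    boundaries: list[tuple[int, int]] = []
    members: list[list[str]] = []
    cur_nodes: list[str] = []
    cur_lo: int | None = None
    for d in sorted(by_degree):
        if cur_lo is None:
            cur_lo = d
        cur_nodes.extend(by_degree[d])
        if len(cur_nodes) >= min_occupancy:
            boundaries.append((cur_lo, d))
            members.append(sorted(cur_nodes))
            cur_nodes, cur_lo = [], None
    if cur_nodes:
        if members:
            lo, _ = boundaries.pop()
            hi = max(g.degree(n) for n in cur_nodes)
            merged = sorted(members.pop() + cur_nodes)
            boundaries.append((lo, hi))
            members.append(merged)
        else:
            boundaries.append((cur_lo if cur_lo is not None else 0,
                               max((g.degree(n) for n in cur_nodes), default=0)))
            members.append(sorted(cur_nodes))
    return DegreeBins(boundaries=boundaries, members=members, min_occupancy=min_occupancy)


def write_summary(g: Interactome, path: str | Path) -> None:
    Path(path).write_text(json.dumps(g.summary(), indent=2) + "\n")
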