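"""Seed-expanded protein–protein interaction networks and their intersection.

A background interactome (an undirected simple graph of gene symbols) is
expanded around two seed sets — putative drug targets and disease DEGs —
and the two expanded networks are merged by edge intersection.  Nodes of
the merged network are candidates for topological screening.

Networks are plain :class:`networkx.Graph` objects; all identifiers are
uppercased and whitespace-trimmed before any set operation so that
``"tp53 "`` and ``"TP53"`` are one node.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_id",
    "build_network",
    "expand_seeds",
    "merge_intersection",
    "network_stats",
    "read_sif",
    "write_sif",
    "read_edgelist",
    "write_edgelist",
    "write_graphml",
]


def normalize_id(identifier: str) -> str:
    """Canonical node identifier: stripped and uppercased."""
    return str(identifier).strip().upper()


def build_network(edges: Iterable[tuple[str, str]], provenance: str | None = None) -> nx.Graph:
    """Build a simple undirected graph from an edge iterable.

    Self-loops are dropped; duplicate edges (in either orientation) are
    deduplicated.  An optional ``provenance`` tag is stored on every edge.
    """
    g = nx.Graph()
    for a, b in edges:
        u, v = normalize_id(a), normalize_id(b)
        if u == v:
            continue
        if provenance is not None:
            g.add_edge(u, v, provenance=provenance)
        else:
            g.add_edge(u, v)
    return g


def expand_seeds(
    seeds: Iterable[str],
    background: nx.Graph,
    include_neighbor_edges: bool = True,
) -> nx.Graph:
    """Expand a seed gene set into its neighborhood network.

    The node set is the seeds present in the background plus their first
    neighbors.  With ``include_neighbor_edges=True`` (default) the edge set
    is every background edge among that node set (the induced subgraph);
    with ``False`` only edges incident to a seed are kept.

    Seeds absent from the background are dropped with a warning; an empty
    overlap yields an empty network (warned, not an error).
    """
    seed_set = {normalize_id(s) for s in seeds}
    present = seed_set & set(background.nodes)
    missing = seed_set - present
    if missing:
        logger.warning("%d/%d seeds absent from background interactome", len(missing), len(seed_set))
    if not present:
        logger.warning("no seed overlaps the background: returning empty network")
        return nx.Graph()

    nodes = set(present)
    for s in present:
        nodes.update(background.neighbors(s))
    if include_neighbor_edges:
        sub = background.subgraph(nodes).copy()
    else:
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        sub.add_edges_from(
            (u, v, d) for u, v, d in background.edges(data=True) if u in present or v in present
        )
    logger.info("expanded %d seeds -> %d nodes, %d edges", len(present), sub.number_of_nodes(), sub.number_of_edges())
    return sub


def merge_intersection(a: nx.Graph, b: nx.Graph, on: str = "edges") -> nx.Graph:
    """Merge two networks by intersection.

    ``on="edges"`` (default): the merged edge set is the intersection of the
    two edge sets; nodes are the endpoints of surviving edges.  ``on="nodes"``
    keeps the node intersection with all edges of either network among those
    nodes (sensitivity-analysis variant).
    """
    if on == "edges":
        eset_b = {frozenset(e) for e in b.edges}
        merged = nx.Graph()
        for u, v in a.edges:
            if frozenset((u, v)) in eset_b:
                merged.add_edge(u, v)
        return merged
    if on == "nodes":
        nodes = set(a.nodes) & set(b.nodes)
        merged = nx.Graph()
        merged.add_nodes_from(nodes)
        for g in (a, b):
            merged.add_edges_from((u, v) for u, v in g.edges if u in nodes and v in nodes)
        return merged
    raise ValueError(f"unknown intersection mode {on!r}")


def network_stats(g: nx.Graph) -> dict:
    """Node, edge and component counts plus the median degree.

    The median degree of an empty network is reported as ``None``.
    """
    n = g.number_of_nodes()
    degrees = sorted(d for _, d in g.degree())
    if n == 0:
        median = None
    else:
        mid = n // 2
        median = float(degrees[mid]) if n % 2 else (degrees[mid - 1] + degrees[mid]) / 2.0
    return {
        "nodes": n,
        "edges": g.number_of_edges(),
        "components": nx.number_connected_components(g) if n else 0,
        "median_degree": median,
    }


# ---------------------------------------------------------------------------
# File interchange: SIF, 2-column edge list, GraphML

def read_sif(path: str | Path) -> nx.Graph:
    """Read a SIF file (``nodeA<TAB>interaction<TAB>nodeB`` per line)."""
    edges = []
    isolated = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                edges.append((parts[0], parts[2]))
            elif len(parts) == 1 and parts[0].strip():
                isolated.append(parts[0])
    g = build_network(edges)
    g.add_nodes_from(normalize_id(n) for n in isolated)
    return g


def write_sif(g: nx.Graph, path: str | Path, interaction: str = "pp") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for n in sorted(nx.isolates(g)):
            fh.write(f"{n}\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    """Read a 2-column TSV edge list (header optional, detected)."""
    edges = []
    with open(path) as fh:
        first = True
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            if first and parts[0].lower() in {"source", "node_a", "nodea", "from", "gene1"}:
                first = False
                continue
            first = False
            edges.append((parts[0], parts[1]))
    return build_network(edges)


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u}\t{v}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    """GraphML export for Cytoscape interchange."""
    nx.write_graphml(g, path)
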