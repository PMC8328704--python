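"""Node centralities and the two-stage median-threshold screening cascade.

The merged candidate network is screened in two stages on three
centralities computed from first principles:

* degree centrality (DC) — incident edge count;
* betweenness centrality (BC) — Brandes' accumulation over shortest-path
  dependencies, normalized per connected component;
* closeness centrality (CC) — ``(n_c - 1) / sum of distances`` within the
  node's connected component of size ``n_c``.

Stage 1 keeps nodes whose degree strictly exceeds twice the median degree
of the full network.  Stage 2 recomputes all three centralities on the
stage-1 induced subgraph and keeps nodes strictly exceeding all three of
the stage-1 medians.  Strict ``>`` is used at both stages, and the median
of an even-length sample is the mean of the two central order statistics.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "centrality_table",
    "CascadeResult",
    "cascade_screen",
    "verify_thresholds",
    "read_centrality_table",
    "write_centrality_table",
]


def degree_centrality(g: nx.Graph) -> dict[str, int]:
    """Incident edge count per node (raw degree, not the 1/(n-1) scaling)."""
    return {v: d for v, d in g.degree()}


def _single_source_shortest_paths(g: nx.Graph, s):
    """BFS from ``s``: visit order, predecessor lists, path counts, distances."""
    order = []
    pred: dict = {v: [] for v in g}
    sigma = dict.fromkeys(g, 0.0)
    dist = dict.fromkeys(g, -1)
    sigma[s] = 1.0
    dist[s] = 0
    queue = deque([s])
    while queue:
        v = queue.popleft()
        order.append(v)
        dv = dist[v]
        for w in g[v]:
            if dist[w] < 0:
                dist[w] = dv + 1
                queue.append(w)
            if dist[w] == dv + 1:
                sigma[w] += sigma[v]
                pred[w].append(v)
    return order, pred, sigma, dist


def betweenness_centrality(
    g: nx.Graph,
    normalized: bool = True,
    divisor: str = "pairs",
) -> dict[str, float]:
    """Betweenness centrality by Brandes' dependency accumulation.

    For each node ``v``, BC(v) = sum over ordered pairs ``s != t != v`` of
    ``sigma_st(v) / sigma_st`` where ``sigma_st`` counts shortest s–t paths;
    on an undirected graph each unordered pair is counted once.

    When ``normalized``, values are divided per connected component of size
    ``n_c`` by the number of node pairs excluding ``v``:
    ``(n_c-1)(n_c-2)/2`` for ``divisor="pairs"`` (unordered pairs, the
    networkx convention) or ``(n_c-1)(n_c-2)`` for ``divisor="ordered"``.
    Components with fewer than 3 nodes have BC 0.
    """
    if divisor not in ("pairs", "ordered"):
        raise ValueError(f"divisor must be 'pairs' or 'ordered', got {divisor!r}")
    bc = dict.fromkeys(g, 0.0)
    for s in g:
        order, pred, sigma, _ = _single_source_shortest_paths(g, s)
        delta = dict.fromkeys(order, 0.0)
        while order:
            w = order.pop()
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in pred[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    for v in bc:  # each unordered pair visited from both endpoints
        bc[v] /= 2.0
    if normalized:
        for comp in nx.connected_components(g):
            nc = len(comp)
            scale = (nc - 1) * (nc - 2) / 2.0 if divisor == "pairs" else float((nc - 1) * (nc - 2))
            for v in comp:
                bc[v] = bc[v] / scale if scale > 0 else 0.0
    return bc


def closeness_centrality(g: nx.Graph) -> dict[str, float]:
    """Component-local closeness: ``(n_c - 1) / sum_u d(v, u)``.

    Distances are taken within the node's connected component of size
    ``n_c``; an isolated node has closeness 0 by convention.
    """
    cc = {}
    for v in g:
        _, _, _, dist = _single_source_shortest_paths(g, v)
        reach = [d for d in dist.values() if d > 0]
        cc[v] = len(reach) / sum(reach) if reach else 0.0
    return cc


def centrality_table(g: nx.Graph, divisor: str = "pairs") -> pd.DataFrame:
    """DC/BC/CC for every node as a DataFrame (columns gene, degree, betweenness, closeness)."""
    dc = degree_centrality(g)
    bc = betweenness_centrality(g, normalized=True, divisor=divisor)
    cc = closeness_centrality(g)
    df = pd.DataFrame(
        {
            "gene": list(g.nodes),
            "degree": [dc[v] for v in g.nodes],
            "betweenness": [bc[v] for v in g.nodes],
            "closeness": [cc[v] for v in g.nodes],
        }
    )
    return df.sort_values("degree", ascending=False, kind="mergesort").reset_index(drop=True)


def _median(values) -> float:
    """Mean of the two central order statistics when the length is even."""
    return float(np.median(np.asarray(list(values), dtype=float)))


@dataclass
class CascadeResult:
    """Outcome of the two-stage centrality screening cascade."""

    stage1_threshold: float
    stage2_thresholds: dict = field(default_factory=dict)  # keys: degree, betweenness, closeness
    stage1_network: nx.Graph = field(default_factory=nx.Graph)
    stage2_network: nx.Graph = field(default_factory=nx.Graph)
    survivor_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    status: str = "ok"

    @property
    def survivors(self) -> list[str]:
        return list(self.stage2_network.nodes)


def cascade_screen(merged: nx.Graph, recompute: bool = True, divisor: str = "pairs") -> CascadeResult:
    """Run the two-stage median screening cascade on the merged network.

    Stage 1: keep nodes with ``DC > 2 * median(DC)`` over the full merged
    network.  Stage 2: on the stage-1 induced subgraph, keep nodes strictly
    exceeding the medians of DC, BC and CC.  With ``recompute=False`` the
    stage-2 comparison reuses the merged-network centrality values instead
    of recomputing them on the subgraph.

    A degenerate stage (no survivor, e.g. a regular graph where no degree
    exceeds twice the median) returns an empty result with an explanatory
    ``status`` rather than raising.
    """
    if merged.number_of_nodes() == 0:
        raise ValueError("cascade_screen requires a nonempty network")

    dc0 = degree_centrality(merged)
    thr1 = 2.0 * _median(dc0.values())
    stage1_nodes = [v for v, d in dc0.items() if d > thr1]
    logger.info("cascade stage 1: DC > %.6g keeps %d/%d nodes", thr1, len(stage1_nodes), merged.number_of_nodes())
    if not stage1_nodes:
        return CascadeResult(stage1_threshold=thr1, status="stage1-empty: no degree exceeds twice the median")

    stage1 = merged.subgraph(stage1_nodes).copy()

    if recompute:
        df = centrality_table(stage1, divisor=divisor)
    else:
        bc0 = betweenness_centrality(merged, divisor=divisor)
        cc0 = closeness_centrality(merged)
        df = pd.DataFrame(
            {
                "gene": stage1_nodes,
                "degree": [dc0[v] for v in stage1_nodes],
                "betweenness": [bc0[v] for v in stage1_nodes],
                "closeness": [cc0[v] for v in stage1_nodes],
            }
        )
    thr2 = {
        "degree": _median(df["degree"]),
        "betweenness": _median(df["betweenness"]),
        "closeness": _median(df["closeness"]),
    }
    mask = (
        (df["degree"] > thr2["degree"])
        & (df["betweenness"] > thr2["betweenness"])
        & (df["closeness"] > thr2["closeness"])
    )
    survivors = df.loc[mask].reset_index(drop=True)
    logger.info(
        "cascade stage 2: DC > %.6g, BC > %.6g, CC > %.6g keeps %d/%d nodes",
        thr2["degree"], thr2["betweenness"], thr2["closeness"], len(survivors), len(df),
    )
    stage2 = stage1.subgraph(survivors["gene"]).copy()
    status = "ok" if len(survivors) else "stage2-empty: no node exceeds all three medians"
    return CascadeResult(
        stage1_threshold=thr1,
        stage2_thresholds=thr2,
        stage1_network=stage1,
        stage2_network=stage2,
        survivor_table=survivors.sort_values("degree", ascending=False, kind="mergesort").reset_index(drop=True),
        status=status,
    )


def verify_thresholds(table: pd.DataFrame, dc: float, bc: float, cc: float) -> int:
    """Count table rows strictly exceeding all three centrality thresholds."""
    required = {"degree", "betweenness", "closeness"}
    if len(table) and not required.issubset(table.columns):
        raise ValueError(f"centrality table must have columns {sorted(required)}")
    if not len(table):
        return 0
    mask = (table["degree"] > dc) & (table["betweenness"] > bc) & (table["closeness"] > cc)
    return int(mask.sum())


def read_centrality_table(path: str | Path) -> pd.DataFrame:
    """Read a centrality TSV with at least columns gene, betweenness, closeness, degree."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "betweenness", "closeness", "degree"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_centrality_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
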