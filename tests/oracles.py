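"""Independent reference implementations used only by the tests.

These deliberately avoid the algorithms used in the package:

* betweenness via Floyd–Warshall distances and adjacency-matrix-power
  shortest-path counts (no Brandes accumulation);
* the hypergeometric upper tail by exact rational enumeration of all
  more-extreme overlap tables.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np


def betweenness_oracle(g: nx.Graph, normalized: bool = True) -> dict:
    """Betweenness by path counting: sigma_st = (A^d(s,t))[s,t].

    Walks shorter than the shortest path do not exist, so the number of
    walks of length d(s,t) equals the number of shortest paths, and
    sigma_st(v) = sigma_sv * sigma_vt whenever d(s,v) + d(v,t) = d(s,t).
    """
    nodes = list(g)
    n = len(nodes)
    if n == 0:
        return {}
    a = nx.to_numpy_array(g, nodelist=nodes)
    dist = np.full((n, n), np.inf)
    dist[a > 0] = 1.0
    np.fill_diagonal(dist, 0.0)
    for k in range(n):  # Floyd-Warshall
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])

    finite = np.isfinite(dist)
    maxd = int(dist[finite].max()) if finite.any() else 0
    power = np.eye(n)
    sigma = np.zeros((n, n))
    for d in range(maxd + 1):
        mask = finite & (dist == d)
        sigma[mask] = power[mask]
        power = power @ a

    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not finite[s, t]:
                continue
            on_path = finite[s, :] & finite[:, t] & (dist[s, :] + dist[:, t] == dist[s, t])
            on_path[s] = on_path[t] = False
            bc[on_path] += sigma[s, on_path] * sigma[on_path, t] / sigma[s, t]

    result = dict(zip(nodes, bc))
    if normalized:
        for comp in nx.connected_components(g):
            nc = len(comp)
            scale = (nc - 1) * (nc - 2) / 2.0
            for v in comp:
                result[v] = result[v] / scale if scale > 0 else 0.0
    return result


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n) by enumeration."""
    denom = comb(N, n)
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1) if n - j <= N - K)
    return Fraction(num, denom)
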