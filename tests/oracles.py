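"""Independent brute-force oracles used to cross-check the implementation.

Everything here enumerates simple paths explicitly and counts geodesics
with exact :class:`fractions.Fraction` arithmetic; nothing is shared with
the production code paths (which go through Brandes/Dijkstra).  Test graphs
use weights whose inverse lengths are exact binary floats, so tie detection
in the float implementation is also exact.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

#: weights whose inverses (1/w = 4, 2, 1) are exact binary floats
DYADIC_WEIGHTS = (0.25, 0.5, 1.0)


def _all_simple_paths(adj: dict[int, list[int]], s: int, t: int) -> list[list[int]]:
    paths: list[list[int]] = []
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nb in adj[node]:
            if nb not in path:
                stack.append((nb, path + [nb]))
    return paths


def brute_force_betweenness(
    weights: np.ndarray,
) -> tuple[np.ndarray, dict[tuple[int, int], Fraction]]:
    """Exact node and edge betweenness by geodesic enumeration.

    Lengths are 1/w as exact Fractions.  Node betweenness excludes pairs
    where the node is an endpoint; edge betweenness includes the edge's
    own endpoint pair.  Tied geodesics contribute fractionally.
    """
    n = weights.shape[0]
    adj = {i: [j for j in range(n) if weights[i, j] > 0] for i in range(n)}
    lengths = {
        (i, j): Fraction(1) / Fraction(weights[i, j])
        for i in range(n)
        for j in range(n)
        if weights[i, j] > 0
    }
    node_bc = [Fraction(0)] * n
    edge_bc: dict[tuple[int, int], Fraction] = {
        (i, j): Fraction(0) for i in range(n) for j in range(i + 1, n) if weights[i, j] > 0
    }
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_simple_paths(adj, s, t)
            if not paths:
                continue
            plens = [
                sum(lengths[(a, b)] for a, b in zip(p[:-1], p[1:]))
                for p in paths
            ]
            dmin = min(plens)
            geos = [p for p, pl in zip(paths, plens) if pl == dmin]
            rho = len(geos)
            for g in geos:
                for node in g[1:-1]:
                    node_bc[node] += Fraction(1, rho)
                for a, b in zip(g[:-1], g[1:]):
                    edge_bc[(min(a, b), max(a, b))] += Fraction(1, rho)
    return np.array([float(x) for x in node_bc]), edge_bc


def random_dyadic_graph(rng: np.random.Generator, n: int, p: float = 0.5) -> np.ndarray:
    """Random connected weighted graph with dyadic weights, or None."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                val = float(rng.choice(DYADIC_WEIGHTS))
                w[i, j] = w[j, i] = val
    # connectivity check by BFS
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in range(n):
            if w[i, j] > 0 and j not in seen:
                seen.add(j)
                frontier.append(j)
    return w if len(seen) == n else None
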