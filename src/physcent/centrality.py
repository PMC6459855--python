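"""Centrality measures, hub/bridge detection, and cumulative-share curves.

The Physarum centrality of an edge is its *criticality*: the sum over all
source–sink pairs of the converged absolute flux it carries,

    c_ij = sum_k |Q^k_ij|,   k = 1 .. n(n-1)/2,

and the Physarum node centrality is the sum of the criticalities of the
edges attached to the node.  Degree centrality counts edges at a node
(binarized weights); betweenness counts the fraction of all-pairs shortest
paths through a node (endpoints excluded) or edge (endpoint pairs
included), with tied geodesics split fractionally.  Betweenness uses the
same inverse-weight lengths as the Physarum solver so the shortest-path
assumption is the only thing that differs between the measures.

Hubs (nodes) and bridges (edges) are map entries exceeding the map mean by
more than one sample standard deviation; the threshold is invariant under
positive affine transforms, so detection commutes with Z-transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .netio import ConnectivityMatrix
from .physarum import AllPairsFlux, build_lengths

NODE_MEASURES = ("C_D_node", "C_B_node", "C_P_node")
EDGE_MEASURES = ("C_B_edge", "C_P_edge", "criticality")


@dataclass(frozen=True)
class CentralityMap:
    """One node-level centrality map."""

    measure: str
    values: np.ndarray
    labels: tuple[str, ...]
    z: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.labels),):
            raise ValueError("one value per node required")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class EdgeCentralityMap:
    """One edge-level centrality map, defined on existing edges only."""

    measure: str
    u: np.ndarray
    v: np.ndarray
    values: np.ndarray
    labels: tuple[str, ...]
    z: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if not (len(self.u) == len(self.v) == len(vals)):
            raise ValueError("u, v, values must align")
        object.__setattr__(self, "values", vals)

    @property
    def n_edges(self) -> int:
        return len(self.values)

    def edge_labels(self) -> list[tuple[str, str]]:
        return [(self.labels[i], self.labels[j]) for i, j in zip(self.u, self.v)]


@dataclass(frozen=True)
class HubSet:
    """Nodes whose centrality exceeds mean + 1 SD of the map."""

    members: frozenset[str]
    threshold: float
    measure: str


@dataclass(frozen=True)
class BridgeSet:
    """Edges whose centrality exceeds mean + 1 SD of the map."""

    members: frozenset[tuple[str, str]]
    threshold: float
    measure: str


# ---------------------------------------------------------------------------
# Physarum centralities
# ---------------------------------------------------------------------------


def edge_criticality(flux_maps: AllPairsFlux) -> EdgeCentralityMap:
    """Criticality c_ij: per-edge sum of converged flux over all pairs."""
    n = len(flux_maps.labels)
    expected = n * (n - 1) // 2
    if flux_maps.n_pairs != expected:
        raise ValueError(
            f"criticality needs all {expected} pair maps, got {flux_maps.n_pairs}"
        )
    return EdgeCentralityMap(
        measure="criticality",
        u=flux_maps.u,
        v=flux_maps.v,
        values=flux_maps.flux_abs.sum(axis=0),
        labels=flux_maps.labels,
    )


def physarum_node_centrality(crit: EdgeCentralityMap) -> CentralityMap:
    """C_P,node(i): sum of the criticalities of edges attached to node i."""
    values = np.zeros(len(crit.labels))
    np.add.at(values, crit.u, crit.values)
    np.add.at(values, crit.v, crit.values)
    return CentralityMap(measure="C_P_node", values=values, labels=crit.labels)


def physarum_edge_centrality(crit: EdgeCentralityMap) -> EdgeCentralityMap:
    """C_P,edge is the criticality itself, retagged."""
    return replace(crit, measure="C_P_edge")


# ---------------------------------------------------------------------------
# comparison measures
# ---------------------------------------------------------------------------


def degree_centrality(m: ConnectivityMatrix, weighted: bool = False) -> CentralityMap:
    """C_D,node(i): number of edges at i (column sum of the binarized matrix).

    ``weighted=True`` returns node strength (sum of weights) instead; that
    variant is not the degree centrality used for hub comparison.
    """
    w = m.weights if weighted else (m.weights > 0).astype(float)
    return CentralityMap(measure="C_D_node", values=w.sum(axis=0), labels=m.labels)


def _length_graph(m: ConnectivityMatrix, length_mapping: str) -> nx.Graph:
    u, v = m.edge_index
    lengths = build_lengths(m, length_mapping)
    G = nx.Graph()
    G.add_nodes_from(range(m.n))
    G.add_weighted_edges_from(zip(u, v, lengths), weight="length")
    return G


def betweenness_node(
    m: ConnectivityMatrix, length_mapping: str = "inverse"
) -> CentralityMap:
    """C_B,node(i) = sum over pairs j != i != k of rho_jk(i) / rho_jk.

    All tied shortest paths count fractionally; pairs with i as an endpoint
    are excluded.  Distances are the same lengths the Physarum solver uses.
    """
    G = _length_graph(m, length_mapping)
    bc = nx.betweenness_centrality(G, normalized=False, weight="length")
    return CentralityMap(
        measure="C_B_node",
        values=np.array([bc[i] for i in range(m.n)]),
        labels=m.labels,
    )


def betweenness_edge(
    m: ConnectivityMatrix, length_mapping: str = "inverse"
) -> EdgeCentralityMap:
    """Fraction-weighted count of shortest paths traversing each edge.

    The edge's own endpoint pair is included (a direct edge lying on a
    geodesic of its endpoints counts toward it).
    """
    G = _length_graph(m, length_mapping)
    ebc = nx.edge_betweenness_centrality(G, normalized=False, weight="length")
    u, v = m.edge_index
    values = np.array([ebc.get((i, j), ebc.get((j, i), 0.0)) for i, j in zip(u, v)])
    return EdgeCentralityMap(
        measure="C_B_edge", u=u, v=v, values=values, labels=m.labels
    )


# ---------------------------------------------------------------------------
# normalization, hubs, bridges, cumulative share
# ---------------------------------------------------------------------------


def _zscores(values: np.ndarray, what: str) -> np.ndarray:
    if values.size < 2 or np.ptp(values) == 0:
        raise ValueError(f"zero variance: cannot Z-transform {what}")
    sd = values.std(ddof=1)
    return (values - values.mean()) / sd


def z_transform(map_):
    """Z-transform a node or edge map: mean 0, sample SD 1 (ddof=1)."""
    if isinstance(map_, CentralityMap):
        return replace(map_, values=_zscores(map_.values, "node map"), z=True)
    if isinstance(map_, EdgeCentralityMap):
        return replace(map_, values=_zscores(map_.values, "edge map"), z=True)
    raise TypeError(f"cannot Z-transform {type(map_).__name__}")


def _threshold(values: np.ndarray, what: str) -> float:
    if values.size < 2 or np.ptp(values) == 0:
        raise ValueError(f"constant {what}: hub/bridge threshold undefined")
    return float(values.mean() + values.std(ddof=1))


def detect_hubs(map_: CentralityMap) -> HubSet:
    """Nodes strictly above mean + 1 sample SD of the map."""
    thr = _threshold(map_.values, "node map")
    members = frozenset(
        lab for lab, val in zip(map_.labels, map_.values) if val > thr
    )
    return HubSet(members=members, threshold=thr, measure=map_.measure)


def detect_bridges(edge_map: EdgeCentralityMap) -> BridgeSet:
    """Edges strictly above mean + 1 sample SD of the map (existing edges only)."""
    thr = _threshold(edge_map.values, "edge map")
    members = frozenset(
        (a, b) if a <= b else (b, a)
        for (a, b), val in zip(edge_map.edge_labels(), edge_map.values)
        if val > thr
    )
    return BridgeSet(members=members, threshold=thr, measure=edge_map.measure)


def cumulative_share(
    map_: CentralityMap, order_by: CentralityMap, q: float
) -> float:
    """Share of ``map_``'s total mass held by the top ``q`` fraction of nodes.

    Nodes are sorted descending by ``order_by`` (highest value first, ties
    broken by node order for determinism); the top ceil(q*n) nodes'
    ``map_`` values are summed and divided by the map total.
    """
    if map_.labels != order_by.labels:
        raise ValueError("maps must share the same nodes")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if np.any(map_.values < 0):
        raise ValueError("cumulative share requires nonnegative map values")
    total = map_.values.sum()
    if total == 0:
        raise ValueError("map total is zero")
    order = np.lexsort((np.arange(map_.n), -order_by.values))
    k = int(np.ceil(q * map_.n))
    return float(map_.values[order[:k]].sum() / total)
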