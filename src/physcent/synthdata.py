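"""Seeded generators for toy graphs and synthetic connectome cohorts.

Real structural connectomes here are emulated, not downloaded: the
generator produces symmetric, connected, FA-weighted matrices with the
gross features the analysis cares about — sparse modular topology, a small
set of deliberately high-degree hub nodes, mirrored left/right hemispheric
structure, and weights in (0, 1) drawn from a Beta distribution shaped like
tract-averaged fractional anisotropy.  A cohort is one base network plus
per-subject multiplicative log-normal weight noise and a small fraction of
degree-preserving edge rewires.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a
seed pins every fixture bit-for-bit across platforms and releases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .netio import ConnectivityMatrix, connected_components

#: multiplicative preference for intra-module candidate edges
_MODULE_BOOST = 4.0
#: multiplicative preference per designated-hub endpoint
_HUB_BOOST = 8.0
#: multiplicative preference for homotopic (mirror-pair) edges
_HOMOTOPIC_BOOST = 2.0
#: mixing fraction for mirrored-weight correlation
_MIRROR_MIX = 0.5


@dataclass(frozen=True)
class ConnectomeSpec:
    """Parameters of the synthetic connectome generator.

    Defaults emulate the shape of AAL-parcellated cortical networks:
    78 nodes, ~15% edge density, four modules mirrored across hemispheres,
    ~10% designated hubs, and Beta(4, 3) FA-like weights (mean ≈ 0.57).
    """

    n: int = 78
    density: float = 0.15
    n_modules: int = 4
    hemispheric: bool = True
    hub_fraction: float = 0.1
    weight_alpha: float = 4.0
    weight_beta: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.n < 2:
            raise ValueError("need at least 2 nodes")
        if self.hemispheric and self.n % 2:
            raise ValueError("hemispheric networks need an even node count")
        if self.n_modules < 1 or self.n_modules > self.n:
            raise ValueError("invalid module count")
        if not 0 <= self.hub_fraction < 1:
            raise ValueError("hub_fraction must be in [0, 1)")
        if min(self.weight_alpha, self.weight_beta) <= 0:
            raise ValueError("weight distribution parameters must be > 0")


FIXTURE_NAMES = ("path3", "path4", "star4", "cycle4", "tworoute", "random_tree", "k4")


def fixture(name: str) -> ConnectivityMatrix:
    """Deterministic canonical toy networks used throughout the tests.

    ``tworoute`` is the triangle with weights (1, 1, 1/3): under inverse
    lengths the two-hop route s-a-t costs 2 while the direct s-t edge costs
    3, so the adaptive flow must abandon the direct edge.
    """
    if name == "path3":
        w = _from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])
    elif name == "path4":
        w = _from_edges(4, [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])
    elif name == "star4":
        w = _from_edges(4, [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)])
    elif name == "cycle4":
        w = _from_edges(4, [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 0, 1.0)])
    elif name == "tworoute":
        w = _from_edges(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0 / 3.0)])
    elif name == "random_tree":
        rng = np.random.default_rng(20190411)
        nn = 10
        edges = [
            (int(rng.integers(0, i)), i, float(rng.uniform(0.2, 0.9)))
            for i in range(1, nn)
        ]
        w = _from_edges(nn, edges)
    elif name == "k4":
        w = np.ones((4, 4)) - np.eye(4)
    else:
        raise ValueError(f"unknown fixture {name!r} (choose from {FIXTURE_NAMES})")
    return ConnectivityMatrix(w)


def _from_edges(n: int, edges) -> np.ndarray:
    w = np.zeros((n, n))
    for i, j, val in edges:
        w[i, j] = w[j, i] = val
    return w


# ---------------------------------------------------------------------------
# connectome generator
# ---------------------------------------------------------------------------


def _module_assignment(spec: ConnectomeSpec) -> np.ndarray:
    if spec.hemispheric:
        half = spec.n // 2
        left = np.array_split(np.arange(half), spec.n_modules)
        mod = np.empty(spec.n, dtype=int)
        for mi, nodes in enumerate(left):
            mod[nodes] = mi
            mod[nodes + half] = mi  # mirrored module membership
        return mod
    return np.sort(np.arange(spec.n) % spec.n_modules)


def _hub_nodes(spec: ConnectomeSpec, rng: np.random.Generator) -> np.ndarray:
    k = int(round(spec.hub_fraction * spec.n))
    if k == 0:
        return np.array([], dtype=int)
    if spec.hemispheric:
        half = spec.n // 2
        n_pairs = max(1, k // 2)
        lefts = rng.choice(half, size=n_pairs, replace=False)
        hubs = np.concatenate([lefts, lefts + half])
        if k % 2 and len(hubs) < spec.n:
            extra = rng.choice(np.setdiff1d(np.arange(spec.n), hubs))
            hubs = np.append(hubs, extra)
        return np.sort(hubs[:max(k, 2 * n_pairs)])
    return np.sort(rng.choice(spec.n, size=k, replace=False))


def generate_connectome(spec: ConnectomeSpec) -> ConnectivityMatrix:
    """Generate one synthetic FA-weighted connectome.

    The edge count is exactly ``ceil(density * n(n-1)/2)``: a random
    spanning tree guarantees connectivity, and the remaining edges are
    sampled without replacement with preference for intra-module,
    hub-incident, and homotopic candidate pairs.  Weights are Beta
    distributed; when both an edge and its hemispheric mirror exist, the
    mirror's weight is a 50/50 mix of the original and a fresh draw, giving
    correlated bilateral weights.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    m_target = math.ceil(spec.density * n * (n - 1) / 2)
    if m_target < n - 1:
        raise ValueError(
            f"density {spec.density} gives {m_target} edges; "
            f"{n - 1} needed to connect {n} nodes"
        )
    modules = _module_assignment(spec)
    hubs = _hub_nodes(spec, rng)
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hubs] = True
    half = n // 2

    def score(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        s = np.ones(np.broadcast(i, j).shape)
        s *= np.where(modules[i] == modules[j], _MODULE_BOOST, 1.0)
        s *= np.where(is_hub[i], _HUB_BOOST, 1.0)
        s *= np.where(is_hub[j], _HUB_BOOST, 1.0)
        if spec.hemispheric:
            s *= np.where(np.abs(i - j) == half, _HOMOTOPIC_BOOST, 1.0)
        return s

    # spanning tree: attach each node to a score-weighted earlier node
    order = rng.permutation(n)
    w = np.zeros((n, n))
    chosen = np.zeros((n, n), dtype=bool)
    for pos in range(1, n):
        node = order[pos]
        anchors = order[:pos]
        p = score(np.full(pos, node), anchors)
        anchor = int(rng.choice(anchors, p=p / p.sum()))
        chosen[node, anchor] = chosen[anchor, node] = True

    iu, iv = np.triu_indices(n, k=1)
    free = ~chosen[iu, iv]
    n_extra = m_target - (n - 1)
    if n_extra > 0:
        cand_u, cand_v = iu[free], iv[free]
        p = score(cand_u, cand_v)
        pick = rng.choice(len(cand_u), size=n_extra, replace=False, p=p / p.sum())
        chosen[cand_u[pick], cand_v[pick]] = True
        chosen[cand_v[pick], cand_u[pick]] = True

    eu, ev = np.nonzero(np.triu(chosen, k=1))
    weights = rng.beta(spec.weight_alpha, spec.weight_beta, size=eu.size)
    w[eu, ev] = weights
    w[ev, eu] = weights
    if spec.hemispheric:
        _correlate_mirrors(w, half, rng, spec)

    labels = _hemispheric_labels(n) if spec.hemispheric else tuple(
        f"N{i + 1:02d}" for i in range(n)
    )
    return ConnectivityMatrix(w, labels)


def _hemispheric_labels(n: int) -> tuple[str, ...]:
    half = n // 2
    return tuple(f"N{i + 1:02d}.L" for i in range(half)) + tuple(
        f"N{i + 1:02d}.R" for i in range(half)
    )


def _correlate_mirrors(
    w: np.ndarray, half: int, rng: np.random.Generator, spec: ConnectomeSpec
) -> None:
    """Mix mirrored edge weights so bilateral connections are correlated."""
    for i in range(half):
        for j in range(i + 1, half):
            mi, mj = i + half, j + half
            if w[i, j] > 0 and w[mi, mj] > 0:
                fresh = rng.beta(spec.weight_alpha, spec.weight_beta)
                mixed = _MIRROR_MIX * w[i, j] + (1 - _MIRROR_MIX) * fresh
                w[mi, mj] = w[mj, mi] = mixed


def designated_hubs(spec: ConnectomeSpec) -> tuple[str, ...]:
    """Labels of the hub nodes a given spec designates (same seed stream)."""
    rng = np.random.default_rng(spec.seed)
    hubs = _hub_nodes(spec, rng)
    labels = _hemispheric_labels(spec.n) if spec.hemispheric else tuple(
        f"N{i + 1:02d}" for i in range(spec.n)
    )
    return tuple(labels[i] for i in hubs)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


def generate_cohort(
    base: ConnectivityMatrix,
    n_subjects: int = 20,
    weight_noise_sd: float = 0.1,
    topology_rewire_p: float = 0.05,
    seed: int = 0,
    max_retries: int = 50,
) -> list[ConnectivityMatrix]:
    """Per-subject variants of a base connectome.

    Each subject applies (a) multiplicative log-normal noise
    ``w -> w * exp(N(0, weight_noise_sd))`` to every edge weight, clipped to
    (0, 1], so the per-edge coefficient of variation across subjects is
    ≈ ``weight_noise_sd`` for small values, and (b) degree-preserving double
    edge swaps touching about ``topology_rewire_p`` of the edges, redrawn in
    full if a swap set disconnects the network.
    """
    if weight_noise_sd < 0 or topology_rewire_p < 0:
        raise ValueError("noise parameters must be >= 0")
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        _one_subject(base, weight_noise_sd, topology_rewire_p, s, max_retries)
        for s in streams
    ]


def _one_subject(
    base: ConnectivityMatrix,
    noise_sd: float,
    rewire_p: float,
    stream: np.random.SeedSequence,
    max_retries: int,
) -> ConnectivityMatrix:
    rng = np.random.default_rng(stream)
    n_swaps = int(round(rewire_p * base.n_edges / 2))  # each swap touches 2 edges
    for _ in range(max_retries):
        w = _rewired(base.weights, n_swaps, rng)
        if noise_sd > 0:
            iu, iv = np.nonzero(np.triu(w, k=1))
            factors = np.exp(rng.normal(0.0, noise_sd, size=iu.size))
            vals = np.minimum(w[iu, iv] * factors, 1.0)
            w = np.zeros_like(w)
            w[iu, iv] = vals
            w[iv, iu] = vals
        m = ConnectivityMatrix(w, base.labels)
        if len(connected_components(m)) == 1:
            return m
    raise RuntimeError(
        f"could not generate a connected subject after {max_retries} retries"
    )


def _rewired(weights: np.ndarray, n_swaps: int, rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving double edge swaps, weights carried with the stubs."""
    w = weights.copy()
    done = 0
    attempts = 0
    while done < n_swaps and attempts < 100 * max(n_swaps, 1):
        attempts += 1
        iu, iv = np.nonzero(np.triu(w, k=1))
        e1, e2 = rng.choice(iu.size, size=2, replace=False)
        a, b = int(iu[e1]), int(iv[e1])
        c, d = int(iu[e2]), int(iv[e2])
        if len({a, b, c, d}) < 4:
            continue
        if w[a, d] > 0 or w[c, b] > 0:
            continue
        wa, wc = w[a, b], w[c, d]
        w[a, b] = w[b, a] = 0.0
        w[c, d] = w[d, c] = 0.0
        w[a, d] = w[d, a] = wa
        w[c, b] = w[b, c] = wc
        done += 1
    return w
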