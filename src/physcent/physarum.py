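"""Adaptive Physarum flow solver.

The model treats each edge of a weighted network as a tube of length
``L_ij`` and conductivity ``D_ij`` carrying Hagen–Poiseuille flow.  For one
source–sink pair ``(s, t)`` a unit of flux ``I0`` is pushed through the
network; pressures follow Kirchhoff's law

    sum_i (D_ij / L_ij) (p_i - p_j) = -I0 (j = s), +I0 (j = t), 0 otherwise,

edge fluxes are ``Q_ij = (D_ij / L_ij)(p_i - p_j)``, and conductivities
adapt by the positive-feedback ODE ``dD/dt = f(|Q|) - gamma * D``.  Tubes
carrying flux widen, unused tubes decay and are eventually removed.  With
linear feedback ``f(x) = x`` and ``gamma = 1`` the surviving tube network
converges to the shortest s–t path under the lengths ``L`` (or splits flux
evenly over exactly tied routes); with the default sublinear saturating
feedback the equilibrium spreads flux over all competitive routes, which is
what makes the resulting centrality measure distinct from betweenness.

The ODE is discretized with a semi-implicit Euler step,

    D' = (D + dt * f(|Q|)) / (1 + dt * gamma),

which preserves positivity for any ``dt``; with linear ``f`` and
``dt = gamma = 1`` it is the classic averaging update ``D' = (D + |Q|)/2``.

Two execution paths produce identical dynamics: :func:`run_pair` is a plain
readable loop over the single-pair operations (and supports a per-iteration
callback for diagnostics), while :func:`all_pairs_flux` evolves many
source–sink pairs at once with batched dense linear solves — the pressure
systems of all unconverged pairs are solved in a single LAPACK call per
iteration, which is what makes all-pairs centrality on ~80-node networks
practical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .netio import ConnectivityMatrix, connected_components

logger = logging.getLogger(__name__)


class FlowImpossibleError(ValueError):
    """Source and sink are not connected in the (alive) network."""


@dataclass(frozen=True)
class PhysarumParams:
    """Solver parameters.

    Attributes
    ----------
    i0:
        Total flux injected at the source and removed at the sink.
    gamma:
        Tube decay rate in ``dD/dt = f(|Q|) - gamma * D``.
    f_kind:
        Feedback function: ``"saturating"`` (``f(x) = x**mu / (1 + x**mu)``,
        the default) or ``"linear"`` (``f(x) = x``).  With linear feedback
        the converged network provably carries all flux on the single
        shortest s-t path, which collapses the resulting node centrality
        onto an affine image of betweenness; the sublinear saturating form
        keeps an equilibrium in which every route retains flux in
        proportion to its quality, so the measure blends local (degree-like)
        and global (betweenness-like) structure.
    mu:
        Exponent of the saturating feedback.  ``mu < 1`` (default 0.8) is
        the multi-path regime; ``mu > 1`` behaves winner-take-all like the
        linear form.
    dt:
        Semi-implicit Euler step.
    d0:
        Initial conductivity of every existing edge (deterministic start).
    tol:
        Convergence threshold on the max conductivity change per step.  When
        iteration stops, edges still on a geometric decay to zero (feedback
        far below their decay term) necessarily have conductivity of order
        ``tol``; they are settled — pruned, with one final pressure solve —
        so the reported state contains no half-dead tubes.
    max_iter:
        Iteration cap; hitting it is reported as non-convergence, not raised.
    flux_eps:
        Conductivity level below which a tube is removed (permanently zero).
    """

    i0: float = 1.0
    gamma: float = 1.0
    f_kind: str = "saturating"
    mu: float = 0.8
    dt: float = 1.0
    d0: float = 1.0
    tol: float = 1e-6
    max_iter: int = 10_000
    flux_eps: float = 1e-8
    #: iterations integrated at the base step before the ramp starts
    dt_ramp_after: int = 50
    #: geometric growth of the step per iteration during the ramp
    dt_growth: float = 1.1
    #: cap on the step, as a multiple of the base step
    dt_max_factor: float = 1000.0
    #: iterations without meaningful progress before a pair is declared
    #: stalled (quasi-tied routes creep indefinitely; reported unconverged)
    stall_window: int = 300

    def __post_init__(self) -> None:
        for name in ("i0", "gamma", "dt", "d0", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.flux_eps < 0:
            raise ValueError("flux_eps must be >= 0")
        if self.f_kind not in ("linear", "saturating"):
            raise ValueError(f"unknown f_kind {self.f_kind!r}")
        if self.f_kind == "saturating" and self.mu <= 0:
            raise ValueError("mu must be > 0")

    def feedback(self, q_abs: np.ndarray) -> np.ndarray:
        """The increasing feedback f with f(0) = 0, applied to |Q|."""
        if self.f_kind == "linear":
            return q_abs
        qmu = q_abs**self.mu
        return qmu / (1.0 + qmu)

    def step_at(self, iteration: int) -> float:
        """Integration step used at a given iteration.

        The fixed points of the dynamics do not depend on the step, and the
        semi-implicit update is positivity-preserving for any step, so once
        the transient has been integrated accurately at the base ``dt`` the
        step is grown geometrically to traverse the slow terminal
        contraction (near-tied routes creep toward resolution at a rate set
        by their tiny length gap) in wall-clock-bounded time.
        """
        if iteration < self.dt_ramp_after or self.dt_growth <= 1.0:
            return self.dt
        import math

        k = iteration - self.dt_ramp_after
        if k * math.log(self.dt_growth) >= math.log(self.dt_max_factor):
            return self.dt * self.dt_max_factor
        return self.dt * self.dt_growth**k


def build_lengths(m: ConnectivityMatrix, mapping: str = "inverse") -> np.ndarray:
    """Tube lengths per existing edge (aligned with ``m.edge_index``).

    ``inverse`` sets ``L = 1/w`` so stronger connections are shorter —
    the same distance semantics used for weighted betweenness; ``unit``
    sets ``L = 1`` (topology only).
    """
    w = m.edge_weights
    if mapping == "inverse":
        if np.any(w <= 0):
            raise ValueError("inverse length mapping needs strictly positive weights")
        return 1.0 / w
    if mapping == "unit":
        return np.ones_like(w)
    raise ValueError(f"unknown length mapping {mapping!r}")


@dataclass
class PhysarumState:
    """Mutable per-pair solver state.

    Edge arrays are aligned: edge ``e`` runs between nodes ``u[e]`` and
    ``v[e]`` with length ``lengths[e]`` and conductivity ``D[e]``.  Pruned
    edges have ``D == 0`` permanently.  Pressures are sink-referenced
    (``p[t] == 0``); nodes cut off from the sink by pruning are held at 0.
    """

    n: int
    u: np.ndarray
    v: np.ndarray
    lengths: np.ndarray
    D: np.ndarray
    s: int
    t: int
    p: np.ndarray | None = None

    @property
    def alive(self) -> np.ndarray:
        return self.D > 0

    def reachable_from_sink(self) -> np.ndarray:
        """Boolean node mask: connected to the sink in the alive subgraph."""
        return _reachable(self.n, self.u, self.v, self.alive, self.t)


def _reachable(
    n: int, u: np.ndarray, v: np.ndarray, alive: np.ndarray, start: int
) -> np.ndarray:
    reach = np.zeros(n, dtype=bool)
    reach[start] = True
    while True:
        cross = alive & (reach[u] ^ reach[v])
        if not cross.any():
            return reach
        reach[u[cross]] = True
        reach[v[cross]] = True


def solve_pressures(state: PhysarumState, params: PhysarumParams) -> np.ndarray:
    """Solve the Kirchhoff pressure system with the sink grounded at 0.

    Nodes disconnected from the sink in the alive subgraph are excluded
    (held at pressure 0; no alive edge crosses to them, so their fluxes are
    zero).  Raises :class:`FlowImpossibleError` if the source is among them.
    The solution satisfies the linear system to a residual below
    ``1e-10 * i0``; one step of iterative refinement is applied if the
    direct solve falls short.
    """
    reach = state.reachable_from_sink()
    if not reach[state.s]:
        raise FlowImpossibleError(
            f"flow impossible: source {state.s} and sink {state.t} are "
            "disconnected in the alive subgraph"
        )
    g = np.where(state.alive, state.D / state.lengths, 0.0)
    lap = np.zeros((state.n, state.n))
    lap[state.u, state.v] = -g
    lap[state.v, state.u] = -g
    deg = np.zeros(state.n)
    np.add.at(deg, state.u, g)
    np.add.at(deg, state.v, g)
    grounded = ~reach
    grounded[state.t] = True
    keep = ~grounded
    lap *= keep[:, None]
    lap *= keep[None, :]
    idx = np.arange(state.n)
    lap[idx, idx] = np.where(grounded, 1.0, deg)
    b = np.zeros(state.n)
    b[state.s] = params.i0
    p = np.linalg.solve(lap, b)
    resid = np.max(np.abs(lap @ p - b))
    if resid > 1e-10 * params.i0:  # one refinement step for ill-conditioned systems
        p = p + np.linalg.solve(lap, b - lap @ p)
    state.p = p
    return p


def compute_fluxes(state: PhysarumState) -> np.ndarray:
    """Signed edge fluxes ``Q_e = (D_e/L_e)(p_u - p_v)`` (antisymmetric)."""
    if state.p is None:
        raise RuntimeError("pressures not solved")
    g = np.where(state.alive, state.D / state.lengths, 0.0)
    return g * (state.p[state.u] - state.p[state.v])


def update_conductivities(
    D: np.ndarray, Q: np.ndarray, params: PhysarumParams, dt: float | None = None
) -> np.ndarray:
    """Semi-implicit Euler step of ``dD/dt = f(|Q|) - gamma*D``, with pruning.

    Edges whose updated conductivity falls below ``flux_eps`` are removed
    (set to exactly 0); a removed edge has ``f(0) = 0`` feedback, so it
    stays at 0 under further updates.  ``dt`` overrides the base step (used
    by the ramp schedule of :meth:`PhysarumParams.step_at`).
    """
    dt = params.dt if dt is None else dt
    fq = params.feedback(np.abs(Q))
    Dn = (D + dt * fq) / (1.0 + dt * params.gamma)
    Dn[D == 0] = 0.0
    Dn[Dn < params.flux_eps] = 0.0
    return Dn


def _settle_prune(D: np.ndarray, Q: np.ndarray, params: PhysarumParams) -> np.ndarray:
    """Edges to prune once iteration has stopped.

    At stopping time every edge is either near a fixed point of the
    dynamics — where ``f(|Q|) = gamma*D`` exactly, so the feedback/decay
    ratio is within ``tol/D`` of 1 — or decaying geometrically toward zero
    at a ratio set by the length gap of its losing route (its flux is
    proportional to its own conductivity, so the decay never reverses).
    An edge with ``f(|Q|) < 0.998*gamma*D`` is therefore a dying tube, and
    the stopping rule ``|D' - D| < tol`` bounds its conductivity by
    ``500*tol*(1 + dt*gamma)/(dt*gamma)`` — negligible.  Pruning the dying
    tubes and re-solving once yields the asymptotic flux distribution.
    Routes losing by a relative length gap under 0.2% are kept: they are
    numerically indistinguishable from exact ties at this tolerance.
    """
    return (D > 0) & (params.feedback(np.abs(Q)) < 0.998 * params.gamma * D)


@dataclass(frozen=True)
class PairResult:
    """Converged (or last) flux map for one source–sink pair."""

    s: int
    t: int
    u: np.ndarray
    v: np.ndarray
    flux_abs: np.ndarray  # |Q| per edge, aligned with (u, v)
    D: np.ndarray
    iterations: int
    converged: bool

    @property
    def surviving(self) -> np.ndarray:
        """Boolean edge mask of tubes not pruned by the dynamics."""
        return self.D > 0


def run_pair(
    m: ConnectivityMatrix,
    s: int,
    t: int,
    params: PhysarumParams | None = None,
    length_mapping: str = "inverse",
    on_iteration: Callable[[int, PhysarumState, np.ndarray], None] | None = None,
) -> PairResult:
    """Evolve the Physarum dynamics for one pair until convergence.

    Iterates pressure solve -> flux -> conductivity update until the maximum
    conductivity change drops below ``params.tol`` (or ``max_iter`` is hit,
    which warns and returns the last state with ``converged=False``).  The
    reported fluxes come from a final pressure solve against the settled
    conductivities.  ``on_iteration(i, state, Q)`` is called after each
    pressure solve with the signed fluxes of that iteration.
    """
    params = params or PhysarumParams()
    if s == t:
        raise ValueError("source and sink must differ")
    u, v = m.edge_index
    lengths = build_lengths(m, length_mapping)
    state = PhysarumState(
        n=m.n, u=u, v=v, lengths=lengths, D=np.full(u.shape, params.d0), s=s, t=t
    )
    delta = np.inf
    best_delta = np.inf
    stall = 0
    converged = False
    settled = False
    iterations = 0
    while True:
        solve_pressures(state, params)
        Q = compute_fluxes(state)
        if on_iteration is not None:
            on_iteration(iterations, state, Q)
        if settled:
            converged = True
            break
        if delta < params.tol:
            dying = _settle_prune(state.D, Q, params)
            if not dying.any():
                converged = True
                break
            state.D = np.where(dying, 0.0, state.D)
            settled = True  # one final solve against the settled tubes
            continue
        if iterations >= params.max_iter or stall > params.stall_window:
            logger.warning(
                "pair (%d, %d) not converged after %d iterations "
                "(max conductivity change %.3g%s)",
                s, t, iterations, delta,
                ", stalled on quasi-tied routes" if stall > params.stall_window else "",
            )
            break
        Dn = update_conductivities(state.D, Q, params, dt=params.step_at(iterations))
        delta = float(np.max(np.abs(Dn - state.D))) if Dn.size else 0.0
        if delta < 0.7 * best_delta:
            best_delta = delta
            stall = 0
        else:
            stall += 1
        state.D = Dn
        iterations += 1
    return PairResult(
        s=s, t=t, u=u, v=v,
        flux_abs=np.abs(Q), D=state.D.copy(),
        iterations=iterations, converged=converged,
    )


# ---------------------------------------------------------------------------
# batched all-pairs engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AllPairsFlux:
    """Converged flux maps for every unordered node pair of a network.

    ``flux_abs[k]`` is the converged ``|Q|`` over edges ``(u, v)`` for pair
    ``pairs[k]``; pair order is the upper-triangle order (0,1), (0,2), ...
    """

    labels: tuple[str, ...]
    u: np.ndarray
    v: np.ndarray
    pairs: np.ndarray        # (K, 2)
    flux_abs: np.ndarray     # (K, E)
    iterations: np.ndarray   # (K,)
    converged: np.ndarray    # (K,) bool

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


def all_pairs_flux(
    m: ConnectivityMatrix,
    params: PhysarumParams | None = None,
    length_mapping: str = "inverse",
    pairs: Sequence[tuple[int, int]] | None = None,
    chunk_size: int = 512,
) -> AllPairsFlux:
    """Converged Physarum flux for all ``n(n-1)/2`` source–sink pairs.

    Each pair starts from fresh conductivities ``d0`` (pairs are
    independent).  Requires a connected network; for subsets use ``pairs``.
    Per-pair dynamics are identical to :func:`run_pair`; unconverged pairs
    are reported in ``converged`` and logged, not raised.
    """
    params = params or PhysarumParams()
    comps = connected_components(m)
    if pairs is None:
        if len(comps) > 1:
            raise FlowImpossibleError(
                f"network has {len(comps)} components "
                f"(sizes {[len(c) for c in comps]}); all-pairs flow impossible"
            )
        iu, iv = np.triu_indices(m.n, k=1)
        pair_arr = np.column_stack([iu, iv])
    else:
        pair_arr = np.asarray(list(pairs), dtype=int).reshape(-1, 2)
        comp_of = np.empty(m.n, dtype=int)
        for ci, nodes in enumerate(comps):
            comp_of[nodes] = ci
        bad = pair_arr[comp_of[pair_arr[:, 0]] != comp_of[pair_arr[:, 1]]]
        if len(bad):
            raise FlowImpossibleError(
                f"flow impossible for cross-component pairs, e.g. "
                f"({bad[0, 0]}, {bad[0, 1]})"
            )
    u, v = m.edge_index
    lengths = build_lengths(m, length_mapping)
    K = pair_arr.shape[0]
    E = u.size
    flux = np.zeros((K, E))
    iters = np.zeros(K, dtype=int)
    conv = np.zeros(K, dtype=bool)
    for lo in range(0, K, chunk_size):
        sl = slice(lo, min(lo + chunk_size, K))
        f, it, cv = _evolve_chunk(m.n, u, v, lengths, pair_arr[sl], params)
        flux[sl], iters[sl], conv[sl] = f, it, cv
    n_bad = int((~conv).sum())
    if n_bad:
        logger.warning("%d of %d pairs did not converge", n_bad, K)
    else:
        logger.info("all %d pairs converged (max %d iterations)",
                    K, int(iters.max(initial=0)))
    return AllPairsFlux(
        labels=m.labels, u=u, v=v, pairs=pair_arr,
        flux_abs=flux, iterations=iters, converged=conv,
    )


def _evolve_chunk(
    n: int,
    u: np.ndarray,
    v: np.ndarray,
    lengths: np.ndarray,
    pairs: np.ndarray,
    params: PhysarumParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evolve a batch of pairs; one batched dense solve per iteration."""
    K = pairs.shape[0]
    E = u.size
    inv_len = 1.0 / lengths
    idx = np.arange(n)

    D = np.full((K, E), params.d0)
    delta = np.full(K, np.inf)
    best_delta = np.full(K, np.inf)
    stall = np.zeros(K, dtype=int)
    # nodes reachable from each pair's sink through alive edges; initially the
    # sink's component of the base graph (recomputed per pair after pruning)
    comp_of = np.full(n, -1)
    all_alive = np.ones(E, dtype=bool)
    for node in range(n):
        if comp_of[node] < 0:
            comp_of[_reachable(n, u, v, all_alive, node)] = node
    reach = comp_of[None, :] == comp_of[pairs[:, 1]][:, None]

    out_flux = np.zeros((K, E))
    out_iters = np.zeros(K, dtype=int)
    out_conv = np.zeros(K, dtype=bool)
    settled = np.zeros(K, dtype=bool)  # final solve pending after settlement
    active = np.arange(K)
    it = 0
    while active.size:
        A = active.size
        g = D[active] * inv_len  # (A, E)
        lap = np.zeros((A, n, n))
        lap[:, u, v] = -g
        lap[:, v, u] = -g
        deg = -lap.sum(axis=2)
        grounded = ~reach[active]
        grounded[np.arange(A), pairs[active, 1]] = True
        keep = ~grounded
        lap *= keep[:, None, :]
        lap *= keep[:, :, None]
        lap[:, idx, idx] = np.where(grounded, 1.0, deg)
        b = np.zeros((A, n))
        b[np.arange(A), pairs[active, 0]] = params.i0
        p = np.linalg.solve(lap, b[..., None])[..., 0]
        Q = g * (p[:, u] - p[:, v])

        # retire pairs: settled last iteration, converged with nothing left to
        # settle, or out of budget
        conv_now = delta[active] < params.tol
        dying = _settle_prune(D[active], Q, params)
        needs_settle = conv_now & ~settled[active] & dying.any(axis=1)
        done = settled[active] | (conv_now & ~needs_settle)
        exhausted = np.zeros(A, dtype=bool)
        stalled = stall[active] > params.stall_window
        if it >= params.max_iter:
            exhausted = ~done
            done = np.ones(A, dtype=bool)
        elif stalled.any():
            exhausted = stalled & ~done
            done = done | stalled
        if done.any():
            ids = active[done]
            out_flux[ids] = np.abs(Q[done])
            out_iters[ids] = it
            out_conv[ids] = ~exhausted[done]
        if needs_settle.any():
            ids = active[needs_settle]
            D[ids] = np.where(dying[needs_settle], 0.0, D[ids])
            settled[ids] = True
            for k in ids:
                reach[k] = _reachable(n, u, v, D[k] > 0, pairs[k, 1])
        run_on = ~(done | needs_settle | settled[active])
        still = active[~done]
        if not still.size:
            break
        if run_on.any():
            sel = run_on[~done] if done.any() else run_on
            upd = still[sel]
            dt_it = params.step_at(it)
            fq = params.feedback(np.abs(Q[run_on]))
            Dn = (D[upd] + dt_it * fq) / (1.0 + dt_it * params.gamma)
            Dn[D[upd] == 0] = 0.0
            newly_pruned = (Dn < params.flux_eps) & (Dn > 0)
            Dn[Dn < params.flux_eps] = 0.0
            delta[upd] = np.max(np.abs(Dn - D[upd]), axis=1) if E else 0.0
            improved = delta[upd] < 0.7 * best_delta[upd]
            best_delta[upd] = np.where(improved, delta[upd], best_delta[upd])
            stall[upd] = np.where(improved, 0, stall[upd] + 1)
            D[upd] = Dn
            if newly_pruned.any():
                for k_local in np.flatnonzero(newly_pruned.any(axis=1)):
                    k = upd[k_local]
                    reach[k] = _reachable(n, u, v, D[k] > 0, pairs[k, 1])
        active = still
        it += 1
    return out_flux, out_iters, out_conv
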