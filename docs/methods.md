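# Methods

## Model

`physcent` measures the importance of nodes and edges in a weighted
undirected network by simulating adaptive fluid flow, the transport
mechanism of the slime mould *Physarum polycephalum*. Each edge `e_ij` is a
tube of fixed length `L_ij` and adaptive conductivity `D_ij`. For a
source–sink pair `(s, t)`, a constant current `I0` is forced through the
network. Assuming Hagen–Poiseuille flow, edge flux is

    Q_ij = (D_ij / L_ij) (p_i − p_j),

with node pressures determined by Kirchhoff conservation,

    Σ_i (D_ij / L_ij)(p_i − p_j) = −I0 (j = s), +I0 (j = t), 0 otherwise,

and conductivities adapt with positive feedback and decay,

    dD_ij/dt = f(|Q_ij|) − γ D_ij,

where `f` is increasing with `f(0) = 0`. Tubes that carry flux widen;
unused tubes decay and are removed. At equilibrium the surviving tube
network carries the converged flux distribution for that pair.

Given converged per-pair flux maps `|Q^k|` for all `k = 1..n(n−1)/2`
unordered pairs, the **criticality** of an edge is `c_ij = Σ_k |Q^k_ij|`,
the **Physarum edge centrality** is the criticality itself, and the
**Physarum node centrality** is `C_P,node(i) = Σ_j c_ij` over edges at `i`.
Comparison measures are **degree** (number of edges at a node — the
binarized column sum; weighted strength is available behind a flag but is
not `C_D`) and **betweenness** (fraction-weighted geodesic counts, node
version excluding endpoint pairs, edge version including them, ties split
fractionally). **Hubs**/**bridges** are nodes/edges more than one sample
standard deviation above the map mean — a threshold invariant under
positive affine transforms, so it commutes with Z-transformation.

Edge weights are unitless connection strengths (for structural brain
networks, mean fractional anisotropy along tracts, in (0, 1]). The
weight→length mapping is `L = 1/w` (stronger connection = shorter tube), so
the flow model and weighted betweenness share one distance semantics and
differ *only* in the shortest-path assumption. A `unit` mapping (`L = 1`)
is available for topology-only analyses.

## Choice of the feedback function

The feedback `f` is only constrained to be increasing with `f(0) = 0`, but
the choice is structural, not cosmetic:

* **Linear `f(x) = x`** (with `γ = 1`) provably converges to the single
  shortest s–t path: the surviving tubes are the geodesic and carry the
  full `I0` (exactly tied routes split evenly). This makes the solver a
  useful shortest-path oracle, and the package tests it as such. However,
  at full convergence with generically unique geodesics it also makes the
  node measure an *affine image of betweenness*:
  `C_P,node = 2·I0·C_B,node + (n−1)·I0`, because every pair contributes
  `I0` on exactly the geodesic edges. After Z-transformation the two maps
  are identical — the measure would add nothing.
* **Sublinear saturating `f(x) = x^μ/(1+x^μ)` with `μ < 1`** (default
  `μ = 0.8`) has a globally attracting equilibrium in which *every
  competitive route retains flux* in proportion to its quality. This is the
  regime in which the flow measure genuinely blends local (degree-like) and
  global (betweenness-like) information: it correlates strongly with
  betweenness yet remains distinct, spreads its mass more evenly across
  nodes, and is markedly more stable across noisy subjects. `μ > 1` (and
  the linear form) are winner-take-all and collapse back onto betweenness.

The package therefore defaults to the saturating form with `μ = 0.8`;
`f_kind="linear"` is the documented switch for shortest-path behaviour.

## Parameters

| name | default | meaning |
|---|---|---|
| `i0` | 1 | injected flux (flow units); all fluxes and criticalities scale linearly with it |
| `gamma` | 1 | tube decay rate (1/time) |
| `f_kind`, `mu` | `saturating`, 0.8 | feedback form (see above) |
| `dt` | 1 | base integration step (time units) |
| `d0` | 1 | initial conductivity of every existing edge (deterministic start; no random seed in the solver) |
| `tol` | 1e-6 | stop when max |ΔD| per step falls below this |
| `max_iter` | 10000 | iteration cap; exceeding it is a warning, not an error |
| `flux_eps` | 1e-8 | conductivity below which a tube is removed (permanently 0) |
| `dt_ramp_after`, `dt_growth`, `dt_max_factor` | 50, 1.1, 1000 | step-ramp schedule (below) |
| `stall_window` | 300 | stagnation horizon for quasi-tie detection (below) |

Characteristic scales (`L̄`, `D̄`, `p̄ = I0·L̄/D̄`) are nondimensionalization
commentary and are not computed.

## Numerical design

**Discretization.** Semi-implicit Euler,
`D' = (D + dt·f(|Q|)) / (1 + dt·γ)`, positivity-preserving for any `dt`;
with linear `f`, `dt = γ = 1` it reduces to the classic averaging update
`D' = (D + |Q|)/2`. The fixed points `D* = f(|Q*|)/γ` do not depend on
`dt`.

**Pressure solve.** The sink is grounded (`p_t = 0`) and the grounded
Laplacian system is solved densely (LAPACK). Nodes cut off from the sink by
pruning are held at pressure 0 and excluded from the solve; no alive edge
crosses to them, so their fluxes are zero. The single-pair path verifies a
residual below `1e-10·I0` and applies one step of iterative refinement if a
solve falls short. Pairs whose source is disconnected from the sink raise a
"flow impossible" error naming the pair.

**Settlement at stop.** Iteration stops when `max |ΔD| < tol`. At that
moment every edge is either near a fixed point (`f(|Q|) = γD` within
`~tol/D`) or decaying geometrically to zero at a rate set by its route's
length deficit. Edges with `f(|Q|) < 0.998·γD` are therefore dying tubes —
the stopping rule bounds their conductivity by `500·tol·(1+dtγ)/(dtγ)` — and
are pruned, followed by one final pressure solve. The reported state thus
contains no half-dead tubes: on the two-route triangle the long edge ends
at exactly `D = 0` and the short route carries exactly `I0`. Routes losing
by a relative length gap under 0.2% are kept; at this tolerance they are
indistinguishable from exact ties.

**Step ramp.** After 50 iterations at the base `dt` (which integrate the
transient accurately), the step grows by ×1.1 per iteration up to
1000·`dt`. This traverses the slow terminal contraction — near-tied routes
creep toward resolution at a rate proportional to their tiny length gap —
in bounded wall-clock time. Converged fluxes agree with the pure `dt = 1`
dynamics to ~1e-15 (checked on 60 pairs of a 78-node network); the ramp is
purely an accelerator. Setting `dt_growth = 1` disables it.

**Stall detection.** Pairs whose best `max |ΔD|` stops improving for 300
consecutive iterations are quasi-ties: routes so close in length that the
dynamics drifts along a near-fixed-point manifold indefinitely. They retire
with their current (split-flux) map and `converged = False` — the same
semantics as exhausting `max_iter`, reported in diagnostics and logged,
never raised. On realistic synthetic connectomes this affects ~1% of pairs;
their split flux between near-equivalent routes is exactly what the
centrality sum wants from them.

**Batching.** `run_pair` is a readable reference loop over the single-pair
operations; `all_pairs_flux` evolves many pairs at once, assembling all
unconverged pairs' grounded Laplacians into one `(batch, n, n)` array and
solving them in a single batched LAPACK call per iteration (chunks of 512
pairs). The two paths implement identical dynamics; tests assert their flux
maps agree to 1e-8 and their convergence flags match. Pairs are independent:
each starts from fresh `D = d0`.

## Group statistics

Per-subject maps are Z-transformed (sample SD, ddof = 1) before any
cross-measure comparison; degree counts, path fractions and flux sums live
on incommensurable scales. Edge-map statistics (Z-transform, bridge
thresholds) are computed over existing edges only — absent edges have no
centrality. Group hubs are detected on the mean of per-subject Z-maps, not
on a group-averaged network. The per-node comparison of measures is a
one-way ANOVA (groups = measures, observations = subjects) with
Benjamini–Hochberg FDR across nodes; at FDR-significant nodes the three
pairwise two-sample t-tests are Bonferroni-corrected (×3) and reported as
ordered pairs. Intersubject variability is the coefficient of variation
`CV = σ/μ` of a node's Z-transformed centrality across subjects (sample
SD); cells with |mean| < 1e-12 are undefined and reported as missing. CV
vectors of two measures are compared with a two-tailed *paired-by-node*
t-test across hub nodes (the pairing is a design choice; nodes are the
natural blocking unit). Jaccard overlap of two hub/bridge sets is
intersection over union; two empty sets return 1 with a warning (vacuously
perfect overlap). The cumulative-share curve sorts nodes descending by a
reference map (ties broken by node order) and reports the fraction of a
map's total mass in the top `⌈q·n⌉` nodes.

## Synthetic data

The generator emulates the *outputs* of a structural-connectome pipeline —
AAL-style 78-node, FA-weighted, sparse symmetric matrices — not the
pipeline itself. One base network is built from: an exact edge count
`⌈density·n(n−1)/2⌉`; a random spanning tree (connectivity by
construction); preference weights for intra-module (×4), hub-incident (×8)
and homotopic (×2) candidate edges; mirrored module membership across
hemispheres; Beta(4, 3) weights (mean ≈ 0.57, shaped like tract-averaged
FA); and mirrored-edge weights mixed 50/50 with fresh draws so bilateral
connections correlate. Cohorts apply per-subject multiplicative log-normal
weight noise (per-edge CV ≈ `weight_noise_sd`), clipped to (0, 1], plus
degree-preserving double edge swaps touching ≈ `topology_rewire_p` of the
edges, with connectivity enforced by bounded redraws. All randomness flows
through NumPy's PCG64 (`default_rng`), so fixtures are stable across
platforms and releases.

What the generator does **not** emulate: tractography biases, distance- or
geometry-dependent connection probability, realistic degree distributions,
community structure fitted to real cortex, or inter-regional weight
correlations beyond hemispheric mirroring. Passing cohort tests therefore
show that the *machinery* behaves correctly and that the qualitative
cross-measure relationships hold under controlled noise — not that effect
sizes match any real population. Two consequences are worth knowing:
degree-preserving rewiring makes the degree map identical across subjects,
so CV(C_D) is exactly 0 by construction (the most extreme version of
"local structure is stable"); and hemispheric mirroring creates near-tied
route pairs, which is the main source of quasi-tie stalls.

## Problem sizes used by the test suite and acceptance script

Cohort-level checks run on 40-node networks with 12 subjects and 3 seeds
(tests) or the `--seed` argument (acceptance script); solver and generator
parameters are otherwise at their defaults. These sizes give stable
orderings and complete quickly on a single CPU; the implementation handles
the 78-node, 3003-pair case in about a minute per subject and scales as
`O(pairs × iterations × n³)` beyond that. Property checks (conservation,
shortest-path recovery, tree closed forms, betweenness oracle) use graphs
of 3–30 nodes where exact or brute-force references exist.

## Known limitations

* Dense pressure solves cap practical network size at a few hundred nodes;
  a sparse/CG backend would be the natural extension.
* Quasi-tied routes are reported unconverged rather than resolved; their
  flux is split between near-equivalent routes, which is benign for summed
  criticality but means `converged.all()` is not guaranteed on real-world
  networks.
* The ANOVA treats measures as independent groups (the named test); a
  repeated-measures design over subjects would also be defensible.
* Bridge tables Z-transform edge maps over existing edges; with very few
  edges (< 2 distinct values) the transform is undefined and refused.
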