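# Methods

## Model

A body-bar network is a graph whose `N` vertices are rigid bodies with 6
degrees of freedom (DOF) each and whose edges bundle `bars` distance
constraints between two bodies.  Generic rigidity is assumed: only the
constraint topology matters, not coordinates.  Edges are quenched (always
present; covalent bonds) or fluctuating (present with probability `p`;
hydrogen bonds).  Every edge defaults to 5 bars, the standard count for
modelling a bond between two atom-centred bodies; at most 6 independent
constraints can join one pair of bodies.

Three estimators of the ensemble-average number of internal DOF `F` (and of
rigid-cluster structure) are implemented, in decreasing order of cost and
exactness:

1. **Pebble game (PG).**  Exact per-topology counting.  Each vertex starts
   with 6 free pebbles.  To place an edge of capacity `c` between `u` and
   `v`: 6 pebbles are collected and held on one endpoint, then `c` pebbles
   are sought for the other by repeated breadth-first searches over directed
   edge coverings, each successful search reversing coverage along its path.
   If the full request is gathered the edge is covered (independent); a
   failed search proves the shortfall redundant and every vertex visited by
   the exhausted search forms a minimally rigid (Laman) subgraph, condensed
   at once into a single vertex.  Condensation is what keeps typical runs
   near `O(N)`.  Ensemble averages come from exhaustive enumeration of all
   `2**N_f` topologies (exact, guarded at `N_f <= 20`) or from Monte-Carlo
   sampling.
2. **Virtual pebble game (VPG).**  The same machine run once on mean
   capacities: a fluctuating edge carries `bars * p` pebbles of capacity.
   Free pebbles and coverings become real-valued probability flows; the
   result is a deterministic mean-field estimate of the ensemble average
   with zero statistical error.  Empirically it lies at or below the exact
   ensemble mean (a conjectured lower bound, checked — not assumed — by the
   test suite) and is exact at `p = 0` and `p = 1`.
3. **Maxwell constraint counting (MCC).**  `F_MCC = max(6N − ⟨C⟩ − 6, 0)`
   with `⟨C⟩` the expected bar count.  A rigorous lower bound for every
   topology; on a periodic lattice `⟨C⟩ = 5 d L^d (q_fix + p q_fluct)` and
   `F_MCC = 0` defines the Maxwell threshold `p*`.

The bar-PG variant samples each of an edge's 5 bars independently at
probability `p` (non-cooperative fluctuations).  It shares the VPG's mean
capacity but has far smaller edge-level variance, which is why its ensemble
mean tracks the VPG closely while the cooperative PG deviates most.

## Numerical choices

* **Fixed-point arithmetic.**  1 pebble = 10⁹ integer units; all pebble
  comparisons are exact integer comparisons, so results are bit-reproducible
  and independent of edge placement order and of how capacities are split
  into parts.  VPG capacities are `round(bars * p * 10⁹)` units.
* **Directional coverage.**  Each edge stores two non-negative covered
  amounts, one per endpoint side.  A search may traverse from `x` toward `y`
  only through the amount covered from `x`'s side; retrieval reverses that
  amount, preserving the bipartite-matching/network-flow structure (verified
  in tests against a max-flow oracle).
* **Role convention.**  For each placement the 6 pebbles are held on the
  endpoint that currently has more free pebbles (ties to the lower vertex
  id) and the request is gathered on the other.  Totals are provably
  role-independent; this convention minimizes backtracking and reproduces
  the canonical worked-example bookkeeping step for step.
* **Per-pair cap.**  No more than 6 pebbles can cover one pair of bodies.  A
  single request is capped at 6 up front; shortfalls relative to *existing*
  cover are discovered by the search itself, so an over-full merged edge
  triggers the failed search and condensation that the theory prescribes.
* **Condensation bookkeeping.**  The representative of a condensed region
  keeps the 6 pebbles held by the search root; pebbles covering internal
  edges — exactly `6(k−1)` for a `k`-vertex Laman region — move to an
  `absorbed` pool, so `free + cover + absorbed = 6N` holds after every
  operation (asserted in checked runs).  Boundary edges re-attach to the
  representative, parallels merging by summing per-direction cover.
* **Degenerate inputs.**  Edges whose endpoints already share a
  representative are wholly redundant without a search (a rigid body absorbs
  no internal constraint).  Parallel input edges merge by summing bars.
  Self-loops at input time are rejected.
* **Rigid clusters.**  With 6 pebbles collected and held on a seed vertex,
  every live vertex that cannot call up any additional free amount (≥ 1
  unit, i.e. 10⁻⁹ pebble — the tolerance that replaces a strict-zero test in
  fractional arithmetic) joins the seed's cluster; condensed vertices
  inherit their representative's label.  Largest-cluster ties in the reduced
  metrics are broken by lowest cluster id.
* **Disconnected graphs.**  `internal_dof` subtracts a single 6 (matching
  the Maxwell convention); `internal_dof_per_component` subtracts 6 per
  connected component and is reported alongside.
* **Threshold location.**  VPG internal DOF is non-increasing in `p`
  (property-tested), so the first grid point with zero DOF is found by
  bisection over the `Δp = 0.001` grid — identical to an ascending scan at a
  fraction of the cost.

## Synthetic data

The lattice generator draws one uniform per nearest-neighbour pair of a
periodic `d`-dimensional grid (`d ∈ {2, 3}`), in (axis, row-major site)
order: quenched below `q_fix`, fluctuating below `q_fix + q_fluct`, missing
otherwise, 5 bars per placed edge.  These disordered lattices are
deliberately *harsher* than real molecular networks: uniform `p` across all
fluctuating edges maximizes constraint-density fluctuations, the worst case
for any mean-field method.  What they do not emulate is protein-specific
structure — a covalently bonded backbone, realistic hydrogen-bond geometry,
or per-bond probabilities — so passing tests bound the mean-field error
under stress conditions rather than predicting accuracy for any particular
protein (where the error is known to be far smaller).  Protein-style
networks enter only as pre-built edge lists through the TSV reader.

`random_small_net` produces seeded arbitrary-topology networks whose
fluctuating count stays small enough for exhaustive enumeration; they anchor
the exactness tests (generic rigidity-matrix rank oracle, pairwise
rank-increment cluster oracle, max-flow collection oracle).

## Problem sizes and defaults

Ensemble sweeps default to a `Δp = 0.05` grid and threshold location to
`Δp = 0.001`.  The packaged worst-case-error experiment uses the fully
fluctuating cubic lattice (`q_fix = 0`, `q_fluct = 1`) at `L = 10`
(`N = 1000`) with 50 cooperative-PG realizations per grid point (the
in-suite copy runs `L = 8` with 30); since `F/N` is intensive, the size
choice affects sampling noise, not the expected value, and the measured
maximum gap of ≈ 0.6 DOF per vertex sits near the rigidity transition.
Seeds: a master seed spawns one child stream per sample, recorded so any
realization can be replayed.

## Known limitations

* The VPG-below-exact-mean property is an observed conjecture, not a
  theorem; the suite reports any counterexample rather than assuming none.
* Incremental (bootstrapped) PG sweeps correlate successive `p` values and
  are flagged as such in the output; incremental VPG sweeps are exactly
  path-independent.
* Cluster decomposition does cost one reachability pass per cluster, so
  dense sweeps that need ACS/RCS on large flexible networks are slower than
  DOF-only sweeps (`compute_clusters=False`).
* Stressed (over-constrained) regions are reported only as per-edge
  redundant capacity, not decomposed; 2-pebble (2D bar-joint) and
  3-pebble (bond-bending) games are out of scope, as is building networks
  from PDB coordinates.
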