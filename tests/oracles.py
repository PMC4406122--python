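"""Independent oracles for the pebble engine.

Everything here avoids the engine's own machinery: internal DOF come from
the numeric rank of a generic body-bar rigidity matrix, pair rigidity from
rank increments, and pebble collectability from a network-flow computation
on the directed coverage graph.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from pebblekit.engine import UNIT, PebbleState
from pebblekit.network import Realization


def _bar_rows(u: int, v: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """One generic bar between bodies u and v: row of the rigidity matrix.

    Body coordinates are (velocity, angular velocity); a bar attached at
    random points p_u, p_v constrains the relative point velocity along the
    bar direction d = p_u - p_v:  d.(v_u + w_u x p_u) - d.(v_v + w_v x p_v) = 0,
    i.e. columns [d, p_u x d] for u and -[d, p_v x d] for v.
    """
    pu = rng.normal(size=3)
    pv = rng.normal(size=3)
    d = pu - pv
    row = np.zeros(6 * n)
    row[6 * u : 6 * u + 3] = d
    row[6 * u + 3 : 6 * u + 6] = np.cross(pu, d)
    row[6 * v : 6 * v + 3] = -d
    row[6 * v + 3 : 6 * v + 6] = -np.cross(pv, d)
    return row


def rigidity_matrix(real: Realization, rng: np.random.Generator) -> np.ndarray:
    rows = []
    for e, bars in zip(real.base.edges, real.present_bars):
        for _ in range(bars):
            rows.append(_bar_rows(e.u, e.v, real.n_vertices, rng))
    if not rows:
        return np.zeros((0, 6 * real.n_vertices))
    return np.vstack(rows)


def internal_dof_oracle(real: Realization, seed: int = 0) -> int:
    """6N - 6 - rank of a generic rigidity matrix (single global -6)."""
    rng = np.random.default_rng(seed)
    m = rigidity_matrix(real, rng)
    rank = np.linalg.matrix_rank(m) if m.size else 0
    return 6 * real.n_vertices - 6 - rank


def rigid_pair_oracle(real: Realization, seed: int = 0) -> list[set[int]]:
    """Rigid clusters by pairwise rank tests.

    Two bodies are mutually rigid iff locking them together (6 extra generic
    bars) adds nothing to the rank of the rigidity matrix.
    """
    n = real.n_vertices
    rng = np.random.default_rng(seed)
    m = rigidity_matrix(real, rng)
    base_rank = np.linalg.matrix_rank(m) if m.size else 0
    clusters: list[set[int]] = []
    assigned: set[int] = set()
    for i in range(n):
        if i in assigned:
            continue
        cluster = {i}
        for j in range(i + 1, n):
            if j in assigned:
                continue
            lock = np.vstack([_bar_rows(i, j, n, rng) for _ in range(6)])
            stacked = np.vstack([m, lock]) if m.size else lock
            if np.linalg.matrix_rank(stacked) == base_rank + 0:
                cluster.add(j)
        # base_rank must be recomputed including nothing; a pair is rigid iff
        # rank increase is exactly 0
        assigned |= cluster
        clusters.append(cluster)
    return clusters


def max_collectable_oracle(
    state: PebbleState, v: int, held: frozenset[int] = frozenset()
) -> int:
    """Upper bound on free pebbles gatherable on live vertex ``v``.

    Maximum flow from a super-source feeding every other vertex's free
    pebbles, through the directed coverage graph (edge x->y has capacity
    cov[x][y]), into ``v``; held vertices are removed.  The gatherable total
    is v's own free pool plus this flow.
    """
    v = state.find(v)
    g = nx.DiGraph()
    src = "S"
    for x in state.live_vertices:
        if x in held or x == v:
            continue
        if state.free[x] > 0:
            g.add_edge(src, x, capacity=state.free[x])
    for x in state.live_vertices:
        if x in held:
            continue
        for y, c in state.cov[x].items():
            if y in held or c == 0:
                continue
            # traversable x -> y by the amount covered from x's side; flow of
            # retrieved pebbles runs opposite to the search, toward the root
            g.add_edge(y, x, capacity=c)
    if v not in g:
        return state.free[v]
    flow, _ = nx.maximum_flow(g, src, v) if src in g else (0, None)
    return state.free[v] + flow
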