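"""Derived rigidity metrics.

* ACS — average rigid-cluster size, ``(1/N_c) sum_c N_V(c)``; its reduced
  form excludes the largest cluster.
* RCS — rigid cluster susceptibility, the reduced second moment of cluster
  sizes excluding the largest cluster; its peak over the fluctuating-edge
  probability marks the rigidity transition, as in percolation theory.
* Heterogeneity index h_I — the sample standard deviation of vertex degrees
  in the *plucked* network (dangling ends removed), quantifying local
  constraint-density fluctuations.
* max_dof_error — the worst-case difference over p between the ensemble-mean
  pebble-game internal DOF per vertex and the deterministic virtual-pebble-
  game value, max_p [F_pg(p) - F_vpg(p)] / N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import RigidClusterDecomposition
from .network import Realization

__all__ = [
    "ClusterStats",
    "HeterogeneityStats",
    "acs",
    "acs_reduced",
    "rcs",
    "cluster_stats",
    "pluck",
    "heterogeneity_index",
    "max_dof_error",
]


@dataclass(frozen=True)
class ClusterStats:
    acs: float
    acs_reduced: float | None  # None for a single cluster
    rcs: float | None  # None for a single cluster
    n_clusters: int


@dataclass(frozen=True)
class HeterogeneityStats:
    h_index: float | None  # None when the plucked network has < 2 vertices
    mean_degree: float | None
    plucked_size: int


def acs(dec: RigidClusterDecomposition) -> float:
    """Mean cluster size; equals N / N_c."""
    return float(np.mean(dec.sizes))


def _largest_index(dec: RigidClusterDecomposition) -> int:
    # ties broken by lowest cluster id
    sizes = np.asarray(dec.sizes)
    return int(np.argmax(sizes))


def acs_reduced(dec: RigidClusterDecomposition) -> float | None:
    """ACS excluding exactly one largest cluster (lowest id among ties)."""
    if dec.n_clusters < 2:
        return None
    keep = [s for i, s in enumerate(dec.sizes) if i != _largest_index(dec)]
    return float(np.mean(keep))


def rcs(dec: RigidClusterDecomposition) -> float | None:
    """Reduced second moment of cluster sizes, excluding the largest cluster.

    ``(1/(N_c - 1)) * sum_{c != largest} (N_V(c) - ACS_reduced)**2``; undefined
    (None) for a single cluster.
    """
    if dec.n_clusters < 2:
        return None
    keep = np.array([s for i, s in enumerate(dec.sizes) if i != _largest_index(dec)], float)
    return float(np.mean((keep - keep.mean()) ** 2))


def cluster_stats(dec: RigidClusterDecomposition) -> ClusterStats:
    return ClusterStats(acs(dec), acs_reduced(dec), rcs(dec), dec.n_clusters)


def pluck(real: Realization) -> tuple[list[int], list[tuple[int, int]]]:
    """Strip dangling ends: iteratively delete vertices of degree <= 1.

    Adjacency counts an edge present iff it has at least one bar in the
    realization.  The survivor is the 2-core — the subnetwork that can
    actually support percolation of rigidity (a tree plucks away entirely;
    an isolated ring survives untouched).  Returns the surviving vertex ids
    and edges.
    """
    adj: dict[int, set[int]] = {v: set() for v in range(real.n_vertices)}
    for e, k in zip(real.base.edges, real.present_bars):
        if k > 0:
            adj[e.u].add(e.v)
            adj[e.v].add(e.u)
    queue = [v for v, nb in adj.items() if len(nb) <= 1]
    alive = set(adj)
    while queue:
        v = queue.pop()
        if v not in alive:
            continue
        alive.discard(v)
        for w in adj[v]:
            adj[w].discard(v)
            if w in alive and len(adj[w]) <= 1:
                queue.append(w)
        adj[v].clear()
    vertices = sorted(alive)
    edges = [(u, w) for u in vertices for w in adj[u] if u < w]
    return vertices, edges


def heterogeneity_index(real: Realization) -> HeterogeneityStats:
    """Sample standard deviation of plucked-network degrees (h_I).

    Uses the N-1 normalization with N the plucked vertex count; all-equal
    degrees (e.g. isolated rings, full lattices) give h_I = 0.  Undefined
    when plucking leaves fewer than 2 vertices.
    """
    vertices, edges = pluck(real)
    if len(vertices) < 2:
        return HeterogeneityStats(None, None, len(vertices))
    deg = {v: 0 for v in vertices}
    for u, w in edges:
        deg[u] += 1
        deg[w] += 1
    d = np.array([deg[v] for v in vertices], float)
    return HeterogeneityStats(
        float(np.std(d, ddof=1)), float(d.mean()), len(vertices)
    )


def max_dof_error(
    curve_pg: Sequence[float],
    curve_vpg: Sequence[float],
    n_vertices: int,
    p_grid: Sequence[float] | None = None,
) -> tuple[float, float | None]:
    """Worst-case per-vertex DOF gap, max_p (F_pg - F_vpg) / N.

    The two curves must share the same p grid.  Returns ``(max gap, argmax
    p)``; the argmax is None when no grid is supplied.
    """
    pg = np.asarray(curve_pg, float)
    vpg = np.asarray(curve_vpg, float)
    if pg.shape != vpg.shape:
        raise ValueError("curves must share the same p grid")
    diff = (pg - vpg) / n_vertices
    i = int(np.argmax(diff))
    p_at = None if p_grid is None else float(p_grid[i])
    return float(diff[i]), p_at
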