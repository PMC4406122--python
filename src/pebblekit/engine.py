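"""The shared pebble-game / virtual-pebble-game engine.

Every vertex of a body-bar network carries 6 pebbles (3 translational + 3
rotational degrees of freedom).  Placing an edge of capacity ``c`` consumes
``c`` pebbles if they can be gathered on its endpoints; a shortfall marks the
uncoverable part of the constraint redundant and condenses the minimally
rigid ("Laman") region found by the failed search into a single vertex.

With integer capacities (``bars`` pebbles per edge) the engine is the exact
body-bar pebble game (PG).  With fractional capacities (``bars * p`` for a
fluctuating edge present with probability ``p``) it is the virtual pebble
game (VPG): a mean-field isomorph in which pebble counts are probabilities
and a single deterministic run stands in for the ensemble average over all
``2**n_fluct`` constraint topologies.

All pebble amounts are exact fixed-point integers with 1 pebble = ``UNIT`` =
10**9 units, so comparisons are exact and results are bit-reproducible and
independent of the order in which edges are placed.

Coverage is directional: ``cov[x][y]`` units of an edge are covered by
pebbles from ``x``'s side, and a pebble search may traverse from ``x`` toward
``y`` only through that directional coverage, reversing it when free pebbles
are retrieved back along the path.  This preserves the bipartite-matching /
network-flow structure that makes the game exact.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .network import FLUCTUATING, QUENCHED, BodyBarNetwork, Realization

__all__ = [
    "UNIT",
    "PebbleState",
    "PlacementOutcome",
    "GameResult",
    "RigidClusterDecomposition",
    "init_state",
    "collect_pebbles",
    "place_edge",
    "condense",
    "run_game",
    "rigid_clusters",
    "placements_for",
]

UNIT = 10**9  # integer units per pebble ("1 pebble broken into 1 billion parts")
SIX = 6 * UNIT


@dataclass
class PlacementOutcome:
    """Per-edge bookkeeping of one :func:`place_edge` call."""

    u: int
    v: int
    capacity: int  # requested, in units
    covered: int  # newly covered, in units
    redundant: int  # uncoverable part, in units
    condensed: frozenset[int] = frozenset()  # original vertices merged, if any


class PebbleState:
    """Mutable engine state: free pebbles, directed coverings, condensation.

    Attributes
    ----------
    free :
        Per original vertex, free pebble amount in units.  Only entries of
        live representatives are meaningful.
    cov :
        ``cov[x][y]`` = units covering edge x-y from x's side (x, y live).
        Both directions always coexist as keys; their sum is the total cover.
    parent :
        Union-find map implementing Laman-subgraph condensation.
    absorbed :
        Units locked inside condensed rigid bodies (6(k-1) pebbles for a
        k-vertex region); together with free and cover this conserves the
        original ``6 * n_vertices`` pebbles.
    """

    __slots__ = (
        "n",
        "free",
        "cov",
        "parent",
        "absorbed",
        "redundant",
        "covered_total",
        "placed_total",
        "members",
        "log",
    )

    def __init__(self, n: int):
        self.n = n
        self.free = [SIX] * n
        self.cov: dict[int, dict[int, int]] = {v: {} for v in range(n)}
        self.parent = list(range(n))
        self.absorbed = 0
        self.redundant = 0
        self.covered_total = 0
        self.placed_total = 0
        self.members: dict[int, list[int]] = {v: [v] for v in range(n)}
        self.log: list[PlacementOutcome] = []

    def find(self, v: int) -> int:
        parent = self.parent
        root = v
        while parent[root] != root:
            root = parent[root]
        while parent[v] != root:
            parent[v], v = root, parent[v]
        return root

    @property
    def live_vertices(self) -> list[int]:
        return [v for v in range(self.n) if self.parent[v] == v]

    @property
    def total_free(self) -> int:
        return sum(self.free[v] for v in self.live_vertices)

    @property
    def total_cover(self) -> int:
        return sum(c for v in self.live_vertices for c in self.cov[v].values())

    def check_conservation(self) -> None:
        total = self.total_free + self.total_cover + self.absorbed
        if total != SIX * self.n:
            raise AssertionError(
                f"pebble conservation violated: {total} != {SIX * self.n}"
            )

    def copy(self) -> "PebbleState":
        dup = PebbleState.__new__(PebbleState)
        dup.n = self.n
        dup.free = list(self.free)
        dup.cov = {v: dict(d) for v, d in self.cov.items()}
        dup.parent = list(self.parent)
        dup.absorbed = self.absorbed
        dup.redundant = self.redundant
        dup.covered_total = self.covered_total
        dup.placed_total = self.placed_total
        dup.members = {v: list(m) for v, m in self.members.items()}
        dup.log = list(self.log)
        return dup


@dataclass(frozen=True)
class RigidClusterDecomposition:
    """Partition of the original vertices into rigid clusters."""

    label: tuple[int, ...]  # per original vertex, cluster id (0..n_clusters-1)
    sizes: tuple[int, ...]  # per cluster, vertex count

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def as_sets(self) -> list[frozenset[int]]:
        groups: dict[int, set[int]] = {}
        for v, c in enumerate(self.label):
            groups.setdefault(c, set()).add(v)
        return [frozenset(groups[c]) for c in range(self.n_clusters)]

    def canonical(self) -> frozenset[frozenset[int]]:
        """Label-free form for comparing partitions."""
        return frozenset(self.as_sets())


@dataclass
class GameResult:
    """Outcome of a full PG/VPG run.

    ``internal_dof`` is the number of internal degrees of freedom F in
    pebbles: total free pebbles minus the 6 global rigid-body motions
    (a single -6 regardless of connectivity, matching the Maxwell-counting
    convention; ``internal_dof_per_component`` subtracts 6 per connected
    component instead).
    """

    n_vertices: int
    total_free: float  # pebbles
    internal_dof: float  # pebbles
    internal_dof_per_component: float
    redundant: float  # pebbles
    n_components: int
    clusters: RigidClusterDecomposition | None
    edge_log: list[PlacementOutcome]
    state: PebbleState

    @property
    def dof_per_vertex(self) -> float:
        return self.internal_dof / self.n_vertices


def init_state(net: BodyBarNetwork | Realization | int) -> PebbleState:
    """Start a game: isolated vertices, 6 free pebbles each, no coverings."""
    if isinstance(net, int):
        n = net
    elif isinstance(net, Realization):
        n = net.base.n_vertices
    else:
        n = net.n_vertices
    return PebbleState(n)


def _search_once(
    state: PebbleState, root: int, need: int, held: frozenset[int] | set[int]
) -> tuple[int, set[int]]:
    """One breadth-first pebble search from ``root``.

    Follows directional coverage (an edge is traversable from ``x`` toward
    ``y`` by the amount covered from ``x``'s side) until a vertex with free
    pebbles is found; retrieves ``min(need, path bottleneck, free)`` back to
    ``root``, reversing the coverage along the path.  Held vertices are
    flagged visited up front, so they are never drained nor traversed.

    Returns ``(amount retrieved, visited set)``; amount 0 signals a failed
    (exhaustive) search whose visited set is a minimally rigid region.
    """
    free = state.free
    cov = state.cov
    visited = set(held)
    visited.add(root)
    prev: dict[int, int] = {}
    queue = deque([root])
    while queue:
        x = queue.popleft()
        cx = cov[x]
        for y in sorted(cx):  # ascending-id frontier order
            if y in visited or cx[y] == 0:
                continue
            visited.add(y)
            prev[y] = x
            if free[y] > 0:
                # walk back to root to find the path bottleneck
                path = [y]
                while path[-1] != root:
                    path.append(prev[path[-1]])
                amount = min(need, free[y])
                for a, b in zip(path[1:], path[:-1]):  # edges root..y direction
                    amount = min(amount, cov[a][b])
                # reverse coverage along the path, move pebbles to root
                free[y] -= amount
                free[root] += amount
                for a, b in zip(path[1:], path[:-1]):
                    cov[a][b] -= amount
                    cov[b][a] += amount
                return amount, visited
            queue.append(y)
    return 0, visited


def collect_pebbles(
    state: PebbleState,
    v: int,
    target: int,
    held: Iterable[int] = (),
) -> tuple[int, set[int] | None]:
    """Accumulate up to ``target`` units of free pebbles on live vertex ``v``.

    Repeats breadth-first searches until the target is met or a search finds
    no free pebbles.  Returns ``(free now on v, visited set of the failed
    search or None on success)``.  Failure is a normal outcome: the visited
    set of the exhausted search is the Laman region to condense.
    """
    v = state.find(v)
    held = frozenset(state.find(h) for h in held)
    while state.free[v] < target:
        got, visited = _search_once(state, v, target - state.free[v], held)
        if got == 0:
            return state.free[v], visited
    return state.free[v], None


def condense(state: PebbleState, vertices: Iterable[int]) -> int:
    """Merge a set of live vertices into one representative (lowest id).

    Edges internal to the set are dropped and their covering pebbles moved to
    the ``absorbed`` pool (they embody the 6(k-1) constraints that make the
    region one rigid body); boundary edges re-attach to the representative,
    parallels merging by summing per-direction cover.  The representative's
    free pool is the sum of the members' free pebbles — exactly 6 for a
    failed-search region, where the search root holds 6 and every other
    visited vertex is drained.
    """
    group = {state.find(v) for v in vertices}
    if len(group) < 2:
        return next(iter(group)) if group else -1
    rep = min(group)
    merged_cov: dict[int, int] = {}
    free_sum = 0
    for s in group:
        free_sum += state.free[s]
        state.free[s] = 0
        for y, c in state.cov[s].items():
            if y in group:
                state.absorbed += c  # internal edge side
            else:
                merged_cov[y] = merged_cov.get(y, 0) + c
        del state.cov[s]
    # rebuild outside endpoints' views
    rep_cov: dict[int, int] = {}
    for y in merged_cov:
        inward = 0
        ycov = state.cov[y]
        for s in group:
            if s in ycov:
                inward += ycov.pop(s)
        ycov[rep] = inward
        rep_cov[y] = merged_cov[y]
        if inward + merged_cov[y] > SIX:
            raise AssertionError("boundary edge cover exceeds 6 pebbles")
    state.cov[rep] = rep_cov
    members_rep: list[int] = []
    for s in group:
        members_rep.extend(state.members.pop(s))
        state.parent[s] = rep
    state.parent[rep] = rep
    state.members[rep] = members_rep
    state.free[rep] = free_sum
    if free_sum > SIX:
        raise AssertionError("condensed region holds more than 6 free pebbles")
    return rep


def place_edge(state: PebbleState, u: int, v: int, capacity: int) -> PlacementOutcome:
    """Insert an edge bundle of ``capacity`` units between original vertices.

    Maps the endpoints through the condensation, holds 6 pebbles on the
    endpoint that currently has more free pebbles (ties to the lower id),
    then gathers the full request on the other endpoint.  On success the
    request covers the edge from the collector's side; on failure the
    partial amount collected covers it, the shortfall is recorded redundant
    and the visited region of the exhausted search is condensed.

    A request whose endpoints already share a representative is absorbed
    entirely as redundant: a rigid body accepts no internal constraints.
    """
    if capacity <= 0:
        raise ValueError("edge capacity must be positive")
    state.placed_total += capacity
    ru, rv = state.find(u), state.find(v)
    if ru == rv:
        state.redundant += capacity
        out = PlacementOutcome(u, v, capacity, 0, capacity)
        state.log.append(out)
        return out
    if state.free[ru] > state.free[rv] or (
        state.free[ru] == state.free[rv] and ru < rv
    ):
        hold, coll = ru, rv
    else:
        hold, coll = rv, ru
    # no single placement can cover more than the 6 pebbles a pair can share;
    # shortfalls relative to *existing* cover are left to the search itself
    target = capacity if capacity <= SIX else SIX
    _, failed = collect_pebbles(state, hold, SIX)
    if failed is not None:  # 6 pebbles are always collectable on any vertex
        raise AssertionError("failed to hold 6 pebbles on an endpoint")
    _, failed = collect_pebbles(state, coll, target, held=(hold,))
    if failed is None:
        covered = target
        condensed: frozenset[int] = frozenset()
    else:
        covered = state.free[coll]  # partial cover with everything gathered
        condensed = frozenset(
            w for r in failed for w in state.members[state.find(r)]
        )
    state.free[coll] -= covered
    if covered or coll in state.cov[hold]:
        ccov = state.cov[coll]
        ccov[hold] = ccov.get(hold, 0) + covered
        hcov = state.cov[hold]
        hcov.setdefault(coll, 0)
        if ccov[hold] + hcov[coll] > SIX:
            raise AssertionError("edge cover exceeds 6 pebbles")
    state.covered_total += covered
    state.redundant += capacity - covered
    if failed is not None:
        condense(state, failed)
    out = PlacementOutcome(u, v, capacity, covered, capacity - covered, condensed)
    state.log.append(out)
    return out


def _components(state: PebbleState) -> int:
    live = state.live_vertices
    seen: set[int] = set()
    n_comp = 0
    for v in live:
        if v in seen:
            continue
        n_comp += 1
        stack = [v]
        seen.add(v)
        while stack:
            x = stack.pop()
            for y in state.cov[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
    return n_comp


def rigid_clusters(state: PebbleState) -> RigidClusterDecomposition:
    """Decompose the final network into rigid clusters.

    Two vertices belong to the same rigid cluster when at most 6 degrees of
    freedom are shared between them: with 6 pebbles collected and held on a
    seed vertex, every live vertex unable to call up any additional free
    pebble amount (>= 1 unit, i.e. 10^-9 pebble) joins the seed's cluster.
    Vertices absorbed by condensation inherit their representative's label.
    """
    labels: dict[int, int] = {}
    next_label = 0
    for v in sorted(state.live_vertices):
        if v in labels:
            continue
        _, failed = collect_pebbles(state, v, SIX)
        if failed is not None:
            raise AssertionError("6 pebbles must always be collectable")
        # vertices that can still reach a free pebble (reverse reachability
        # over directional coverage) are flexible relative to v
        flexible: set[int] = set()
        queue: deque[int] = deque()
        for w in state.live_vertices:
            if w != v and state.free[w] > 0:
                flexible.add(w)
                queue.append(w)
        while queue:
            x = queue.popleft()
            for w, c in state.cov[x].items():
                # w -> x traversable iff covered from w's side
                if w != v and w not in flexible and state.cov[w][x] > 0:
                    flexible.add(w)
                    queue.append(w)
        for w in state.live_vertices:
            if w not in flexible and w not in labels:
                labels[w] = next_label
        next_label += 1
    out = [0] * state.n
    for rep, lab in labels.items():
        for w in state.members[rep]:
            out[w] = lab
    sizes = [0] * next_label
    for lab in out:
        sizes[lab] += 1
    return RigidClusterDecomposition(tuple(out), tuple(sizes))


def placements_for(
    net: BodyBarNetwork | Realization,
    mode: str,
    p: float | None = None,
) -> list[tuple[int, int, int]]:
    """Translate a network or realization into (u, v, capacity-units) tuples.

    ``pg`` needs a :class:`Realization` (integer bar counts); ``vpg`` takes
    the base network, assigning ``bars`` pebbles to quenched edges and
    ``round(bars * p * UNIT)`` units to fluctuating ones.
    """
    if mode == "pg":
        if not isinstance(net, Realization):
            raise TypeError("pg mode requires a Realization with integer bars")
        return [
            (e.u, e.v, k * UNIT)
            for e, k in zip(net.base.edges, net.present_bars)
            if k > 0
        ]
    if mode == "vpg":
        base = net.base if isinstance(net, Realization) else net
        out = []
        for e in base.edges:
            if e.kind == QUENCHED:
                cap = e.bars * UNIT
            else:
                pe = e.p if p is None else p
                if not 0.0 <= pe <= 1.0:
                    raise ValueError(f"probability {pe} outside [0, 1]")
                cap = round(e.bars * pe * UNIT)
            if cap > 0:
                out.append((e.u, e.v, cap))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def run_game(
    net: BodyBarNetwork | Realization,
    mode: str = "pg",
    p: float | None = None,
    edge_order: Sequence[int] | None = None,
    compute_clusters: bool = True,
    check: bool = False,
) -> GameResult:
    """Play a complete game and summarize it.

    Parameters
    ----------
    net :
        A :class:`Realization` for ``mode="pg"``; a :class:`BodyBarNetwork`
        (or realization, whose base is used) for ``mode="vpg"``.
    mode :
        ``"pg"`` for the exact integer game on one constraint topology,
        ``"vpg"`` for the deterministic mean-field game at probability ``p``.
    edge_order :
        Optional permutation of the placement list.  The internal DOF count,
        redundancy and cluster decomposition do not depend on it.
    check :
        Verify pebble conservation after every placement (slow; for tests).
    """
    placements = placements_for(net, mode, p)
    if edge_order is not None:
        if sorted(edge_order) != list(range(len(placements))):
            raise ValueError("edge_order must permute the placement list")
        placements = [placements[i] for i in edge_order]
    n = net.base.n_vertices if isinstance(net, Realization) else net.n_vertices
    state = PebbleState(n)
    for u, v, cap in placements:
        place_edge(state, u, v, cap)
        if check:
            state.check_conservation()
    total_free = state.total_free
    n_comp = _components(state)
    clusters = rigid_clusters(state) if compute_clusters else None
    return GameResult(
        n_vertices=n,
        total_free=total_free / UNIT,
        internal_dof=(total_free - SIX) / UNIT,
        internal_dof_per_component=(total_free - SIX * n_comp) / UNIT,
        redundant=state.redundant / UNIT,
        n_components=n_comp,
        clusters=clusters,
        edge_log=state.log,
        state=state,
    )
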