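"""Body-bar constraint networks, disordered-lattice generators and edge-list I/O.

A body-bar network models a molecular framework as a graph whose vertices are
rigid bodies with 6 degrees of freedom each and whose edges bundle ``bars``
(distance constraints) between two bodies.  Edges are either *quenched*
(always present, e.g. covalent bonds) or *fluctuating* (present with some
probability ``p``, e.g. hydrogen bonds).  Disordered lattices place quenched /
fluctuating / missing edges at random between nearest neighbours of a periodic
hyper-cubic grid, which is the standard stress test for mean-field rigidity
estimates because constraint-density fluctuations are maximal there.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "EdgeSpec",
    "BodyBarNetwork",
    "LatticeSpec",
    "Realization",
    "generate_lattice",
    "realize",
    "enumerate_realizations",
    "read_edgelist",
    "write_edgelist",
]

QUENCHED = "quenched"
FLUCTUATING = "fluctuating"

EdgeKind = Literal["quenched", "fluctuating"]
RealizeMode = Literal["cooperative", "per_bar"]


@dataclass(frozen=True)
class EdgeSpec:
    """A bundle of bars between two rigid bodies.

    Parameters
    ----------
    u, v :
        0-based vertex ids, ``u != v``.
    kind :
        ``"quenched"`` (always present) or ``"fluctuating"``.
    bars :
        Number of distance constraints bundled in the edge (default 5,
        the convention for modelling covalent and hydrogen bonds).
    p :
        Presence probability.  Forced to 1 for quenched edges.  For
        fluctuating edges this is a stored default that a run-time uniform
        ``p`` overrides.
    """

    u: int
    v: int
    kind: EdgeKind = QUENCHED
    bars: int = 5
    p: float = 1.0

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError(f"self-loop at vertex {self.u} is not allowed")
        if self.kind not in (QUENCHED, FLUCTUATING):
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if self.bars < 1:
            raise ValueError("bars must be >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"presence probability {self.p} outside [0, 1]")
        if self.kind == QUENCHED and self.p != 1.0:
            raise ValueError("quenched edges must have p = 1")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.u, self.v) if self.u < self.v else (self.v, self.u)


class BodyBarNetwork:
    """An immutable body-bar constraint network.

    Parallel input edges between the same unordered pair are merged by summing
    their bar counts; the merge requires matching ``kind`` and ``p``.
    """

    def __init__(self, n_vertices: int, edges: Sequence[EdgeSpec] = ()):
        if n_vertices < 1:
            raise ValueError("need at least one vertex")
        merged: dict[tuple[int, int], EdgeSpec] = {}
        for e in edges:
            if not (0 <= e.u < n_vertices and 0 <= e.v < n_vertices):
                raise ValueError(f"edge {e.u}-{e.v} outside vertex range")
            key = e.pair
            if key in merged:
                old = merged[key]
                if old.kind != e.kind or old.p != e.p:
                    raise ValueError(
                        f"conflicting duplicate edge {key}: kind/p mismatch"
                    )
                warnings.warn(
                    f"duplicate edge {key} merged by summing bars", stacklevel=2
                )
                merged[key] = EdgeSpec(key[0], key[1], old.kind, old.bars + e.bars, old.p)
            else:
                merged[key] = EdgeSpec(key[0], key[1], e.kind, e.bars, e.p)
        self.n_vertices = int(n_vertices)
        self.edges: tuple[EdgeSpec, ...] = tuple(
            merged[k] for k in sorted(merged)
        )

    @property
    def n_fluct(self) -> int:
        """Number of fluctuating edges (the ensemble size is ``2**n_fluct``)."""
        return sum(1 for e in self.edges if e.kind == FLUCTUATING)

    @property
    def fluctuating_edges(self) -> tuple[EdgeSpec, ...]:
        return tuple(e for e in self.edges if e.kind == FLUCTUATING)

    @property
    def quenched_edges(self) -> tuple[EdgeSpec, ...]:
        return tuple(e for e in self.edges if e.kind == QUENCHED)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BodyBarNetwork)
            and self.n_vertices == other.n_vertices
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return (
            f"BodyBarNetwork(n_vertices={self.n_vertices}, "
            f"n_edges={len(self.edges)}, n_fluct={self.n_fluct})"
        )


@dataclass(frozen=True)
class LatticeSpec:
    """Parameters of a periodic disordered hyper-cubic lattice.

    ``d`` is the dimension (2 for a sheet embedded in 3-space, 3 for a cube),
    ``L`` the number of vertices per dimension, so ``N = L**d``.  Each of the
    ``d * L**d`` nearest-neighbour pairs independently receives a quenched edge
    with probability ``q_fix``, a fluctuating edge with probability
    ``q_fluct``, and no edge otherwise.
    """

    d: int
    L: int
    q_fix: float
    q_fluct: float
    periodic: bool = True
    bars: int = 5

    def __post_init__(self) -> None:
        if self.d not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if min(self.q_fix, self.q_fluct) < 0 or self.q_fix + self.q_fluct > 1:
            raise ValueError("require 0 <= q_fix, q_fluct and q_fix + q_fluct <= 1")
        if not self.periodic:
            raise ValueError("only periodic boundaries are supported")

    @property
    def n_vertices(self) -> int:
        return self.L**self.d


@dataclass
class Realization:
    """A concrete constraint topology drawn from a network's ensemble.

    ``present_bars[i]`` is the number of bars actually present on
    ``base.edges[i]``: always ``bars`` for quenched edges; 0 or ``bars`` for
    fluctuating edges in cooperative mode; anything in ``0..bars`` in per-bar
    mode.
    """

    base: BodyBarNetwork
    present_bars: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.present_bars) != len(self.base.edges):
            raise ValueError("present_bars must align with base.edges")
        for e, k in zip(self.base.edges, self.present_bars):
            if e.kind == QUENCHED and k != e.bars:
                raise ValueError("quenched edges must keep all bars")
            if not 0 <= k <= e.bars:
                raise ValueError("present_bars outside 0..bars")

    @property
    def n_vertices(self) -> int:
        return self.base.n_vertices

    def degrees(self) -> np.ndarray:
        """Vertex degrees counting an edge as present iff it has >= 1 bar."""
        deg = np.zeros(self.base.n_vertices, dtype=int)
        for e, k in zip(self.base.edges, self.present_bars):
            if k > 0:
                deg[e.u] += 1
                deg[e.v] += 1
        return deg


def _lattice_pairs(spec: LatticeSpec) -> Iterator[tuple[int, int]]:
    # Row-major linearization; one candidate pair per (axis, site), site
    # iterated lexicographically, neighbour at +1 along the axis modulo L.
    L, d = spec.L, spec.d
    shape = (L,) * d
    for axis in range(d):
        for site in itertools.product(range(L), repeat=d):
            nbr = list(site)
            nbr[axis] = (nbr[axis] + 1) % L
            u = int(np.ravel_multi_index(site, shape))
            v = int(np.ravel_multi_index(tuple(nbr), shape))
            yield u, v


def generate_lattice(spec: LatticeSpec, seed: int | np.random.Generator) -> BodyBarNetwork:
    """Draw a disordered lattice: one uniform per nearest-neighbour pair.

    ``x <= q_fix`` places a quenched edge, ``q_fix < x <= q_fix + q_fluct`` a
    fluctuating edge, otherwise the pair stays disconnected.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    edges: list[EdgeSpec] = []
    for u, v in _lattice_pairs(spec):
        x = rng.random()
        if x <= spec.q_fix:
            edges.append(EdgeSpec(u, v, QUENCHED, spec.bars))
        elif x <= spec.q_fix + spec.q_fluct:
            edges.append(EdgeSpec(u, v, FLUCTUATING, spec.bars))
    return BodyBarNetwork(spec.n_vertices, edges)


def realize(
    net: BodyBarNetwork,
    p: float | None,
    mode: RealizeMode = "cooperative",
    seed: int | np.random.Generator = 0,
) -> Realization:
    """Draw one constraint topology from the fluctuating-edge ensemble.

    Cooperative mode draws one uniform per fluctuating edge and keeps all or
    none of its bars; per-bar mode draws one uniform per bar.  Quenched edges
    are untouched.  ``p=None`` uses each edge's stored presence probability.
    """
    rng = np.random.default_rng(seed)
    present: list[int] = []
    for e in net.edges:
        if e.kind == QUENCHED:
            present.append(e.bars)
            continue
        pe = e.p if p is None else p
        if not 0.0 <= pe <= 1.0:
            raise ValueError(f"probability {pe} outside [0, 1]")
        if mode == "cooperative":
            present.append(e.bars if rng.random() <= pe else 0)
        elif mode == "per_bar":
            present.append(int(np.sum(rng.random(e.bars) <= pe)))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return Realization(net, tuple(present))


def enumerate_realizations(
    net: BodyBarNetwork, p: float, max_fluct: int = 20
) -> Iterator[tuple[Realization, float]]:
    """Yield all ``2**n_fluct`` cooperative realizations with their weights.

    The weight of a realization with ``k`` of the ``n_fluct`` fluctuating
    edges present is ``p**k * (1-p)**(n_fluct-k)``; weights sum to 1.
    """
    nf = net.n_fluct
    if nf > max_fluct:
        raise ValueError(
            f"{nf} fluctuating edges exceed the enumeration guard ({max_fluct})"
        )
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    fluct_idx = [i for i, e in enumerate(net.edges) if e.kind == FLUCTUATING]
    base = [e.bars for e in net.edges]
    for mask in itertools.product((0, 1), repeat=nf):
        present = list(base)
        for i, bit in zip(fluct_idx, mask):
            if not bit:
                present[i] = 0
        k = sum(mask)
        weight = p**k * (1.0 - p) ** (nf - k)
        yield Realization(net, tuple(present)), weight


# ---------------------------------------------------------------------------
# Edge-list text format: '#' comments, a `vertices <N>` header, then one line
# per edge: `u  v  kind  bars  p` (TSV, 0-based ids).


def write_edgelist(net: BodyBarNetwork, path: str | Path) -> None:
    path = Path(path)
    lines = [f"vertices\t{net.n_vertices}"]
    for e in net.edges:
        lines.append(f"{e.u}\t{e.v}\t{e.kind}\t{e.bars}\t{e.p:g}")
    path.write_text("\n".join(lines) + "\n")


def read_edgelist(path: str | Path) -> BodyBarNetwork:
    path = Path(path)
    n_vertices: int | None = None
    edges: list[EdgeSpec] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if n_vertices is None:
            if len(tokens) != 2 or tokens[0] != "vertices":
                raise ValueError(f"{path}:{lineno}: expected 'vertices <N>' header")
            n_vertices = int(tokens[1])
            continue
        if len(tokens) != 5:
            raise ValueError(f"{path}:{lineno}: expected 'u v kind bars p'")
        u, v = int(tokens[0]), int(tokens[1])
        kind = tokens[2]
        if kind not in (QUENCHED, FLUCTUATING):
            raise ValueError(f"{path}:{lineno}: unknown edge kind {kind!r}")
        edges.append(EdgeSpec(u, v, kind, int(tokens[3]), float(tokens[4])))
    if n_vertices is None:
        raise ValueError(f"{path}: missing 'vertices <N>' header")
    return BodyBarNetwork(n_vertices, edges)
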