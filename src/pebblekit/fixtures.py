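"""Small built-in networks: the in-text worked examples and seeded generators.

These load without any random draws and anchor the test suite: the
three-vertex capacity-placement example exercises every engine operation
(covering, backtracking, merging, failed search, condensation), and the
eight-vertex lattice patch with three fluctuating hydrogen-bond edges is
small enough to enumerate its full 2**3-realization ensemble exactly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .engine import UNIT
from .network import (
    FLUCTUATING,
    QUENCHED,
    BodyBarNetwork,
    EdgeSpec,
    read_edgelist,
)

__all__ = [
    "worked_example_placements",
    "lattice_patch_network",
    "lattice_patch_path",
    "random_small_net",
]


def worked_example_placements() -> tuple[int, list[tuple[int, int, int]]]:
    """The three-vertex worked example: (n_vertices, placements).

    Placements are (u, v, capacity-units) in the printed order:
    v1-2.5-v2, v2-5.0-v3, v1-2.0-v3, v2-1.5-v3 (0-based ids here).  Playing
    them leaves 0.5 pebbles redundant, condenses v2 and v3, and counts 1.5
    internal DOF.
    """
    placements = [
        (0, 1, 5 * UNIT // 2),
        (1, 2, 5 * UNIT),
        (0, 2, 2 * UNIT),
        (1, 2, 3 * UNIT // 2),
    ]
    return 3, placements


def lattice_patch_path() -> Path:
    """Path of the shipped edge-list file for the eight-vertex example."""
    return Path(resources.files("pebblekit").joinpath("data/lattice_patch.tsv"))


def lattice_patch_network() -> BodyBarNetwork:
    """Eight-vertex square-lattice patch: 5 quenched covalent edges
    (v1-v2, v2-v6, v6-v7, v3-v7, v3-v4), 3 fluctuating hydrogen-bond edges
    (v1-v5, v2-v3, v7-v8), 5 bars each; v5-v6 and the remaining neighbour
    pairs are missing interactions."""
    return read_edgelist(lattice_patch_path())


def random_small_net(
    n_vertices: int,
    n_edges: int,
    fluct_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
    bars: int = 5,
) -> BodyBarNetwork:
    """Seeded generator of small, oracle-checkable networks.

    Samples ``n_edges`` distinct vertex pairs uniformly and marks each
    fluctuating with probability ``fluct_fraction``.  Keep the fluctuating
    count small (<= ~12) when exhaustive enumeration is intended.
    """
    if n_edges > n_vertices * (n_vertices - 1) // 2:
        raise ValueError("more edges requested than distinct pairs")
    rng = np.random.default_rng(seed)
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < n_edges:
        u, v = rng.integers(0, n_vertices, size=2)
        if u != v:
            pairs.add((min(u, v), max(u, v)))
    edges = [
        EdgeSpec(u, v, FLUCTUATING if rng.random() < fluct_fraction else QUENCHED, bars)
        for u, v in sorted(pairs)
    ]
    return BodyBarNetwork(n_vertices, edges)
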