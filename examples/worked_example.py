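"""Replay the three-vertex virtual-pebble-game walkthrough step by step.

Four capacity placements (2.5, 5.0, 2.0, 1.5) exercise covering,
backtracking, capacity merging and Laman-subgraph condensation.  The printed
free-pebble amounts are internal degrees of freedom still available at each
vertex; the final 1.5 internal DOF mean the network keeps one and a half
average motions beyond its global translations/rotations, and the 0.5
redundant pebbles are constraint capacity the network could not absorb.
"""

from pebblekit import UNIT, init_state, place_edge, rigid_clusters
from pebblekit.fixtures import worked_example_placements

n, placements = worked_example_placements()
state = init_state(n)
for i, (u, v, cap) in enumerate(placements, start=1):
    out = place_edge(state, u, v, cap)
    print(
        f"edge {i}: v{u+1}-v{v+1} capacity {cap / UNIT:.1f} -> "
        f"covered {out.covered / UNIT:.1f}, redundant {out.redundant / UNIT:.1f}"
        + (f", condensed {sorted(f'v{w+1}' for w in out.condensed)}" if out.condensed else "")
    )
    print(f"         free pebbles: "
          + ", ".join(f"v{w+1}={state.free[w] / UNIT:.1f}" for w in state.live_vertices))

print(f"\ninternal DOF  : {(state.total_free - 6 * UNIT) / UNIT:.1f} pebbles")
print(f"redundant     : {state.redundant / UNIT:.1f} pebbles")
dec = rigid_clusters(state)
print(f"rigid clusters: {[sorted(f'v{w+1}' for w in c) for c in dec.as_sets()]}")
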