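# pebblekit

Body-bar pebble games for ensemble-average graph rigidity of molecular-style
networks.

## The problem

Molecular frameworks — proteins, polymers, glasses — are usefully modelled as
*body-bar networks*: each vertex is a rigid body carrying 6 degrees of freedom
(DOF), and each edge bundles a number of *bars* (distance constraints, 5 per
bond by convention) between two bodies.  Covalent bonds are *quenched* edges,
always present; hydrogen bonds are *fluctuating* edges, present with some
probability `p` as they break and reform.  Questions about flexibility —
how many internal motions remain, which regions are rigid, where the network
sits relative to its rigidity transition — are answered by constraint
counting on this graph.

`pebblekit` implements three levels of that counting:

* **PG — the exact body-bar pebble game.**  Six pebbles per vertex; placing an
  edge of capacity `c` succeeds when `c` pebbles can be gathered on its
  endpoints (with 6 held on one of them) by reversing directed edge
  coverings.  A shortfall marks constraints redundant and condenses the
  minimally rigid (Laman) region found by the failed search.  One run
  characterizes one constraint topology; averaging over the `2**N_f`
  topologies generated by `N_f` fluctuating edges (or a Monte-Carlo sample of
  them) gives ensemble properties.
* **VPG — the virtual pebble game.**  A mean-field isomorph of the PG in
  which pebble counts become real numbers: a fluctuating edge carries
  capacity `5p` instead of being present-or-absent, and pebble movements
  become probability flow.  One deterministic run (exact fixed-point
  arithmetic, 1 pebble = 10⁹ units) stands in for the whole ensemble average,
  with zero sampling error.
* **MCC — Maxwell constraint counting.**  The global mean-field bound
  `F_MCC = max(6N − ⟨C⟩ − 6, 0)`, with `⟨C⟩ = 5dL^d(q_fix + p·q_fluct)` on a
  periodic disordered lattice; `F_MCC = 0` defines the Maxwell rigidity
  threshold `p*`.

On top of the games sit rigid-cluster metrics (average cluster size ACS,
rigid cluster susceptibility RCS whose peak over `p` marks the rigidity
transition), the heterogeneity index `h_I` (standard deviation of vertex
degrees after plucking dangling ends), disordered-lattice generators with
quenched/fluctuating/missing edges drawn per nearest-neighbour pair, and
ensemble drivers including incremental ("bootstrapped") p-sweeps.

## A worked example

The engine's operations on a three-vertex network with capacity placements
2.5, 5.0, 2.0, 1.5:

```sh
python examples/worked_example.py
```

```
edge 1: v1-v2 capacity 2.5 -> covered 2.5, redundant 0.0
         free pebbles: v1=6.0, v2=3.5, v3=6.0
edge 2: v2-v3 capacity 5.0 -> covered 5.0, redundant 0.0
         free pebbles: v1=4.5, v2=0.0, v3=6.0
edge 3: v1-v3 capacity 2.0 -> covered 2.0, redundant 0.0
         free pebbles: v1=2.5, v2=0.0, v3=6.0
edge 4: v2-v3 capacity 1.5 -> covered 1.0, redundant 0.5, condensed ['v2', 'v3']
         free pebbles: v1=1.5, v2=6.0

internal DOF  : 1.5 pebbles
redundant     : 0.5 pebbles
rigid clusters: [['v1'], ['v2', 'v3']]
```

Edge 1 is covered by 2.5 of v2's pebbles, leaving it 3.5 free.  Edge 2 needs
5 on v2, so 1.5 pebbles are backtracked through the covered v1–v2 edge.
Edge 4 merges with the 5 already covering v2–v3 into a 6.5-pebble request;
only 6 pebbles can ever sit between two bodies, the search fails, 0.5
pebbles are redundant and v2, v3 condense into one rigid cluster.  The final
1.5 internal DOF are the motions remaining beyond global translation and
rotation.

Other narrative scripts in `examples/` compare the exact enumerated ensemble
mean against the VPG and MCC (`enumeration_vs_vpg.py`), sweep a fully
fluctuating cubic lattice through its rigidity transition with all four
methods (`lattice_sweep.py`), and compute cluster metrics and `h_I` on a
disordered-lattice realization (`clusters_and_heterogeneity.py`).

A thin CLI mirrors the library:

```sh
pebblekit generate -d 3 -L 10 --qfix 0 --qfluct 1 --seed 7 -o lat.tsv
pebblekit run --mode vpg --net lat.tsv --p 0.45
pebblekit sweep --net lat.tsv --methods pg,vpg,mcc --p-grid 0:1:0.05 --samples 100 -o sweep.tsv
```

Networks travel as a plain TSV edge list (`vertices N` header, then
`u v kind bars p` per edge, 0-based ids).

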