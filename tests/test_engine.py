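from __future__ import annotations

import numpy as np
import pytest

from oracles import internal_dof_oracle, max_collectable_oracle, rigid_pair_oracle
from pebblekit.engine import (
    SIX,
    UNIT,
    PebbleState,
    collect_pebbles,
    condense,
    init_state,
    place_edge,
    rigid_clusters,
    run_game,
)
from pebblekit.fixtures import worked_example_placements, random_small_net
from pebblekit.mcc import mcc_dof
from pebblekit.network import BodyBarNetwork, EdgeSpec, enumerate_realizations, realize


def play(n, placements):
    state = init_state(n)
    for u, v, cap in placements:
        place_edge(state, u, v, cap)
        state.check_conservation()
    return state


class TestInitAndCollect:
    def test_initial_pool_is_six_per_vertex(self):
        state = init_state(3)
        assert state.total_free == 18 * UNIT
        assert state.total_cover == 0

    def test_empty_game_internal_dof(self):
        # with no constraints, internal DOF = 6(N-1)
        for n in (1, 5):
            res = run_game(BodyBarNetwork(n), mode="vpg", p=0.0)
            assert res.internal_dof == 6 * (n - 1)

    def test_isolated_vertex_collects_six_immediately(self):
        state = init_state(4)
        got, failed = collect_pebbles(state, 2, SIX)
        assert got == SIX and failed is None

    def test_collect_matches_maxflow_oracle(self):
        # the repeated reversing breadth-first search gathers exactly the
        # maximum network flow of free pebbles into the target vertex
        rng = np.random.default_rng(5)
        for trial in range(40):
            net = random_small_net(7, 10, 0.5, seed=100 + trial)
            real = realize(net, 0.6, seed=trial)
            state = play(7, [(e.u, e.v, k * UNIT)
                             for e, k in zip(net.edges, real.present_bars) if k])
            v = state.find(int(rng.integers(0, 7)))
            target = int(rng.integers(1, 7)) * UNIT
            expected = min(target, max_collectable_oracle(state, v))
            got, _ = collect_pebbles(state, v, target)
            assert min(got, target) == expected


class TestPlaceEdge:
    def test_first_edge_partially_drains_coverer(self):
        state = play(2, [(0, 1, 5 * UNIT // 2)])
        assert state.redundant == 0
        assert sorted(state.free) == [int(3.5 * UNIT), 6 * UNIT]

    def test_seven_parallel_unit_bars_cap_at_six(self):
        state = play(2, [(0, 1, UNIT)] * 7)
        assert state.covered_total == 6 * UNIT
        assert state.redundant == UNIT

    def test_rejects_nonpositive_capacity(self):
        state = init_state(2)
        with pytest.raises(ValueError):
            place_edge(state, 0, 1, 0)

    def test_self_loop_after_condensation_fully_redundant(self):
        state = play(2, [(0, 1, 6 * UNIT), (0, 1, UNIT)])  # second placement condenses
        assert len(state.live_vertices) == 1
        out = place_edge(state, 0, 1, 3 * UNIT)
        assert out.redundant == 3 * UNIT and out.covered == 0


class TestWorkedExampleReplay:
    """The three-vertex worked example, checkpoint by checkpoint."""

    def test_full_replay(self):
        n, placements = worked_example_placements()
        state = init_state(n)
        place_edge(state, *placements[0])
        assert state.free[1] == int(3.5 * UNIT)  # v2 covered the 2.5 edge
        before = state.cov[0].get(1, 0)
        place_edge(state, *placements[1])
        # 1.5 pebbles backtracked through v1-v2 while gathering 5 on v2
        assert state.cov[0][1] - before == int(1.5 * UNIT)
        place_edge(state, *placements[2])
        out = place_edge(state, *placements[3])
        # merged 6.5-capacity edge: only 6 coverable, search fails
        assert out.covered == UNIT and out.redundant == UNIT // 2
        assert out.condensed == frozenset({1, 2})
        assert len(state.live_vertices) == 2
        assert state.total_free == int(7.5 * UNIT)
        state.check_conservation()
        dec = rigid_clusters(state)
        assert dec.canonical() == frozenset({frozenset({0}), frozenset({1, 2})})

    def test_totals(self):
        n, placements = worked_example_placements()
        state = play(n, placements)
        assert (state.total_free - SIX) / UNIT == 1.5
        assert state.redundant / UNIT == 0.5


class TestCondense:
    def test_two_vertex_condensation_conserves_pebbles(self):
        state = play(2, [(0, 1, 6 * UNIT)])
        condense(state, [0, 1])
        assert state.live_vertices == [0]
        assert state.free[0] == SIX
        state.check_conservation()

    def test_small_set_is_noop(self):
        state = init_state(3)
        assert condense(state, [1]) == 1
        assert len(state.live_vertices) == 3

    def test_condensed_regions_are_minimally_rigid(self):
        # a failed search isolates a Laman subgraph: replaying the internal
        # placements alone yields exactly zero internal DOF
        for seed in range(25):
            net = random_small_net(8, 14, 0.5, seed=400 + seed)
            real = realize(net, 0.8, seed=seed)
            state = init_state(8)
            placements = [(e.u, e.v, k * UNIT)
                          for e, k in zip(net.edges, real.present_bars) if k]
            for i, (u, v, cap) in enumerate(placements):
                out = place_edge(state, u, v, cap)
                if out.condensed:
                    idx = sorted(out.condensed)
                    remap = {w: j for j, w in enumerate(idx)}
                    inner = [
                        (remap[a], remap[b], c)
                        for a, b, c in placements[: i + 1]
                        if a in remap and b in remap
                    ]
                    sub = play(len(idx), inner)
                    assert sub.total_free == SIX  # 6 DOF: one rigid body


class TestRunGameExactness:
    def test_matches_generic_rank_oracle(self):
        for seed in range(30):
            net = random_small_net(6, 10, 0.5, seed=seed)
            real = realize(net, 0.7, seed=seed)
            res = run_game(real, mode="pg", compute_clusters=False, check=True)
            assert res.internal_dof == internal_dof_oracle(real, seed=seed)

    def test_clusters_match_pairwise_rank_oracle(self):
        for seed in range(20):
            net = random_small_net(5, 7, 0.5, seed=200 + seed)
            real = realize(net, 0.75, seed=seed)
            res = run_game(real, mode="pg")
            expected = {frozenset(c) for c in rigid_pair_oracle(real, seed=seed)}
            assert res.clusters.canonical() == expected

    def test_pg_mode_requires_realization(self, lattice_patch):
        with pytest.raises(TypeError):
            run_game(lattice_patch, mode="pg")


class TestInvariants:
    def test_order_independence(self, small_net):
        real = realize(small_net, 0.6, seed=1)
        ref = run_game(real, mode="pg")
        rng = np.random.default_rng(8)
        n_placements = sum(1 for k in real.present_bars if k)
        for _ in range(25):
            order = rng.permutation(n_placements).tolist()
            res = run_game(real, mode="pg", edge_order=order)
            assert res.internal_dof == ref.internal_dof
            assert res.redundant == ref.redundant
            assert res.clusters.canonical() == ref.clusters.canonical()

    def test_vpg_path_independence_under_capacity_splitting(self, small_net):
        # split every capacity into unequal parts, place in random interleaved
        # order: identical internal DOF, redundancy and clusters
        from pebblekit.engine import placements_for

        placements = placements_for(small_net, "vpg", p=0.55)
        ref = play(small_net.n_vertices, placements)
        ref_dec = rigid_clusters(ref)
        rng = np.random.default_rng(17)
        for _ in range(10):
            parts = []
            for u, v, cap in placements:
                k = int(rng.integers(1, 5))
                cuts = sorted(rng.integers(1, cap, size=k - 1).tolist()) if k > 1 else []
                bounds = [0, *cuts, cap]
                parts.extend(
                    (u, v, b - a) for a, b in zip(bounds, bounds[1:]) if b > a
                )
            rng.shuffle(parts)
            state = play(small_net.n_vertices, parts)
            assert state.total_free == ref.total_free
            assert state.redundant == ref.redundant
            assert rigid_clusters(state).canonical() == ref_dec.canonical()

    def test_vpg_at_limits_equals_pg(self, small_net):
        all_present = realize(small_net, 1.0, seed=0)
        none_present = realize(small_net, 0.0, seed=0)
        assert (
            run_game(small_net, "vpg", p=1.0).internal_dof
            == run_game(all_present, "pg").internal_dof
        )
        assert (
            run_game(small_net, "vpg", p=0.0).internal_dof
            == run_game(none_present, "pg").internal_dof
        )

    def test_vpg_monotone_nonincreasing_in_p(self, small_net):
        curve = [
            run_game(small_net, "vpg", p=p, compute_clusters=False).internal_dof
            for p in np.linspace(0, 1, 21)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(curve, curve[1:]))

    def test_maxwell_counting_is_lower_bound(self, small_net):
        for seed in range(10):
            real = realize(small_net, 0.5, seed=seed)
            constraints = sum(real.present_bars)
            res = run_game(real, "pg", compute_clusters=False)
            assert res.internal_dof >= mcc_dof(6, constraints).dof - 1e-12

    def test_vpg_below_exact_ensemble_mean(self, small_net):
        # observed (conjectured) lower-bound property of the mean-field game
        for p in (0.3, 0.5, 0.8):
            exact = sum(
                w * run_game(r, "pg", compute_clusters=False).internal_dof
                for r, w in enumerate_realizations(small_net, p)
            )
            vpg = run_game(small_net, "vpg", p=p, compute_clusters=False).internal_dof
            assert vpg <= exact + 1e-9


class TestRigidClusters:
    def test_no_edges_all_singletons(self):
        state = init_state(5)
        dec = rigid_clusters(state)
        assert dec.n_clusters == 5
        assert set(dec.sizes) == {1}

    def test_six_covered_pair_is_one_cluster(self):
        state = play(2, [(0, 1, 6 * UNIT)])
        assert rigid_clusters(state).n_clusters == 1

    def test_partially_covered_pair_stays_split(self):
        state = play(2, [(0, 1, 4 * UNIT)])
        assert rigid_clusters(state).n_clusters == 2
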