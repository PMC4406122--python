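"""Ensemble drivers: averaged pebble games, deterministic VPG sweeps,
incremental ("bootstrapped") p-sweeps and the VPG rigidity-threshold locator.

The exact route to an ensemble average runs the integer pebble game on many
sampled constraint topologies and averages; the virtual pebble game replaces
the whole ensemble with one deterministic run per ``p``, so its entries carry
zero sampling error by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .engine import SIX, UNIT, GameResult, PebbleState, place_edge, rigid_clusters, run_game
from .mcc import expected_constraints, mcc_dof
from .network import FLUCTUATING, BodyBarNetwork, Realization, realize

__all__ = [
    "EnsembleSummary",
    "ensemble_average",
    "sweep_p",
    "vpg_rigidity_threshold",
]

Mode = Literal["cooperative", "per_bar"]


@dataclass
class EnsembleSummary:
    """Aggregated per-p curves for one or more methods.

    ``table`` has one row per (method, p) with columns ``F_mean``, ``F_sd``,
    ``f_per_vertex`` (= F_mean / N), ``acs_mean``, ``acs_sd``, ``rcs_mean``,
    ``rcs_sd`` and ``n_samples``.  Deterministic methods (vpg, mcc) carry
    zero standard deviations.  ``correlated`` flags incremental pebble-game
    sweeps, whose successive p values share constraint placements.
    """

    table: pd.DataFrame
    n_vertices: int
    seed: int | None = None
    correlated: bool = False

    def curve(self, method: str, column: str = "F_mean") -> tuple[np.ndarray, np.ndarray]:
        sub = self.table[self.table["method"] == method].sort_values("p")
        return sub["p"].to_numpy(), sub[column].to_numpy()


def _summarize(values: Sequence[float | None]) -> tuple[float, float]:
    vals = [v for v in values if v is not None]
    if not vals:
        return float("nan"), float("nan")
    arr = np.asarray(vals, float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def ensemble_average(
    net: BodyBarNetwork,
    p: float,
    n_samples: int,
    mode: Mode = "cooperative",
    seed: int | np.random.SeedSequence = 0,
    compute_clusters: bool = True,
) -> tuple[list[GameResult], dict[str, float]]:
    """Run the exact pebble game on ``n_samples`` independent realizations.

    One child random stream per sample is spawned from the master seed, so
    any sample can be replayed in isolation.  Returns the per-sample results
    and a summary dict (mean/SD of internal DOF, and of ACS/RCS when cluster
    decompositions are computed).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n_samples)
    results: list[GameResult] = []
    for child in streams:
        real = realize(net, p, mode=mode, seed=np.random.default_rng(child))
        results.append(run_game(real, mode="pg", compute_clusters=compute_clusters))
    f_mean, f_sd = _summarize([r.internal_dof for r in results])
    summary = {"F_mean": f_mean, "F_sd": f_sd, "n_samples": float(n_samples)}
    if compute_clusters:
        summary["acs_mean"], summary["acs_sd"] = _summarize(
            [_metrics.acs(r.clusters) for r in results]
        )
        summary["rcs_mean"], summary["rcs_sd"] = _summarize(
            [_metrics.rcs(r.clusters) for r in results]
        )
    return results, summary


def _state_stats(state: PebbleState, n: int, compute_clusters: bool) -> dict[str, float]:
    f = (state.total_free - SIX) / UNIT
    row = {"F_mean": f, "F_sd": 0.0}
    if compute_clusters:
        dec = rigid_clusters(state)
        row["acs_mean"], row["acs_sd"] = _metrics.acs(dec), 0.0
        r = _metrics.rcs(dec)
        row["rcs_mean"], row["rcs_sd"] = (np.nan if r is None else r), 0.0
    return row


def _vpg_capacity(bars: int, p: float) -> int:
    return round(bars * p * UNIT)


def sweep_p(
    net: BodyBarNetwork,
    p_grid: Sequence[float],
    methods: Sequence[str] = ("pg", "vpg", "mcc"),
    n_samples: int = 100,
    incremental: bool = False,
    seed: int = 0,
    compute_clusters: bool = True,
) -> EnsembleSummary:
    """Sweep the fluctuating-edge probability for several methods.

    Methods: ``pg`` (cooperative ensemble average), ``barpg`` (per-bar
    ensemble average), ``vpg`` (one deterministic run per p), ``mcc``
    (closed-form Maxwell line from the network's expected constraints).

    ``incremental=True`` builds constraint density up without restarting:
    the pebble game keeps its state and adds the edges that newly become
    present at each p (which correlates successive rows — flagged in the
    summary); the VPG increments every fluctuating capacity in place, which
    by path independence is identical to restarting at every p.
    """
    p_grid = list(p_grid)
    if incremental and sorted(p_grid) != p_grid:
        raise ValueError("incremental sweeps need an ascending p grid")
    rows: list[dict] = []
    ss = np.random.SeedSequence(seed)
    for method in methods:
        if method in ("pg", "barpg"):
            mode: Mode = "cooperative" if method == "pg" else "per_bar"
            if incremental:
                rows.extend(
                    _incremental_pg_rows(
                        net, p_grid, mode, n_samples, ss.spawn(1)[0], compute_clusters
                    )
                )
            else:
                for p in p_grid:
                    _, summ = ensemble_average(
                        net, p, n_samples, mode, ss.spawn(1)[0], compute_clusters
                    )
                    rows.append({"method": method, "p": p, **summ})
            continue
        if method == "vpg":
            if incremental:
                rows.extend(_incremental_vpg_rows(net, p_grid, compute_clusters))
            else:
                for p in p_grid:
                    res = run_game(net, mode="vpg", p=p, compute_clusters=compute_clusters)
                    row = {"method": "vpg", "p": p, "F_mean": res.internal_dof,
                           "F_sd": 0.0, "n_samples": 1.0}
                    if compute_clusters:
                        row["acs_mean"], row["acs_sd"] = _metrics.acs(res.clusters), 0.0
                        r = _metrics.rcs(res.clusters)
                        row["rcs_mean"] = np.nan if r is None else r
                        row["rcs_sd"] = 0.0
                    rows.append(row)
            continue
        if method == "mcc":
            for p in p_grid:
                est = mcc_dof(net.n_vertices, expected_constraints(net, p))
                rows.append({"method": "mcc", "p": p, "F_mean": est.dof,
                             "F_sd": 0.0, "n_samples": 1.0})
            continue
        raise ValueError(f"unknown method {method!r}")
    table = pd.DataFrame(rows)
    table["f_per_vertex"] = table["F_mean"] / net.n_vertices
    return EnsembleSummary(table, net.n_vertices, seed=seed,
                           correlated=incremental and any(m in ("pg", "barpg") for m in methods))


def _incremental_pg_rows(
    net: BodyBarNetwork,
    p_grid: Sequence[float],
    mode: Mode,
    n_samples: int,
    seed: np.random.SeedSequence,
    compute_clusters: bool,
) -> list[dict]:
    """Bootstrapped sweep: each sample adds random fluctuating edges (or bars,
    in per-bar mode) as p grows, continuing from the previous state."""
    fluct = [e for e in net.edges if e.kind == FLUCTUATING]
    n_units = (
        len(fluct) if mode == "cooperative" else sum(e.bars for e in fluct)
    )
    per_sample: dict[float, list[float]] = {p: [] for p in p_grid}
    method = "pg" if mode == "cooperative" else "barpg"
    for child in seed.spawn(n_samples):
        rng = np.random.default_rng(child)
        if mode == "cooperative":
            order = [(e.u, e.v, e.bars * UNIT) for e in fluct]
        else:
            order = [(e.u, e.v, UNIT) for e in fluct for _ in range(e.bars)]
        rng.shuffle(order)
        state = PebbleState(net.n_vertices)
        for e in net.quenched_edges:
            place_edge(state, e.u, e.v, e.bars * UNIT)
        placed = 0
        for p in p_grid:
            k = round(p * n_units)
            while placed < k:
                u, v, cap = order[placed]
                place_edge(state, u, v, cap)
                placed += 1
            per_sample[p].append((state.total_free - SIX) / UNIT)
    rows = []
    for p in p_grid:
        mean, sd = _summarize(per_sample[p])
        rows.append({"method": method, "p": p, "F_mean": mean, "F_sd": sd,
                     "n_samples": float(n_samples)})
    return rows


def _incremental_vpg_rows(
    net: BodyBarNetwork, p_grid: Sequence[float], compute_clusters: bool
) -> list[dict]:
    state = PebbleState(net.n_vertices)
    for e in net.quenched_edges:
        place_edge(state, e.u, e.v, e.bars * UNIT)
    prev = {i: 0 for i, e in enumerate(net.edges) if e.kind == FLUCTUATING}
    rows = []
    for p in p_grid:
        for i in prev:
            e = net.edges[i]
            cap = _vpg_capacity(e.bars, p)
            delta = cap - prev[i]
            if delta > 0:
                place_edge(state, e.u, e.v, delta)
                prev[i] = cap
        row = {"method": "vpg", "p": p, "n_samples": 1.0,
               **_state_stats(state, net.n_vertices, compute_clusters)}
        rows.append(row)
    return rows


def vpg_rigidity_threshold(
    net: BodyBarNetwork, dp: float = 0.001
) -> float | None:
    """First p on the grid ``{0, dp, 2 dp, ...}`` where the VPG counts zero
    internal DOF.

    The VPG internal DOF is non-increasing in p, so the grid is bisected;
    the result is identical to an exhaustive ascending scan at step ``dp``.
    Returns None when the network is still flexible at p = 1.
    """

    def dof_units(p: float) -> int:
        res = run_game(net, mode="vpg", p=p, compute_clusters=False)
        return res.state.total_free - SIX

    n_steps = int(round(1.0 / dp))
    if dof_units(1.0) > 0:
        return None
    lo, hi = 0, n_steps  # F(lo*dp) > 0 (unless rigid at 0), F(hi*dp) == 0
    if dof_units(0.0) == 0:
        return 0.0
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if dof_units(mid * dp) == 0:
            hi = mid
        else:
            lo = mid
    return hi * dp
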