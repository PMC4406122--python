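"""Maxwell constraint counting (MCC): the global mean-field DOF estimate.

MCC subtracts the expected number of constraints and the 6 trivial
rigid-body motions from the 6N available degrees of freedom,

    F_MCC = max(6 N - <C> - 6, 0),

and is a rigorous lower bound on the internal DOF of every realization-level
pebble-game result.  On a periodic disordered lattice with 5 bars per edge
the expected constraint count is 5 d L^d (q_fix + p * q_fluct), and setting
F_MCC = 0 defines the Maxwell rigidity threshold p*.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import FLUCTUATING, BodyBarNetwork, LatticeSpec

__all__ = ["MccResult", "expected_constraints", "mcc_dof", "mcc_lattice_dof", "mcc_threshold"]


@dataclass(frozen=True)
class MccResult:
    """Clamped estimate plus the raw balance (negative = redundant count)."""

    dof: float  # max(6N - C - 6, 0)
    unclamped: float  # 6N - C - 6; when negative, |value| counts redundancies


def expected_constraints(net: BodyBarNetwork, p: float | None = None) -> float:
    """Mean number of bars present: sum of bars * presence probability."""
    total = 0.0
    for e in net.edges:
        pe = 1.0 if e.kind != FLUCTUATING else (e.p if p is None else p)
        total += e.bars * pe
    return total


def mcc_dof(n_vertices: int, constraints: float) -> MccResult:
    """Maxwell estimate for ``n_vertices`` bodies and ``constraints`` bars."""
    if constraints < 0:
        raise ValueError("expected constraint count must be >= 0")
    raw = 6 * n_vertices - constraints - 6
    return MccResult(max(raw, 0.0), raw)


def mcc_lattice_dof(spec: LatticeSpec, p: float) -> MccResult:
    """Closed form on the periodic lattice: 6L^d - 5dL^d(q_fix + p q_fluct) - 6."""
    n = spec.n_vertices
    constraints = spec.bars * spec.d * n * (spec.q_fix + p * spec.q_fluct)
    return mcc_dof(n, constraints)


def mcc_threshold(spec: LatticeSpec) -> float:
    """Maxwell rigidity threshold p*: the p solving F_MCC = 0, clamped to [0, 1].

    Undefined when there are no fluctuating edges (``q_fluct = 0``); raises.
    """
    if spec.q_fluct <= 0:
        raise ValueError("threshold undefined for q_fluct = 0 (no fluctuating edges)")
    n = spec.n_vertices
    p_star = (6 * n - 6 - spec.bars * spec.d * n * spec.q_fix) / (
        spec.bars * spec.d * n * spec.q_fluct
    )
    return min(max(p_star, 0.0), 1.0)
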