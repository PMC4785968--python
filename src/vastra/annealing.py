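"""Simulated annealing over arterial tree configurations.

Two moves span the whole configuration space: translating any non-root
node (bifurcation or terminal) by an isotropic Gaussian step, and
swapping the parent attachments of two non-root nodes (rejected when one
is an ancestor of the other, which would close a loop).  Performed
consecutively these reach every labelled topology — there are
``(2n-3)!!`` of them for ``n`` terminals — so the chain is ergodic.

Acceptance follows the Metropolis rule: downhill always, uphill with
probability ``exp(-dC_T / T)``; the temperature anneals geometrically
from ``T_initial`` (1e10) to ``T_final`` (1e-5).  Because the supply
weight is effectively a constraint, the supply term decides acceptance
by downhill search whenever it changes, while the remaining costs are
annealed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costs import CostState, CostWeights, Move
from .substrate import (
    DistanceMap,
    PerfusionParams,
    SupplyMap,
    TissueSubstrate,
    compute_distance_map,
    paint_supply,
)
from .tree import BIFURCATION, ROOT, TERMINAL, ArterialTree, assign_radii

__all__ = [
    "Schedule",
    "AnnealState",
    "AnnealResult",
    "acceptance_probability",
    "temperature_at",
    "propose_translation",
    "propose_swap",
    "anneal",
    "ergodicity_check",
    "count_labelled_topologies",
]


@dataclass(frozen=True)
class Schedule:
    """Geometric cooling schedule and proposal-width annealing.

    ``T_k = T_initial * (T_final/T_initial)^(k/n_updates)``.  The
    translation step scale anneals the same way between
    ``sigma_max_factor`` and ``sigma_min_factor`` times the supply
    radius.  ``p_translation`` is the probability of proposing a
    translation rather than a parent swap.
    """

    n_updates: int
    T_initial: float = 1e10
    T_final: float = 1e-5
    cooling: str = "geometric"
    p_translation: float = 0.5
    sigma_max_factor: float = 2.0
    sigma_min_factor: float = 0.1
    move_terminals: bool = True

    def __post_init__(self):
        if not (self.T_initial > self.T_final > 0):
            raise ValueError("need T_initial > T_final > 0")
        if self.n_updates < 0:
            raise ValueError("n_updates must be non-negative")
        if self.cooling != "geometric":
            raise ValueError("only geometric cooling is implemented")


def temperature_at(schedule: Schedule, k: int) -> float:
    frac = k / max(schedule.n_updates, 1)
    return schedule.T_initial * (schedule.T_final / schedule.T_initial) ** frac


def _sigma_at(schedule: Schedule, k: int, R_supply: float) -> float:
    frac = k / max(schedule.n_updates, 1)
    return R_supply * (
        schedule.sigma_max_factor
        * (schedule.sigma_min_factor / schedule.sigma_max_factor) ** frac
    )


def acceptance_probability(delta_C: float, T: float) -> float:
    """Metropolis rule: 1 for downhill, ``exp(-dC/T)`` for uphill."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta_C <= 0:
        return 1.0
    x = -delta_C / T
    if x < -745.0:  # exp underflow
        return 0.0
    return math.exp(x)


def propose_translation(
    tree: ArterialTree,
    substrate: TissueSubstrate,
    rng: np.random.Generator,
    sigma: float,
    move_terminals: bool = True,
) -> Move | None:
    """Gaussian displacement of a uniformly chosen non-root node.

    Returns None (a rejected proposal) when the chosen displacement
    would put a terminal outside the tissue or any node outside the
    grid; both rejections are position-symmetric so proposal symmetry
    P(x -> x') = P(x' -> x) is preserved.
    """
    if move_terminals:
        movable = np.flatnonzero(tree.kind != ROOT)
    else:
        movable = np.flatnonzero((tree.kind != ROOT) & (tree.kind != TERMINAL))
    if len(movable) == 0:
        return None
    node = int(movable[rng.integers(len(movable))])
    step = rng.normal(0.0, sigma, size=3)
    new_pos = tree.positions[node] + step
    lo, hi = substrate.bbox
    if np.any(new_pos < lo) or np.any(new_pos >= hi):
        return None
    if tree.kind[node] == TERMINAL and not substrate.is_tissue_point(new_pos):
        return None
    return Move("translate", node=node, new_position=new_pos)


def propose_swap(tree: ArterialTree, rng: np.random.Generator) -> Move | None:
    """Uniform unordered pair of distinct non-root nodes to parent-swap."""
    nodes = np.flatnonzero(tree.kind != ROOT)
    if len(nodes) < 2:
        return None
    i, j = rng.choice(len(nodes), size=2, replace=False)
    return Move("swap", a=int(nodes[i]), b=int(nodes[j]))


@dataclass
class AnnealState:
    """Mutable annealing state (useful for checkpointing / inspection)."""

    cost_state: CostState
    schedule: Schedule
    step: int
    T: float
    best_key: tuple
    best_tree: ArterialTree
    rng: np.random.Generator


@dataclass
class AnnealResult:
    best_tree: ArterialTree
    final_tree: ArterialTree
    best_breakdown: "object"
    trace: pd.DataFrame
    n_proposed: int
    n_accepted: int
    n_illegal: int


def anneal(
    tree: ArterialTree,
    substrate: TissueSubstrate,
    perfusion: PerfusionParams,
    schedule: Schedule,
    seed: int | np.random.Generator = 0,
    weights: CostWeights = CostWeights(),
    distance_map: DistanceMap | None = None,
    supply_map: SupplyMap | None = None,
    trace_every: int | None = None,
) -> AnnealResult:
    """Run the Metropolis chain and return the best tree encountered.

    The input tree is optimized in place (the returned ``final_tree`` is
    the same object); ``best_tree`` is a copy of the lowest-cost
    configuration seen, compared lexicographically on
    ``(C_s, weighted rest)``.  Identical (seed, inputs) replay exactly.
    A zero-update budget returns the input unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if distance_map is None:
        distance_map = compute_distance_map(substrate)
    if supply_map is None:
        supply_map = paint_supply(
            substrate, tree.positions[tree.terminal_ids], perfusion.R_supply
        )
    state = CostState(tree, substrate, distance_map, supply_map, weights)
    best_key = state.cost_key()
    best_tree = tree.copy()
    best_breakdown = state.breakdown()

    if trace_every is None:
        trace_every = max(1, schedule.n_updates // 200)
    rows = []

    def record(k, T):
        b = state.breakdown()
        rows.append(
            (k, T, b.C_v, b.C_w, b.C_s, b.C_o, b.C_p, b.C_T, best_key[0], best_key[1])
        )

    n_acc = n_illegal = 0
    record(0, schedule.T_initial)
    for k in range(schedule.n_updates):
        T = temperature_at(schedule, k)
        if rng.random() < schedule.p_translation:
            move = propose_translation(
                tree, substrate, rng, _sigma_at(schedule, k, perfusion.R_supply),
                schedule.move_terminals,
            )
        else:
            move = propose_swap(tree, rng)
        if move is None:
            n_illegal += 1
            continue
        applied = state.apply_move(move)
        if applied is None:  # loop-forming swap, counts against the budget
            n_illegal += 1
            continue
        delta_eff = weights.A_s * applied.d_Cs + applied.d_rest
        if delta_eff <= 0 or rng.random() < acceptance_probability(delta_eff, T):
            n_acc += 1
            key = state.cost_key()
            if key < best_key:
                best_key = key
                best_tree = tree.copy()
                best_breakdown = state.breakdown()
        else:
            state.revert_move(applied)
        if (k + 1) % trace_every == 0:
            record(k + 1, T)

    assign_radii(tree)
    assign_radii(best_tree)
    trace = pd.DataFrame(
        rows,
        columns=[
            "step", "T", "C_v", "C_w", "C_s", "C_o", "C_p", "C_T",
            "best_C_s", "best_rest",
        ],
    )
    return AnnealResult(
        best_tree=best_tree,
        final_tree=tree,
        best_breakdown=best_breakdown,
        trace=trace,
        n_proposed=schedule.n_updates,
        n_accepted=n_acc,
        n_illegal=n_illegal,
    )


# ---------------------------------------------------------------------------
# topology-space ergodicity


def count_labelled_topologies(n_terminals: int) -> int:
    """(2n-3)!! rooted binary topologies on n labelled terminals."""
    if n_terminals < 1:
        raise ValueError("need at least one terminal")
    out = 1
    for m in range(2 * n_terminals - 3, 1, -2):
        out *= m
    return out


def _swap_parents_topology(tree: ArterialTree, a: int, b: int) -> bool:
    """Pointer-only parent swap used for topology enumeration."""
    if a == b or tree.parent[a] < 0 or tree.parent[b] < 0:
        return False
    if tree.is_ancestor(a, b) or tree.is_ancestor(b, a):
        return False
    pa, pb = int(tree.parent[a]), int(tree.parent[b])
    for p, old, new in ((pa, a, b), (pb, b, a)):
        row = tree.children[p]
        row[np.flatnonzero(row == old)[0]] = new
    tree.parent[a] = pb
    tree.parent[b] = pa
    return True


def _canonical_topology(tree: ArterialTree):
    def canon(node: int):
        kids = tree.child_list(node)
        if not kids:
            return int(node)
        if len(kids) == 1:
            return canon(kids[0])
        return frozenset((canon(kids[0]), canon(kids[1])))

    return tuple(canon(int(r)) for r in sorted(tree.root_ids))


def _caterpillar_tree(n_terminals: int) -> ArterialTree:
    """Maximally unbalanced single-root tree on synthetic positions."""
    M = 2 * n_terminals
    positions = np.zeros((M, 3))
    positions[:, 0] = np.arange(M, dtype=float)
    parent = np.full(M, -1, dtype=np.int64)
    kind = np.zeros(M, dtype=np.uint8)
    children = np.full((M, 2), -1, dtype=np.int64)
    kind[0] = ROOT
    terminals = list(range(1, n_terminals + 1))
    bifs = list(range(n_terminals + 1, M))
    for t in terminals:
        kind[t] = TERMINAL
    for bnode in bifs:
        kind[bnode] = BIFURCATION
    if n_terminals == 1:
        parent[1] = 0
        children[0, 0] = 1
    else:
        spine = bifs
        children[0, 0] = spine[0]
        parent[spine[0]] = 0
        for i, bnode in enumerate(spine):
            left = terminals[i]
            right = spine[i + 1] if i + 1 < len(spine) else terminals[i + 1]
            children[bnode] = (left, right)
            parent[left] = bnode
            parent[right] = bnode
    t = ArterialTree(positions=positions, parent=parent, kind=kind, children=children)
    t.recompute_subtree_counts()
    return t


def ergodicity_check(n_terminals: int) -> int:
    """Number of distinct labelled topologies reachable by parent swaps.

    Breadth-first closure of the swap move from a caterpillar start; for
    an ergodic move set this equals ``(2n-3)!!``.  Intended for small n
    (<= 6): the topology count grows double-factorially.
    """
    if n_terminals > 6:
        raise ValueError("enumeration limited to n_terminals <= 6")
    start = _caterpillar_tree(n_terminals)
    seen = {_canonical_topology(start)}
    frontier = [start]
    non_root = [int(i) for i in np.flatnonzero(start.kind != ROOT)]
    while frontier:
        cur = frontier.pop()
        for ai in range(len(non_root)):
            for bi in range(ai + 1, len(non_root)):
                nxt = cur.copy()
                if not _swap_parents_topology(nxt, non_root[ai], non_root[bi]):
                    continue
                key = _canonical_topology(nxt)
                if key not in seen:
                    seen.add(key)
                    frontier.append(nxt)
    return len(seen)
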