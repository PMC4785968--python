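"""Scripted computational experiments at configurable scale.

Two sweeps mirror the method's validation workflow: growing trees of
increasing terminal count (morphometry converges towards anatomy as
size grows, with the update budget scaled quadratically in size), and
varying the metabolic constant ``m_b`` (small ``m_b`` favours long
winding trunks, large ``m_b`` short straight symmetric ones; rescaling
``m_b`` by ``A^6`` is equivalent to rescaling all lengths by ``A``).

Defaults are desk-scale (tens to hundreds of terminals, 1e5-1e7
updates); ``PAPER_SCALE`` records the full published regime (6000
terminals, ~1e10 updates) for cluster runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import element_stats, strahler_orders
from .annealing import Schedule, anneal
from .costs import CostWeights
from .substrate import PerfusionParams, TissueSubstrate, compute_distance_map
from .tree import ArterialTree, random_tree

__all__ = ["PAPER_SCALE", "SweepResult", "size_sweep", "mb_sweep", "trunk_tortuosity"]

#: Published full-scale regime (not intended for interactive use).
PAPER_SCALE = {"n_terminals": 6000, "n_updates": int(4e10 / 4), "n_roots": 2}


@dataclass
class SweepResult:
    key: float
    best_cost_key: tuple
    tree: ArterialTree
    order_table: pd.DataFrame
    seed: int
    extras: dict


def _default_roots(substrate: TissueSubstrate, n_roots: int) -> np.ndarray:
    lo, hi = substrate.bbox
    center = 0.5 * (lo + hi)
    top = hi[2] - substrate.voxel_size
    if n_roots == 1:
        return np.array([[center[0], center[1], top]])
    off = 0.25 * (hi[0] - lo[0])
    return np.array(
        [[center[0] - off, center[1], top], [center[0] + off, center[1], top]]
    )


def _run_one(
    substrate,
    n_terminals,
    n_updates,
    seed,
    weights,
    demand_ml_min_g,
    Q0_total,
    n_roots,
    dmap,
):
    if Q0_total is None:
        perf = PerfusionParams.for_substrate(
            substrate, n_terminals, demand_ml_min_g=demand_ml_min_g
        )
    else:
        perf = PerfusionParams.from_physiology(
            n_terminals, Q0_total=Q0_total, demand_ml_min_g=demand_ml_min_g
        )
    tree = random_tree(
        substrate, n_terminals, _default_roots(substrate, n_roots), seed,
        Q0_total=perf.Q0_total,
    )
    sched = Schedule(n_updates=n_updates)
    return anneal(
        tree, substrate, perf, sched, seed=seed, weights=weights, distance_map=dmap
    )


def size_sweep(
    substrate: TissueSubstrate,
    terminal_counts: list[int],
    seeds: list[int] = (0, 1, 2),
    base_updates: int = 200_000,
    weights: CostWeights = CostWeights(),
    demand_ml_min_g: float = 1.13,
    Q0_total: float | None = None,
    n_roots: int = 1,
) -> dict[int, SweepResult]:
    """Anneal one tree per terminal count, keeping the best seed per size.

    The update budget scales with the square of the terminal count
    (doubling the node count costs roughly four times the updates):
    ``n_updates = base_updates * (n / counts[0])^2``.  Among repeated
    seeds the lowest-cost run is reported.
    """
    if list(terminal_counts) != sorted(terminal_counts):
        raise ValueError("terminal counts must be ascending")
    dmap = compute_distance_map(substrate)
    out: dict[int, SweepResult] = {}
    n0 = terminal_counts[0]
    for n in terminal_counts:
        n_updates = int(base_updates * (n / n0) ** 2)
        best = None
        for seed in seeds:
            res = _run_one(
                substrate, n, n_updates, seed, weights, demand_ml_min_g, Q0_total, n_roots, dmap
            )
            key = (res.best_breakdown.C_s, res.best_breakdown.C_T_rescaled)
            if best is None or key < best[0]:
                best = (key, res, seed)
        key, res, seed = best
        tbl = element_stats(res.best_tree, strahler_orders(res.best_tree))
        out[n] = SweepResult(
            key=n,
            best_cost_key=key,
            tree=res.best_tree,
            order_table=tbl,
            seed=seed,
            extras={"n_updates": n_updates, "n_accepted": res.n_accepted},
        )
    return out


def trunk_tortuosity(tree: ArterialTree) -> float:
    """Path length / straight span of the largest-radius root-to-leaf path.

    A proxy for how much the main trunk winds around the tissue: 1 for a
    perfectly straight trunk, larger when it meanders.
    """
    from .tree import assign_radii

    if tree.radius is None:
        assign_radii(tree)
    node = int(tree.root_ids[0])
    path_len = 0.0
    start = tree.positions[node]
    while True:
        kids = tree.child_list(node)
        if not kids:
            break
        nxt = max(kids, key=lambda c: tree.radius[c])
        path_len += float(np.linalg.norm(tree.positions[nxt] - tree.positions[node]))
        node = int(nxt)
    span = float(np.linalg.norm(tree.positions[node] - start))
    return path_len / max(span, 1e-300)


def mb_sweep(
    substrate: TissueSubstrate,
    mb_values: list[float],
    seed: int = 0,
    n_terminals: int = 60,
    n_updates: int = 150_000,
    weights: CostWeights = CostWeights(),
    demand_ml_min_g: float = 1.13,
    Q0_total: float | None = None,
) -> dict[float, SweepResult]:
    """Optimize one tree per metabolic constant ``m_b`` (J s^-1 m^-3).

    Reports the trunk-tortuosity proxy and the high-order symmetry
    ratios: small ``m_b`` yields winding trunks with asymmetric
    branching, large ``m_b`` straight trunks with symmetric branching.
    """
    if any(m <= 0 for m in mb_values):
        raise ValueError("m_b values must be positive")
    dmap = compute_distance_map(substrate)
    out: dict[float, SweepResult] = {}
    for mb in mb_values:
        w = CostWeights(
            A_wv=weights.A_wv,
            A_o=weights.A_o,
            A_p=weights.A_p,
            A_s=weights.A_s,
            m_b=mb,
            R_cutoff=weights.R_cutoff,
            excl_length_scale=weights.excl_length_scale,
        )
        res = _run_one(
            substrate, n_terminals, n_updates, seed, w, demand_ml_min_g, Q0_total, 1, dmap
        )
        tbl = element_stats(res.best_tree, strahler_orders(res.best_tree))
        top = tbl.tail(2)
        out[mb] = SweepResult(
            key=mb,
            best_cost_key=(res.best_breakdown.C_s, res.best_breakdown.C_T_rescaled),
            tree=res.best_tree,
            order_table=tbl,
            seed=seed,
            extras={
                "tortuosity": trunk_tortuosity(res.best_tree),
                "top_order_Ds_over_Dp": float(top["Ds_over_Dp"].mean()),
            },
        )
    return out
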