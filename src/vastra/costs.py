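"""Energetic cost terms for arterial trees and their incremental evaluation.

The total cost of a tree is

    C_T = A_wv (C_w + C_v) + A_o C_o + A_p C_p + A_s C_s

with C_v the metabolic cost of maintaining the blood volume
(``m_b * V_tree``), C_w the total Poiseuille pumping power
(``sum Q_i^2 R_i``), C_s the tissue-supply penalty (10 per unsupplied
voxel, ``(b-1)^2`` per voxel covered ``b`` times), C_o the exclusion
penalty that keeps vessels wider than ``R_cutoff`` out of the tissue
bulk, and C_p an optional terminal-pressure-uniformity penalty (weight
zero by default).

The supply weight ``A_s = 1e30`` is so large that any change in C_s
decides acceptance on its own; deltas are therefore tracked as the pair
``(dC_s, d_rest)`` with C_s kept in exact integer arithmetic, which is
numerically identical to the literal weighted sum but immune to the
loss of precision when adding O(1e30) and O(1e4) terms.

The exclusion integrand ``(D * Lt)^6`` is evaluated with distances in
millimetres (configurable via ``excl_length_scale``): at this scale the
per-voxel terms are O(1)-O(1e6), which is what makes the modest weight
``A_o = 100`` act as a near-constraint; in metres the sixth power would
flush the whole term to ~1e-30 and the penalty could never steer the
optimization.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np

from .substrate import DistanceMap, SupplyMap, TissueSubstrate
from .tree import TERMINAL, ArterialTree, assign_radii, compute_pressures, segment_resistance

__all__ = [
    "CostWeights",
    "CostBreakdown",
    "metabolic_cost",
    "pumping_cost",
    "supply_cost",
    "pressure_cost",
    "exclusion_cost",
    "total_cost",
    "reduced_segment_cost",
    "traverse_segment_voxels",
    "CostState",
    "Move",
    "delta_cost",
]


@dataclass(frozen=True)
class CostWeights:
    """Weights and constants of the total cost function.

    ``m_b`` is the metabolic power cost per unit blood volume in
    J s^-1 m^-3; ``R_cutoff`` (m) is the radius above which a vessel may
    not penetrate tissue; ``excl_length_scale`` converts metres to the
    length unit used inside the exclusion integrand (1e3 = millimetres).
    """

    A_wv: float = 1e4
    A_o: float = 100.0
    A_p: float = 0.0
    A_s: float = 1e30
    m_b: float = 641.3
    R_cutoff: float = 0.01e-3
    excl_length_scale: float = 1e3
    P_term: float = 0.0

    def __post_init__(self):
        for name in ("A_wv", "A_o", "A_p", "A_s", "m_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CostBreakdown:
    C_v: float
    C_w: float
    C_s: int
    C_o: float
    C_p: float
    C_T: float
    C_T_rescaled: float
    V_tree: float
    W_total: float


def metabolic_cost(tree: ArterialTree, m_b: float) -> float:
    """``C_v = m_b * V_tree`` with ``V_tree = sum pi r^2 L`` (W)."""
    if tree.radius is None:
        assign_radii(tree)
    seg = tree.segment_ids
    L = tree.segment_lengths()[seg]
    return m_b * float(np.sum(np.pi * tree.radius[seg] ** 2 * L))


def pumping_cost(tree: ArterialTree) -> float:
    """Total pumping power ``C_w = sum Q_i^2 R_i`` (W)."""
    seg = tree.segment_ids
    Q = tree.segment_flows()[seg]
    R = tree.segment_resistances()[seg]
    return float(np.sum(Q**2 * R))


def _supply_penalty(b: np.ndarray) -> np.ndarray:
    """Per-voxel supply penalty: 10 where unsupplied, else (b-1)^2."""
    b = np.asarray(b, dtype=np.int64)
    return np.where(b == 0, 10, (b - 1) ** 2)


def supply_cost(supply_map: SupplyMap, substrate: TissueSubstrate) -> int:
    """Sum of the supply penalty over tissue voxels (exact integer)."""
    b = supply_map.counts[substrate.occupancy]
    return int(_supply_penalty(b).sum())


def pressure_cost(terminal_pressures: np.ndarray, P_term: float) -> float:
    """Sum of squared terminal-pressure deviations from ``P_term``."""
    p = np.asarray(terminal_pressures, dtype=float)
    return float(np.sum((p - P_term) ** 2))


def traverse_segment_voxels(
    p0: np.ndarray,
    p1: np.ndarray,
    shape: tuple[int, int, int],
    voxel_size: float,
    origin: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact voxel ray-march of the segment centre-line (Amanatides-Woo).

    Returns ``(indices, lengths)`` where ``indices`` is (K, 3) integer
    voxel coordinates pierced by the open segment ``p0 -> p1`` (clipped
    to the grid) and ``lengths[k]`` is the in-voxel path length (m).
    The in-grid lengths sum to the in-grid portion of the segment.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    L = float(np.linalg.norm(d))
    if L == 0.0:
        return np.empty((0, 3), dtype=np.int64), np.empty(0)
    lo = np.asarray(origin, dtype=float)
    hi = lo + np.asarray(shape) * voxel_size
    # clip parametric range [t0, t1] to the grid box (slab method)
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if d[ax] == 0.0:
            if not (lo[ax] <= p0[ax] < hi[ax]):
                return np.empty((0, 3), dtype=np.int64), np.empty(0)
        else:
            ta = (lo[ax] - p0[ax]) / d[ax]
            tb = (hi[ax] - p0[ax]) / d[ax]
            if ta > tb:
                ta, tb = tb, ta
            t0 = max(t0, ta)
            t1 = min(t1, tb)
    if t0 >= t1:
        return np.empty((0, 3), dtype=np.int64), np.empty(0)

    # all parametric boundary crossings per axis, merged and sorted
    # (vectorized equivalent of stepping voxel-by-voxel)
    cuts = [np.array([t0, t1])]
    for ax in range(3):
        if d[ax] == 0.0:
            continue
        a0 = (p0[ax] + t0 * d[ax] - lo[ax]) / voxel_size
        a1 = (p0[ax] + t1 * d[ax] - lo[ax]) / voxel_size
        first = np.ceil(min(a0, a1))
        last = np.floor(max(a0, a1))
        if last < first:
            continue
        planes = lo[ax] + np.arange(first, last + 1) * voxel_size
        cuts.append((planes - p0[ax]) / d[ax])
    t_all = np.unique(np.concatenate(cuts))
    t_all = t_all[(t_all >= t0) & (t_all <= t1)]
    if len(t_all) < 2:
        t_all = np.array([t0, t1])
    mids = 0.5 * (t_all[:-1] + t_all[1:])
    lengths = np.diff(t_all) * L
    keep = lengths > 0
    mids, lengths = mids[keep], lengths[keep]
    pts = p0[None, :] + mids[:, None] * d[None, :]
    idx = np.floor((pts - lo[None, :]) / voxel_size).astype(np.int64)
    np.clip(idx, 0, np.asarray(shape) - 1, out=idx)
    return idx, lengths


def _segment_excl_geom(
    p0: np.ndarray,
    p1: np.ndarray,
    dmap: DistanceMap,
    origin: np.ndarray,
    length_scale: float,
) -> float:
    """``sum_voxels (D * Lt)^6`` along one centre-line, distances scaled."""
    idx, lens = traverse_segment_voxels(p0, p1, dmap.values.shape, dmap.voxel_size, origin)
    if len(idx) == 0:
        return 0.0
    D = dmap.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return float(np.sum((D * length_scale * lens * length_scale) ** 6))


def exclusion_cost(
    tree: ArterialTree,
    distance_map: DistanceMap,
    substrate: TissueSubstrate,
    R_cutoff: float = 0.01e-3,
    length_scale: float = 1e3,
) -> float:
    """Tissue-penetration penalty of all segments wider than ``R_cutoff``.

    Per segment: ``pi r^2 * sum_voxels (D_ijk * Lt_ijk)^6`` over the
    voxels pierced by its centre-line, with r, D and Lt expressed in
    units of ``1/length_scale`` metres (millimetres by default).
    Segments with ``r <= R_cutoff`` contribute nothing.
    """
    if tree.radius is None:
        assign_radii(tree)
    total = 0.0
    for c in tree.segment_ids:
        r = tree.radius[c]
        if r <= R_cutoff:
            continue
        g = _segment_excl_geom(
            tree.positions[tree.parent[c]],
            tree.positions[c],
            distance_map,
            substrate.origin,
            length_scale,
        )
        total += np.pi * (r * length_scale) ** 2 * g
    return total


def total_cost(
    C_v: float,
    C_w: float,
    C_s: float,
    C_o: float,
    C_p: float,
    weights: CostWeights,
) -> float:
    """Weighted total ``C_T``; divide by ``A_wv`` for the rescaled form."""
    return (
        weights.A_wv * (C_w + C_v)
        + weights.A_o * C_o
        + weights.A_p * C_p
        + weights.A_s * float(C_s)
    )


def reduced_segment_cost(r, l, Q, m_b: float, mu: float = 3.6e-3):
    """Per-segment cost once supply and exclusion act as satisfied constraints.

    ``C = m_b pi r^2 l + 8 mu l Q^2 / (pi r^4)``.  Rescaling all lengths
    by A is equivalent to rescaling the metabolic constant:
    ``C(A r, A l; m_b) = A^-3 C(r, l; A^6 m_b)``.
    """
    r = np.asarray(r, dtype=float)
    l = np.asarray(l, dtype=float)
    Q = np.asarray(Q, dtype=float)
    return m_b * np.pi * r**2 * l + 8.0 * mu * l * Q**2 / (np.pi * r**4)


# ---------------------------------------------------------------------------
# incremental evaluation


@dataclass
class Move:
    """A proposed tree update: ``translate`` a node or ``swap`` two parents."""

    kind: str  # "translate" | "swap"
    node: int = -1
    new_position: np.ndarray | None = None
    a: int = -1
    b: int = -1


@dataclass
class _AppliedMove:
    move: Move
    d_rest: float
    d_Cs: int
    old_position: np.ndarray | None = None
    old_seg: dict = field(default_factory=dict)  # seg -> (L, r, vol, pump, eg, excl)
    old_parent: dict = field(default_factory=dict)
    ndesc_path_a: list = field(default_factory=list)
    ndesc_path_b: list = field(default_factory=list)
    ndesc_delta: int = 0
    old_Cp: float = 0.0
    new_Cp: float = 0.0


class CostState:
    """Tree + substrate maps + per-segment cost caches for O(path) updates.

    Caches, all keyed by the segment's child node id: length (m), volume
    integrand ``pi r^2 L``, pumping power ``Q^2 R``, the geometric
    exclusion factor ``sum (D Lt)^6`` and the full exclusion term.
    Totals are maintained incrementally; ``C_s`` is an exact integer.
    """

    def __init__(
        self,
        tree: ArterialTree,
        substrate: TissueSubstrate,
        distance_map: DistanceMap,
        supply_map: SupplyMap,
        weights: CostWeights,
    ):
        self.tree = tree
        self.substrate = substrate
        self.dmap = distance_map
        self.smap = supply_map
        self.weights = weights
        self.refresh()

    # -- full (re)computation ---------------------------------------------

    def refresh(self) -> None:
        tree = self.tree
        assign_radii(tree)
        self._cache_tree_constants()
        M = tree.n_nodes
        self.length = tree.segment_lengths()
        self.vol = np.zeros(M)
        self.pump = np.zeros(M)
        self.excl_geom = np.zeros(M)
        self.excl = np.zeros(M)
        seg = tree.segment_ids
        r = tree.radius
        Q = tree.segment_flows()
        self.vol[seg] = np.pi * r[seg] ** 2 * self.length[seg]
        Rres = segment_resistance(r[seg], self.length[seg], tree.mu)
        self.pump[seg] = Q[seg] ** 2 * Rres
        for c in seg:
            self.excl_geom[c] = _segment_excl_geom(
                tree.positions[tree.parent[c]],
                tree.positions[c],
                self.dmap,
                self.substrate.origin,
                self.weights.excl_length_scale,
            )
        self._set_excl_from_geom(seg)
        self.S_vol = float(self.vol.sum())
        self.S_pump = float(self.pump.sum())
        self.S_excl = float(self.excl.sum())
        self.C_s = supply_cost(self.smap, self.substrate)
        self.C_p = self._pressure_cost() if self.weights.A_p > 0 else 0.0

    def _cache_tree_constants(self) -> None:
        # invariant under both move types (terminal count never changes)
        t = self.tree
        self._r_term = t.r_term
        self._Q_N = t.Q_N
        self._inv_gamma = 1.0 / t.gamma
        self._mu8_over_pi = 8.0 * t.mu / math.pi

    def _set_excl_from_geom(self, seg_ids) -> None:
        w = self.weights
        r = self.tree.radius
        for c in np.atleast_1d(seg_ids):
            if r[c] > w.R_cutoff:
                self.excl[c] = np.pi * (r[c] * w.excl_length_scale) ** 2 * self.excl_geom[c]
            else:
                self.excl[c] = 0.0

    def _pressure_cost(self) -> float:
        sol = compute_pressures(self.tree, terminal_reference=self.weights.P_term)
        return pressure_cost(sol.terminal_pressures, self.weights.P_term)

    # -- reporting ---------------------------------------------------------

    @property
    def C_v(self) -> float:
        return self.weights.m_b * self.S_vol

    @property
    def C_w(self) -> float:
        return self.S_pump

    @property
    def C_o(self) -> float:
        return self.S_excl

    def rest_cost(self) -> float:
        """All weighted terms except the supply constraint."""
        w = self.weights
        return w.A_wv * (self.C_w + self.C_v) + w.A_o * self.C_o + w.A_p * self.C_p

    def cost_key(self) -> tuple[int, float]:
        """Lexicographic comparison key: supply first, then the rest."""
        return (self.C_s, self.rest_cost())

    def breakdown(self) -> CostBreakdown:
        w = self.weights
        C_T = total_cost(self.C_v, self.C_w, self.C_s, self.C_o, self.C_p, w)
        return CostBreakdown(
            C_v=self.C_v,
            C_w=self.C_w,
            C_s=self.C_s,
            C_o=self.C_o,
            C_p=self.C_p,
            C_T=C_T,
            C_T_rescaled=C_T / w.A_wv,
            V_tree=self.S_vol,
            W_total=self.S_pump,
        )

    # -- segment cache updates ---------------------------------------------

    def _recompute_segment(self, c: int, applied: _AppliedMove, geometry_changed: bool) -> None:
        tree = self.tree
        w = self.weights
        if c not in applied.old_seg:
            applied.old_seg[c] = (
                self.length[c],
                tree.radius[c],
                self.vol[c],
                self.pump[c],
                self.excl_geom[c],
                self.excl[c],
            )
        p = int(tree.parent[c])
        if geometry_changed:
            dx = tree.positions[c] - tree.positions[p]
            self.length[c] = math.sqrt(dx[0] * dx[0] + dx[1] * dx[1] + dx[2] * dx[2])
            self.excl_geom[c] = _segment_excl_geom(
                tree.positions[p],
                tree.positions[c],
                self.dmap,
                self.substrate.origin,
                w.excl_length_scale,
            )
        n = int(tree.n_desc[c])
        r = self._r_term * n**self._inv_gamma
        tree.radius[c] = r
        L = float(self.length[c])
        r2 = r * r
        self.vol[c] = math.pi * r2 * L
        Q = n * self._Q_N
        self.pump[c] = Q * Q * self._mu8_over_pi * L / (r2 * r2)
        if r > w.R_cutoff:
            self.excl[c] = math.pi * (r * w.excl_length_scale) ** 2 * self.excl_geom[c]
        else:
            self.excl[c] = 0.0

    def _finish(self, applied: _AppliedMove) -> _AppliedMove:
        dS_vol = dS_pump = dS_excl = 0.0
        for c, (L0, r0, vol0, pump0, eg0, excl0) in applied.old_seg.items():
            dS_vol += self.vol[c] - vol0
            dS_pump += self.pump[c] - pump0
            dS_excl += self.excl[c] - excl0
        self.S_vol += dS_vol
        self.S_pump += dS_pump
        self.S_excl += dS_excl
        w = self.weights
        applied.d_rest = w.A_wv * (dS_pump + w.m_b * dS_vol) + w.A_o * dS_excl
        if w.A_p > 0:
            applied.old_Cp = self.C_p
            applied.new_Cp = self._pressure_cost()
            applied.d_rest += w.A_p * (applied.new_Cp - applied.old_Cp)
            self.C_p = applied.new_Cp
        return applied

    # -- supply accounting --------------------------------------------------

    def _paint(self, position: np.ndarray, sign: int) -> int:
        """Add/remove one supply sphere; returns the change in C_s."""
        slices, mask = self.smap.sphere_patch(position)
        patch = self.smap.counts[slices]
        tissue = self.substrate.occupancy[slices]
        sel = mask & tissue
        before = int(_supply_penalty(patch[sel]).sum())
        patch[mask] += sign
        after = int(_supply_penalty(patch[sel]).sum())
        return after - before

    # -- moves --------------------------------------------------------------

    def apply_translation(self, node: int, new_position: np.ndarray) -> _AppliedMove:
        tree = self.tree
        applied = _AppliedMove(
            move=Move("translate", node=node, new_position=np.asarray(new_position, float)),
            d_rest=0.0,
            d_Cs=0,
            old_position=tree.positions[node].copy(),
        )
        if tree.kind[node] == TERMINAL:
            d = self._paint(applied.old_position, -1)
            tree.positions[node] = new_position
            d += self._paint(tree.positions[node], +1)
            applied.d_Cs = d
            self.C_s += d
        else:
            tree.positions[node] = new_position
        affected = [node] if tree.parent[node] >= 0 else []
        affected += tree.child_list(node)
        for c in affected:
            self._recompute_segment(c, applied, geometry_changed=True)
        return self._finish(applied)

    def revert_translation(self, applied: _AppliedMove) -> None:
        tree = self.tree
        node = applied.move.node
        if tree.kind[node] == TERMINAL:
            self._paint(tree.positions[node], -1)
            self._paint(applied.old_position, +1)
            self.C_s -= applied.d_Cs
        tree.positions[node] = applied.old_position
        self._restore(applied)

    def apply_swap(self, a: int, b: int) -> _AppliedMove | None:
        """Exchange the parents of ``a`` and ``b``; None if it would loop."""
        tree = self.tree
        if a == b or tree.parent[a] < 0 or tree.parent[b] < 0:
            return None
        if tree.is_ancestor(a, b) or tree.is_ancestor(b, a):
            return None
        pa, pb = int(tree.parent[a]), int(tree.parent[b])
        applied = _AppliedMove(move=Move("swap", a=a, b=b), d_rest=0.0, d_Cs=0)
        applied.old_parent = {a: pa, b: pb}
        # rewire
        self._set_child(pa, a, b)
        self._set_child(pb, b, a)
        tree.parent[a] = pb
        tree.parent[b] = pa
        # subtree terminal counts along both old-parent root paths
        na, nb = int(tree.n_desc[a]), int(tree.n_desc[b])
        delta = nb - na
        applied.ndesc_delta = delta
        if delta != 0:
            path_a = [pa] + tree.ancestors(pa)
            path_b = [pb] + tree.ancestors(pb)
            applied.ndesc_path_a = path_a
            applied.ndesc_path_b = path_b
            for n in path_a:
                tree.n_desc[n] += delta
            for n in path_b:
                tree.n_desc[n] -= delta
        else:
            path_a = [pa] + tree.ancestors(pa)
            path_b = [pb] + tree.ancestors(pb)
        affected = {a, b}
        affected.update(n for n in path_a if tree.parent[n] >= 0)
        affected.update(n for n in path_b if tree.parent[n] >= 0)
        for c in affected:
            self._recompute_segment(c, applied, geometry_changed=(c in (a, b)))
        return self._finish(applied)

    def revert_swap(self, applied: _AppliedMove) -> None:
        tree = self.tree
        a, b = applied.move.a, applied.move.b
        pa, pb = applied.old_parent[a], applied.old_parent[b]
        self._set_child(pa, b, a)
        self._set_child(pb, a, b)
        tree.parent[a] = pa
        tree.parent[b] = pb
        delta = applied.ndesc_delta
        if delta != 0:
            for n in applied.ndesc_path_a:
                tree.n_desc[n] -= delta
            for n in applied.ndesc_path_b:
                tree.n_desc[n] += delta
        self._restore(applied)

    def _set_child(self, parent: int, old_child: int, new_child: int) -> None:
        row = self.tree.children[parent]
        slot = np.flatnonzero(row == old_child)
        if len(slot) == 0:
            raise ValueError(f"node {old_child} is not a child of {parent}")
        row[slot[0]] = new_child

    def _restore(self, applied: _AppliedMove) -> None:
        dS_vol = dS_pump = dS_excl = 0.0
        for c, (L0, r0, vol0, pump0, eg0, excl0) in applied.old_seg.items():
            dS_vol += vol0 - self.vol[c]
            dS_pump += pump0 - self.pump[c]
            dS_excl += excl0 - self.excl[c]
            self.length[c] = L0
            self.tree.radius[c] = r0
            self.vol[c] = vol0
            self.pump[c] = pump0
            self.excl_geom[c] = eg0
            self.excl[c] = excl0
        self.S_vol += dS_vol
        self.S_pump += dS_pump
        self.S_excl += dS_excl
        if self.weights.A_p > 0:
            self.C_p = applied.old_Cp

    def apply_move(self, move: Move) -> _AppliedMove | None:
        if move.kind == "translate":
            return self.apply_translation(move.node, move.new_position)
        if move.kind == "swap":
            return self.apply_swap(move.a, move.b)
        raise ValueError(f"unknown move kind {move.kind!r}")

    def revert_move(self, applied: _AppliedMove) -> None:
        if applied.move.kind == "translate":
            self.revert_translation(applied)
        else:
            self.revert_swap(applied)


def delta_cost(state: CostState, move: Move) -> tuple[float, int]:
    """Change ``(d_rest, dC_s)`` the move would cause; state is unchanged.

    ``d_rest`` collects the weighted non-supply terms; the full change of
    the literal total is ``A_s * dC_s + d_rest``.  Raises ValueError for
    an illegal (loop-forming) swap.
    """
    applied = state.apply_move(move)
    if applied is None:
        raise ValueError("illegal move (would form a loop or detach a root)")
    d_rest, d_Cs = applied.d_rest, applied.d_Cs
    state.revert_move(applied)
    return d_rest, d_Cs
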