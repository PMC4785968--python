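"""Rooted binary arterial trees: topology, geometry and haemodynamics.

A tree (or a two-root forest sharing one terminal pool) is stored as flat
arrays indexed by node id.  Every non-root node ``c`` carries the segment
``parent(c) -> c``; segments are therefore keyed by their child node.

Haemodynamics follow the laminar steady-flow model: every terminal
arteriole carries the same flow ``Q_N``, each segment is a Poiseuille
resistor ``R = 8 mu L / (pi r^4)``, and radii obey a fixed bifurcation
exponent ``gamma``: ``r_p^gamma = r_d1^gamma + r_d2^gamma``.  With equal
terminal flows this radius rule closes to ``r = r_term * n^(1/gamma)``
where ``n`` is the number of terminals downstream, and the combined-root
constraint ``sum_roots r_root^gamma = r_constraint^gamma`` fixes
``r_term = r_constraint * N_total^(-1/gamma)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROOT",
    "BIFURCATION",
    "TERMINAL",
    "ArterialTree",
    "PressureSolution",
    "random_tree",
    "assign_radii",
    "segment_resistance",
    "compute_flows",
    "compute_pressures",
    "validate",
]

ROOT, BIFURCATION, TERMINAL = 0, 1, 2

#: Blood viscosity, Pa s.
MU_BLOOD = 3.6e-3
#: Default bifurcation exponent (Murray's original value is 3.0; the
#: larger coronary arteries are better described by ~2.1).
GAMMA_DEFAULT = 2.1
#: Combined-root radius constraint, m.
R_ROOT_CONSTRAINT = 2.1e-3
#: Total inflow, m^3 s^-1.
Q0_TOTAL = 4.16e-6


def segment_resistance(r: float, L: float, mu: float = MU_BLOOD):
    """Poiseuille resistance ``8 mu L / (pi r^4)`` in Pa s m^-3."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("vessel radius must be positive")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("vessel length must be non-negative")
    return 8.0 * mu * L / (np.pi * r**4)


@dataclass
class PressureSolution:
    """Node pressures (Pa) from the root-to-leaf Poiseuille sweep."""

    node_pressures: np.ndarray
    terminal_pressures: np.ndarray
    root_pressures: dict[int, float]


@dataclass
class ArterialTree:
    positions: np.ndarray  # (M, 3) float, m
    parent: np.ndarray  # (M,) int, -1 for roots
    kind: np.ndarray  # (M,) uint8
    children: np.ndarray  # (M, 2) int, -1 where absent
    gamma: float = GAMMA_DEFAULT
    r_root_constraint: float = R_ROOT_CONSTRAINT
    Q0_total: float = Q0_TOTAL
    mu: float = MU_BLOOD
    n_desc: np.ndarray = None  # terminals at or below each node
    radius: np.ndarray = None  # per segment (keyed by child node), m

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.kind = np.asarray(self.kind, dtype=np.uint8)
        self.children = np.asarray(self.children, dtype=np.int64)

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root_ids(self) -> np.ndarray:
        return np.flatnonzero(self.parent < 0)

    @property
    def terminal_ids(self) -> np.ndarray:
        return np.flatnonzero(self.kind == TERMINAL)

    @property
    def segment_ids(self) -> np.ndarray:
        """Child node id of every segment."""
        return np.flatnonzero(self.parent >= 0)

    @property
    def n_terminals(self) -> int:
        return int((self.kind == TERMINAL).sum())

    @property
    def Q_N(self) -> float:
        return self.Q0_total / self.n_terminals

    @property
    def r_term(self) -> float:
        return self.r_root_constraint * self.n_terminals ** (-1.0 / self.gamma)

    def child_list(self, node: int) -> list[int]:
        return [int(c) for c in self.children[node] if c >= 0]

    def topological_order(self) -> np.ndarray:
        """Node ids ordered roots-first (every parent before its children)."""
        order = np.empty(self.n_nodes, dtype=np.int64)
        stack = list(self.root_ids)
        i = 0
        while stack:
            n = stack.pop()
            order[i] = n
            i += 1
            stack.extend(self.child_list(n))
        if i != self.n_nodes:
            raise ValueError("tree contains nodes unreachable from any root")
        return order

    def ancestors(self, node: int) -> list[int]:
        """Path of ancestors from ``parent(node)`` up to (and incl.) the root."""
        out = []
        p = int(self.parent[node])
        guard = self.n_nodes
        while p >= 0:
            out.append(p)
            p = int(self.parent[p])
            guard -= 1
            if guard < 0:
                raise ValueError("cycle detected while walking ancestors")
        return out

    def is_ancestor(self, a: int, b: int) -> bool:
        """True when ``a`` lies on the path from ``b`` to its root."""
        p = int(self.parent[b])
        guard = self.n_nodes
        while p >= 0:
            if p == a:
                return True
            p = int(self.parent[p])
            guard -= 1
            if guard < 0:
                raise ValueError("cycle detected while walking ancestors")
        return False

    def copy(self) -> "ArterialTree":
        return ArterialTree(
            positions=self.positions.copy(),
            parent=self.parent.copy(),
            kind=self.kind.copy(),
            children=self.children.copy(),
            gamma=self.gamma,
            r_root_constraint=self.r_root_constraint,
            Q0_total=self.Q0_total,
            mu=self.mu,
            n_desc=None if self.n_desc is None else self.n_desc.copy(),
            radius=None if self.radius is None else self.radius.copy(),
        )

    # -- geometry / haemodynamics ------------------------------------------

    def segment_lengths(self) -> np.ndarray:
        """Length (m) of the incoming segment per node (0 at roots)."""
        L = np.zeros(self.n_nodes)
        seg = self.segment_ids
        L[seg] = np.linalg.norm(self.positions[seg] - self.positions[self.parent[seg]], axis=1)
        return L

    def recompute_subtree_counts(self) -> np.ndarray:
        order = self.topological_order()
        n = np.zeros(self.n_nodes, dtype=np.int64)
        for node in order[::-1]:
            kids = self.child_list(node)
            n[node] = 1 if self.kind[node] == TERMINAL else sum(int(n[c]) for c in kids)
        self.n_desc = n
        return n

    def segment_flows(self) -> np.ndarray:
        """Flow (m^3 s^-1) through the incoming segment of each node."""
        if self.n_desc is None:
            self.recompute_subtree_counts()
        return self.n_desc * self.Q_N

    def segment_resistances(self) -> np.ndarray:
        if self.radius is None:
            assign_radii(self)
        R = np.zeros(self.n_nodes)
        seg = self.segment_ids
        L = self.segment_lengths()
        R[seg] = segment_resistance(self.radius[seg], L[seg], self.mu)
        return R


def assign_radii(tree: ArterialTree) -> ArterialTree:
    """Assign every segment radius from topology and the root constraint.

    Equivalent to the leaf-to-root gamma-sum sweep: terminals get
    ``r_term = r_constraint * N_total^(-1/gamma)`` and every parent gets
    ``(r_d1^gamma + r_d2^gamma)^(1/gamma)``, which closes to
    ``r = r_term * n_desc^(1/gamma)``.  Root entries get the radius of
    their trunk segment.
    """
    n = tree.recompute_subtree_counts()
    r = tree.r_term * np.power(n.astype(float), 1.0 / tree.gamma)
    for root in tree.root_ids:
        kids = tree.child_list(int(root))
        if kids:
            r[root] = r[kids[0]]
    tree.radius = r
    return tree


def compute_flows(tree: ArterialTree) -> np.ndarray:
    """Per-segment flows; terminal segments carry Q_N, parents the sum."""
    return tree.segment_flows()


def compute_pressures(
    tree: ArterialTree,
    terminal_reference: float = 0.0,
    root_pressure: float | None = None,
) -> PressureSolution:
    """Root-to-leaf pressure sweep under the constant-terminal-flow model.

    Flows are independent of pressure here, so the pressure field of each
    root's tree is defined up to an additive constant.  If
    ``root_pressure`` is given it is used for every root; otherwise each
    root's pressure is set so its *lowest* terminal pressure equals
    ``terminal_reference`` (the worst-supplied terminal sits exactly at
    the reference).
    """
    if tree.radius is None:
        assign_radii(tree)
    Q = tree.segment_flows()
    R = tree.segment_resistances()
    drop = Q * R  # per segment, Pa
    order = tree.topological_order()
    # cumulative drop from root down to each node
    cum = np.zeros(tree.n_nodes)
    for node in order:
        p = tree.parent[node]
        cum[node] = drop[node] + (cum[p] if p >= 0 else 0.0)

    root_of = np.empty(tree.n_nodes, dtype=np.int64)
    for node in order:
        p = tree.parent[node]
        root_of[node] = node if p < 0 else root_of[p]

    pressures = np.zeros(tree.n_nodes)
    root_ps: dict[int, float] = {}
    for root in tree.root_ids:
        members = root_of == root
        terms = members & (tree.kind == TERMINAL)
        if root_pressure is not None:
            p0 = float(root_pressure)
        else:
            p0 = terminal_reference + float(cum[terms].max(initial=0.0))
        pressures[members] = p0 - cum[members]
        root_ps[int(root)] = p0
    return PressureSolution(
        node_pressures=pressures,
        terminal_pressures=pressures[tree.kind == TERMINAL],
        root_pressures=root_ps,
    )


@dataclass
class TreeDiagnostics:
    has_cycle: bool
    orphan_nodes: list[int]
    degree_violations: list[int]
    non_finite_nodes: list[int]

    @property
    def ok(self) -> bool:
        return not (
            self.has_cycle or self.orphan_nodes or self.degree_violations or self.non_finite_nodes
        )


def validate(tree: ArterialTree) -> TreeDiagnostics:
    """Pure structural report: cycles, orphans, bad degrees, NaN geometry."""
    M = tree.n_nodes
    non_finite = [int(i) for i in np.flatnonzero(~np.isfinite(tree.positions).all(axis=1))]
    degree_bad = []
    for i in range(M):
        k = len(tree.child_list(i))
        kind = tree.kind[i]
        if kind == TERMINAL and k != 0:
            degree_bad.append(i)
        elif kind == BIFURCATION and k != 2:
            degree_bad.append(i)
        elif kind == ROOT and k != 1:
            degree_bad.append(i)
        # child/parent pointer consistency
        for c in tree.child_list(i):
            if tree.parent[c] != i and i not in degree_bad:
                degree_bad.append(i)
    has_cycle = False
    reached = np.zeros(M, dtype=bool)
    for i in range(M):
        p = int(tree.parent[i])
        steps = 0
        while p >= 0:
            p = int(tree.parent[p])
            steps += 1
            if steps > M:
                has_cycle = True
                break
        if has_cycle:
            break
    if not has_cycle:
        stack = list(tree.root_ids)
        while stack:
            n = stack.pop()
            if reached[n]:
                has_cycle = True
                break
            reached[n] = True
            stack.extend(tree.child_list(n))
        orphans = [int(i) for i in np.flatnonzero(~reached)]
    else:
        orphans = []
    return TreeDiagnostics(
        has_cycle=has_cycle,
        orphan_nodes=orphans,
        degree_violations=degree_bad,
        non_finite_nodes=non_finite,
    )


def random_tree(
    substrate,
    n_terminals: int,
    roots: np.ndarray,
    seed: int | np.random.Generator = 0,
    *,
    gamma: float = GAMMA_DEFAULT,
    r_root_constraint: float = R_ROOT_CONSTRAINT,
    Q0_total: float = Q0_TOTAL,
    mu: float = MU_BLOOD,
) -> ArterialTree:
    """Random initial tree: uniform terminals in tissue, uniform topology.

    Terminals are placed uniformly over the union of tissue voxels.  The
    topology is built by sequential random attachment — each new terminal
    splits a uniformly chosen existing segment with a fresh bifurcation —
    which samples labelled topologies uniformly.  New bifurcations start
    at the midpoint of the segment they split.

    ``roots`` is an (n_roots, 3) array of fixed entry positions (1 or 2
    roots); with several roots the segment pool is shared, so terminal
    counts per root are themselves random.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    roots = np.atleast_2d(np.asarray(roots, dtype=float))
    n_roots = len(roots)
    if not 1 <= n_roots <= 2:
        raise ValueError("1 or 2 roots supported")
    if n_terminals < n_roots:
        raise ValueError("need at least one terminal per root")
    tissue_idx = np.argwhere(substrate.occupancy)
    if len(tissue_idx) == 0:
        raise ValueError("substrate has no tissue voxels")
    if n_terminals > len(tissue_idx):
        raise ValueError("more terminals than tissue voxels")
    pick = rng.choice(len(tissue_idx), size=n_terminals, replace=False)
    jitter = rng.uniform(0.0, 1.0, size=(n_terminals, 3))
    term_pos = substrate.origin + (tissue_idx[pick] + jitter) * substrate.voxel_size

    M = n_roots + n_terminals + (n_terminals - n_roots)  # roots + terms + bifs
    positions = np.zeros((M, 3))
    parent = np.full(M, -1, dtype=np.int64)
    kind = np.zeros(M, dtype=np.uint8)
    children = np.full((M, 2), -1, dtype=np.int64)

    def set_child(p, old, new):
        row = children[p]
        row[np.flatnonzero(row == old)[0]] = new

    next_id = 0
    segments: list[int] = []  # child-node ids of existing segments
    term_ids = []
    for i in range(n_roots):
        rid = next_id
        next_id += 1
        positions[rid] = roots[i]
        kind[rid] = ROOT
        tid = next_id
        next_id += 1
        positions[tid] = term_pos[i]
        kind[tid] = TERMINAL
        parent[tid] = rid
        children[rid, 0] = tid
        segments.append(tid)
        term_ids.append(tid)

    for t in range(n_roots, n_terminals):
        c = segments[rng.integers(len(segments))]
        p = int(parent[c])
        bif = next_id
        next_id += 1
        kind[bif] = BIFURCATION
        positions[bif] = 0.5 * (positions[p] + positions[c])
        tid = next_id
        next_id += 1
        positions[tid] = term_pos[t]
        kind[tid] = TERMINAL
        # splice: p -> bif -> {c, tid}
        set_child(p, c, bif)
        parent[bif] = p
        parent[c] = bif
        parent[tid] = bif
        children[bif] = (c, tid)
        segments.append(bif)
        segments.append(tid)
        term_ids.append(tid)

    tree = ArterialTree(
        positions=positions,
        parent=parent,
        kind=kind,
        children=children,
        gamma=gamma,
        r_root_constraint=r_root_constraint,
        Q0_total=Q0_total,
        mu=mu,
    )
    assign_radii(tree)
    return tree
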