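"""Strahler-order morphometry of arterial trees.

Terminal segments get order 1; where two daughters of equal order meet,
the parent's order is one higher, otherwise it inherits the larger
daughter order.  Maximal runs of consecutive same-order segments form
*elements* — the vessel unit used in corrosion-cast morphometry — whose
diameters, lengths and daughter/parent diameter ratios are aggregated
per order for comparison with anatomical tables.

Because simulated trees terminate early (their smallest vessels are far
larger than true arterioles), order numbers are offset so the root
matches the anatomical root order (11 for coronary input arteries in
the porcine diameter-defined scheme).  A diameter-adjusted variant
re-bins elements into the order whose diameter band they fall in,
iterated to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import TERMINAL, ArterialTree, assign_radii

__all__ = [
    "strahler_orders",
    "diameter_adjusted_orders",
    "offset_orders",
    "ElementTable",
    "build_elements",
    "element_stats",
    "compare_to_reference",
    "length_radius_ratios",
]


def strahler_orders(tree: ArterialTree) -> np.ndarray:
    """Per-node Strahler order of the incoming segment (roots mirror trunk).

    Terminals are order 1; a parent of two equal-order daughters is one
    order higher, otherwise it takes the larger daughter order.
    """
    order = np.zeros(tree.n_nodes, dtype=np.int64)
    for node in tree.topological_order()[::-1]:
        kids = tree.child_list(node)
        if tree.kind[node] == TERMINAL:
            order[node] = 1
        elif len(kids) == 1:  # root entry
            order[node] = order[kids[0]]
        else:
            o1, o2 = order[kids[0]], order[kids[1]]
            order[node] = o1 + 1 if o1 == o2 else max(o1, o2)
    return order


def offset_orders(orders: np.ndarray, tree: ArterialTree, root_target_order: int = 11) -> np.ndarray:
    """Shift all orders so the largest root order equals ``root_target_order``."""
    root_order = max(int(orders[r]) for r in tree.root_ids)
    return orders + (root_target_order - root_order)


@dataclass
class ElementTable:
    """Vessel elements: maximal chains of same-order segments.

    ``element_of`` maps each segment (child-node id) to an element row.
    Element diameter is the length-weighted mean of member segment
    diameters; element length is the summed member length.
    """

    element_of: np.ndarray  # per node, -1 for roots
    order: np.ndarray  # per element
    diameter: np.ndarray  # per element, m
    length: np.ndarray  # per element, m


def build_elements(tree: ArterialTree, orders: np.ndarray) -> ElementTable:
    if tree.radius is None:
        assign_radii(tree)
    seg_len = tree.segment_lengths()
    element_of = np.full(tree.n_nodes, -1, dtype=np.int64)
    next_el = 0
    for node in tree.topological_order():
        if tree.parent[node] < 0:
            continue
        p = int(tree.parent[node])
        if tree.parent[p] >= 0 and orders[p] == orders[node]:
            element_of[node] = element_of[p]
        else:
            element_of[node] = next_el
            next_el += 1
    n_el = next_el
    length = np.zeros(n_el)
    wdiam = np.zeros(n_el)
    order = np.zeros(n_el, dtype=np.int64)
    for node in tree.segment_ids:
        e = element_of[node]
        length[e] += seg_len[node]
        wdiam[e] += 2.0 * tree.radius[node] * seg_len[node]
        order[e] = orders[node]
    with np.errstate(invalid="ignore"):
        diameter = np.where(length > 0, wdiam / np.maximum(length, 1e-300), 0.0)
    # zero-length elements (coincident nodes): fall back to member radius mean
    for e in np.flatnonzero(length == 0):
        members = np.flatnonzero(element_of == e)
        diameter[e] = float(np.mean(2.0 * tree.radius[members]))
    return ElementTable(element_of=element_of, order=order, diameter=diameter, length=length)


def diameter_adjusted_orders(
    tree: ArterialTree,
    base_orders: np.ndarray,
    max_iter: int = 50,
) -> tuple[np.ndarray, bool]:
    """Re-bin elements into diameter bands, iterated to a fixed point.

    Each iteration computes per-order mean and SD of element diameters,
    places the boundary between adjacent orders at
    ``((mean_n + sd_n) + (mean_{n+1} - sd_{n+1})) / 2``, and moves any
    element whose diameter falls beyond a boundary one order towards it.
    Returns ``(orders, converged)``; if the cap is hit the last
    assignment is returned with ``converged=False``.
    """
    orders = base_orders.copy()
    for _ in range(max_iter):
        et = build_elements(tree, orders)
        uniq = np.unique(et.order)
        mean = {o: float(et.diameter[et.order == o].mean()) for o in uniq}
        sd = {o: float(et.diameter[et.order == o].std(ddof=0)) for o in uniq}
        bound = {}
        for o in uniq[:-1]:
            nxt = o + 1
            if nxt in mean:
                bound[o] = 0.5 * ((mean[o] + sd[o]) + (mean[nxt] - sd[nxt]))
        new_el_order = et.order.copy()
        for e in range(len(et.order)):
            o = int(et.order[e])
            d = et.diameter[e]
            if o in bound and d > bound[o]:
                new_el_order[e] = o + 1
            elif (o - 1) in bound and d < bound[o - 1]:
                new_el_order[e] = o - 1
        if np.array_equal(new_el_order, et.order):
            return orders, True
        new_orders = orders.copy()
        for node in tree.segment_ids:
            new_orders[node] = new_el_order[et.element_of[node]]
        for r in tree.root_ids:
            kids = tree.child_list(int(r))
            if kids:
                new_orders[r] = new_orders[kids[0]]
        orders = new_orders
    return orders, False


def element_stats(tree: ArterialTree, orders: np.ndarray) -> pd.DataFrame:
    """Per-order element statistics and daughter/parent diameter ratios.

    Columns: ``order``, ``n_elements``, ``diameter_mm`` / ``length_mm``
    (means) with standard errors over elements, and mean ``Ds_over_Dp``
    / ``Dl_over_Dp`` — the smallest and largest daughter *element*
    diameter over the parent element diameter at each bifurcation,
    aggregated by parent order.  A daughter continuing the parent's
    element yields a ratio of exactly 1.
    """
    et = build_elements(tree, orders)
    rows = []
    # daughter/parent ratios per bifurcation, keyed by parent element order
    ratios_s: dict[int, list[float]] = {}
    ratios_l: dict[int, list[float]] = {}
    for node in tree.segment_ids:
        kids = tree.child_list(int(node))
        if len(kids) != 2:
            continue
        pe = et.element_of[node]
        dp = et.diameter[pe]
        d1 = et.diameter[et.element_of[kids[0]]]
        d2 = et.diameter[et.element_of[kids[1]]]
        o = int(et.order[pe])
        ratios_s.setdefault(o, []).append(min(d1, d2) / dp)
        ratios_l.setdefault(o, []).append(max(d1, d2) / dp)
    for o in np.unique(et.order):
        sel = et.order == o
        n = int(sel.sum())
        d = et.diameter[sel] * 1e3
        ln = et.length[sel] * 1e3
        rows.append(
            {
                "order": int(o),
                "n_elements": n,
                "diameter_mm": d.mean(),
                "diameter_mm_se": d.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                "length_mm": ln.mean(),
                "length_mm_se": ln.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                "Ds_over_Dp": float(np.mean(ratios_s[o])) if o in ratios_s else np.nan,
                "Dl_over_Dp": float(np.mean(ratios_l[o])) if o in ratios_l else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("order", ignore_index=True)


def compare_to_reference(order_table: pd.DataFrame, reference) -> pd.DataFrame:
    """Outer-join an order table with a reference morphometry table.

    ``reference`` is a CSV path or DataFrame with an ``order`` column
    plus any subset of the order-table columns; matching numeric columns
    gain ``<col>_ref`` and ``<col>_rel_diff`` fields.  Orders present on
    only one side are kept with NaNs — never imputed.
    """
    if isinstance(reference, (str, bytes)) or hasattr(reference, "read"):
        ref = pd.read_csv(reference)
    else:
        ref = pd.DataFrame(reference)
    if "order" not in ref.columns:
        raise ValueError("reference table must have an 'order' column")
    for col in ref.columns:
        if not np.issubdtype(ref[col].dtype, np.number):
            bad = ref[pd.to_numeric(ref[col], errors="coerce").isna()]
            row = int(bad.index[0]) if len(bad) else 0
            raise ValueError(f"reference column {col!r} is not numeric (row {row})")
    merged = order_table.merge(ref, on="order", how="outer", suffixes=("", "_ref"))
    for col in ref.columns:
        if col == "order" or f"{col}_ref" not in merged.columns:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            merged[f"{col}_rel_diff"] = (merged[col] - merged[f"{col}_ref"]) / merged[
                f"{col}_ref"
            ]
    ref_side = [
        f"{c}_ref" if f"{c}_ref" in merged.columns else c
        for c in ref.columns
        if c != "order"
    ]
    merged["missing_in_reference"] = merged[ref_side].isna().all(axis=1)
    return merged.sort_values("order", ignore_index=True)


def length_radius_ratios(tree: ArterialTree, per: str = "element") -> np.ndarray:
    """L/r of each element (or raw segment); radius is diameter/2."""
    if per == "segment":
        seg = tree.segment_ids
        if tree.radius is None:
            assign_radii(tree)
        L = tree.segment_lengths()[seg]
        return L / tree.radius[seg]
    if per == "element":
        et = build_elements(tree, strahler_orders(tree))
        return et.length / (et.diameter / 2.0)
    raise ValueError(f"unknown granularity {per!r}")
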