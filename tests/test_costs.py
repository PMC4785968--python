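"""Cost terms, voxel traversal, scale equivalence, incremental deltas."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vastra as v
from vastra.costs import _segment_excl_geom
from vastra.tree import BIFURCATION, ROOT, TERMINAL, ArterialTree


def one_segment_tree(p0, p1, radius_override=None):
    t = ArterialTree(
        positions=np.array([p0, p1], dtype=float),
        parent=np.array([-1, 0]),
        kind=np.array([ROOT, TERMINAL], dtype=np.uint8),
        children=np.array([[1, -1], [-1, -1]]),
    )
    v.assign_radii(t)
    if radius_override is not None:
        t.radius[:] = radius_override
    return t


@pytest.fixture()
def cost_state(sphere_substrate, sphere_distance_map, small_tree):
    t, perf = small_tree
    smap = v.paint_supply(sphere_substrate, t.positions[t.terminal_ids], perf.R_supply)
    w = v.CostWeights()
    return v.CostState(t, sphere_substrate, sphere_distance_map, smap, w), t, smap, w


class TestMetabolicCost:
    def test_zero_for_empty_geometry(self):
        t = one_segment_tree((0, 0, 0), (0, 0, 0))
        assert v.metabolic_cost(t, 641.3) == 0.0

    def test_single_segment_value(self):
        # m_b * pi r^2 L with r=1mm, L=10mm, m_b=641.3 J/s/m^3
        t = one_segment_tree((0, 0, 0), (0, 0, 1e-2), radius_override=1e-3)
        assert v.metabolic_cost(t, 641.3) == pytest.approx(641.3 * np.pi * 1e-8, rel=1e-12)
        assert v.metabolic_cost(t, 641.3) == pytest.approx(2.015e-5, rel=1e-3)

    def test_linear_in_length(self, small_tree):
        t, _ = small_tree
        c1 = v.metabolic_cost(t, 641.3)
        t2 = t.copy()
        t2.positions *= 2  # doubles every length
        assert v.metabolic_cost(t2, 641.3) == pytest.approx(2 * c1, rel=1e-12)


class TestPumpingCost:
    def test_single_segment(self):
        t = one_segment_tree((0, 0, 0), (0, 0, 1e-2), radius_override=1e-3)
        expected = t.Q_N**2 * 8 * t.mu * 1e-2 / (np.pi * 1e-12)
        assert v.pumping_cost(t) == pytest.approx(expected, rel=1e-12)

    def test_equals_pressure_flow_product(self, small_tree):
        """C_w identity: sum of Q_i^2 R_i equals sum of dP_i * Q_i."""
        t, _ = small_tree
        Q = t.segment_flows()
        R = t.segment_resistances()
        seg = t.segment_ids
        assert v.pumping_cost(t) == pytest.approx(float(np.sum(Q[seg] * Q[seg] * R[seg])))
        drops = Q[seg] * R[seg]
        assert v.pumping_cost(t) == pytest.approx(float(np.sum(drops * Q[seg])), rel=1e-12)


class TestSupplyCost:
    def make(self, counts, occ=None):
        counts = np.asarray(counts, dtype=np.int32)
        occ = np.ones_like(counts, dtype=bool) if occ is None else occ
        sub = v.TissueSubstrate(occupancy=occ, voxel_size=1e-3)
        smap = v.SupplyMap(counts=counts, R_supply=1e-3, voxel_size=1e-3, origin=sub.origin)
        return smap, sub

    def test_perfect_tiling_is_free(self):
        smap, sub = self.make(np.ones((3, 3, 3)))
        assert v.supply_cost(smap, sub) == 0

    def test_unsupplied_voxel_costs_ten(self):
        c = np.ones((3, 3, 3))
        c[0, 0, 0] = 0
        smap, sub = self.make(c)
        assert v.supply_cost(smap, sub) == 10

    def test_oversupply_quadratic(self):
        c = np.ones((3, 3, 3))
        c[1, 1, 1] = 3
        smap, sub = self.make(c)
        assert v.supply_cost(smap, sub) == 4

    def test_non_tissue_voxels_ignored(self):
        occ = np.ones((3, 3, 3), dtype=bool)
        occ[2, 2, 2] = False
        c = np.ones((3, 3, 3))
        c[2, 2, 2] = 50
        smap, sub = self.make(c, occ)
        assert v.supply_cost(smap, sub) == 0


class TestTraversal:
    def test_axis_aligned_center_to_center(self):
        h = 1e-3
        idx, lens = v.traverse_segment_voxels(
            (0.5 * h, 0.5 * h, 0.5 * h), (2.5 * h, 0.5 * h, 0.5 * h), (4, 4, 4), h, np.zeros(3)
        )
        assert [tuple(i) for i in idx] == [(0, 0, 0), (1, 0, 0), (2, 0, 0)]
        assert lens == pytest.approx([h / 2, h, h / 2], rel=1e-12)

    def test_length_conservation_random_segments(self):
        rng = np.random.default_rng(3)
        h = 1e-3
        shape = (12, 12, 12)
        hi = np.array(shape) * h
        for _ in range(1000):
            p0 = rng.uniform(0, 1, 3) * hi
            p1 = rng.uniform(0, 1, 3) * hi
            idx, lens = v.traverse_segment_voxels(p0, p1, shape, h, np.zeros(3))
            assert lens.sum() == pytest.approx(np.linalg.norm(p1 - p0), rel=1e-9)

    def test_segment_within_one_voxel(self):
        h = 1e-3
        idx, lens = v.traverse_segment_voxels(
            (0.2 * h, 0.2 * h, 0.2 * h), (0.8 * h, 0.7 * h, 0.3 * h), (4, 4, 4), h, np.zeros(3)
        )
        assert len(idx) == 1 and tuple(idx[0]) == (0, 0, 0)
        assert lens[0] == pytest.approx(np.linalg.norm([0.6 * h, 0.5 * h, 0.1 * h]), rel=1e-12)

    def test_zero_length_segment(self):
        idx, lens = v.traverse_segment_voxels((0, 0, 0), (0, 0, 0), (4, 4, 4), 1e-3, np.zeros(3))
        assert len(idx) == 0

    def test_pierced_voxels_really_intersect_line(self):
        rng = np.random.default_rng(4)
        h = 1e-3
        shape = (10, 10, 10)
        for _ in range(50):
            p0, p1 = rng.uniform(0, 10 * h, (2, 3))
            idx, lens = v.traverse_segment_voxels(p0, p1, shape, h, np.zeros(3))
            d = p1 - p0
            for i, ell in zip(idx, lens):
                # independent slab clip: chord length inside this voxel box
                lo, hi = i * h, (i + 1) * h
                t0, t1 = 0.0, 1.0
                ok = True
                for ax in range(3):
                    if d[ax] == 0.0:
                        ok &= lo[ax] <= p0[ax] <= hi[ax]
                    else:
                        ta, tb = sorted(((lo[ax] - p0[ax]) / d[ax], (hi[ax] - p0[ax]) / d[ax]))
                        t0, t1 = max(t0, ta), min(t1, tb)
                assert ok and t1 > t0
                assert ell == pytest.approx((t1 - t0) * np.linalg.norm(d), rel=1e-9)


class TestExclusionCost:
    def test_outside_tissue_is_free(self, sphere_substrate, sphere_distance_map):
        lo, hi = sphere_substrate.bbox
        edge = lo + 0.2 * sphere_substrate.voxel_size
        t = one_segment_tree(edge, edge + (0, 0, 2e-3), radius_override=2e-3)
        assert (
            v.exclusion_cost(t, sphere_distance_map, sphere_substrate) == 0.0
        )

    def test_small_vessels_exempt(self, sphere_substrate, sphere_distance_map):
        center = 0.5 * (sphere_substrate.bbox[0] + sphere_substrate.bbox[1])
        t = one_segment_tree(center, center + (0, 0, 3e-3), radius_override=0.005e-3)
        assert v.exclusion_cost(t, sphere_distance_map, sphere_substrate) == 0.0

    def test_single_voxel_closed_form(self):
        occ = np.zeros((5, 5, 5), dtype=bool)
        occ[2, 2, 2] = True
        sub = v.TissueSubstrate(occupancy=occ, voxel_size=1e-3)
        dmap = v.compute_distance_map(sub)
        d = dmap.values[2, 2, 2]
        c0 = sub.index_center((2, 2, 2))
        p0, p1 = c0 - (0.4e-3, 0, 0), c0 + (0.4e-3, 0, 0)
        t = one_segment_tree(p0, p1, radius_override=1e-3)
        ell = 0.8e-3
        expected = np.pi * (1e-3 * 1e3) ** 2 * ((d * 1e3) * (ell * 1e3)) ** 6
        assert v.exclusion_cost(t, dmap, sub) == pytest.approx(expected, rel=1e-9)

    def test_monotone_with_depth_in_slab(self):
        """Pushing a wide segment deeper along the distance gradient costs more."""
        sub = v.build_toy_substrate("slab", thickness=9, extent=16, voxel_size=1e-3)
        dmap = v.compute_distance_map(sub)
        lo, hi = sub.bbox
        mid = 0.5 * (lo + hi)
        costs = []
        for zfrac in (0.15, 0.3, 0.5):  # approach the mid-plane
            z = lo[2] + zfrac * (hi[2] - lo[2])
            t = one_segment_tree(
                (mid[0] - 4e-3, mid[1], z), (mid[0] + 4e-3, mid[1], z), radius_override=1e-3
            )
            costs.append(v.exclusion_cost(t, dmap, sub))
        assert costs[0] < costs[1] < costs[2]


class TestPressureCost:
    def test_uniform_terminals_free(self):
        assert v.pressure_cost([5.0, 5.0, 5.0], 5.0) == 0.0

    def test_single_and_symmetric_deviations(self):
        assert v.pressure_cost([5.0 + 3.0], 5.0) == pytest.approx(9.0)
        assert v.pressure_cost([5.0 + 3.0, 5.0 - 3.0], 5.0) == pytest.approx(18.0)


class TestTotalCost:
    def test_all_zero(self):
        assert v.total_cost(0, 0, 0, 0, 0, v.CostWeights()) == 0.0

    def test_default_weighting(self):
        # C_w + C_v = 1 and all else zero weighs in at A_wv = 1e4
        assert v.total_cost(0.4, 0.6, 0, 0, 0, v.CostWeights()) == pytest.approx(1e4)

    def test_global_scaling_preserves_minima(self):
        w = v.CostWeights()
        k = 7.5
        scaled = v.CostWeights(A_wv=k * w.A_wv, A_o=k * w.A_o, A_p=k * w.A_p, A_s=k * w.A_s)
        a = v.total_cost(0.1, 0.2, 3, 0.4, 0.0, w)
        b = v.total_cost(0.1, 0.2, 3, 0.4, 0.0, scaled)
        assert b == pytest.approx(k * a, rel=1e-12)


class TestScaleEquivalence:
    @given(
        r=st.floats(1e-5, 1e-2),
        l=st.floats(1e-4, 1e-1),
        Q=st.floats(1e-10, 1e-5),
        A=st.floats(0.1, 10.0),
    )
    def test_length_rescaling_equals_mb_rescaling(self, r, l, Q, A):
        """C(Ar, Al; m_b) = A^-3 C(r, l; A^6 m_b) to machine precision."""
        m_b = 641.3
        lhs = v.reduced_segment_cost(A * r, A * l, Q, m_b)
        rhs = A ** (-3) * v.reduced_segment_cost(r, l, Q, A**6 * m_b)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestRelabelingInvariance:
    def test_costs_invariant_under_node_relabeling(self, small_tree):
        t, _ = small_tree
        c_v, c_w = v.metabolic_cost(t, 641.3), v.pumping_cost(t)
        perm = np.random.default_rng(0).permutation(t.n_nodes)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(t.n_nodes)
        remap = lambda a: np.where(a >= 0, inv[np.clip(a, 0, None)], -1)
        t2 = ArterialTree(
            positions=t.positions[perm],
            parent=remap(t.parent[perm]),
            kind=t.kind[perm],
            children=remap(t.children[perm]),
            gamma=t.gamma,
            r_root_constraint=t.r_root_constraint,
            Q0_total=t.Q0_total,
        )
        v.assign_radii(t2)
        assert v.metabolic_cost(t2, 641.3) == pytest.approx(c_v, rel=1e-12)
        assert v.pumping_cost(t2) == pytest.approx(c_w, rel=1e-12)


class TestDeltaCost:
    def full_key(self, state, sub):
        w = state.weights
        C_v = v.metabolic_cost(state.tree, w.m_b)
        C_w = v.pumping_cost(state.tree)
        C_s = v.supply_cost(state.smap, sub)
        C_o = v.exclusion_cost(state.tree, state.dmap, sub, w.R_cutoff, w.excl_length_scale)
        return C_s, w.A_wv * (C_w + C_v) + w.A_o * C_o

    def test_null_translation_is_free(self, cost_state):
        state, t, smap, w = cost_state
        node = int(t.terminal_ids[0])
        d_rest, d_Cs = v.delta_cost(state, v.Move("translate", node=node,
                                                  new_position=t.positions[node].copy()))
        assert d_Cs == 0 and abs(d_rest) < 1e-12

    def test_thousand_random_moves_match_full_recompute(self, cost_state, sphere_substrate):
        """Incremental deltas track full recomputation through 1000 moves of both kinds."""
        state, t, smap, w = cost_state
        rng = np.random.default_rng(42)
        nonroot = np.flatnonzero(t.kind != ROOT)
        lo, hi = sphere_substrate.bbox
        checked = 0
        for i in range(1000):
            if rng.random() < 0.5:
                n = int(nonroot[rng.integers(len(nonroot))])
                newp = np.clip(
                    t.positions[n] + rng.normal(0, 1.5e-3, 3), lo + 1e-12, hi - 1e-12
                )
                if t.kind[n] == TERMINAL and not sphere_substrate.is_tissue_point(newp):
                    continue
                mv = v.Move("translate", node=n, new_position=newp)
            else:
                a, b = rng.choice(nonroot, 2, replace=False)
                mv = v.Move("swap", a=int(a), b=int(b))
            before = self.full_key(state, sphere_substrate)
            applied = state.apply_move(mv)
            if applied is None:
                continue
            after = self.full_key(state, sphere_substrate)
            assert applied.d_Cs == after[0] - before[0]
            # 1e-8 relative to the recomputed total (the oracle's own difference
            # of two large sums carries that rounding)
            assert abs(applied.d_rest - (after[1] - before[1])) <= 1e-8 * max(
                1.0, abs(after[1]), abs(before[1])
            )
            checked += 1
            if rng.random() < 0.4:
                state.revert_move(applied)
                again = self.full_key(state, sphere_substrate)
                assert again[0] == before[0]
                assert again[1] == pytest.approx(before[1], rel=1e-10)
        assert checked > 300

    def test_swap_delta_detects_loops(self, cost_state):
        state, t, smap, w = cost_state
        term = int(t.terminal_ids[0])
        anc = t.ancestors(term)[0]
        with pytest.raises(ValueError):
            v.delta_cost(state, v.Move("swap", a=anc, b=term))
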