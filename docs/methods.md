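# Methods

## Model

A tissue substrate is a boolean occupancy grid with isotropic voxel
spacing `h`; voxel `(i,j,k)` owns the half-open cell starting at
`origin + (i,j,k)·h` and its physical position is the cell centre.  The
arterial tree is a rooted binary forest stored as flat node arrays;
every non-root node keys the segment from its parent.  Node kinds are
root (fixed entry point, one child), bifurcation (two children) and
terminal (no children).  Segments are straight resistor elements — no
curvature discretization — with Poiseuille resistance `R = 8μL/(πr⁴)`,
blood viscosity `μ = 3.6×10⁻³ Pa s`.

Flow is steady, laminar and non-pulsatile, and every terminal carries
the same flow `Q_N = Q_0/N`.  Under these assumptions flows follow from
subtree terminal counts alone, and with a fixed bifurcation exponent γ
the radius recursion `r_p^γ = r_d1^γ + r_d2^γ` closes to

    r(segment feeding n terminals) = r_term · n^(1/γ),

implemented in this closed form (identical to the leaf-to-root sweep,
and O(path length) to update after a topology change).  The combined
root constraint `Σ_roots r_root^γ = r_c^γ` forces
`r_term = r_c · N_total^(−1/γ)`; with `r_c = 2.1 mm`, γ = 2.1 and 6000
terminals, `r_term ≈ 0.033 mm`.  Pressures are a single root-to-leaf
sweep; since flows do not depend on pressure, each root's field is
defined up to a constant.  Convention: the root pressure is set so the
lowest terminal pressure equals the requested reference (the
worst-supplied terminal sits exactly at it).  A general nodal-analysis
solve exists in the test suite as an independent oracle.

## Cost function

    C_T = A_wv (C_w + C_v) + A_o C_o + A_p C_p + A_s C_s

* `C_v = m_b · V_tree` with `V_tree = Σ πr²L`; default
  `m_b = 641.3 J s⁻¹ m⁻³` (per cubic metre of blood).
* `C_w = Σ Q²R`, the total pumping power (identically `Σ Δp·Q`).
* `C_s = Σ_tissue-voxels s(b)`, `s = 10` when the voxel is covered by no
  supply sphere and `(b−1)²` when covered `b` times.  Each terminal
  covers the voxel centres within `R_supply` of its position, with
  `(4/3)πR³_supply · q_required = Q_N` and
  `q_required = ρ · demand ≈ 2×10⁻² s⁻¹` (ρ = 1.06×10³ kg m⁻³, demand
  1.13 ml min⁻¹ g⁻¹; the alternative literature value
  0.8 ml min⁻¹ g⁻¹ ships as a preset).  Counts are exact integers.
* `C_o = Σ_{segments, r > R_cutoff} πr² Σ_voxels (D·L̃)⁶`, where `D` is
  the Euclidean distance transform of the tissue sampled at each voxel
  the segment's centre-line pierces and `L̃` the in-voxel path length.
  `R_cutoff = 0.01 mm`.  **Unit choice:** `r`, `D` and `L̃` enter in
  millimetres.  The sixth power makes the term's magnitude hinge on the
  length unit; in millimetres per-voxel terms are O(1)–O(10⁶), which is
  what lets the modest weight `A_o = 100` act as a soft constraint with
  a useful gradient (deeper penetration by wider vessels costs visibly
  more).  In metres the whole term would be ~10⁻³⁰ and inert.  The scale
  is a config field (`excl_length_scale`).
* `C_p = Σ_terminals (P_i − P_term)²`, computed but weighted 0 by
  default: for trees of a few thousand nodes the root-to-terminal drop
  is a tiny fraction of the physiological total, so uniformity is not
  worth its cost.

Weights default to `A_wv = 10⁴`, `A_o = 100`, `A_p = 0`, `A_s = 10³⁰`.
The supply weight is conceptually infinite (unsupplied tissue dies);
numerically the Metropolis delta is assembled as `A_s·ΔC_s + Δrest` with
the two parts accumulated separately — ΔC_s in integer arithmetic — so a
supply change always decides acceptance and no precision is lost adding
O(10³⁰) to O(10⁴).  The reported `C_T` uses the literal weighted sum.

The per-voxel centre-line decomposition uses an exact boundary-crossing
traversal (vectorized; in-voxel lengths sum to the segment length to
10⁻⁹ relative).  `D` is sampled at the voxel, not averaged along the
chord — the simplest reading of a per-voxel distance penalty.

## Annealing

Two moves: (i) translate a uniformly chosen non-root node (terminals
included — they must stay inside tissue and any node must stay inside
the grid box; violating draws are discarded, which preserves proposal
symmetry) by an isotropic Gaussian step; (ii) swap the parent
attachments of two uniformly chosen non-root nodes, rejected before
evaluation if one is an ancestor of the other (a loop would form).
Rejected-before-evaluation proposals count against the update budget.
Swap closure reaches all `(2n−3)!!` labelled topologies (verified by
breadth-first enumeration for n ≤ 6), so with translations the chain is
ergodic over configurations.

Acceptance is Metropolis (`1` downhill, `exp(−ΔC_T/T)` uphill) under a
geometric schedule `T_k = T_i (T_f/T_i)^{k/n}`, `T_i = 10¹⁰`,
`T_f = 10⁻⁵`.  The translation step scale anneals geometrically from 2×
to 0.1× the supply radius (both configurable); moves split 50/50 between
the two kinds by default.  Cost bookkeeping is incremental: per-segment
caches (length, volume term, pumping term, exclusion geometry factor)
are updated only along the affected root paths, supply counts only in
the two spheres a terminal move touches; agreement with full
recomputation is tested over 10³ random moves of both kinds.  When
`A_p > 0` the pressure term is recomputed globally (a pressure change
propagates through the whole root tree).  Runs are exactly reproducible
from (inputs, seed); the best-so-far tree under the lexicographic key
`(C_s, weighted rest)` is tracked and returned alongside a cost trace.

## Substrates

Built-in generators: toy sphere/slab/shell masks, and an idealized
ventricular substrate — an outer ellipsoid (default semi-axes 45, 45,
65 mm) minus a concentric left-ventricular cavity (a 0.72-scaled copy of
the outer ellipsoid) minus a laterally offset right-ventricular cavity
shaped as a super-ellipsoid of exponent 2.5, truncated by a basal plane
placed so the voxelized mass hits the 218 g target (voxel-layer
granularity limits this to ~1% at the 1.5 mm default voxel; the builder
raises if the requested tolerance is unreachable).  The exact semi-axes
are free configuration: only mass, cavity shapes and the truncation
rationale are anatomically pinned, and the acceptance checks depend only
on those.  Substrates persist as HDF5 (occupancy + distance + supply
maps) and import/export as NIfTI masks; trees export as SWC text,
segment CSV and ASCII legacy-VTK polylines.

For toy substrates, `PerfusionParams.for_substrate` matches the total
inflow to `q_required · V_tissue`, making a perfect one-cover of the
tissue geometrically possible — the published heart parameters
(`Q_0 = 4.16×10⁻⁶ m³ s⁻¹` against 218 g / 1.06 g cm⁻³) already satisfy
this consistency within a few percent.

## Morphometry

Strahler orders: terminals 1; a parent takes `max` of differing daughter
orders, `+1` when they match.  Elements merge consecutive same-order
segments; element diameter is the length-weighted mean of member
diameters (length-weighting chosen over a plain mean so long members
dominate, matching how a cast vessel would be measured), element length
the member sum.  Daughter/parent ratios are evaluated per bifurcation
between the parent-segment's element and the two child-segment elements
(a daughter continuing the trunk element contributes a ratio of exactly
1, which is what produces the `D_l/D_p → 1` trunk signature at high
orders).  Orders can be offset so the root matches an anatomical root
order (default 11), and a diameter-adjusted variant iteratively re-bins
elements into per-order mean±SD diameter bands until a fixed point (cap
50 iterations; the unadjusted ordering always remains available).
Standard errors are computed over elements.  Reference tables join on
order; missing orders are flagged, never imputed.

## What the synthetic substrates do and do not show

Toy spheres and the ellipsoidal heart capture the features the method
actually exercises — finite tissue with a surface, thin-walled cavities,
uniform demand — but not fibre orientation, heterogeneous regional
demand (the data model supports per-voxel demand; the default is
uniform), moving geometry, or real epicardial curvature.  Tests passing
on these substrates validate the optimization machinery and its
invariants, not anatomical fidelity of any particular run.

## Problem sizes and convergence

Full-scale runs (6000 terminals, ~10¹⁰ updates) are cluster-scale; the
package's tests and the acceptance script run a scaled-down condition:
200 terminals, two roots, 10⁶ updates on a 2.5 mm-voxel heart (~5 min).
This is orders of magnitude below the converged regime, with visible
consequences that shrink as the budget grows: segment lengths remain
above the supply-sphere spacing, so the vessel slenderness statistic
L/r stays in the hundreds rather than the tens, while locally-driven
quantities (low-order branching symmetry near `2^(−1/γ)` ≈ 0.72, supply
tiling, the Murray relation, flow/pressure identities) are already
stable at this scale.

## Numerical choices and limitations

* Exact Euclidean distance transform (not chamfer), voxel-centre
  sampling, half-open cells.
* Supply-sphere membership tests voxel centres, not partial volumes.
* New bifurcations initialize at the midpoint of the segment they split
  (initialization only; positions anneal freely afterwards).
* Random initial topologies are uniform over labelled topologies
  (sequential uniform-edge attachment).
* Degenerate zero-length segments are legal (zero resistance, zero
  cost, empty traversal).
* Cached cost sums drift only by float rounding (~10⁻¹⁰ relative over
  10⁶ updates); `CostState.refresh()` rebuilds from scratch if needed.
* Non-Newtonian and pulsatile rheology, per-order variable γ, and
  sprouting-style growth dynamics are out of scope by design.
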