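"""Anneal a small arterial tree into a spherical toy substrate.

A 40-terminal tree is randomized, then optimized for 60k Metropolis
updates.  Watch the supply penalty C_s collapse first (terminals spread
out to tile the tissue), then the weighted power + volume cost anneal
down as the topology reorganizes.
"""

import numpy as np

import vastra as v
from vastra.io import to_swc

sub = v.build_toy_substrate("sphere", radius=6, voxel_size=2e-3)
perf = v.PerfusionParams.for_substrate(sub, 40)
print(f"supply sphere radius {perf.R_supply * 1e3:.2f} mm, Q_N = {perf.Q_N:.3e} m^3/s")

lo, hi = sub.bbox
root = [[0.5 * (lo[0] + hi[0]), 0.5 * (lo[1] + hi[1]), hi[2] - sub.voxel_size]]
tree = v.random_tree(sub, 40, root, seed=4, Q0_total=perf.Q0_total)

res = v.anneal(tree, sub, perf, v.Schedule(n_updates=60_000), seed=4)
b = res.best_breakdown
print(f"accepted {res.n_accepted} of {res.n_proposed} updates")
print(f"best tree: C_s = {b.C_s} (unsupplied/oversupplied voxel penalty)")
print(f"           C_v = {b.C_v:.3e} W (blood-volume upkeep)")
print(f"           C_w = {b.C_w:.3e} W (pumping power)")
print(f"           rescaled total C~_T = {b.C_T_rescaled:.3e} (supply-dominated while C_s > 0)")

swc = to_swc(res.best_tree)
print(f"SWC export: {swc.count(chr(10))} lines, first two:")
print("\n".join(swc.splitlines()[:2]))
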