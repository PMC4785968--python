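import numpy as np
import pytest
from hypothesis import settings

import vastra as v

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sphere_substrate():
    return v.build_toy_substrate("sphere", radius=6, voxel_size=1e-3)


@pytest.fixture(scope="session")
def sphere_distance_map(sphere_substrate):
    return v.compute_distance_map(sphere_substrate)


@pytest.fixture()
def small_tree(sphere_substrate):
    """30-terminal random tree with substrate-matched inflow."""
    perf = v.PerfusionParams.for_substrate(sphere_substrate, 30)
    t = v.random_tree(
        sphere_substrate, 30, [[0.001, 0.001, 0.0005]], seed=7, Q0_total=perf.Q0_total
    )
    return t, perf


@pytest.fixture(scope="session")
def coarse_heart():
    """Heart-shaped substrate at coarse resolution (fast to anneal into)."""
    return v.build_heart_substrate(voxel_size=2.5e-3)


@pytest.fixture(scope="session")
def annealed_heart(coarse_heart):
    """A 200-terminal tree annealed into the coarse heart substrate.

    Scaled-down optimization (1e6 updates) shared by the morphometry
    checks: large enough to develop several Strahler orders, small
    enough to run in minutes.
    """
    sub = coarse_heart
    n_terminals = 200
    perf = v.PerfusionParams.from_physiology(n_terminals)  # Q0 = 4.16e-6 m^3/s
    lo, hi = sub.bbox
    center = 0.5 * (lo + hi)
    top = hi[2] - sub.voxel_size
    roots = np.array(
        [[center[0] - 0.012, center[1], top], [center[0] + 0.012, center[1], top]]
    )
    tree = v.random_tree(sub, n_terminals, roots, seed=11, Q0_total=perf.Q0_total)
    res = v.anneal(
        tree, sub, perf, v.Schedule(n_updates=1_000_000), seed=11
    )
    return res.best_tree, res, sub
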