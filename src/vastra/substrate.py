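"""Voxelized tissue substrates and the maps defined on them.

A substrate is a binary occupancy grid with isotropic physical spacing:
the geometry that an arterial tree has to supply with blood.  Two derived
voxel maps drive the optimization:

* the *distance map*: Euclidean distance of every tissue voxel centre to
  the nearest non-tissue voxel centre (zero outside tissue), used to
  penalize large vessels that dive into the parenchyma;
* the *supply map*: for each voxel, the number of terminal arterioles
  whose spherical microcirculatory territory covers its centre.

Each terminal supplies a sphere of radius ``R_supply`` sized so that the
sphere volume times the tissue's volumetric flow demand ``q_required``
equals the constant terminal flow ``Q_N = Q_0 / N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RHO_MYOCARDIUM",
    "DEMAND_RESTING",
    "DEMAND_MEAN_CARDIAC",
    "TissueSubstrate",
    "DistanceMap",
    "SupplyMap",
    "PerfusionParams",
    "ml_min_g_to_si",
    "flow_demand_per_volume",
    "supply_radius",
    "build_toy_substrate",
    "build_heart_substrate",
    "compute_distance_map",
    "paint_supply",
]

#: Density of myocardium, kg m^-3.
RHO_MYOCARDIUM = 1.06e3
#: Resting myocardial perfusion demand, ml min^-1 g^-1 (preset used to
#: derive q_required ~ 2e-2 s^-1).
DEMAND_RESTING = 1.13
#: Alternative mean cardiac perfusion preset, ml min^-1 g^-1.
DEMAND_MEAN_CARDIAC = 0.8


def ml_min_g_to_si(demand: float) -> float:
    """Convert a perfusion demand from ml min^-1 g^-1 to m^3 s^-1 kg^-1."""
    return demand * 1e-6 / 60.0 * 1e3


def flow_demand_per_volume(rho: float, demand_per_mass: float, *, units: str = "ml/min/g") -> float:
    """Volumetric flow demand per unit tissue volume, ``q_required`` (s^-1).

    Parameters
    ----------
    rho
        Tissue density in kg m^-3.
    demand_per_mass
        Perfusion demand per unit tissue mass.  Interpreted in
        ml min^-1 g^-1 by default, or in SI m^3 s^-1 kg^-1 when
        ``units="si"``.  Zero demand is allowed (yields zero).
    """
    if rho <= 0:
        raise ValueError(f"tissue density must be positive, got {rho}")
    if demand_per_mass < 0:
        raise ValueError(f"perfusion demand must be non-negative, got {demand_per_mass}")
    if units == "ml/min/g":
        demand_si = ml_min_g_to_si(demand_per_mass)
    elif units == "si":
        demand_si = demand_per_mass
    else:
        raise ValueError(f"unknown demand units {units!r}")
    return rho * demand_si


@dataclass(frozen=True)
class PerfusionParams:
    """Perfusion bookkeeping linking total inflow to per-terminal territories.

    Attributes are all SI: ``q_required`` (s^-1) is flow demand per unit
    tissue volume, ``Q_N = Q0_total / N_terminals`` the constant flow
    through each terminal, and ``R_supply`` the radius of the spherical
    territory with ``(4/3) pi R^3 q_required = Q_N``.
    """

    rho: float
    demand_per_mass: float  # m^3 s^-1 kg^-1
    Q0_total: float
    N_terminals: int
    q_required: float = field(init=False)
    Q_N: float = field(init=False)
    R_supply: float = field(init=False)

    def __post_init__(self) -> None:
        if self.N_terminals < 1:
            raise ValueError("need at least one terminal")
        if self.Q0_total <= 0:
            raise ValueError("total inflow must be positive")
        q = flow_demand_per_volume(self.rho, self.demand_per_mass, units="si")
        if q <= 0:
            raise ValueError("flow demand must be positive to size supply spheres")
        object.__setattr__(self, "q_required", q)
        object.__setattr__(self, "Q_N", self.Q0_total / self.N_terminals)
        object.__setattr__(self, "R_supply", (3.0 * self.Q_N / (4.0 * np.pi * q)) ** (1.0 / 3.0))

    @classmethod
    def from_physiology(
        cls,
        N_terminals: int,
        *,
        Q0_total: float = 4.16e-6,
        rho: float = RHO_MYOCARDIUM,
        demand_ml_min_g: float = DEMAND_RESTING,
    ) -> "PerfusionParams":
        return cls(
            rho=rho,
            demand_per_mass=ml_min_g_to_si(demand_ml_min_g),
            Q0_total=Q0_total,
            N_terminals=N_terminals,
        )

    @classmethod
    def for_substrate(
        cls,
        substrate: "TissueSubstrate",
        N_terminals: int,
        *,
        demand_ml_min_g: float = DEMAND_RESTING,
    ) -> "PerfusionParams":
        """Inflow matched to the substrate: ``Q0 = q_required * V_tissue``.

        With this choice the N supply spheres have exactly the tissue
        volume in total, so a perfect tiling (every voxel covered once)
        is geometrically possible.  The full-heart parameters are
        self-consistent in this sense already; use this for toy
        substrates of other sizes.
        """
        demand_si = ml_min_g_to_si(demand_ml_min_g)
        q = flow_demand_per_volume(substrate.rho, demand_si, units="si")
        V_tissue = substrate.tissue_voxel_count * substrate.voxel_size**3
        return cls(
            rho=substrate.rho,
            demand_per_mass=demand_si,
            Q0_total=q * V_tissue,
            N_terminals=N_terminals,
        )


def supply_radius(params: PerfusionParams) -> float:
    """Radius (m) of one terminal's spherical supply territory."""
    return params.R_supply


@dataclass
class TissueSubstrate:
    """Binary tissue occupancy on a regular isotropic voxel grid.

    Voxel ``(i, j, k)`` occupies the half-open cell
    ``origin + [i, i+1) * h`` (per axis) with its physical *centre* at
    ``origin + (i + 0.5) h``; a point belongs to the voxel whose centre
    is nearest.
    """

    occupancy: np.ndarray  # bool, 3-D
    voxel_size: float  # m, isotropic
    origin: np.ndarray = None  # physical coordinate of the grid corner
    rho: float = RHO_MYOCARDIUM

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3-D grid")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def tissue_voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def tissue_mass(self) -> float:
        """Tissue mass in kg: rho * h^3 * (number of tissue voxels)."""
        return self.rho * self.voxel_size**3 * self.tissue_voxel_count

    @property
    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box (lo, hi) of the whole grid."""
        hi = self.origin + np.asarray(self.shape) * self.voxel_size
        return self.origin.copy(), hi

    def point_to_index(self, point: np.ndarray) -> np.ndarray:
        """Integer voxel index containing ``point`` (no bounds check)."""
        return np.floor((np.asarray(point) - self.origin) / self.voxel_size).astype(int)

    def index_center(self, index: np.ndarray) -> np.ndarray:
        """Physical centre of voxel ``index``."""
        return self.origin + (np.asarray(index, dtype=float) + 0.5) * self.voxel_size

    def in_grid(self, point: np.ndarray) -> bool:
        lo, hi = self.bbox
        p = np.asarray(point)
        return bool(np.all(p >= lo) and np.all(p < hi))

    def is_tissue_point(self, point: np.ndarray) -> bool:
        """True when ``point`` lies inside the grid in a tissue voxel."""
        if not self.in_grid(point):
            return False
        i, j, k = self.point_to_index(point)
        return bool(self.occupancy[i, j, k])

    def tissue_voxel_centers(self) -> np.ndarray:
        """(n_tissue, 3) physical centres of all tissue voxels."""
        idx = np.argwhere(self.occupancy)
        return self.origin + (idx + 0.5) * self.voxel_size


@dataclass
class DistanceMap:
    """Per-voxel Euclidean distance (m) to the tissue surface.

    ``values`` is zero on every non-tissue voxel and strictly positive
    inside tissue.
    """

    values: np.ndarray
    voxel_size: float


def compute_distance_map(substrate: TissueSubstrate) -> DistanceMap:
    """Exact Euclidean distance transform of the tissue mask.

    Each tissue voxel gets the distance from its centre to the nearest
    non-tissue voxel centre; voxels outside tissue get exactly zero.
    """
    occ = substrate.occupancy
    n_tissue = occ.sum()
    if n_tissue == 0 or n_tissue == occ.size:
        raise ValueError("substrate must contain both tissue and non-tissue voxels")
    values = ndimage.distance_transform_edt(occ, sampling=substrate.voxel_size)
    return DistanceMap(values=values, voxel_size=substrate.voxel_size)


def _voxel_center_grids(shape: tuple[int, int, int], voxel_size: float, origin: np.ndarray):
    axes = [origin[d] + (np.arange(shape[d]) + 0.5) * voxel_size for d in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def build_toy_substrate(
    shape: str,
    *,
    voxel_size: float = 1e-3,
    radius: float | None = None,
    thickness: int | None = None,
    outer: float | None = None,
    inner: float | None = None,
    extent: int = 20,
    pad: int = 2,
    rho: float = RHO_MYOCARDIUM,
) -> TissueSubstrate:
    """Deterministic test-friendly substrates: ``sphere``, ``slab`` or ``shell``.

    ``radius``/``outer``/``inner`` are in voxel units; ``thickness`` and
    ``extent`` are voxel counts.  The mask is padded by ``pad`` empty
    voxels on every side so a distance transform is well defined.
    """
    if shape == "sphere":
        if radius is None or radius <= 0:
            raise ValueError("sphere needs a positive radius (voxels)")
        n = int(2 * (np.ceil(radius) + pad) + 1)
        c = (n - 1) / 2.0
        ii, jj, kk = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
        occ = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2 <= radius**2
    elif shape == "slab":
        if thickness is None or thickness < 1:
            raise ValueError("slab needs a positive thickness (voxels)")
        nx = extent + 2 * pad
        nz = thickness + 2 * pad
        occ = np.zeros((nx, nx, nz), dtype=bool)
        occ[pad:-pad, pad:-pad, pad : pad + thickness] = True
    elif shape == "shell":
        if outer is None or inner is None or not (0 < inner < outer):
            raise ValueError("shell needs 0 < inner < outer (voxels)")
        n = int(2 * (np.ceil(outer) + pad) + 1)
        c = (n - 1) / 2.0
        ii, jj, kk = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
        r2 = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2
        occ = (r2 <= outer**2) & (r2 > inner**2)
    else:
        raise ValueError(f"unknown toy shape {shape!r}")
    return TissueSubstrate(occupancy=occ, voxel_size=voxel_size, rho=rho)


def _superellipsoid_mask(X, Y, Z, center, semiaxes, exponent):
    t = (
        np.abs((X - center[0]) / semiaxes[0]) ** exponent
        + np.abs((Y - center[1]) / semiaxes[1]) ** exponent
        + np.abs((Z - center[2]) / semiaxes[2]) ** exponent
    )
    return t <= 1.0


def build_heart_substrate(
    mass_target: float = 0.218,
    voxel_size: float = 1.5e-3,
    *,
    outer_semiaxes: tuple[float, float, float] = (0.045, 0.045, 0.065),
    lv_cavity_scale: float | None = 0.72,
    rv_semiaxes: tuple[float, float, float] | None = (0.014, 0.030, 0.048),
    rv_center: tuple[float, float, float] = (0.024, 0.0, 0.004),
    rv_exponent: float = 2.5,
    truncate: bool = True,
    mass_tolerance: float = 0.02,
    rho: float = RHO_MYOCARDIUM,
) -> TissueSubstrate:
    """Idealized ventricular myocardium hitting a target mass.

    The muscle is an outer ellipsoid minus a concentric left-ventricular
    cavity (a scaled copy of the outer ellipsoid, scale
    ``lv_cavity_scale``) minus a laterally offset right-ventricular
    cavity shaped as a super-ellipsoid of exponent ``rv_exponent``
    (2.5 by default, a flattened crescent-like chamber).  The basal
    truncation plane (tissue kept *above* it, apex pointing +z) is
    placed so the voxelized tissue mass matches ``mass_target`` (kg)
    within ``mass_tolerance`` relative.

    Set ``lv_cavity_scale=None``/``rv_semiaxes=None``/``truncate=False``
    to disable cavities or truncation (e.g. solid-ellipsoid limits).
    """
    if any(a <= 0 for a in outer_semiaxes):
        raise ValueError("outer semi-axes must be positive")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    a, b, c = outer_semiaxes
    pad = 2 * voxel_size
    lo = -np.array([a, b, c]) - pad
    hi = np.array([a, b, c]) + pad
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / voxel_size)) for d in range(3))
    origin = lo
    X, Y, Z = _voxel_center_grids(shape, voxel_size, origin)

    occ = _superellipsoid_mask(X, Y, Z, (0, 0, 0), outer_semiaxes, 2.0)
    if lv_cavity_scale is not None:
        lv_axes = tuple(s * lv_cavity_scale for s in outer_semiaxes)
        occ &= ~_superellipsoid_mask(X, Y, Z, (0, 0, 0), lv_axes, 2.0)
    if rv_semiaxes is not None:
        occ &= ~_superellipsoid_mask(X, Y, Z, rv_center, rv_semiaxes, rv_exponent)

    if truncate:
        # Mass is a step function of the cut height (voxel-centre test),
        # so pick the z-layer cut whose cumulative mass is closest.
        voxel_mass = rho * voxel_size**3
        layer_counts = occ.sum(axis=(0, 1))  # per z-layer (axis 2)
        # keep layers k..end (tissue above the plane); cumulative from the top? no:
        # keep z >= z_cut means layers with index >= k_cut.
        masses = voxel_mass * np.cumsum(layer_counts[::-1])[::-1]  # masses[k] = mass of layers >= k
        k_best = int(np.argmin(np.abs(masses - mass_target)))
        rel_err = abs(masses[k_best] - mass_target) / mass_target
        if rel_err > mass_tolerance:
            raise ValueError(
                f"cannot reach target mass {mass_target} kg within "
                f"{mass_tolerance:.0%} (best {masses[k_best]:.4f} kg); "
                "adjust geometry or resolution"
            )
        occ = occ.copy()
        occ[:, :, :k_best] = False

    sub = TissueSubstrate(occupancy=occ, voxel_size=voxel_size, origin=origin, rho=rho)
    if not truncate:
        return sub
    if sub.tissue_voxel_count < 1000:
        raise ValueError("resolution too coarse: fewer than 1000 tissue voxels")
    return sub


@dataclass
class SupplyMap:
    """Integer per-voxel count of covering terminal supply spheres.

    ``counts[v]`` is the number of terminals whose centre lies within
    ``R_supply`` of the voxel centre ``v``.  Painting is additive, so a
    terminal move is the removal of its old sphere plus the addition of
    the new one; both touch only a local bounding box.
    """

    counts: np.ndarray  # int32
    R_supply: float
    voxel_size: float
    origin: np.ndarray

    def sphere_patch(self, position: np.ndarray):
        """Local (slices, mask) of voxels whose centre is within R_supply.

        The slices index into ``counts``; ``mask`` selects covered
        voxels inside that box.  Spheres sticking out of the grid are
        silently clipped (out-of-grid voxels hold no tissue).
        """
        p = np.asarray(position, dtype=float)
        h = self.voxel_size
        shape = self.counts.shape
        lo_idx = np.floor((p - self.R_supply - self.origin) / h - 0.5).astype(int)
        hi_idx = np.ceil((p + self.R_supply - self.origin) / h - 0.5).astype(int) + 1
        lo_idx = np.maximum(lo_idx, 0)
        hi_idx = np.minimum(hi_idx, shape)
        if np.any(lo_idx >= hi_idx):
            empty = (slice(0, 0), slice(0, 0), slice(0, 0))
            return empty, np.zeros((0, 0, 0), dtype=bool)
        slices = tuple(slice(int(lo_idx[d]), int(hi_idx[d])) for d in range(3))
        ax0, ax1, ax2 = (
            self.origin[d] + (np.arange(lo_idx[d], hi_idx[d]) + 0.5) * h - p[d] for d in range(3)
        )
        mask = (
            ax0[:, None, None] ** 2 + ax1[None, :, None] ** 2 + ax2[None, None, :] ** 2
            <= self.R_supply**2
        )
        return slices, mask

    def add_terminal(self, position: np.ndarray) -> None:
        slices, mask = self.sphere_patch(position)
        self.counts[slices][mask] += 1

    def remove_terminal(self, position: np.ndarray) -> None:
        slices, mask = self.sphere_patch(position)
        patch = self.counts[slices]
        if np.any(patch[mask] < 1):
            raise ValueError("removing a terminal sphere that was never painted")
        patch[mask] -= 1

    def copy(self) -> "SupplyMap":
        return SupplyMap(self.counts.copy(), self.R_supply, self.voxel_size, self.origin.copy())


def paint_supply(
    substrate: TissueSubstrate,
    terminal_positions: np.ndarray,
    R_supply: float,
) -> SupplyMap:
    """Paint all terminal supply spheres onto a fresh count map."""
    counts = np.zeros(substrate.shape, dtype=np.int32)
    smap = SupplyMap(
        counts=counts,
        R_supply=R_supply,
        voxel_size=substrate.voxel_size,
        origin=substrate.origin,
    )
    for p in np.atleast_2d(np.asarray(terminal_positions, dtype=float)):
        smap.add_terminal(p)
    return smap
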