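"""Persistence: substrates as HDF5, trees as SWC / CSV / legacy VTK.

SWC is the field's plain-text morphology interchange format: one node
per line, ``id type x y z radius parent`` with coordinates here written
in micrometres and a 1-based id scheme.  The richer CSV adds per-segment
flow, pressure and Strahler order.  The VTK writer emits ASCII legacy
polydata (one polyline per segment with radius as point data) for 3-D
rendering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import strahler_orders
from .substrate import DistanceMap, SupplyMap, TissueSubstrate
from .tree import BIFURCATION, ROOT, TERMINAL, ArterialTree, assign_radii, compute_pressures

__all__ = [
    "save_substrate",
    "load_substrate",
    "to_swc",
    "tree_to_csv",
    "to_vtk_polydata",
    "mask_to_nifti",
    "mask_from_nifti",
]

_SWC_TYPE = {ROOT: 1, BIFURCATION: 5, TERMINAL: 6}  # root, fork point, endpoint


def save_substrate(
    path,
    substrate: TissueSubstrate,
    distance_map: DistanceMap | None = None,
    supply_map: SupplyMap | None = None,
) -> None:
    """Write occupancy (+optional maps) into one HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("occupancy", data=substrate.occupancy, compression="gzip")
        f.attrs["voxel_size"] = substrate.voxel_size
        f.attrs["origin"] = substrate.origin
        f.attrs["rho"] = substrate.rho
        if distance_map is not None:
            f.create_dataset("distance", data=distance_map.values, compression="gzip")
        if supply_map is not None:
            f.create_dataset("supply", data=supply_map.counts, compression="gzip")
            f.attrs["R_supply"] = supply_map.R_supply


def load_substrate(path) -> tuple[TissueSubstrate, DistanceMap | None, SupplyMap | None]:
    import h5py

    with h5py.File(path, "r") as f:
        sub = TissueSubstrate(
            occupancy=f["occupancy"][...],
            voxel_size=float(f.attrs["voxel_size"]),
            origin=np.asarray(f.attrs["origin"]),
            rho=float(f.attrs["rho"]),
        )
        dmap = None
        if "distance" in f:
            dmap = DistanceMap(values=f["distance"][...], voxel_size=sub.voxel_size)
        smap = None
        if "supply" in f:
            smap = SupplyMap(
                counts=f["supply"][...],
                R_supply=float(f.attrs["R_supply"]),
                voxel_size=sub.voxel_size,
                origin=sub.origin,
            )
    return sub, dmap, smap


def to_swc(tree: ArterialTree, path=None) -> str:
    """Serialize the tree as SWC text (micrometre coordinates).

    Returns the text; also writes it when ``path`` is given.  Node ids
    are remapped to consecutive 1-based integers in topological order so
    every parent precedes its children, as SWC consumers expect.
    """
    if tree.radius is None:
        assign_radii(tree)
    order = tree.topological_order()
    remap = {int(n): i + 1 for i, n in enumerate(order)}
    lines = ["# id type x y z radius parent  (units: um)"]
    for n in order:
        n = int(n)
        p = int(tree.parent[n])
        x, y, z = tree.positions[n] * 1e6
        r = tree.radius[n] * 1e6
        lines.append(
            f"{remap[n]} {_SWC_TYPE[int(tree.kind[n])]} "
            f"{x:.6f} {y:.6f} {z:.6f} {r:.6f} {remap[p] if p >= 0 else -1}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as f:
            f.write(text)
    return text


def tree_to_csv(tree: ArterialTree, path=None) -> pd.DataFrame:
    """Segment table with geometry, flow, pressure drop and Strahler order."""
    if tree.radius is None:
        assign_radii(tree)
    sol = compute_pressures(tree)
    orders = strahler_orders(tree)
    seg = tree.segment_ids
    L = tree.segment_lengths()
    Q = tree.segment_flows()
    R = tree.segment_resistances()
    df = pd.DataFrame(
        {
            "node": seg,
            "parent": tree.parent[seg],
            "x_mm": tree.positions[seg, 0] * 1e3,
            "y_mm": tree.positions[seg, 1] * 1e3,
            "z_mm": tree.positions[seg, 2] * 1e3,
            "parent_x_mm": tree.positions[tree.parent[seg], 0] * 1e3,
            "parent_y_mm": tree.positions[tree.parent[seg], 1] * 1e3,
            "parent_z_mm": tree.positions[tree.parent[seg], 2] * 1e3,
            "length_mm": L[seg] * 1e3,
            "radius_mm": tree.radius[seg] * 1e3,
            "flow_m3_s": Q[seg],
            "pressure_Pa": sol.node_pressures[seg],
            "pressure_drop_Pa": Q[seg] * R[seg],
            "strahler_order": orders[seg],
        }
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df


def to_vtk_polydata(tree: ArterialTree, path) -> None:
    """ASCII legacy-VTK polydata: one polyline per segment, radius as data."""
    if tree.radius is None:
        assign_radii(tree)
    pts = tree.positions
    seg = tree.segment_ids
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\narterial tree\nASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            f.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        f.write(f"LINES {len(seg)} {3 * len(seg)}\n")
        for c in seg:
            f.write(f"2 {int(tree.parent[c])} {int(c)}\n")
        f.write(f"POINT_DATA {len(pts)}\nSCALARS radius float 1\nLOOKUP_TABLE default\n")
        for r in tree.radius:
            f.write(f"{r:.9e}\n")


def mask_to_nifti(substrate: TissueSubstrate, path) -> None:
    """Export the occupancy mask as NIfTI (spacing carried in the affine)."""
    import nibabel as nib

    affine = np.diag([substrate.voxel_size * 1e3] * 3 + [1.0])  # mm per NIfTI convention
    affine[:3, 3] = substrate.origin * 1e3
    img = nib.Nifti1Image(substrate.occupancy.astype(np.uint8), affine)
    nib.save(img, path)


def mask_from_nifti(path, rho: float | None = None) -> TissueSubstrate:
    """Import a binary mask volume; requires isotropic spacing."""
    import nibabel as nib

    from .substrate import RHO_MYOCARDIUM

    img = nib.load(path)
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError(f"anisotropic voxels {zooms} not supported")
    occ = np.asarray(img.dataobj) > 0
    origin = np.asarray(img.affine[:3, 3], dtype=float) * 1e-3
    return TissueSubstrate(
        occupancy=occ,
        voxel_size=float(zooms[0]) * 1e-3,
        origin=origin,
        rho=RHO_MYOCARDIUM if rho is None else rho,
    )
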