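"""Periodic Delaunay triangulation and Voronoi partition of leaflet lipid
centers; per-lipid areas and 2D/3D leaflet areas.

The triangulation tiles the 2D points over the 3x3 periodic images, runs
qhull on the tiled set, and reduces the result to a triangulation of the
torus by canonical deduplication: each simplex is translated so its
lowest-id vertex sits in the central cell and kept once.  The resulting
mesh satisfies the torus Euler relation V - E + F = 0, and its Voronoi
dual partitions the box cross-section exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, Voronoi

from .core import Frame, Topology, Trajectory
from .neighbors import min_image_displacement

JITTER = 1e-6  # A; deterministic degeneracy-breaking amplitude


def _jitter(n: int) -> np.ndarray:
    """Deterministic per-index jitter in (-JITTER, JITTER), hash-style."""
    idx = np.arange(n, dtype=float)
    jx = np.modf(np.sin(idx * 12.9898 + 78.233) * 43758.5453)[0]
    jy = np.modf(np.sin(idx * 26.6517 + 151.718) * 24634.6345)[0]
    return (np.column_stack([jx, jy]) - 0.5) * 2 * JITTER


_SHIFTS = np.array([(sx, sy) for sx in (-1, 0, 1) for sy in (-1, 0, 1)])
# central copy first so tiled index < n means "image in central cell"
_SHIFTS = np.vstack([[0, 0], _SHIFTS[np.any(_SHIFTS != 0, axis=1)]])


@dataclass
class PeriodicTessellation:
    """Torus Delaunay triangulation of 2D points in a periodic box."""

    points: np.ndarray                  # (n, 2), wrapped, un-jittered
    box: np.ndarray                     # (2,)
    mol_ids: np.ndarray                 # (n,) molecule index (or 0..n-1)
    triangles: np.ndarray               # (T, 3) point indices
    tri_offsets: np.ndarray             # (T, 3, 2) integer image offsets
    n_edges: int                        # distinct torus edges
    edge_pairs: np.ndarray = field(repr=False, default=None)  # (E, 2) ids per edge

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def euler_characteristic(self) -> int:
        return self.n_points - self.n_edges + self.n_triangles

    def neighbor_counts(self) -> np.ndarray:
        """Number of distinct torus edges incident to each point."""
        c = np.zeros(self.n_points, dtype=int)
        for i, j in self.edge_pairs:
            c[i] += 1
            if j != i:
                c[j] += 1
        return c


def _tile(points: np.ndarray, box: np.ndarray):
    n = len(points)
    tiled = np.concatenate([points + s * box for s in _SHIFTS])
    src = np.tile(np.arange(n), len(_SHIFTS))
    offs = np.repeat(_SHIFTS, n, axis=0)
    return tiled, src, offs


def periodic_delaunay(points: np.ndarray, box, mol_ids=None) -> PeriodicTessellation:
    """Delaunay triangulation of 2D points on the periodic box (torus).

    Requires >= 4 points; cocircular degeneracies (regular lattices) are
    broken by a deterministic 1e-6 A jitter so output is reproducible.
    Raises on collinear input.
    """
    points = np.asarray(points, dtype=float)
    box = np.asarray(box, dtype=float)[:2]
    n = len(points)
    if n < 4:
        raise ValueError("periodic Delaunay needs at least 4 points")
    if mol_ids is None:
        mol_ids = np.arange(n)
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate point set: all points collinear")
    pts = np.mod(points, box) + _jitter(n)
    tiled, src, offs = _tile(pts, box)
    try:
        tri = Delaunay(tiled)
    except Exception as e:  # qhull degenerate input
        raise ValueError(f"degenerate point set (collinear?): {e}") from e

    seen: dict[tuple, tuple[tuple[int, ...], np.ndarray]] = {}
    for simplex in tri.simplices:
        if not np.any(simplex < n):
            continue
        ids = src[simplex]
        off = offs[simplex]
        verts = sorted(zip(ids.tolist(), off.tolist()))
        a_id, a_off = verts[0]
        shifted = [(i, (o[0] - a_off[0], o[1] - a_off[1])) for i, o in verts]
        key = tuple(shifted)
        if key not in seen:
            seen[key] = (
                tuple(i for i, _ in shifted),
                np.array([o for _, o in shifted], dtype=int),
            )
    triangles = np.array([v[0] for v in seen.values()], dtype=int)
    tri_offsets = np.array([v[1] for v in seen.values()], dtype=int)

    edge_keys = set()
    for t, toff in zip(triangles, tri_offsets):
        for a, b in ((0, 1), (0, 2), (1, 2)):
            ia, ib = int(t[a]), int(t[b])
            oa, ob = toff[a], toff[b]
            if (ia, tuple(oa)) <= (ib, tuple(ob)):
                i, j, rel = ia, ib, ob - oa
            else:
                i, j, rel = ib, ia, oa - ob
            if i == j and tuple(rel) < tuple(-rel):
                rel = -rel
            edge_keys.add((i, j, int(rel[0]), int(rel[1])))
    edge_pairs = np.array([(k[0], k[1]) for k in sorted(edge_keys)], dtype=int)
    return PeriodicTessellation(
        points=np.mod(points, box),
        box=box,
        mol_ids=np.asarray(mol_ids),
        triangles=triangles,
        tri_offsets=tri_offsets,
        n_edges=len(edge_keys),
        edge_pairs=edge_pairs,
    )


def voronoi_areas(tess: PeriodicTessellation) -> np.ndarray:
    """Per-point Voronoi cell areas (A^2); they partition the box exactly."""
    pts = tess.points + _jitter(tess.n_points)
    tiled, _, _ = _tile(pts, tess.box)
    vor = Voronoi(tiled)
    areas = np.empty(tess.n_points)
    for i in range(tess.n_points):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("unbounded Voronoi cell for a central point")
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return areas


# ---------------------------------------------------------------------------
# Lipid centers and leaflet areas


def lipid_centers(
    frame: Frame, topo: Topology, leaflet: str | None = None, headgroup_only: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Mass-weighted centers of mass of (leaflet) lipids, wrapped into the box.

    Molecules straddling the periodic boundary are made whole by min-image
    reconstruction relative to their first atom before averaging, so the
    COM is continuous as lipids cross the boundary.  Returns
    (molecule ids, COM (n,3)); the xy columns are the 2D projection.
    """
    reg = topo.registry
    mols = []
    for m in topo.molecules:
        if not reg[m.species].is_lipid:
            continue
        if leaflet is not None:
            if m.leaflet == "none":
                raise ValueError(f"molecule {m.index} has no leaflet assigned")
            if m.leaflet != leaflet:
                continue
        mols.append(m)
    if not mols:
        raise ValueError(f"no lipids in leaflet {leaflet!r}")
    out = np.empty((len(mols), 3))
    for k, m in enumerate(mols):
        pos = frame.positions[m.atoms]
        masses = topo.masses[m.atoms]
        if headgroup_only:
            sdef = reg[m.species]
            ref = sdef.atom_index(sdef.headgroup_ref)
            out[k] = pos[ref]
            continue
        ref = pos[0]
        rel = min_image_displacement(ref, pos, frame.box)
        com = ref + (masses[:, None] * rel).sum(axis=0) / masses.sum()
        out[k] = np.mod(com, frame.box)
    return np.array([m.index for m in mols]), out


def leaflet_tessellation(frame: Frame, topo: Topology, leaflet: str) -> tuple[PeriodicTessellation, np.ndarray]:
    """Periodic Delaunay tessellation of one leaflet's projected COMs.

    Returns (tessellation, COM z per point) so 3D areas can restore height.
    """
    ids, com = lipid_centers(frame, topo, leaflet)
    tess = periodic_delaunay(com[:, :2], frame.box[:2], mol_ids=ids)
    return tess, com[:, 2]


def mesh_area_3d(tess: PeriodicTessellation, z: np.ndarray) -> float:
    """Total area of the 3D triangle mesh obtained by restoring per-point z."""
    total = 0.0
    for t, off in zip(tess.triangles, tess.tri_offsets):
        xy = tess.points[t] + off * tess.box
        v = np.column_stack([xy, z[t]])
        total += 0.5 * np.linalg.norm(np.cross(v[1] - v[0], v[2] - v[0]))
    return float(total)


def leaflet_area_3d(frame: Frame, topo: Topology, leaflet: str) -> float:
    """3D (rugged) leaflet area from the periodic Delaunay mesh of lipid COMs.

    Always >= the projected 2D box cross-section; equality for a flat leaflet.
    """
    tess, z = leaflet_tessellation(frame, topo, leaflet)
    return mesh_area_3d(tess, z)


@dataclass
class LeafletAreaResult:
    """Per-frame leaflet areas plus per-lipid Voronoi area distributions."""

    areas: pd.DataFrame          # frame, time, leaflet, area_3d, area_2d
    per_lipid: pd.DataFrame      # frame, leaflet, mol, species, voronoi_area


def area_timeseries(traj: Trajectory, leaflets=("inner", "outer")) -> LeafletAreaResult:
    """3D mesh area, projected box area and per-lipid Voronoi areas per frame."""
    topo = traj.topology
    area_rows, lipid_rows = [], []
    for fi, fr in enumerate(traj.frames):
        box_area = float(fr.box[0] * fr.box[1])
        for leaflet in leaflets:
            tess, z = leaflet_tessellation(fr, topo, leaflet)
            a3 = mesh_area_3d(tess, z)
            area_rows.append(
                {"frame": fi, "time": fr.time, "leaflet": leaflet,
                 "area_3d": a3, "area_2d": box_area}
            )
            va = voronoi_areas(tess)
            for mol, a in zip(tess.mol_ids, va):
                lipid_rows.append(
                    {"frame": fi, "leaflet": leaflet, "mol": int(mol),
                     "species": topo.molecules[int(mol)].species, "voronoi_area": float(a)}
                )
    return LeafletAreaResult(pd.DataFrame(area_rows), pd.DataFrame(lipid_rows))
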