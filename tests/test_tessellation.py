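"""Periodic Delaunay/Voronoi correctness: circumcircle oracle, torus Euler
relation, area conservation, 3D mesh areas."""
import numpy as np
import pytest

from ionbridge import synth
from ionbridge.core import assign_leaflets
from ionbridge.tessellation import (
    area_timeseries,
    leaflet_area_3d,
    leaflet_tessellation,
    lipid_centers,
    mesh_area_3d,
    periodic_delaunay,
    voronoi_areas,
)


def hex_lattice(nx=6, ny=6, a=5.0):
    pts = [
        [(i + 0.5 * (j % 2)) * a, j * a * np.sqrt(3) / 2]
        for i in range(nx)
        for j in range(ny)
    ]
    return np.array(pts), np.array([nx * a, ny * a * np.sqrt(3) / 2])


def test_hexagonal_lattice_has_six_neighbors():
    pts, box = hex_lattice()
    tess = periodic_delaunay(pts, box)
    assert set(tess.neighbor_counts().tolist()) == {6}
    assert tess.euler_characteristic() == 0


def test_translation_invariance_of_edges(rng):
    pts = rng.uniform(0, 40, (25, 2))
    box = np.array([40.0, 40.0])
    t0 = periodic_delaunay(pts, box)
    t1 = periodic_delaunay(pts + box * np.array([2, -1]), box)
    e0 = {tuple(sorted(e)) for e in t0.edge_pairs.tolist()}
    e1 = {tuple(sorted(e)) for e in t1.edge_pairs.tolist()}
    assert e0 == e1


def test_collinear_points_rejected():
    pts = np.column_stack([np.linspace(1, 9, 6), np.full(6, 5.0)])
    with pytest.raises(ValueError, match="degenerate|collinear"):
        periodic_delaunay(pts, [10.0, 10.0])


def test_too_few_points_rejected():
    with pytest.raises(ValueError, match="at least 4"):
        periodic_delaunay(np.zeros((3, 2)), [10.0, 10.0])


def _circumcircle(p1, p2, p3):
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    c = np.array([ux, uy])
    return c, np.linalg.norm(p1 - c)


@pytest.mark.parametrize("n_points,seed", [(10, 0), (20, 1), (30, 2)])
def test_triangles_pass_empty_circumcircle_oracle(n_points, seed):
    """Delaunay property on the torus: no minimum-image point strictly
    inside any triangle's circumcircle."""
    rng = np.random.default_rng(seed)
    box = np.array([30.0, 30.0])
    pts = rng.uniform(0, 1, (n_points, 2)) * box
    tess = periodic_delaunay(pts, box)
    for tri, off in zip(tess.triangles, tess.tri_offsets):
        verts = tess.points[tri] + off * box
        center, radius = _circumcircle(*verts)
        for j in range(n_points):
            for sx in (-1, 0, 1):
                for sy in (-1, 0, 1):
                    q = tess.points[j] + np.array([sx, sy]) * box
                    d = np.linalg.norm(q - center)
                    assert d >= radius - 1e-5, (tri, j)


def test_voronoi_square_lattice_equal_cells():
    pts = np.array([[5.0, 5.0], [15.0, 5.0], [5.0, 15.0], [15.0, 15.0]])
    tess = periodic_delaunay(pts, [20.0, 20.0])
    areas = voronoi_areas(tess)
    assert np.allclose(areas, 100.0, rtol=1e-4)


def test_voronoi_areas_partition_box(rng):
    box = np.array([35.0, 27.0])
    pts = rng.uniform(0, 1, (40, 2)) * box
    tess = periodic_delaunay(pts, box)
    areas = voronoi_areas(tess)
    assert np.all(areas > 0)
    assert areas.sum() == pytest.approx(box[0] * box[1], rel=1e-6)


def test_voronoi_matches_rasterisation_oracle(rng):
    """Nearest-center integration on a 0.1 A grid agrees within 0.5%."""
    box = np.array([20.0, 20.0])
    pts = rng.uniform(0, 1, (12, 2)) * box
    tess = periodic_delaunay(pts, box)
    areas = voronoi_areas(tess)
    step = 0.1
    xs = np.arange(step / 2, box[0], step)
    ys = np.arange(step / 2, box[1], step)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    # min-image distance to every center
    d2 = np.zeros((len(grid), len(pts)))
    for k, p in enumerate(pts):
        d = np.abs(grid - p)
        d = np.minimum(d, box - d)
        d2[:, k] = (d**2).sum(axis=1)
    counts = np.bincount(np.argmin(d2, axis=1), minlength=len(pts))
    raster = counts * step * step
    assert np.allclose(areas, raster, rtol=5e-3, atol=0.05)


def test_euler_relation_many_random_sets(rng):
    for n in (5, 8, 16, 33, 64):
        box = np.array([rng.uniform(20, 40), rng.uniform(20, 40)])
        pts = rng.uniform(0, 1, (n, 2)) * box
        tess = periodic_delaunay(pts, box)
        assert tess.euler_characteristic() == 0
        assert np.all(tess.neighbor_counts() >= 3)


def test_lipid_centers_continuous_across_boundary(small_bilayer):
    fr = small_bilayer.frames[0]
    topo = small_bilayer.topology
    ids, com = lipid_centers(fr, topo, "inner")
    assert len(ids) == 64
    assert np.all((com >= 0) & (com < fr.box))
    # straddling molecule: translate everything so a lipid crosses x=0
    from ionbridge.core import Frame as F

    shift = np.array([3.3, 0, 0])
    fr2 = F(fr.time, fr.box, np.mod(fr.positions + shift, fr.box))
    _, com2 = lipid_centers(fr2, topo, "inner")
    d = np.abs(com2 - com - shift)
    d = np.minimum(d, fr.box - d)
    assert np.max(d) < 1e-6


def test_flat_leaflet_3d_area_equals_box_area():
    # single-species leaflet: every COM sits at the same height -> flat mesh
    spec = synth.CompositionSpec(
        outer={"POPC": 1.0}, inner={"POPC": 1.0}, molecules_per_leaflet=36
    )
    traj = assign_leaflets(synth.build_bilayer(spec, seed=2, add_ions=False))
    fr = traj.frames[0]
    a3 = leaflet_area_3d(fr, traj.topology, "inner")
    box_area = fr.box[0] * fr.box[1]
    assert a3 == pytest.approx(box_area, rel=1e-9)


def test_sinusoidal_corrugation_approaches_quadrature(rng):
    """z = a sin(2 pi x / Lx): mesh area converges to the analytic integral."""
    from scipy.integrate import quad

    L = 40.0
    amp = 3.0
    box = np.array([L, L])

    def mesh_area(n_side):
        xs = (np.arange(n_side) + 0.5) * L / n_side
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        pts += rng.uniform(-0.05, 0.05, pts.shape)  # break exact degeneracy
        z = amp * np.sin(2 * np.pi * pts[:, 0] / L)
        tess = periodic_delaunay(pts, box)
        return mesh_area_3d(tess, z)

    exact = L * quad(lambda x: np.sqrt(1 + (amp * 2 * np.pi / L * np.cos(2 * np.pi * x / L)) ** 2), 0, L)[0]
    err_coarse = abs(mesh_area(8) - exact) / exact
    err_fine = abs(mesh_area(24) - exact) / exact
    assert err_fine < err_coarse
    assert err_fine < 0.01


def test_3d_area_always_geq_projected(rng):
    box = np.array([30.0, 30.0])
    pts = rng.uniform(0, 1, (30, 2)) * box
    z = rng.uniform(-2, 2, 30)
    tess = periodic_delaunay(pts, box)
    assert mesh_area_3d(tess, z) >= box[0] * box[1] - 1e-9


def test_area_timeseries_bumpy_inner_exceeds_flat_outer(small_bilayer):
    topo = small_bilayer.topology
    fr = small_bilayer.frames[0]
    pos = fr.positions.copy()
    # corrugate the inner leaflet only
    for m in topo.molecules:
        if m.leaflet == "inner":
            x = pos[m.start, 0]
            pos[m.atoms, 2] += 2.5 * np.sin(2 * np.pi * x / fr.box[0])
    from ionbridge.core import Frame as F, Trajectory as T

    bumpy = T(topo, [F(0.0, fr.box, np.mod(pos, fr.box)), F(100.0, fr.box, np.mod(pos, fr.box) + 0)])
    res = area_timeseries(bumpy)
    wide = res.areas.pivot(index="frame", columns="leaflet", values="area_3d")
    assert np.all(wide["inner"].values > wide["outer"].values)
    # static repeat: constant series
    assert np.allclose(wide["inner"].values, wide["inner"].values[0])
    # per-lipid Voronoi areas partition the box per leaflet and frame
    per = res.per_lipid
    for (_f, _l), grp in per.groupby(["frame", "leaflet"]):
        assert grp["voronoi_area"].sum() == pytest.approx(fr.box[0] * fr.box[1], rel=1e-6)
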