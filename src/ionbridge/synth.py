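"""Synthetic bilayer trajectories with planted, known statistical structure.

Every analysis stage in this package is validated against trajectories
whose ground truth is constructed rather than simulated: lipids on a
regular grid with seeded random species arrangement, 2D Brownian motion
with known diffusion constants, cations planted as 1-/2-/3-bridges with
specified lifetimes, water shells of fixed occupancy, and exact
hydrogen-bond geometries.  Builders return the planted truth ("ledger")
alongside the trajectory so detectors can be checked for exact agreement.

The default composition mirrors an asymmetric plasma-membrane model:
outer leaflet 75% POPC / 25% cholesterol; inner leaflet 50% DOPE /
25% cholesterol / 15% DOPS / 10% polyphosphoinositide, 400 molecules per
leaflet on a 1 nm grid, neutralised and salted to 150 mM.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import Frame, Molecule, Topology, Trajectory, wrap_positions
from .species import SpeciesDef, SpeciesRegistry, default_registry

AVOGADRO = 6.02214076e23
A3_TO_L = 1e-27


# ---------------------------------------------------------------------------
# Composition


@dataclass
class CompositionSpec:
    """Per-leaflet mole fractions plus grid geometry."""

    outer: dict[str, float]
    inner: dict[str, float]
    molecules_per_leaflet: int = 400
    grid_spacing: float = 10.0          # Angstrom (1 nm)
    ppi_species: str = "PI45P2"
    ppi_charge: float = -4.0            # e; -3, -4 or -5
    leaflet_offset: float = 18.0        # headgroup plane distance from midplane, A
    box_height: float = 80.0            # A

    def __post_init__(self) -> None:
        for name, fr in (("outer", self.outer), ("inner", self.inner)):
            s = sum(fr.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{name} leaflet fractions sum to {s}, not 1")


def physiological_composition(
    ppi: str = "PI45P2",
    ppi_charge: float = -4.0,
    molecules_per_leaflet: int = 400,
    grid_spacing: float = 10.0,
) -> CompositionSpec:
    """The asymmetric physiological composition used as the reference system."""
    return CompositionSpec(
        outer={"POPC": 0.75, "CHL1": 0.25},
        inner={"DOPE": 0.50, "CHL1": 0.25, "DOPS": 0.15, ppi: 0.10},
        molecules_per_leaflet=molecules_per_leaflet,
        grid_spacing=grid_spacing,
        ppi_species=ppi,
        ppi_charge=ppi_charge,
    )


def largest_remainder_counts(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Integer counts from mole fractions by the largest-remainder method.

    Ties in the remainders are broken by species name order, so the result
    is deterministic and the counts always sum to ``total`` exactly.
    """
    names = sorted(fractions)
    exact = np.array([fractions[n] * total for n in names])
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = total - int(base.sum())
    # stable argsort on (-remainder, name order)
    order = np.argsort(-rem, kind="stable")
    for k in order[:short]:
        base[k] += 1
    return {n: int(c) for n, c in zip(names, base)}


def reference_area_mismatch(spec: CompositionSpec, registry: SpeciesRegistry | None = None) -> float:
    """Relative area mismatch between leaflets from per-species reference areas.

    Asymmetric leaflets are balanced by molecule count here, so this check
    reports how far apart the two leaflets' nominal areas (sum of per-lipid
    reference areas) fall; the builder's compositions keep it below 5%.
    """
    reg = registry or default_registry()
    areas = []
    for fr in (spec.outer, spec.inner):
        counts = largest_remainder_counts(fr, spec.molecules_per_leaflet)
        a = 0.0
        for name, c in counts.items():
            ra = reg[name].reference_area
            if ra is None:
                raise ValueError(f"no reference area for species {name}")
            a += c * ra
        areas.append(a)
    return abs(areas[0] - areas[1]) / max(areas)


# ---------------------------------------------------------------------------
# Topology assembly helpers


class _Assembler:
    """Accumulates molecules (species templates placed at centers)."""

    def __init__(self, registry: SpeciesRegistry):
        self.registry = registry
        self.molecules: list[Molecule] = []
        self.names: list[str] = []
        self.masses: list[float] = []
        self.coords: list[np.ndarray] = []
        self._pos = 0

    def add(
        self,
        species: str,
        center: np.ndarray,
        mirror_z: bool = False,
        rot_z: float = 0.0,
        leaflet: str = "none",
    ) -> int:
        sdef = self.registry[species]
        off = sdef.offsets.copy()
        if rot_z:
            c, s = np.cos(rot_z), np.sin(rot_z)
            xy = off[:, :2] @ np.array([[c, s], [-s, c]])
            off = np.column_stack([xy, off[:, 2]])
        if mirror_z:
            off[:, 2] *= -1
        idx = len(self.molecules)
        self.molecules.append(
            Molecule(idx, species, self._pos, self._pos + sdef.n_atoms, leaflet)
        )
        self.names.extend(sdef.atom_names)
        self.masses.extend(sdef.masses.tolist())
        self.coords.append(np.asarray(center, dtype=float) + off)
        self._pos += sdef.n_atoms
        return idx

    def build(self, box, time: float = 0.0) -> Trajectory:
        topo = Topology(
            self.molecules,
            np.array(self.names, dtype=object),
            np.array(self.masses, dtype=float),
            self.registry,
        )
        box = np.asarray(box, dtype=float)
        pos = wrap_positions(np.concatenate(self.coords), box)
        return Trajectory(topo, [Frame(time, box, pos)])


def _registry_with_ppi_charge(registry: SpeciesRegistry, species: str, charge: float) -> SpeciesRegistry:
    if registry[species].charge == charge:
        return registry
    defs = dict(registry.defs)
    defs[species] = dataclasses.replace(defs[species], charge=charge)
    return SpeciesRegistry(defs)


# ---------------------------------------------------------------------------
# Bilayer builder


def build_bilayer(
    spec: CompositionSpec,
    seed: int,
    ion_species: str = "CAL",
    ionic_strength_mM: float = 150.0,
    add_ions: bool = True,
    registry: SpeciesRegistry | None = None,
) -> Trajectory:
    """Construct a single-frame bilayer on a regular grid.

    Lipids sit on an n x n grid per leaflet (molecules_per_leaflet must be a
    perfect square) with species assigned by a seeded shuffle; the outer
    leaflet occupies the upper headgroup plane.  Neutralising cations of
    ``ion_species`` plus salt at ``ionic_strength_mM`` (counted from the
    solvent slab volume) are scattered in the solvent, at least 3 A from
    any lipid atom.
    """
    reg = _registry_with_ppi_charge(registry or default_registry(), spec.ppi_species, spec.ppi_charge)
    n_side = round(np.sqrt(spec.molecules_per_leaflet))
    if n_side * n_side != spec.molecules_per_leaflet:
        raise ValueError(
            f"molecules_per_leaflet={spec.molecules_per_leaflet} is not a perfect square"
        )
    L = n_side * spec.grid_spacing
    box = np.array([L, L, spec.box_height])
    z_mid = spec.box_height / 2.0
    rng = np.random.default_rng(seed)
    asm = _Assembler(reg)

    gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    sites = (np.column_stack([gx.ravel(), gy.ravel()]) + 0.5) * spec.grid_spacing

    lipid_charge = 0.0
    for leaflet, fractions, zc, mirror in (
        ("outer", spec.outer, z_mid + spec.leaflet_offset, False),
        ("inner", spec.inner, z_mid - spec.leaflet_offset, True),
    ):
        counts = largest_remainder_counts(fractions, spec.molecules_per_leaflet)
        names = [n for n in sorted(counts) for _ in range(counts[n])]
        rng.shuffle(names)
        for (x, y), name in zip(sites, names):
            asm.add(name, np.array([x, y, zc]), mirror_z=mirror, leaflet=leaflet)
            lipid_charge += reg[name].charge

    if add_ions:
        z_cat = reg[ion_species].charge
        if z_cat <= 0:
            raise ValueError("ion_species must be a cation")
        n_neutral = int(np.ceil(max(0.0, -lipid_charge) / z_cat))
        slab = spec.box_height - 2 * (spec.leaflet_offset + 4.0)
        vol_l = L * L * slab * A3_TO_L
        n_salt = int(round(ionic_strength_mM * 1e-3 * vol_l * AVOGADRO))
        n_cat = n_neutral + n_salt
        n_cl = n_salt * int(z_cat)  # salt is neutral; neutralisers balance the lipids
        lipid_xyz = np.concatenate(asm.coords)
        placed = _scatter_in_solvent(
            rng, n_cat + n_cl, box, z_mid, spec.leaflet_offset, lipid_xyz, min_dist=3.0
        )
        for k in range(n_cat):
            asm.add(ion_species, placed[k])
        for k in range(n_cat, n_cat + n_cl):
            asm.add("CLA", placed[k])

    return asm.build(box)


def _scatter_in_solvent(rng, n, box, z_mid, leaflet_offset, lipid_xyz, min_dist=3.0):
    """Uniform random points in the solvent slab, excluded near lipid atoms."""
    from scipy.spatial import cKDTree

    lo = z_mid + leaflet_offset + 3.0
    hi = z_mid - leaflet_offset - 3.0  # below the inner leaflet (wraps through z=0)
    span_up = box[2] - lo
    span_dn = hi
    tree = cKDTree(np.mod(lipid_xyz, box))
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 200 * max(n, 1):
            raise RuntimeError("could not place solvent ions without overlap")
        m = n - len(out)
        xy = rng.uniform(0, 1, size=(m, 2)) * box[:2]
        u = rng.uniform(0, span_up + span_dn, size=m)
        z = np.where(u < span_up, lo + u, u - span_up)
        cand = np.column_stack([xy, z])
        d, _ = tree.query(cand)
        # ghost images near box faces are ignored here; the slab keeps ions
        # far from lipids in z, and xy wrapping only matters within min_dist
        ok = d >= min_dist
        out.extend(cand[ok].tolist())
    return np.asarray(out[:n])


# ---------------------------------------------------------------------------
# Brownian motion


@dataclass
class MotionSpec:
    """Per-species lateral diffusion constants for rigid 2D Brownian motion."""

    diffusion: dict[str, float] | float  # A^2/ps per species (scalar = all)
    dt: float = 100.0                    # frame interval, ps
    drift: dict[str, tuple[float, float]] | None = None  # leaflet -> (vx, vy) A/ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        vals = (
            [self.diffusion]
            if np.isscalar(self.diffusion)
            else list(self.diffusion.values())
        )
        if any(d < 0 for d in vals):
            raise ValueError("diffusion constants must be >= 0")

    def d_for(self, species: str) -> float:
        if np.isscalar(self.diffusion):
            return float(self.diffusion)
        return float(self.diffusion.get(species, 0.0))


def simulate_motion(traj: Trajectory, spec: MotionSpec, n_frames: int) -> Trajectory:
    """Extend a trajectory with rigid 2D Brownian steps per molecule.

    Each molecule translates independently in xy with per-axis step variance
    2*D*dt (D looked up by species), plus an optional uniform per-leaflet
    drift; all atoms of a molecule move rigidly and are re-wrapped.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    topo = traj.topology
    rng = np.random.default_rng(spec.seed)
    last = traj.frames[-1]
    box = last.box
    sigma = np.array([np.sqrt(2.0 * spec.d_for(m.species) * spec.dt) for m in topo.molecules])
    drift = np.zeros((topo.n_molecules, 2))
    if spec.drift:
        for m in topo.molecules:
            v = spec.drift.get(m.leaflet)
            if v is not None:
                drift[m.index] = v
    frames = list(traj.frames)
    pos = last.positions.copy()
    t = last.time
    for _ in range(n_frames - 1):
        steps = rng.normal(0.0, 1.0, size=(topo.n_molecules, 2)) * sigma[:, None]
        steps += drift * spec.dt
        for m in topo.molecules:
            pos[m.atoms, :2] += steps[m.index]
        pos = wrap_positions(pos, box)
        t += spec.dt
        frames.append(Frame(t, box, pos.copy()))
    return Trajectory(topo, frames)


# ---------------------------------------------------------------------------
# Bridge planting


@dataclass
class BridgePlantSpec:
    """One planted N-bridge: which ion, which lipids, when, for how long."""

    ion_species: str
    lipids: tuple[int, ...]             # molecule indices; order N = len
    start: int = 0
    lifetime: int | None = None         # frames; None = whole trajectory

    @property
    def order(self) -> int:
        return len(self.lipids)


def _mini_ball(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest enclosing ball of 1-3 points in 3D."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 1:
        return pts[0], 0.0
    if len(pts) == 2:
        c = pts.mean(axis=0)
        return c, float(np.linalg.norm(pts[0] - c))
    # three points: try each side's midpoint, else circumcenter
    best = None
    for i, j in ((0, 1), (0, 2), (1, 2)):
        c = (pts[i] + pts[j]) / 2
        r = np.linalg.norm(pts[i] - c)
        if all(np.linalg.norm(p - c) <= r + 1e-9 for p in pts):
            if best is None or r < best[1]:
                best = (c, float(r))
    if best is not None:
        return best
    a, b, c3 = pts
    ab, ac = b - a, c3 - a
    n = np.cross(ab, ac)
    nn = np.dot(n, n)
    if nn < 1e-18:
        raise ValueError("degenerate (collinear) oxygen triple")
    cc = a + np.cross(np.dot(ab, ab) * ac - np.dot(ac, ac) * ab, n) / (2 * nn)
    return cc, float(np.linalg.norm(a - cc))


def _bridge_site(frame: Frame, topo: Topology, lipids, placement_radius: float) -> np.ndarray:
    """Ion position within placement_radius of >=1 anionic oxygen per lipid.

    Tries one oxygen per lipid over all combinations and takes the smallest
    enclosing ball; raises if no combination fits inside placement_radius.
    """
    from itertools import product as iproduct

    box = frame.box
    cand_atoms = []
    for li in lipids:
        sdef = topo.species_def(li)
        names = sdef.anionic or sdef.acceptors
        if not names:
            raise ValueError(f"lipid species {sdef.name} has no bindable oxygens")
        cand_atoms.append([topo.find_atom(li, nm) for nm in names])
    ref = frame.positions[cand_atoms[0][0]]
    best = None
    for combo in iproduct(*cand_atoms):
        pts = frame.positions[list(combo)]
        # make coordinates min-image consistent relative to the first oxygen
        pts = ref + (pts - ref) - box * np.round((pts - ref) / box)
        c, r = _mini_ball(pts)
        if best is None or r < best[1]:
            best = (c, r)
    c, r = best
    if r > placement_radius + 1e-9:
        raise ValueError(
            f"bridge geometrically infeasible: lipids {tuple(lipids)} require radius "
            f"{r:.2f} A > placement radius {placement_radius:.2f} A"
        )
    return np.mod(c, box)


def plant_bridges(
    traj: Trajectory,
    specs: list[BridgePlantSpec],
    placement_radius: float | None = None,
    parking_gap: float = 2.0,
    validate: bool = True,
) -> tuple[Trajectory, list[dict]]:
    """Insert cations realising the requested N-bridges; return truth ledger.

    During its lifetime each planted ion sits within ``placement_radius``
    (default: the ion's first-shell radius) of one anionic oxygen of every
    listed lipid; outside its lifetime it is parked in the solvent far from
    all lipids.  With ``validate`` the planted geometry is re-checked with
    the molecule-minimum-distance criterion each frame: the bound lipid set
    must equal the listed set exactly, otherwise the plant is rejected as
    infeasible.  The ledger lists one dict per spec with the ion's molecule
    index, species, lipids, order and active frame range.
    """
    topo = traj.topology
    reg = topo.registry
    n_frames = traj.n_frames
    box = traj.frames[0].box

    new_mols = list(topo.molecules)
    names = list(topo.atom_names)
    masses = list(topo.masses)
    ion_mols = []
    for k, sp in enumerate(specs):
        sdef = reg[sp.ion_species]
        if sdef.kind != "ion" or sdef.charge <= 0:
            raise ValueError(f"spec {k}: {sp.ion_species} is not a cation species")
        if len(set(sp.lipids)) != sp.order:
            raise ValueError(f"spec {k}: bound lipids must be distinct")
        idx = len(new_mols)
        start = len(names)
        new_mols.append(Molecule(idx, sp.ion_species, start, start + 1))
        names.extend(sdef.atom_names)
        masses.extend(sdef.masses.tolist())
        ion_mols.append(idx)
    new_topo = Topology(
        new_mols, np.array(names, dtype=object), np.array(masses, dtype=float), reg
    )

    # parked positions: spread along the box top edge, far from the bilayer
    park = np.column_stack(
        [
            (np.arange(len(specs)) + 0.5) * box[0] / max(len(specs), 1),
            np.full(len(specs), 1.0),
            np.full(len(specs), box[2] - 1.0),
        ]
    )

    frames = []
    ledger = []
    for k, sp in enumerate(specs):
        life = sp.lifetime if sp.lifetime is not None else n_frames - sp.start
        ledger.append(
            {
                "ion_mol": ion_mols[k],
                "ion_species": sp.ion_species,
                "lipids": tuple(sorted(sp.lipids)),
                "order": sp.order,
                "start": sp.start,
                "stop": sp.start + life,
            }
        )
    for fi, fr in enumerate(traj.frames):
        ion_pos = np.empty((len(specs), 3))
        for k, sp in enumerate(specs):
            entry = ledger[k]
            if entry["start"] <= fi < entry["stop"]:
                r_p = placement_radius or reg[sp.ion_species].shell_radius
                if r_p is None:
                    raise ValueError(f"no shell radius for {sp.ion_species}")
                ion_pos[k] = _bridge_site(fr, topo, sp.lipids, r_p)
            else:
                ion_pos[k] = park[k]
        frames.append(Frame(fr.time, fr.box, np.vstack([fr.positions, ion_pos])))
    out = Trajectory(new_topo, frames)

    if validate:
        _validate_plants(out, ledger, parking_gap)
    return out, ledger


def _validate_plants(traj: Trajectory, ledger: list[dict], parking_gap: float) -> None:
    from .neighbors import molecule_min_distances

    topo = traj.topology
    reg = topo.registry
    lipid_mols = np.array(
        [m.index for m in topo.molecules if reg[m.species].is_lipid], dtype=np.intp
    )
    for fi, fr in enumerate(traj.frames):
        for entry in ledger:
            d_s = reg[entry["ion_species"]].shell_radius
            active = entry["start"] <= fi < entry["stop"]
            cutoff = d_s if active else 2 * d_s + parking_gap
            pl = molecule_min_distances(
                fr, topo, np.array([entry["ion_mol"]]), lipid_mols, cutoff, fi
            )
            bound = tuple(sorted(int(b) for b in pl.pairs_b))
            want = entry["lipids"] if active else ()
            if bound != want:
                state = "active" if active else "parked"
                raise ValueError(
                    f"planted bridge validation failed at frame {fi} "
                    f"(ion {entry['ion_mol']}, {state}): bound {bound} != planted {want}"
                )


# ---------------------------------------------------------------------------
# Bridge fixture: rosette geometry that makes arbitrary plants feasible


def bridge_fixture(
    n_bridges: int,
    seed: int,
    ion_species: str = "CAL",
    lipid_species: tuple[str, ...] = ("DOPS", "PI45P2"),
    n_frames: int = 5,
    dt: float = 100.0,
    site_spacing: float = 30.0,
    oxygen_gap: float = 1.2,
    registry: SpeciesRegistry | None = None,
    orders: tuple[int, ...] = (1, 2, 3),
) -> tuple[Trajectory, list[dict]]:
    """Random planted 1-/2-/3-bridges with an exact ground-truth ledger.

    Each bridge's lipids are placed as a tight rosette around a site so one
    anionic oxygen per lipid faces the site within the ion's first-shell
    radius; sites sit on a coarse grid so bridges never interfere.  Ion
    lifetimes are random sub-ranges of the trajectory.  Static frames:
    the classification problem, not the dynamics, is under test here.
    """
    reg = registry or default_registry()
    rng = np.random.default_rng(seed)
    n_side = int(np.ceil(np.sqrt(n_bridges)))
    L = max(n_side, 2) * site_spacing
    box = np.array([L, L, 80.0])
    z_head = 22.0
    asm = _Assembler(reg)

    plant_specs = []
    truth_orders = rng.choice(list(orders), size=n_bridges)
    for k in range(n_bridges):
        order = int(truth_orders[k])
        cx = (k % n_side + 0.5) * site_spacing
        cy = (k // n_side + 0.5) * site_spacing
        phase = rng.uniform(0, 2 * np.pi)
        lipids = []
        for j in range(order):
            sp_name = str(rng.choice(list(lipid_species)))
            sdef = reg[sp_name]
            ox = sdef.anionic[0]
            off = sdef.offsets[sdef.atom_index(ox)]
            rho = np.hypot(off[0], off[1])
            theta = phase + 2 * np.pi * j / order
            # rotate the template so the oxygen's xy offset points at the site
            ox_angle = np.arctan2(off[1], off[0])
            rot = (theta + np.pi) - ox_angle
            u = rho + oxygen_gap
            center = np.array([cx + u * np.cos(theta), cy + u * np.sin(theta), z_head])
            mol = asm.add(sp_name, center, mirror_z=True, rot_z=rot, leaflet="inner")
            lipids.append(mol)
        start = int(rng.integers(0, n_frames))
        life = int(rng.integers(1, n_frames - start + 1))
        plant_specs.append(
            BridgePlantSpec(ion_species, tuple(lipids), start=start, lifetime=life)
        )

    traj = asm.build(box)
    frames = [traj.frames[0]] + [
        Frame(traj.frames[0].time + (i + 1) * dt, box, traj.frames[0].positions.copy())
        for i in range(n_frames - 1)
    ]
    traj = Trajectory(traj.topology, frames)
    return plant_bridges(traj, plant_specs)


# ---------------------------------------------------------------------------
# Hydration shells


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (Fibonacci lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def plant_hydration(
    traj: Trajectory,
    ion_mols,
    shell_radius: float,
    n_waters: int,
    overlap_tol: float = 0.5,
) -> Trajectory:
    """Place exactly n_waters water oxygens on a shell around each ion, every frame.

    Waters follow the ion rigidly.  Raises if any placed oxygen would come
    within ``overlap_tol`` of an existing atom or another placed water.
    """
    from scipy.spatial import cKDTree

    topo = traj.topology
    reg = topo.registry
    ion_mols = [int(i) for i in np.atleast_1d(ion_mols)]
    if n_waters == 0:
        return traj
    shell = _fibonacci_sphere(n_waters) * shell_radius
    wdef = reg["TIP3"]

    new_mols = list(topo.molecules)
    names = list(topo.atom_names)
    masses = list(topo.masses)
    offs = []
    for im in ion_mols:
        for w in range(n_waters):
            idx = len(new_mols)
            start = len(names)
            new_mols.append(Molecule(idx, "TIP3", start, start + wdef.n_atoms))
            names.extend(wdef.atom_names)
            masses.extend(wdef.masses.tolist())
            offs.append((im, shell[w]))
    new_topo = Topology(
        new_mols, np.array(names, dtype=object), np.array(masses, dtype=float), reg
    )

    def _rotations():
        # identity first, then a deterministic sweep of axis-angle rotations
        yield np.eye(3)
        golden = np.pi * (3 - 5**0.5)
        for k in range(1, 24):
            ax = _fibonacci_sphere(24)[k % 24]
            ang = golden * k
            c, s = np.cos(ang), np.sin(ang)
            x, y, z = ax
            yield np.array(
                [
                    [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
                    [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
                    [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
                ]
            )

    floor = min(overlap_tol, shell_radius) - 1e-9
    frames = []
    for fr in traj.frames:
        tree = cKDTree(fr.positions)
        blocks = [fr.positions]
        placed_oxy: list[np.ndarray] = []
        by_ion: dict[int, list[np.ndarray]] = {}
        for im in ion_mols:
            ion_xyz = fr.positions[topo.molecules[im].start]
            ok = None
            for rot in _rotations():
                cand = ion_xyz + shell @ rot.T
                d, _ = tree.query(np.mod(cand, fr.box))
                if np.any(d < floor):
                    continue
                if placed_oxy and cKDTree(np.vstack(placed_oxy)).query(cand)[0].min() < overlap_tol:
                    continue
                if n_waters > 1:
                    dw = cKDTree(cand).query(cand, k=2)[0][:, 1]
                    if np.any(dw < overlap_tol):
                        continue
                ok = cand
                break
            if ok is None:
                raise ValueError(
                    f"planted waters overlap existing atoms around ion {im} (all rotations tried)"
                )
            placed_oxy.append(ok)
            by_ion[im] = ok
        widx = {im: 0 for im in ion_mols}
        for im, _off in offs:
            blocks.append(by_ion[im][widx[im]] + wdef.offsets)
            widx[im] += 1
        frames.append(Frame(fr.time, fr.box, wrap_positions(np.concatenate(blocks), fr.box)))
    return Trajectory(new_topo, frames)


# ---------------------------------------------------------------------------
# Hydrogen-bond geometry


def _hbond_registry() -> SpeciesRegistry:
    don = SpeciesDef(
        name="XDON",
        kind="lipid",
        charge=0.0,
        atom_names=("ND", "HD", "CT"),
        masses=np.array([14.007, 1.008, 12.011]),
        offsets=np.zeros((3, 3)),
        headgroup_ref="ND",
        donors=(("ND", "HD"),),
    )
    acc = SpeciesDef(
        name="XACC",
        kind="lipid",
        charge=0.0,
        atom_names=("OA",),
        masses=np.array([15.999]),
        offsets=np.zeros((1, 3)),
        headgroup_ref="OA",
        acceptors=("OA",),
    )
    return SpeciesRegistry({"XDON": don, "XACC": acc})


def plant_hbond_geometry(
    distance: float,
    angle: float,
    dh_length: float = 1.0,
    box_edge: float = 50.0,
) -> Trajectory:
    """Minimal one-frame system with one D-H group and one acceptor at an
    exact donor-acceptor distance and donor-hydrogen-acceptor angle.

    The angle is measured at the hydrogen (D-H...A); 180 degrees is the
    colinear geometry.  Uses a two-species micro-topology (one N-H donor,
    one O acceptor) so detectors see exactly one candidate triple.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if not 0.0 <= angle <= 180.0:
        raise ValueError("angle must lie in [0, 180] degrees")
    reg = _hbond_registry()
    theta = np.radians(angle)
    # D at origin, H at +x * dh_length; acceptor in the xy-plane such that
    # |DA| = distance and the angle at H between D and A equals theta.
    cos_t = np.cos(theta)
    disc = cos_t * cos_t - 1.0 + (distance / dh_length) ** 2
    if disc < 0:
        raise ValueError("requested geometry is unrealisable (acceptor inside D-H bond)")
    s = dh_length * (cos_t + np.sqrt(disc))
    h = np.array([dh_length, 0.0, 0.0])
    w = np.array([-np.cos(theta), np.sin(theta), 0.0])  # angle theta from (D - H) dir
    a_pos = h + s * w

    center = np.full(3, box_edge / 2.0)
    mols = [Molecule(0, "XDON", 0, 3), Molecule(1, "XACC", 3, 4)]
    names = np.array(["ND", "HD", "CT", "OA"], dtype=object)
    masses = np.array([14.007, 1.008, 12.011, 15.999])
    topo = Topology(mols, names, masses, reg)
    pos = np.vstack(
        [center, center + h, center + np.array([0.0, 0.0, -1.5]), center + a_pos]
    )
    return Trajectory(topo, [Frame(0.0, np.full(3, box_edge), pos)])
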