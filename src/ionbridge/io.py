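"""Structure/trajectory readers and writers plus pipeline orchestration.

GRO/PDB structures and XTC/DCD/TRR trajectories are handled through
MDAnalysis, which delivers coordinates in Angstrom and times in ps (GRO's
native nm lengths are converted on read by MDAnalysis itself).  Residue
names map one-to-one onto the species registry; GRO's 5-character residue
field forces short aliases for the phosphoinositide isomers (PI45, PI35).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import Frame, Molecule, Topology, Trajectory, select, wrap_positions
from .species import SpeciesRegistry, default_registry

log = logging.getLogger("ionbridge")

# species name -> GRO/PDB residue name (<= 5 chars); identity if absent
RESNAME_MAP = {"PI45P2": "PI45", "PI35P2": "PI35"}
RESNAME_INVERSE = {v: k for k, v in RESNAME_MAP.items()}


def _mda():
    import MDAnalysis as mda

    return mda


def write_gro(traj: Trajectory, path: str, frame_index: int = 0) -> None:
    """Write one frame as GRO (nm units handled by the writer)."""
    u = _as_universe(traj)
    u.trajectory[frame_index]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)


def write_xtc(traj: Trajectory, path: str) -> None:
    """Write all frames as an XTC trajectory."""
    mda = _mda()
    u = _as_universe(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=u.atoms.n_atoms) as w:
            for ts in u.trajectory:
                w.write(u.atoms)


def _as_universe(traj: Trajectory):
    mda = _mda()
    topo = traj.topology
    n_res = topo.n_molecules
    resnames = [RESNAME_MAP.get(m.species, m.species) for m in topo.molecules]
    u = mda.Universe.empty(
        n_atoms=topo.n_atoms,
        n_residues=n_res,
        atom_resindex=topo.atom_mol,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", topo.atom_names.astype(str))
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.add_TopologyAttr("masses", topo.masses)
    coords = np.stack([f.positions for f in traj.frames]).astype(np.float32)
    dims = np.array(
        [[f.box[0], f.box[1], f.box[2], 90.0, 90.0, 90.0] for f in traj.frames],
        dtype=np.float32,
    )
    times = np.array([f.time for f in traj.frames])
    u.load_new(coords, format=mda.coordinates.memory.MemoryReader, dimensions=dims)
    for ts, t in zip(u.trajectory, times):
        ts.dt = times[1] - times[0] if len(times) > 1 else 1.0
    u.trajectory[0]
    return u


def _topology_from_universe(u, registry: SpeciesRegistry) -> tuple[Topology, list]:
    """Map MDAnalysis residues onto our molecule/species model.

    Unknown residue names are warned about and skipped (returned as a skip
    list); atom names must match the species template.
    """
    molecules, names, masses = [], [], []
    skipped = []
    keep_atoms = []
    pos = 0
    for res in u.residues:
        sp = RESNAME_INVERSE.get(res.resname, res.resname)
        if sp not in registry:
            skipped.append(res.resname)
            continue
        n = len(res.atoms)
        idx = len(molecules)
        molecules.append(Molecule(idx, sp, pos, pos + n))
        names.extend(list(res.atoms.names))
        sdef = registry[sp]
        for nm in res.atoms.names:
            masses.append(
                sdef.masses[sdef.atom_index(nm)] if nm in sdef.atom_names else 0.0
            )
        keep_atoms.extend(res.atoms.indices.tolist())
        pos += n
    if skipped:
        warnings.warn(f"skipping unknown residues: {sorted(set(skipped))}")
    topo = Topology(
        molecules, np.array(names, dtype=object), np.array(masses, dtype=float), registry
    )
    return topo, keep_atoms


def read_structure(path: str, registry: SpeciesRegistry | None = None) -> Trajectory:
    """Read a GRO/PDB structure file into a single-frame trajectory (A units)."""
    mda = _mda()
    reg = registry or default_registry()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
    topo, keep = _topology_from_universe(u, reg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ts = u.trajectory[0]
        box = np.asarray(ts.dimensions[:3], dtype=float)
        if ts.dimensions is not None and not np.allclose(ts.dimensions[3:], 90.0):
            raise ValueError("triclinic boxes are not supported (orthorhombic only)")
        pos = wrap_positions(np.asarray(u.atoms.positions[keep], dtype=float), box)
        t0 = float(ts.time)
    return Trajectory(topo, [Frame(t0, box, pos)])


def _validate_xtc_complete(path: str) -> None:
    """Walk XTC frame headers; raise naming the frame index if the file ends
    mid-frame (readers otherwise drop a truncated final frame silently)."""
    import struct

    size = Path(path).stat().st_size
    ofs = 0
    frame = 0
    with open(path, "rb") as fh:
        while ofs < size:
            if size - ofs < 92:
                raise ValueError(f"truncated trajectory {path}: partial frame {frame}")
            fh.seek(ofs)
            head = fh.read(92)
            magic, natoms = struct.unpack(">ii", head[:8])
            if magic != 1995:
                raise ValueError(f"corrupt trajectory {path} at frame {frame}")
            if natoms <= 9:  # uncompressed tiny-frame layout; skip validation
                return
            nbytes = struct.unpack(">i", head[88:92])[0]
            framelen = 92 + (nbytes + 3) // 4 * 4
            if ofs + framelen > size:
                raise ValueError(f"truncated trajectory {path}: partial frame {frame}")
            ofs += framelen
            frame += 1


def read_trajectory(
    structure_path: str, trajectory_path: str, registry: SpeciesRegistry | None = None
) -> Trajectory:
    """Read structure + XTC/DCD/TRR trajectory; validates atom-count match
    and (for XTC) file completeness."""
    mda = _mda()
    reg = registry or default_registry()
    if trajectory_path.lower().endswith(".xtc"):
        _validate_xtc_complete(trajectory_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(structure_path, trajectory_path)
    topo, keep = _topology_from_universe(u, reg)
    frames = []
    last_t = -np.inf
    for k, ts in enumerate(u.trajectory):
        box = np.asarray(ts.dimensions[:3], dtype=float)
        t = float(ts.time)
        if t <= last_t:  # some writers emit zero times; synthesise ordering
            t = last_t + (ts.dt or 1.0)
        last_t = t
        try:
            frames.append(
                Frame(t, box, wrap_positions(np.asarray(u.atoms.positions[keep], dtype=float), box))
            )
        except ValueError as e:
            raise ValueError(f"bad frame {k} in {trajectory_path}: {e}") from e
    return Trajectory(topo, frames)


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class AnalysisConfig:
    """Everything one run needs; hashable for provenance manifests."""

    output_dir: str
    structure: str | None = None        # GRO/PDB path (else synthetic build)
    trajectory: str | None = None       # XTC/DCD path
    shell_radii: dict = field(default_factory=dict)   # overrides per cation
    hbond_distance: float = 3.4
    hbond_angle: float = 160.0
    salt_bridge_cutoff: float = 3.4
    hydration_eps: float = 0.05
    hydration_rmax: float = 8.0
    n_permutations: int = 1000
    seed: int = 0
    stages: tuple[str, ...] = (
        "bridges", "clusters", "hydration", "bonds", "tessellation", "association", "diffusion",
    )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: AnalysisConfig, traj: Trajectory | None = None) -> dict:
    """Execute the analysis stages on a trajectory, writing tidy CSV outputs
    plus a provenance manifest; returns {stage: output path}.

    Stage order: bridges -> clusters -> hydration -> bonds -> tessellation
    -> association -> diffusion.  A stage failure aborts with the stage
    name in the error.
    """
    from . import association as assoc
    from . import bonds as bondsmod
    from . import bridges as bridgemod
    from . import dynamics, solvation, tessellation

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if traj is None:
        if config.structure is None:
            raise ValueError("config needs a structure path or an in-memory trajectory")
        if config.trajectory:
            traj = read_trajectory(config.structure, config.trajectory)
        else:
            traj = read_structure(config.structure)
    from .core import assign_leaflets

    try:
        traj = assign_leaflets(traj)
    except ValueError:
        pass  # monolayer-style fixtures: leave tags unset
    topo = traj.topology
    radii = dict(solvation.DEFAULT_SHELL_RADII)
    radii.update(config.shell_radii)
    radii = {sp: r for sp, r in radii.items() if any(m.species == sp for m in topo.molecules)}
    results: dict[str, str] = {}

    import pandas as pd

    def _stage(name):
        return name in config.stages

    try:
        per_frame = None
        if _stage("bridges") or _stage("clusters"):
            stage = "bridges"
            per_frame = bridgemod.classify_bridges_trajectory(traj, radii or None)
            curve = bridgemod.charging_curve(traj, radii or None)
            p = out / "bridges.csv"
            curve.to_csv(p, index=False)
            results["bridges"] = str(p)
        if _stage("clusters"):
            stage = "clusters"
            dist = bridgemod.cluster_size_distribution(traj, radii or None)
            p = out / "clusters.csv"
            dist.to_csv(p, index=False)
            results["clusters"] = str(p)
        if _stage("hydration") and radii:
            stage = "hydration"
            waters = np.array(
                [topo.find_atom(m.index, "OH2") for m in topo.molecules if m.species == "TIP3"],
                dtype=np.intp,
            )
            rows = []
            for sp, d_s in radii.items():
                cations = select(traj, f"species {sp}")
                lipids = bridgemod.default_lipid_scope(topo)
                if len(cations) == 0:
                    continue
                prof = solvation.hydration_profile(
                    traj, cations, lipids, waters, d_s,
                    eps=config.hydration_eps, r_max=config.hydration_rmax,
                )
                df = prof.to_frame()
                df.insert(0, "ion_species", sp)
                rows.append(df)
            p = out / "hydration.csv"
            (pd.concat(rows) if rows else pd.DataFrame()).to_csv(p, index=False)
            results["hydration"] = str(p)
        if _stage("bonds"):
            stage = "bonds"
            hb_rows, sb_rows = [], []
            cations = np.array(
                [m.index for m in topo.molecules
                 if topo.registry[m.species].kind == "ion" and topo.registry[m.species].charge > 0],
                dtype=np.intp,
            )
            for fi, fr in enumerate(traj.frames):
                for r in bondsmod.detect_hbonds(
                    fr, topo, config.hbond_distance, config.hbond_angle, fi
                ):
                    hb_rows.append(dataclasses.asdict(r))
                for r in bondsmod.detect_salt_bridges(
                    fr, topo, cations, config.salt_bridge_cutoff, fi
                ):
                    sb_rows.append(dataclasses.asdict(r))
            p1, p2 = out / "hbonds.csv", out / "saltbridges.csv"
            pd.DataFrame(hb_rows).to_csv(p1, index=False)
            pd.DataFrame(sb_rows).to_csv(p2, index=False)
            results["bonds"] = str(p1)
        have_leaflets = any(m.leaflet != "none" for m in topo.molecules)
        if _stage("tessellation") and have_leaflets:
            stage = "tessellation"
            res = tessellation.area_timeseries(traj)
            p = out / "areas.csv"
            res.areas.to_csv(p, index=False)
            res.per_lipid.to_csv(out / "per_lipid_areas.csv", index=False)
            results["tessellation"] = str(p)
        if _stage("association") and have_leaflets:
            stage = "association"
            fr = traj.frames[-1]
            tess, _z = tessellation.leaflet_tessellation(fr, topo, "inner")
            labels = [topo.molecules[int(i)].species for i in tess.mol_ids]
            table = assoc.association_scores(
                tess, labels, n_permutations=config.n_permutations, seed=config.seed
            )
            p = out / "association.csv"
            table.to_csv(p, index=False)
            results["association"] = str(p)
        if _stage("diffusion") and traj.n_frames >= 10:
            stage = "diffusion"
            dres = dynamics.diffusion_by_species(traj)
            rows = [
                {"species": sp, "D_A2_per_ps": r.d_mean, "D_um2_per_s": r.d_um2_per_s,
                 "sd": r.d_sd, "r_squared": r.r_squared, "window_lo": r.window[0],
                 "window_hi": r.window[1]}
                for sp, r in dres.items()
            ]
            p = out / "diffusion.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            results["diffusion"] = str(p)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest = {
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_frames": traj.n_frames,
        "n_molecules": traj.topology.n_molecules,
        "outputs": results,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = str(out / "manifest.json")
    return results


def write_ledger(ledger: list[dict], path: str) -> None:
    """Persist a planted-truth ledger as YAML next to synthetic output."""
    with open(path, "w") as fh:
        yaml.safe_dump([{k: (list(v) if isinstance(v, tuple) else v) for k, v in e.items()} for e in ledger], fh)
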