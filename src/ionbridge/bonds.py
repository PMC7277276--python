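"""Lipid-lipid hydrogen bonds and cation-mediated salt bridges.

Hydrogen bonds use the geometric criterion: donor-acceptor distance
<= 3.4 A with a donor-hydrogen-acceptor angle (measured at the hydrogen)
> 160 degrees.  Salt bridges are lipid-cation-lipid contacts where one
anionic heavy atom from each of two distinct lipids lies within 3.4 A of
the mediating cation; the eligible heavy atoms are the deprotonated
phosphate/carboxylate oxygens of each species (protonated positions, e.g.
OP52 on our PIP2, are excluded and show up as empty heat-map rows).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Frame, Topology, Trajectory
from .neighbors import min_image_displacement, pairs_within

HBOND_DISTANCE = 3.4    # A, donor-acceptor
HBOND_ANGLE = 160.0     # degrees, D-H...A at the hydrogen, strict
SALT_BRIDGE_CUTOFF = 3.4  # A, cation to anionic heavy atom


@dataclass(frozen=True)
class HBondRecord:
    frame: int
    donor_mol: int
    donor_species: str
    donor_atom: str
    hydrogen: str
    acceptor_mol: int
    acceptor_species: str
    acceptor_atom: str
    distance: float     # donor-acceptor, A
    angle: float        # degrees


@dataclass(frozen=True)
class SaltBridgeRecord:
    frame: int
    ion_mol: int
    ion_species: str
    lipid_a: int
    species_a: str
    atom_a: str
    lipid_b: int
    species_b: str
    atom_b: str
    dist_a: float
    dist_b: float


def _donor_triples(topo: Topology) -> list[tuple[int, int, int]]:
    """(mol, donor_atom_idx, hydrogen_atom_idx) for every donor in the system."""
    out = []
    for m in topo.molecules:
        sdef = topo.registry[m.species]
        for d_name, h_name in sdef.donors:
            try:
                d = topo.find_atom(m.index, d_name)
                h = topo.find_atom(m.index, h_name)
            except KeyError:
                raise KeyError(
                    f"species {m.species}: donor {d_name!r} lacks bonded hydrogen {h_name!r} in topology"
                ) from None
            out.append((m.index, d, h))
    return out


def _acceptor_atoms(topo: Topology) -> list[tuple[int, int]]:
    out = []
    for m in topo.molecules:
        for a_name in topo.registry[m.species].acceptors:
            out.append((m.index, topo.find_atom(m.index, a_name)))
    return out


def detect_hbonds(
    frame: Frame,
    topo: Topology,
    distance_cutoff: float = HBOND_DISTANCE,
    angle_min: float = HBOND_ANGLE,
    frame_index: int = 0,
    scope: np.ndarray | None = None,
) -> list[HBondRecord]:
    """All inter-molecular D-H...A triples meeting both geometric criteria.

    ``scope`` restricts donors and acceptors to the given molecules.
    """
    triples = _donor_triples(topo)
    acceptors = _acceptor_atoms(topo)
    if scope is not None:
        keep = set(int(i) for i in scope)
        triples = [t for t in triples if t[0] in keep]
        acceptors = [a for a in acceptors if a[0] in keep]
    if not triples or not acceptors:
        return []
    d_atoms = np.array([t[1] for t in triples], dtype=np.intp)
    a_atoms = np.array([a[1] for a in acceptors], dtype=np.intp)
    by_datom = {t[1]: t for t in triples}
    by_aatom = {a[1]: a for a in acceptors}
    pl = pairs_within(frame, d_atoms, a_atoms, distance_cutoff, frame_index)
    records = []
    for da, aa, dist in zip(pl.pairs_a, pl.pairs_b, pl.distances):
        dmol, d_idx, h_idx = by_datom[int(da)]
        amol, a_idx = by_aatom[int(aa)]
        if dmol == amol:
            continue
        hd = min_image_displacement(frame.positions[h_idx], frame.positions[d_idx], frame.box)
        ha = min_image_displacement(frame.positions[h_idx], frame.positions[a_idx], frame.box)
        cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if ang > angle_min:
            records.append(
                HBondRecord(
                    frame=frame_index,
                    donor_mol=dmol,
                    donor_species=topo.molecules[dmol].species,
                    donor_atom=topo.atom_names[d_idx],
                    hydrogen=topo.atom_names[h_idx],
                    acceptor_mol=amol,
                    acceptor_species=topo.molecules[amol].species,
                    acceptor_atom=topo.atom_names[a_idx],
                    distance=float(dist),
                    angle=ang,
                )
            )
    return records


def detect_salt_bridges(
    frame: Frame,
    topo: Topology,
    cation_mols: np.ndarray,
    cutoff: float = SALT_BRIDGE_CUTOFF,
    frame_index: int = 0,
    scope: np.ndarray | None = None,
) -> list[SaltBridgeRecord]:
    """All lipid-cation-lipid salt bridges at one frame.

    For each cation, every pair of anionic heavy atoms from two distinct
    lipids both within ``cutoff`` yields one record.
    """
    cation_mols = np.asarray(cation_mols, dtype=np.intp)
    anionic = []
    mols = (
        topo.molecules
        if scope is None
        else [topo.molecules[int(i)] for i in scope]
    )
    for m in mols:
        for a_name in topo.registry[m.species].anionic:
            anionic.append((m.index, topo.find_atom(m.index, a_name)))
    if not anionic or len(cation_mols) == 0:
        return []
    an_atoms = np.array([a[1] for a in anionic], dtype=np.intp)
    by_atom = {a[1]: a for a in anionic}
    cat_atoms = np.array([topo.molecules[c].start for c in cation_mols], dtype=np.intp)
    cat_of_atom = {topo.molecules[int(c)].start: int(c) for c in cation_mols}
    pl = pairs_within(frame, cat_atoms, an_atoms, cutoff, frame_index)
    near: dict[int, list[tuple[int, int, float]]] = {}
    for ca, aa, d in zip(pl.pairs_a, pl.pairs_b, pl.distances):
        ion = cat_of_atom[int(ca)]
        mol, atom = by_atom[int(aa)]
        near.setdefault(ion, []).append((mol, atom, float(d)))
    records = []
    for ion in sorted(near):
        hits = near[ion]
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                (ma, aa, da), (mb, ab, db) = hits[i], hits[j]
                if ma == mb:
                    continue
                if (ma, aa) > (mb, ab):
                    (ma, aa, da), (mb, ab, db) = (mb, ab, db), (ma, aa, da)
                records.append(
                    SaltBridgeRecord(
                        frame=frame_index,
                        ion_mol=ion,
                        ion_species=topo.molecules[ion].species,
                        lipid_a=ma,
                        species_a=topo.molecules[ma].species,
                        atom_a=topo.atom_names[aa],
                        lipid_b=mb,
                        species_b=topo.molecules[mb].species,
                        atom_b=topo.atom_names[ab],
                        dist_a=da,
                        dist_b=db,
                    )
                )
    return records


def atom_pair_heatmap(
    records: list[SaltBridgeRecord],
    topo: Topology,
    species_a: str,
    species_b: str,
    n_lipids: int,
) -> pd.DataFrame:
    """Per-lipid-normalised salt-bridge counts keyed by (atom name, atom name).

    Axes carry the union of the two species' atom-name lists; cells whose
    atom is absent from that axis's species are NaN-masked.  For
    within-species pairs each record lands in one canonical cell (row atom
    first in axis order), so the map is independent of which lipid the
    detector listed first and its total times n_lipids equals the number
    of contributing records.
    """
    reg = topo.registry
    names_a = list(reg[species_a].atom_names)
    names_b = list(reg[species_b].atom_names)
    axis = names_a + [n for n in names_b if n not in names_a]
    rank = {n: k for k, n in enumerate(axis)}
    mat = pd.DataFrame(0.0, index=axis, columns=axis)
    same = species_a == species_b
    for r in records:
        if {r.species_a, r.species_b} != {species_a, species_b}:
            continue
        if r.species_a == species_a:
            i, j = r.atom_a, r.atom_b
        else:
            i, j = r.atom_b, r.atom_a
        if same and rank[i] > rank[j]:
            i, j = j, i
        mat.loc[i, j] += 1.0
    mask_rows = [n for n in axis if n not in names_a]
    mask_cols = [n for n in axis if n not in names_b]
    mat.loc[mask_rows, :] = np.nan
    mat.loc[:, mask_cols] = np.nan
    return mat / n_lipids


def occupancy_fraction(
    per_frame_records: list[list],
    species_pair: tuple[str, str],
) -> tuple[float, float]:
    """Fraction of frames with >= 1 bond between the species pair, and the
    mean bonds per frame.

    Works on per-frame lists of either HBondRecord or SaltBridgeRecord.
    """
    want = frozenset(species_pair)
    n_frames = len(per_frame_records)
    if n_frames == 0:
        raise ValueError("no frames")
    hit_frames = 0
    total = 0
    for records in per_frame_records:
        n = 0
        for r in records:
            if isinstance(r, HBondRecord):
                pair = frozenset((r.donor_species, r.acceptor_species))
            else:
                pair = frozenset((r.species_a, r.species_b))
            if pair == want:
                n += 1
        if n:
            hit_frames += 1
        total += n
    return hit_frames / n_frames, total / n_frames
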