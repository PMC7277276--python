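"""Hydrogen-bond and salt-bridge detectors vs planted geometry and
exhaustive oracles."""
import numpy as np
import pytest

from ionbridge import synth
from ionbridge.bonds import (
    atom_pair_heatmap,
    detect_hbonds,
    detect_salt_bridges,
    occupancy_fraction,
)
from ionbridge.core import Frame, Molecule, Topology, Trajectory, select
from ionbridge.neighbors import min_image_displacement, min_image_distance
from ionbridge.species import default_registry


@pytest.mark.parametrize(
    "distance,angle,expected",
    [
        (3.0, 180.0, 1),
        (3.4, 180.0, 1),     # boundary distance accepted (<=)
        (3.6, 180.0, 0),
        (3.0, 150.0, 0),     # angle below the 160-degree criterion
        (3.0, 160.0, 0),     # strict inequality at the angle boundary
        (3.0, 161.0, 1),
        (1.5, 180.0, 1),
    ],
)
def test_hbond_detector_geometric_criteria(distance, angle, expected):
    traj = synth.plant_hbond_geometry(distance, angle)
    recs = detect_hbonds(traj.frames[0], traj.topology)
    assert len(recs) == expected


def _random_frame(rng, n_dope=30, n_dops=20, box_edge=45.0):
    reg = default_registry()
    mols, names, masses, pos = [], [], [], []
    k = 0
    for sp, n in (("DOPE", n_dope), ("DOPS", n_dops)):
        sdef = reg[sp]
        for _ in range(n):
            mols.append(Molecule(len(mols), sp, k, k + sdef.n_atoms))
            names.extend(sdef.atom_names)
            masses.extend(sdef.masses.tolist())
            center = rng.uniform(0, 1, 3) * box_edge
            pos.append(center + sdef.offsets)
            k += sdef.n_atoms
    topo = Topology(mols, np.array(names, dtype=object), np.array(masses), reg)
    box = np.full(3, box_edge)
    return Frame(0.0, box, np.mod(np.concatenate(pos), box)), topo


def _hbond_oracle(frame, topo, dist_cut=3.4, ang_min=160.0):
    out = set()
    reg = topo.registry
    for md in topo.molecules:
        for dn, hn in reg[md.species].donors:
            d = topo.find_atom(md.index, dn)
            h = topo.find_atom(md.index, hn)
            for ma in topo.molecules:
                if ma.index == md.index:
                    continue
                for an in reg[ma.species].acceptors:
                    a = topo.find_atom(ma.index, an)
                    if min_image_distance(frame.positions[d], frame.positions[a], frame.box) > dist_cut:
                        continue
                    hd = min_image_displacement(frame.positions[h], frame.positions[d], frame.box)
                    ha = min_image_displacement(frame.positions[h], frame.positions[a], frame.box)
                    cos = np.dot(hd, ha) / np.linalg.norm(hd) / np.linalg.norm(ha)
                    if np.degrees(np.arccos(np.clip(cos, -1, 1))) > ang_min:
                        out.add((md.index, dn, ma.index, an))
    return out


def test_hbond_detector_matches_exhaustive_oracle(rng):
    # dense random frame so some geometries land in the acceptance region
    frame, topo = _random_frame(rng, n_dope=60, n_dops=40, box_edge=35.0)
    got = {
        (r.donor_mol, r.donor_atom, r.acceptor_mol, r.acceptor_atom)
        for r in detect_hbonds(frame, topo)
    }
    assert got == _hbond_oracle(frame, topo)


def _salt_oracle(frame, topo, cations, cutoff=3.4):
    out = set()
    reg = topo.registry
    for c in cations:
        cpos = frame.positions[topo.molecules[c].start]
        near = []
        for m in topo.molecules:
            for an in reg[m.species].anionic:
                a = topo.find_atom(m.index, an)
                if min_image_distance(cpos, frame.positions[a], frame.box) <= cutoff:
                    near.append((m.index, an))
        for i in range(len(near)):
            for j in range(i + 1, len(near)):
                if near[i][0] != near[j][0]:
                    out.add((c, *sorted((near[i], near[j]))))
    return out


def test_salt_bridge_detector_matches_triple_loop_oracle(rng):
    frame, topo = _random_frame(rng, n_dope=20, n_dops=40, box_edge=30.0)
    # sprinkle cations
    reg = topo.registry
    mols = list(topo.molecules)
    names = list(topo.atom_names)
    masses = list(topo.masses)
    pos = [frame.positions]
    for _ in range(25):
        idx = len(mols)
        mols.append(Molecule(idx, "CAL", len(names), len(names) + 1))
        names.append("CAL")
        masses.append(40.078)
        pos.append(rng.uniform(0, 1, (1, 3)) * frame.box)
    topo2 = Topology(mols, np.array(names, dtype=object), np.array(masses), reg)
    fr2 = Frame(0.0, frame.box, np.concatenate(pos))
    cations = np.array([m.index for m in mols if m.species == "CAL"])
    got = {
        (r.ion_mol, (r.lipid_a, r.atom_a), (r.lipid_b, r.atom_b))
        for r in detect_salt_bridges(fr2, topo2, cations)
    }
    want = {(c, a, b) for c, a, b in _salt_oracle(fr2, topo2, cations)}
    assert got == want


def _planted_salt_bridge_frame(d_a=3.0, d_b=3.0):
    """Ca2+ between OP42 of one PIP2 and OP53 of another."""
    reg = default_registry()
    sdef = reg["PI45P2"]
    mols = [
        Molecule(0, "PI45P2", 0, sdef.n_atoms),
        Molecule(1, "PI45P2", sdef.n_atoms, 2 * sdef.n_atoms),
        Molecule(2, "CAL", 2 * sdef.n_atoms, 2 * sdef.n_atoms + 1),
    ]
    names = np.array(list(sdef.atom_names) * 2 + ["CAL"], dtype=object)
    masses = np.array(sdef.masses.tolist() * 2 + [40.078])
    topo = Topology(mols, names, masses, reg)
    box = np.full(3, 60.0)
    ca = box / 2
    i42 = sdef.atom_index("OP42")
    i53 = sdef.atom_index("OP53")
    # place lipid A so its OP42 sits d_a left of the ion, B so OP53 sits d_b right
    a_center = ca - np.array([d_a, 0, 0]) - sdef.offsets[i42]
    b_center = ca + np.array([d_b, 0, 0]) - sdef.offsets[i53]
    pos = np.vstack([a_center + sdef.offsets, b_center + sdef.offsets, ca[None, :]])
    return Frame(0.0, box, np.mod(pos, box)), topo


def test_planted_salt_bridge_detected_and_boundary():
    fr, topo = _planted_salt_bridge_frame(3.0, 3.0)
    recs = detect_salt_bridges(fr, topo, np.array([2]))
    key_atoms = {(r.atom_a, r.atom_b) for r in recs}
    assert ("OP42", "OP53") in key_atoms or ("OP53", "OP42") in key_atoms
    fr2, topo2 = _planted_salt_bridge_frame(3.0, 3.5)
    recs2 = detect_salt_bridges(fr2, topo2, np.array([2]))
    assert not any({"OP53"} & {r.atom_a, r.atom_b} and r.dist_b > 3.4 for r in recs2)
    assert all(r.dist_a <= 3.4 and r.dist_b <= 3.4 for r in recs2)


def test_heatmap_normalisation_and_protonated_mask():
    fr, topo = _planted_salt_bridge_frame(3.0, 3.0)
    recs = detect_salt_bridges(fr, topo, np.array([2]))
    hm = atom_pair_heatmap(recs, topo, "PI45P2", "PI45P2", n_lipids=40)
    total = np.nansum(hm.values)
    assert total * 40 == pytest.approx(len(recs))
    # protonated OP52 carries no bridges: its row and column are all zero
    assert np.nansum(hm.loc["OP52"].values) == 0
    assert np.nansum(hm["OP52"].values) == 0
    # independence from detector record orientation: canonical cell is filled
    assert np.nansum(hm.values) > 0


def test_occupancy_fraction_planted_schedule():
    traj = synth.plant_hbond_geometry(3.0, 175.0)
    fr_on = traj.frames[0]
    fr_off = Frame(0.0, fr_on.box, np.mod(fr_on.positions + np.array([0, 0, 20.0]) * [[0], [0], [0], [1]], fr_on.box))
    topo = traj.topology
    on = detect_hbonds(fr_on, topo)
    off = detect_hbonds(fr_off, topo)
    assert len(on) == 1 and len(off) == 0
    per_frame = [on] * 30 + [off] * 70
    frac, mean = occupancy_fraction(per_frame, ("XDON", "XACC"))
    assert frac == pytest.approx(0.30)
    assert mean == pytest.approx(0.30)
    frac_all, _ = occupancy_fraction([on] * 10, ("XDON", "XACC"))
    assert frac_all == 1.0


def test_salt_bridge_ions_are_order2_bridges_at_matched_cutoff():
    """With the shell radius relaxed to the 3.4 A salt-bridge cutoff, every
    salt-bridging cation classifies as a bridge of order >= 2."""
    from ionbridge import synth
    from ionbridge.bridges import classify_bridges

    traj, _ = synth.bridge_fixture(10, seed=19, n_frames=3, orders=(2, 3))
    topo = traj.topology
    cations = select(traj, "kind ion")
    for fi, fr in enumerate(traj.frames):
        sb = detect_salt_bridges(fr, topo, cations, cutoff=3.4, frame_index=fi)
        recs = classify_bridges(fr, topo, {"CAL": 3.4}, frame_index=fi)
        multi = {r.ion_mol for r in recs if r.order >= 2}
        assert {r.ion_mol for r in sb} <= multi


def test_occupancy_counting_identity(rng):
    # occupancy (fraction of frames with >=1 bond) can never exceed the
    # mean bonds per frame
    frame, topo = _random_frame(rng, n_dope=50, n_dops=30, box_edge=32.0)
    per_frame = [detect_hbonds(frame, topo)] * 5
    frac, mean = occupancy_fraction(per_frame, ("DOPE", "DOPS"))
    assert frac <= mean + 1e-12 or mean == 0
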