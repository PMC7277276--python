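"""RDFs, first-shell extraction and the conditional hydration profile."""
import numpy as np
import pytest

from ionbridge import synth
from ionbridge.core import Frame, Molecule, Topology, Trajectory, select, select_atoms
from ionbridge.neighbors import min_image_distance
from ionbridge.solvation import (
    RDF,
    compute_rdf,
    first_shell_cutoff,
    hydration_profile,
)
from ionbridge.species import default_registry


def _ion_water_system(rng, n_waters=800, box_edge=30.0, shell=None):
    """One CAL ion at the box center, waters either uniform or on a shell."""
    reg = default_registry()
    mols = [Molecule(0, "CAL", 0, 1)]
    names, masses = ["CAL"], [40.078]
    for k in range(n_waters):
        mols.append(Molecule(k + 1, "TIP3", 1 + 3 * k, 4 + 3 * k))
        names += ["OH2", "H1", "H2"]
        masses += [15.999, 1.008, 1.008]
    topo = Topology(mols, np.array(names, dtype=object), np.array(masses), reg)
    box = np.full(3, box_edge)
    center = box / 2
    pos = [center]
    for _ in range(n_waters):
        if shell is None:
            o = rng.uniform(0, 1, 3) * box
        else:
            v = rng.normal(size=3)
            o = center + v / np.linalg.norm(v) * shell
        pos.extend([o, o + [0.76, 0.59, 0], o + [-0.76, 0.59, 0]])
    fr = Frame(0.0, box, np.mod(np.asarray(pos), box))
    return Trajectory(topo, [fr])


def test_rdf_uniform_gas_is_flat(rng):
    traj = _ion_water_system(rng, n_waters=3000)
    centers = select_atoms(traj, "species CAL")
    oxy = select_atoms(traj, "kind water", name="OH2")
    rdf = compute_rdf(traj, centers, oxy, bin_width=0.5, r_max=12.0)
    far = rdf.g[rdf.r > 4.0]
    assert np.abs(far.mean() - 1.0) < 0.15
    assert np.all(rdf.g >= 0)


def test_rdf_single_planted_shell_peaks_at_radius(rng):
    traj = _ion_water_system(rng, n_waters=500, shell=3.0)
    centers = select_atoms(traj, "species CAL")
    oxy = select_atoms(traj, "kind water", name="OH2")
    rdf = compute_rdf(traj, centers, oxy, bin_width=0.2, r_max=8.0)
    assert rdf.r[np.argmax(rdf.g)] == pytest.approx(3.0, abs=0.2)
    assert rdf.g.sum() > 0


def _two_peak_rdf(trough, bin_width=0.05, r_max=6.0):
    """Analytic two-Gaussian g(r) with its interior minimum planted at `trough`."""
    r = np.arange(bin_width / 2, r_max, bin_width)
    g = 2.5 * np.exp(-((r - (trough - 0.6)) ** 2) / (2 * 0.25**2))
    g += 1.4 * np.exp(-((r - (trough + 0.9)) ** 2) / (2 * 0.45**2))
    return RDF(r=r, g=g, bin_width=bin_width, n_centers=1, n_partners=1, n_frames=1)


def test_first_shell_cutoff_recovers_planted_trough():
    rdf = _two_peak_rdf(trough=2.6)
    assert first_shell_cutoff(rdf) == pytest.approx(2.6, abs=0.05 + 1e-9)
    rdf = _two_peak_rdf(trough=2.3)
    assert first_shell_cutoff(rdf) == pytest.approx(2.3, abs=0.05 + 1e-9)


def test_first_shell_cutoff_noisy_matches_noiseless(rng):
    rdf = _two_peak_rdf(trough=3.0)
    clean = first_shell_cutoff(rdf)
    noisy = RDF(
        r=rdf.r, g=np.clip(rdf.g + rng.normal(0, 0.02, rdf.g.shape), 0, None),
        bin_width=rdf.bin_width, n_centers=1, n_partners=1, n_frames=1,
    )
    assert first_shell_cutoff(noisy) == pytest.approx(clean, abs=rdf.bin_width + 1e-9)


def test_first_shell_cutoff_monotone_errors():
    r = np.arange(0.025, 6.0, 0.05)
    rdf = RDF(r=r, g=np.exp(-r), bin_width=0.05, n_centers=1, n_partners=1, n_frames=1)
    with pytest.raises(ValueError, match="no first shell"):
        first_shell_cutoff(rdf)


def test_hydration_profile_planted_occupancy():
    traj, ledger = synth.bridge_fixture(3, seed=21, n_frames=2, orders=(1,))
    ions = select(traj, "kind ion")
    traj = synth.plant_hydration(traj, ions, shell_radius=2.0, n_waters=6)
    lipids = select(traj, "kind lipid")
    oxy = select_atoms(traj, "kind water", name="OH2")
    prof = hydration_profile(traj, ions, lipids, oxy, shell_radius=2.6, eps=0.05)
    populated = prof.ion_counts > 0
    assert populated.any()
    assert np.allclose(prof.mean_waters[populated], 6.0)
    # marginal: per-bin frequencies sum to the ion counts
    for b, dist in enumerate(prof.water_counts):
        assert sum(dist.values()) == prof.ion_counts[b]


def test_hydration_profile_zero_waters():
    traj, _ = synth.bridge_fixture(2, seed=4, n_frames=2, orders=(1,))
    ions = select(traj, "kind ion")
    lipids = select(traj, "kind lipid")
    prof = hydration_profile(traj, ions, lipids, np.empty(0, dtype=int), 2.6)
    populated = prof.ion_counts > 0
    assert np.allclose(prof.mean_waters[populated], 0.0)


def _triple_loop_profile(traj, ions, lipids, oxy, d_s, eps, r_max):
    """Independent naive implementation over (cation, lipid, water, frame)."""
    topo = traj.topology
    n_bins = int(np.ceil(r_max / eps))
    counts = np.zeros(n_bins, dtype=int)
    waters = [dict() for _ in range(n_bins)]
    for fr in traj.frames:
        for c in ions:
            cm = topo.molecules[c]
            cpos = fr.positions[cm.start]
            nw = sum(
                1 for o in oxy if min_image_distance(cpos, fr.positions[o], fr.box) <= d_s
            )
            for l in lipids:
                lm = topo.molecules[l]
                d = min(
                    min_image_distance(fr.positions[a], fr.positions[b], fr.box)
                    for a in range(cm.start, cm.stop)
                    for b in range(lm.start, lm.stop)
                )
                if d > r_max:
                    continue
                b = min(int(d / eps), n_bins - 1)
                counts[b] += 1
                waters[b][nw] = waters[b].get(nw, 0) + 1
    return counts, waters


def test_hydration_profile_matches_triple_loop_oracle(rng):
    """Randomised fixture: tree-based profile vs the naive triple loop."""
    reg = default_registry()
    mols, names, masses, pos = [], [], [], []
    box = np.full(3, 40.0)
    k = 0

    def add(species):
        nonlocal k
        sdef = reg[species]
        mols.append(Molecule(len(mols), species, k, k + sdef.n_atoms))
        names.extend(sdef.atom_names)
        masses.extend(sdef.masses.tolist())
        center = rng.uniform(0, 1, 3) * box
        pos.append(center + sdef.offsets)
        k += sdef.n_atoms

    for _ in range(8):
        add("CAL")
    for _ in range(10):
        add("DOPS")
    for _ in range(60):
        add("TIP3")
    topo = Topology(mols, np.array(names, dtype=object), np.array(masses), reg)
    frames = [
        Frame(float(t), box, np.mod(np.concatenate(pos) + t * 0.37, box)) for t in range(3)
    ]
    traj = Trajectory(topo, frames)
    ions = select(traj, "species CAL")
    lipids = select(traj, "species DOPS")
    oxy = select_atoms(traj, "kind water", name="OH2")
    prof = hydration_profile(traj, ions, lipids, oxy, shell_radius=2.6, eps=0.1, r_max=8.0)
    counts, waters = _triple_loop_profile(traj, ions, lipids, oxy, 2.6, 0.1, 8.0)
    assert np.array_equal(prof.ion_counts, counts)
    assert prof.water_counts == waters
    assert prof.ion_counts.sum() + prof.overflow == len(ions) * len(lipids) * traj.n_frames


def test_hydration_profile_translation_invariance(rng):
    traj, _ = synth.bridge_fixture(2, seed=8, n_frames=2, orders=(1, 2))
    traj = synth.plant_hydration(traj, select(traj, "kind ion"), 2.0, 3)
    ions = select(traj, "kind ion")
    lipids = select(traj, "kind lipid")
    oxy = select_atoms(traj, "kind water", name="OH2")
    p0 = hydration_profile(traj, ions, lipids, oxy, 2.6)
    shift = rng.uniform(0, 1, 3) * traj.frames[0].box
    moved = Trajectory(
        traj.topology,
        [Frame(f.time, f.box, np.mod(f.positions + shift, f.box)) for f in traj.frames],
    )
    p1 = hydration_profile(moved, ions, lipids, oxy, 2.6)
    assert np.array_equal(p0.ion_counts, p1.ion_counts)
    assert p0.water_counts == p1.water_counts
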