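"""Ion-water RDFs, first-solvation-shell extraction, and the conditional
hydration profile N_ions(r), N_waters(r).

The hydration profile answers: *when a cation sits at minimum distance r
from a lipid, how many waters remain in its first solvation shell?*  For
every (cation, lipid, frame) observation the cation-lipid minimum distance
d_{c,l} is binned at resolution eps (default 0.05 A) and the number of
water oxygens within the shell radius d_s of that cation is recorded,
giving a per-bin distribution of first-shell water counts and its mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory
from .neighbors import molecule_min_distances, pairs_within

# Default first-shell radii (A) from ion-water RDF first minima.
DEFAULT_SHELL_RADII = {"SOD": 3.0, "POT": 3.0, "MGA": 2.3, "CAL": 2.6}


@dataclass
class RDF:
    """Radial distribution function on uniform bins."""

    r: np.ndarray               # bin centers, A
    g: np.ndarray               # dimensionless
    bin_width: float
    n_centers: int
    n_partners: int
    n_frames: int


def compute_rdf(
    traj: Trajectory,
    center_atoms: np.ndarray,
    partner_atoms: np.ndarray,
    bin_width: float = 0.05,
    r_max: float = 8.0,
) -> RDF:
    """Shell-volume- and density-normalised center-partner distance histogram.

    Distances use the minimum-image convention; normalisation assumes the
    partners fill the box at uniform density (g -> 1 at large r for bulk).
    """
    center_atoms = np.asarray(center_atoms, dtype=np.intp)
    partner_atoms = np.asarray(partner_atoms, dtype=np.intp)
    if len(center_atoms) == 0 or len(partner_atoms) == 0:
        raise ValueError("empty center or partner selection")
    n_bins = int(np.ceil(r_max / bin_width))
    hist = np.zeros(n_bins)
    vol = None
    for fi, fr in enumerate(traj.frames):
        pl = pairs_within(fr, center_atoms, partner_atoms, r_max, fi)
        idx = np.minimum((pl.distances / bin_width).astype(int), n_bins - 1)
        np.add.at(hist, idx, 1.0)
        vol = float(np.prod(fr.box))
    edges = np.arange(n_bins + 1) * bin_width
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = len(partner_atoms) / vol
    norm = traj.n_frames * len(center_atoms) * rho * shell_vol
    return RDF(
        r=(edges[:-1] + edges[1:]) / 2.0,
        g=hist / norm,
        bin_width=bin_width,
        n_centers=len(center_atoms),
        n_partners=len(partner_atoms),
        n_frames=traj.n_frames,
    )


def first_shell_cutoff(rdf: RDF, smooth_window: int = 3, min_peak_fraction: float = 0.2) -> float:
    """First-shell radius: the first local minimum after the first maximum
    of the moving-average-smoothed g(r).

    Only maxima reaching ``min_peak_fraction`` of the global maximum count
    as the first peak, so baseline noise in the depleted region below the
    contact distance cannot masquerade as a shell.  Raises
    ``ValueError("no first shell")`` when g(r) has no interior
    maximum-then-minimum structure (e.g. monotone profiles).
    """
    g = np.convolve(rdf.g, np.ones(smooth_window) / smooth_window, mode="same")
    floor = min_peak_fraction * g.max()
    imax = None
    for i in range(1, len(g) - 1):
        if imax is None:
            if g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] >= floor:
                imax = i
        else:
            if g[i] < g[i - 1] and g[i] <= g[i + 1]:
                return float(rdf.r[i])
    raise ValueError("no first shell: g(r) has no interior minimum after a maximum")


@dataclass
class HydrationProfile:
    """Conditional first-shell water-count distribution vs cation-lipid distance."""

    eps: float                          # bin width, A
    r_max: float
    bin_edges: np.ndarray               # (n_bins + 1,)
    ion_counts: np.ndarray              # (n_bins,), observations per bin
    water_counts: list[dict[int, int]] = field(repr=False, default_factory=list)
    overflow: int = 0                   # observations beyond r_max

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def mean_waters(self) -> np.ndarray:
        """Per-bin mean first-shell water count (NaN where no observations)."""
        out = np.full(len(self.ion_counts), np.nan)
        for b, dist in enumerate(self.water_counts):
            tot = sum(dist.values())
            if tot:
                out[b] = sum(k * v for k, v in dist.items()) / tot
        return out

    def to_frame(self):
        """Tidy DataFrame: one row per (bin, n_waters) with frequency."""
        import pandas as pd

        rows = []
        centers = self.bin_centers
        for b, dist in enumerate(self.water_counts):
            for nw, freq in sorted(dist.items()):
                rows.append({"r": centers[b], "n_ions": int(self.ion_counts[b]),
                             "n_waters": nw, "frequency": freq})
        return pd.DataFrame(rows, columns=["r", "n_ions", "n_waters", "frequency"])


def hydration_profile(
    traj: Trajectory,
    cation_mols: np.ndarray,
    lipid_mols: np.ndarray,
    water_oxygens: np.ndarray,
    shell_radius: float,
    eps: float = 0.05,
    r_max: float = 10.0,
) -> HydrationProfile:
    """Eq.-style conditional hydration profile.

    For every cation-lipid molecule pair and frame with minimum distance
    d_{c,l} <= r_max, bins d_{c,l} at resolution ``eps`` (half-open bins
    [r, r+eps)) and records the cation's concurrent first-shell water count
    (water oxygens within ``shell_radius``).  Pairs beyond r_max are
    tallied in ``overflow``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    topo = traj.topology
    cation_mols = np.asarray(cation_mols, dtype=np.intp)
    lipid_mols = np.asarray(lipid_mols, dtype=np.intp)
    water_oxygens = np.asarray(water_oxygens, dtype=np.intp)
    n_bins = int(np.ceil(r_max / eps))
    edges = np.arange(n_bins + 1) * eps
    ion_counts = np.zeros(n_bins, dtype=int)
    water_counts: list[dict[int, int]] = [dict() for _ in range(n_bins)]
    overflow = 0

    cation_atoms = {int(c): topo.molecules[c].start for c in cation_mols}
    for fi, fr in enumerate(traj.frames):
        # first-shell water count per cation
        nw = {int(c): 0 for c in cation_mols}
        if len(water_oxygens):
            catoms = np.array(list(cation_atoms.values()), dtype=np.intp)
            pl = pairs_within(fr, catoms, water_oxygens, shell_radius, fi)
            atom_to_mol = {v: k for k, v in cation_atoms.items()}
            for a in pl.pairs_a:
                nw[atom_to_mol[int(a)]] += 1
        # cation-lipid minimum distances
        pd_pairs = molecule_min_distances(fr, topo, cation_mols, lipid_mols, r_max, fi)
        seen = set(zip(pd_pairs.pairs_a.tolist(), pd_pairs.pairs_b.tolist()))
        overflow += len(cation_mols) * len(lipid_mols) - len(seen)
        for c, _l, d in zip(pd_pairs.pairs_a, pd_pairs.pairs_b, pd_pairs.distances):
            b = min(int(d / eps), n_bins - 1)
            ion_counts[b] += 1
            k = nw[int(c)]
            water_counts[b][k] = water_counts[b].get(k, 0) + 1
    return HydrationProfile(eps, r_max, edges, ion_counts, water_counts, overflow)
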