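"""Periodic-distance primitives: minimum-image distances and k-d-tree pair
search in orthorhombic boxes.

The tree search augments one point set with ghost images within ``cutoff``
of each periodic face so a single non-periodic cKDTree query is exact; the
cutoff must stay below half the shortest box edge for the minimum-image
convention to be valid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, Topology


def min_image_displacement(p1: np.ndarray, p2: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vector(s) p2 - p1."""
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    return d - np.asarray(box) * np.round(d / np.asarray(box))


def min_image_distance(p1, p2, box) -> float | np.ndarray:
    """Euclidean distance under the minimum-image convention (symmetric)."""
    d = min_image_displacement(p1, p2, box)
    return np.sqrt(np.sum(d * d, axis=-1))


@dataclass
class PairList:
    """Pairs (a, b, distance) with min-image distance <= cutoff at one frame."""

    frame_index: int
    pairs_a: np.ndarray             # indices into set_a
    pairs_b: np.ndarray             # indices into set_b
    distances: np.ndarray           # Angstrom
    cutoff: float

    def __len__(self) -> int:
        return len(self.distances)

    def as_set(self) -> set[tuple[int, int]]:
        return set(zip(self.pairs_a.tolist(), self.pairs_b.tolist()))


def _check_cutoff(cutoff: float, box: np.ndarray) -> None:
    if cutoff >= float(np.min(box)) / 2:
        raise ValueError(
            f"cutoff {cutoff} A >= half the shortest box edge ({np.min(box) / 2} A); "
            "minimum-image search is invalid"
        )


def _ghost_tile(points: np.ndarray, box: np.ndarray, cutoff: float):
    """Augment `points` with periodic images within `cutoff` of each face.

    Returns (tiled points, index into the original array per tiled point).
    """
    pts = [points]
    src = [np.arange(len(points))]
    shifts = []
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                if (sx, sy, sz) != (0, 0, 0):
                    shifts.append((sx, sy, sz))
    for shift in shifts:
        shifted = points + np.asarray(shift) * box
        # keep only images within `cutoff` of the central cell
        near = np.all(
            (shifted > -cutoff) & (shifted < box + cutoff), axis=1
        )
        if near.any():
            pts.append(shifted[near])
            src.append(np.nonzero(near)[0])
    return np.concatenate(pts), np.concatenate(src)


def pairs_within(
    frame: Frame,
    set_a: np.ndarray,
    set_b: np.ndarray,
    cutoff: float,
    frame_index: int = 0,
) -> PairList:
    """All (a, b) pairs with min-image distance <= cutoff, a in set_a, b in set_b.

    Returned pair entries are global atom indices.  Self-pairs (the same atom
    index in both sets) are excluded; when the two sets are identical each
    unordered pair is reported once (a < b).
    """
    _check_cutoff(cutoff, frame.box)
    set_a = np.asarray(set_a, dtype=np.intp)
    set_b = np.asarray(set_b, dtype=np.intp)
    if len(set_a) == 0 or len(set_b) == 0:
        e = np.empty(0, dtype=np.intp)
        return PairList(frame_index, e, e, np.empty(0), cutoff)
    pa = frame.positions[set_a]
    pb = frame.positions[set_b]
    tiled_b, src_b = _ghost_tile(pb, frame.box, cutoff)
    tree = cKDTree(tiled_b)
    hits = tree.query_ball_point(pa, cutoff)
    out_a, out_b, out_d = [], [], []
    same = len(set_a) == len(set_b) and np.array_equal(set_a, set_b)
    seen: set[tuple[int, int]] = set()
    for ia, hit in enumerate(hits):
        aa = int(set_a[ia])
        for j in hit:
            bb = int(set_b[src_b[j]])
            if aa == bb:
                continue
            key = (min(aa, bb), max(aa, bb)) if same else (aa, bb)
            if key in seen:
                continue
            seen.add(key)
            d = float(min_image_distance(frame.positions[aa], frame.positions[bb], frame.box))
            if d <= cutoff:
                out_a.append(key[0])
                out_b.append(key[1])
                out_d.append(d)
    return PairList(
        frame_index,
        np.asarray(out_a, dtype=np.intp),
        np.asarray(out_b, dtype=np.intp),
        np.asarray(out_d, dtype=float),
        cutoff,
    )


def molecule_min_distance(frame: Frame, topo: Topology, mol_i: int, mol_j: int) -> float:
    """Minimum min-image distance over all atom pairs of two distinct molecules."""
    if mol_i == mol_j:
        raise ValueError("molecule_min_distance requires two distinct molecules")
    mi, mj = topo.molecules[mol_i], topo.molecules[mol_j]
    pi = frame.positions[mi.atoms]
    pj = frame.positions[mj.atoms]
    d = min_image_displacement(pi[:, None, :], pj[None, :, :], frame.box)
    return float(np.sqrt(np.sum(d * d, axis=-1)).min())


def molecule_min_distances(
    frame: Frame,
    topo: Topology,
    mols_a: np.ndarray,
    mols_b: np.ndarray,
    cutoff: float,
    frame_index: int = 0,
) -> PairList:
    """Molecule-pair minimum distances d_{i,j} <= cutoff via atom-level search.

    Entity ids in the returned PairList are molecule indices.
    """
    mols_a = np.asarray(mols_a, dtype=np.intp)
    mols_b = np.asarray(mols_b, dtype=np.intp)
    if len(mols_a) == 0 or len(mols_b) == 0:
        e = np.empty(0, dtype=np.intp)
        return PairList(frame_index, e, e, np.empty(0), cutoff)
    atoms_a = topo.atoms_of(mols_a)
    atoms_b = topo.atoms_of(mols_b)
    same_mols = len(mols_a) == len(mols_b) and np.array_equal(mols_a, mols_b)
    pl = pairs_within(frame, atoms_a, atoms_b, cutoff, frame_index)
    atom_mol = topo.atom_mol
    best: dict[tuple[int, int], float] = {}
    for ia, ib, d in zip(pl.pairs_a, pl.pairs_b, pl.distances):
        ma = int(atom_mol[ia])
        mb = int(atom_mol[ib])
        if ma == mb:
            continue
        key = (min(ma, mb), max(ma, mb)) if same_mols else (ma, mb)
        if d < best.get(key, np.inf):
            best[key] = float(d)
    if not best:
        e = np.empty(0, dtype=np.intp)
        return PairList(frame_index, e, e, np.empty(0), cutoff)
    ka = np.array([k[0] for k in best], dtype=np.intp)
    kb = np.array([k[1] for k in best], dtype=np.intp)
    dv = np.array(list(best.values()))
    return PairList(frame_index, ka, kb, dv, cutoff)
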