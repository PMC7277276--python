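"""Shared data model: topologies, frames, trajectories and selections.

Conventions used throughout the package: lengths in Angstrom, times in ps,
charges in elementary charge units; orthorhombic periodic boxes only;
0-based indices; coordinates stored wrapped into [0, L) per axis.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .species import SpeciesRegistry, default_registry

LEAFLETS = ("inner", "outer", "none")


class SelectionError(ValueError):
    """Raised for malformed or unresolvable selection expressions."""


@dataclass
class Molecule:
    """One molecule: contiguous atom block [start, stop) in the atom arrays."""

    index: int
    species: str
    start: int
    stop: int
    leaflet: str = "none"

    @property
    def atoms(self) -> slice:
        return slice(self.start, self.stop)

    @property
    def n_atoms(self) -> int:
        return self.stop - self.start


@dataclass
class Topology:
    """Molecule table plus per-atom metadata and the species registry.

    Invariants: each atom belongs to exactly one molecule; molecule atom
    blocks are contiguous and non-overlapping; every species name resolves
    in the registry.
    """

    molecules: list[Molecule]
    atom_names: np.ndarray          # (n_atoms,) str
    masses: np.ndarray              # (n_atoms,) float
    registry: SpeciesRegistry = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        pos = 0
        for mol in self.molecules:
            if mol.start != pos:
                raise ValueError(
                    f"molecule {mol.index}: atoms not contiguous (start {mol.start}, expected {pos})"
                )
            if mol.species not in self.registry:
                raise ValueError(f"molecule {mol.index}: unknown species {mol.species!r}")
            if mol.leaflet not in LEAFLETS:
                raise ValueError(f"molecule {mol.index}: bad leaflet tag {mol.leaflet!r}")
            pos = mol.stop
        if pos != len(self.atom_names) or pos != len(self.masses):
            raise ValueError("atom array length does not match molecule blocks")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def mol_species(self) -> np.ndarray:
        return np.array([m.species for m in self.molecules], dtype=object)

    @property
    def mol_leaflet(self) -> np.ndarray:
        return np.array([m.leaflet for m in self.molecules], dtype=object)

    @property
    def atom_mol(self) -> np.ndarray:
        """Molecule index of each atom."""
        out = np.empty(self.n_atoms, dtype=np.intp)
        for m in self.molecules:
            out[m.start : m.stop] = m.index
        return out

    def atoms_of(self, mol_indices) -> np.ndarray:
        """Atom indices of the given molecules (concatenated, ordered)."""
        return np.concatenate(
            [np.arange(self.molecules[i].start, self.molecules[i].stop) for i in np.atleast_1d(mol_indices)]
        ) if len(np.atleast_1d(mol_indices)) else np.empty(0, dtype=np.intp)

    def species_def(self, mol_index: int):
        return self.registry[self.molecules[mol_index].species]

    def find_atom(self, mol_index: int, name: str) -> int:
        """Global atom index of atom `name` in molecule `mol_index`."""
        m = self.molecules[mol_index]
        names = self.atom_names[m.start : m.stop]
        hits = np.nonzero(names == name)[0]
        if len(hits) == 0:
            raise KeyError(f"molecule {mol_index} ({m.species}) has no atom {name!r}")
        return m.start + int(hits[0])

    def with_leaflets(self, tags) -> "Topology":
        mols = [replace(m, leaflet=t) for m, t in zip(self.molecules, tags)]
        return Topology(mols, self.atom_names, self.masses, self.registry)


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis."""
    return np.mod(positions, box[None, :])


@dataclass
class Frame:
    """One time point: wrapped positions in an orthorhombic box."""

    time: float                     # ps
    box: np.ndarray                 # (3,), Angstrom
    positions: np.ndarray           # (n_atoms, 3), Angstrom, wrapped

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.box.shape != (3,):
            raise ValueError("box must be 3 orthorhombic edge lengths (triclinic boxes are not supported)")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")

    def wrapped(self) -> "Frame":
        return Frame(self.time, self.box, wrap_positions(self.positions, self.box))


@dataclass
class Trajectory:
    """Time-ordered frames over a fixed topology."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        for k, f in enumerate(self.frames):
            if f.positions.shape != (self.topology.n_atoms, 3):
                raise ValueError(f"frame {k}: atom count mismatch with topology")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# Leaflet assignment


def assign_leaflets(traj: Trajectory, flip: bool = False) -> Trajectory:
    """Tag every lipid molecule inner/outer from frame 0 and freeze the tags.

    A lipid is assigned by the sign of its headgroup reference atom's
    z-coordinate relative to the bilayer midplane, taken as the median z of
    all headgroup reference atoms in the first frame.  Upper = outer,
    lower = inner by default (``flip`` swaps the orientation).  Tags are
    frozen: lipids are assumed not to flip leaflets over the trajectory.
    """
    topo = traj.topology
    frame0 = traj.frames[0]
    ref_z, lipid_idx = [], []
    for m in topo.molecules:
        sdef = topo.registry[m.species]
        if not sdef.is_lipid:
            continue
        try:
            a = topo.find_atom(m.index, sdef.headgroup_ref)
        except KeyError:
            raise KeyError(
                f"lipid species {m.species} missing headgroup reference atom {sdef.headgroup_ref!r}"
            ) from None
        ref_z.append(frame0.positions[a, 2])
        lipid_idx.append(m.index)
    if not lipid_idx:
        raise ValueError("no lipid molecules in topology")
    ref_z = np.asarray(ref_z)
    mid = np.median(ref_z)
    upper = ref_z > mid
    if upper.all() or (~upper).all():
        raise ValueError("empty leaflet: all lipids on one side of the midplane")
    hi, lo = ("outer", "inner") if not flip else ("inner", "outer")
    tags = [m.leaflet for m in topo.molecules]
    for i, up in zip(lipid_idx, upper):
        tags[i] = hi if up else lo
    return Trajectory(topo.with_leaflets(tags), traj.frames)


# ---------------------------------------------------------------------------
# Selections
#
# Grammar:  expr    := or_term
#           or_term := and_term ('or' and_term)*
#           and_term:= unary ('and' unary)*
#           unary   := 'not' unary | '(' expr ')' | predicate
#           predicate := 'species' NAME | 'leaflet' TAG | 'kind' KIND
#                        | 'all' | 'none'
# Returns molecule index sets; deterministic (sorted) and composable.

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(query: str) -> list[str]:
    return _TOKEN.findall(query)


class _Parser:
    def __init__(self, tokens: list[str], topo: Topology):
        self.toks = tokens
        self.i = 0
        self.topo = topo

    def peek(self):
        return self.toks[self.i] if self.i < len(self.toks) else None

    def pop(self):
        t = self.peek()
        self.i += 1
        return t

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self):
        m = self.and_term()
        while self.peek() == "or":
            self.pop()
            m = m | self.and_term()
        return m

    def and_term(self):
        m = self.unary()
        while self.peek() == "and":
            self.pop()
            m = m & self.unary()
        return m

    def unary(self):
        t = self.peek()
        if t == "not":
            self.pop()
            return ~self.unary()
        if t == "(":
            self.pop()
            m = self.expr()
            if self.pop() != ")":
                raise SelectionError("unbalanced parentheses")
            return m
        return self.predicate()

    def predicate(self):
        topo = self.topo
        t = self.pop()
        if t is None:
            raise SelectionError("empty selection term")
        n = topo.n_molecules
        if t == "all":
            return np.ones(n, dtype=bool)
        if t == "none":
            return np.zeros(n, dtype=bool)
        if t == "species":
            tok = self.pop()
            if tok is None:
                raise SelectionError("'species' needs a name")
            try:
                names = set(topo.registry.expand(tok))
            except KeyError as e:
                raise SelectionError(str(e)) from None
            sp = topo.mol_species
            return np.isin(sp, list(names))
        if t == "leaflet":
            tag = self.pop()
            if tag not in LEAFLETS:
                raise SelectionError(f"unknown leaflet tag: {tag!r}")
            return topo.mol_leaflet == tag
        if t == "kind":
            kind = self.pop()
            if kind == "lipid":
                kinds = {"lipid", "sterol"}
            elif kind in ("ion", "water", "sterol"):
                kinds = {kind}
            else:
                raise SelectionError(f"unknown kind: {kind!r}")
            return np.array([topo.registry[m.species].kind in kinds for m in topo.molecules])
        raise SelectionError(f"unknown selection token: {t!r}")


def select(traj_or_topo, query: str) -> np.ndarray:
    """Molecule indices matching a selection expression.

    Example: ``select(traj, "species PIP2 and leaflet inner")``.  The empty
    query selects nothing.  Unknown species/leaflet/kind tokens raise
    :class:`SelectionError` naming the offending token.
    """
    topo = traj_or_topo.topology if isinstance(traj_or_topo, Trajectory) else traj_or_topo
    toks = _tokenize(query)
    if not toks:
        return np.empty(0, dtype=np.intp)
    mask = _Parser(toks, topo).parse()
    return np.nonzero(mask)[0]


def select_atoms(traj_or_topo, query: str, name: str | None = None) -> np.ndarray:
    """Atom indices of the selected molecules, optionally restricted by atom name."""
    topo = traj_or_topo.topology if isinstance(traj_or_topo, Trajectory) else traj_or_topo
    mols = select(topo, query)
    if len(mols) == 0:
        return np.empty(0, dtype=np.intp)
    atoms = topo.atoms_of(mols)
    if name is not None:
        atoms = atoms[topo.atom_names[atoms] == name]
    return atoms
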