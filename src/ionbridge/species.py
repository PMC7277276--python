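"""Species registry: CHARMM36-style atom naming, donor/acceptor tables,
charges and first-solvation-shell radii for the molecular species the
analyses understand.

The default registry ships as ``data/species.yaml``; users may load their
own table for other force-field dialects.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

# Query aliases: a selection token on the left expands to the species on
# the right.  PIP2 covers both phosphoinositide bisphosphate isomers; PPI
# covers the whole polyphosphoinositide class including PI.
ALIASES: dict[str, tuple[str, ...]] = {
    "PIP2": ("PI45P2", "PI35P2"),
    "PPI": ("PI", "PI45P2", "PI35P2"),
    "WATER": ("TIP3",),
}


@dataclass(frozen=True)
class SpeciesDef:
    """One molecular species: atom template plus chemistry tables."""

    name: str
    kind: str                       # lipid | sterol | ion | water
    charge: float                   # net charge, e
    atom_names: tuple[str, ...]
    masses: np.ndarray              # (n_atoms,)
    offsets: np.ndarray             # (n_atoms, 3), Angstrom, outer-leaflet frame
    headgroup_ref: str
    donors: tuple[tuple[str, str], ...] = ()
    acceptors: tuple[str, ...] = ()
    anionic: tuple[str, ...] = ()
    reference_area: float | None = None
    shell_radius: float | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_index(self, name: str) -> int:
        try:
            return self.atom_names.index(name)
        except ValueError:
            raise KeyError(f"species {self.name} has no atom named {name!r}") from None

    @property
    def is_lipid(self) -> bool:
        # sterols count as "lipids" for leaflet/tessellation purposes
        return self.kind in ("lipid", "sterol")


@dataclass
class SpeciesRegistry:
    """Mapping species name -> :class:`SpeciesDef` with alias expansion."""

    defs: dict[str, SpeciesDef] = field(default_factory=dict)

    def __getitem__(self, name: str) -> SpeciesDef:
        return self.defs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.defs

    def __iter__(self):
        return iter(self.defs.values())

    def expand(self, token: str) -> tuple[str, ...]:
        """Expand a species token (possibly an alias) to concrete names.

        Raises ``KeyError`` naming the token if it is neither a species nor
        an alias.
        """
        t = token.upper()
        if t in ALIASES:
            return tuple(s for s in ALIASES[t] if s in self.defs) or ALIASES[t]
        if token in self.defs:
            return (token,)
        if t in self.defs:
            return (t,)
        raise KeyError(f"unknown species or alias: {token!r}")

    @property
    def species_table(self) -> dict[str, tuple[str, ...]]:
        return {name: d.atom_names for name, d in self.defs.items()}

    @property
    def donor_acceptor_table(self) -> dict[str, dict]:
        return {
            name: {"donors": d.donors, "acceptors": d.acceptors}
            for name, d in self.defs.items()
        }

    @property
    def charge_per_species(self) -> dict[str, float]:
        return {name: d.charge for name, d in self.defs.items()}

    def shell_radii(self) -> dict[str, float]:
        """Default first-solvation-shell radii (A) for the cation species."""
        return {
            name: d.shell_radius
            for name, d in self.defs.items()
            if d.shell_radius is not None
        }


def _parse_species(name: str, raw: dict) -> SpeciesDef:
    atoms = raw["atoms"]
    names = tuple(a[0] for a in atoms)
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate atom names in species {name}")
    masses = np.array([a[1] for a in atoms], dtype=float)
    offsets = np.array([a[2:5] for a in atoms], dtype=float)
    return SpeciesDef(
        name=name,
        kind=raw["kind"],
        charge=float(raw["charge"]),
        atom_names=names,
        masses=masses,
        offsets=offsets,
        headgroup_ref=raw.get("headgroup_ref", names[0]),
        donors=tuple((d, h) for d, h in raw.get("donors", [])),
        acceptors=tuple(raw.get("acceptors", [])),
        anionic=tuple(raw.get("anionic", [])),
        reference_area=raw.get("reference_area"),
        shell_radius=raw.get("shell_radius"),
    )


def load_registry(path: str | None = None) -> SpeciesRegistry:
    """Load a species registry from YAML (default: the bundled table)."""
    if path is None:
        text = resources.files("ionbridge.data").joinpath("species.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return SpeciesRegistry({name: _parse_species(name, spec) for name, spec in raw.items()})


_DEFAULT: SpeciesRegistry | None = None


def default_registry() -> SpeciesRegistry:
    """The bundled CHARMM36-named registry (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_registry()
    return _DEFAULT
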