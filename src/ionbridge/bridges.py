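"""N-bridge classification, charging curves, and lipid cluster graphs.

An *N-bridge* is a cation whose minimum distance to each of N distinct
lipids lies within the cation's first-solvation-shell radius, i.e. a
desolvated, tightly bound ion shared by N lipids.  Reducing every
lipid-cation-lipid bond of a bridge of order >= 2 to a lipid-lipid edge
yields a per-frame graph whose connected components are the lipid
clusters; 1-bridges contribute no edges and hence no clusters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import Trajectory, Topology, Frame
from .neighbors import molecule_min_distances
from .solvation import DEFAULT_SHELL_RADII

PPI_SPECIES = frozenset({"PI", "PI45P2", "PI35P2"})


@dataclass(frozen=True)
class BridgeRecord:
    """One ion bound to >= 1 lipid at one frame."""

    frame: int
    ion_mol: int
    ion_species: str
    lipids: tuple[int, ...]         # sorted molecule indices
    lipid_species: tuple[str, ...]
    contains_ppi: bool

    @property
    def order(self) -> int:
        return len(self.lipids)


def default_lipid_scope(topo: Topology) -> np.ndarray:
    """Default analysis scope: inner-leaflet lipids (the charged leaflet);
    falls back to all lipids when leaflets are untagged."""
    reg = topo.registry
    inner = [m.index for m in topo.molecules if m.leaflet == "inner" and reg[m.species].is_lipid]
    if inner:
        return np.asarray(inner, dtype=np.intp)
    return np.asarray(
        [m.index for m in topo.molecules if reg[m.species].is_lipid], dtype=np.intp
    )


def classify_bridges(
    frame: Frame,
    topo: Topology,
    shell_radii: dict[str, float] | None = None,
    lipid_scope: np.ndarray | None = None,
    frame_index: int = 0,
) -> list[BridgeRecord]:
    """One BridgeRecord per cation with >= 1 bound lipid.

    Bound means molecule_min_distance(ion, lipid) <= d_s(ion species).
    ``shell_radii`` maps cation species to first-shell radii (defaults:
    Na+/K+ 3.0, Mg2+ 2.3, Ca2+ 2.6 A); species named there must exist.
    """
    radii = shell_radii or DEFAULT_SHELL_RADII
    for sp in radii:
        if sp not in topo.registry:
            raise KeyError(f"unknown ion species in shell spec: {sp!r}")
    scope = lipid_scope if lipid_scope is not None else default_lipid_scope(topo)
    ion_mols = np.asarray(
        [m.index for m in topo.molecules if m.species in radii], dtype=np.intp
    )
    if len(ion_mols) == 0 or len(scope) == 0:
        return []
    r_max = max(radii.values())
    pl = molecule_min_distances(frame, topo, ion_mols, scope, r_max, frame_index)
    bound: dict[int, list[int]] = {}
    for c, l, d in zip(pl.pairs_a, pl.pairs_b, pl.distances):
        if d <= radii[topo.molecules[int(c)].species]:
            bound.setdefault(int(c), []).append(int(l))
    records = []
    for ion in sorted(bound):
        lipids = tuple(sorted(bound[ion]))
        lsp = tuple(topo.molecules[i].species for i in lipids)
        records.append(
            BridgeRecord(
                frame=frame_index,
                ion_mol=ion,
                ion_species=topo.molecules[ion].species,
                lipids=lipids,
                lipid_species=lsp,
                contains_ppi=any(s in PPI_SPECIES for s in lsp),
            )
        )
    return records


def classify_bridges_trajectory(
    traj: Trajectory,
    shell_radii: dict[str, float] | None = None,
    lipid_scope: np.ndarray | None = None,
) -> list[list[BridgeRecord]]:
    """Per-frame bridge records for a whole trajectory."""
    topo = traj.topology
    scope = lipid_scope if lipid_scope is not None else default_lipid_scope(topo)
    return [
        classify_bridges(fr, topo, shell_radii, scope, fi)
        for fi, fr in enumerate(traj.frames)
    ]


def charging_curve(
    traj: Trajectory,
    shell_radii: dict[str, float] | None = None,
    lipid_scope: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bound-ion counts per frame keyed by (ion species, order N, contains_ppi).

    The stacked 1-/2-/3-bridge decomposition of these counts is the
    charging curve: cation accumulation on the charged leaflet over time.
    """
    rows = []
    per_frame = classify_bridges_trajectory(traj, shell_radii, lipid_scope)
    for fi, records in enumerate(per_frame):
        t = traj.frames[fi].time
        keys: dict[tuple, int] = {}
        for r in records:
            k = (r.ion_species, r.order, r.contains_ppi)
            keys[k] = keys.get(k, 0) + 1
        for (sp, order, ppi), count in sorted(keys.items()):
            rows.append(
                {"frame": fi, "time": t, "ion_species": sp, "order": order,
                 "contains_ppi": ppi, "count": count}
            )
    return pd.DataFrame(rows, columns=["frame", "time", "ion_species", "order", "contains_ppi", "count"])


@dataclass
class ClusterGraph:
    """Lipid-lipid bond graph of one frame: nodes are lipids, an edge wherever
    a bridge of order >= 2 links two lipids."""

    frame: int
    graph: nx.Graph = field(repr=False)
    components: list[frozenset[int]] = field(default_factory=list)

    @property
    def sizes(self) -> list[int]:
        return sorted((len(c) for c in self.components), reverse=True)


def build_cluster_graph(records: list[BridgeRecord], frame_index: int | None = None, star: bool = False) -> ClusterGraph:
    """Reduce one frame's bridges to the lipid-lipid cluster graph.

    Every bridge of order >= 2 contributes edges between its bound lipids:
    all pairwise combinations by default (clique), or hub-free star edges
    from the lowest-id lipid when ``star`` (component structure identical).
    Multi-ion edges are deduplicated; mediating ions recorded per edge.
    """
    if frame_index is None:
        frame_index = records[0].frame if records else 0
    g = nx.Graph()
    for r in records:
        if r.order < 2:
            continue
        lip = r.lipids
        pairs = (
            [(lip[0], b) for b in lip[1:]]
            if star
            else [(a, b) for i, a in enumerate(lip) for b in lip[i + 1 :]]
        )
        for a, b in pairs:
            if g.has_edge(a, b):
                g[a][b]["ions"].add(r.ion_mol)
            else:
                g.add_edge(a, b, ions={r.ion_mol})
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return ClusterGraph(frame_index, g, comps)


def cluster_size_distribution(
    traj: Trajectory,
    shell_radii: dict[str, float] | None = None,
    lipid_scope: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame multiset of cluster sizes (N lipids per connected component).

    Returns a tidy frame (frame, time, size, count); the per-frame maximum
    traces cluster growth.
    """
    rows = []
    for fi, records in enumerate(classify_bridges_trajectory(traj, shell_radii, lipid_scope)):
        cg = build_cluster_graph(records, fi)
        sizes = cg.sizes
        t = traj.frames[fi].time
        for s in sorted(set(sizes)):
            rows.append({"frame": fi, "time": t, "size": s, "count": sizes.count(s)})
    return pd.DataFrame(rows, columns=["frame", "time", "size", "count"])
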