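"""Salt-bridge and hydrophobic contact persistence networks.

A frame counts as a contact when the minimum inter-group atom distance is
below the cutoff (salt bridges 0.45 nm between oppositely charged groups,
hydrophobic 0.55 nm between side-chain carbons of apolar residues).
Records with persistence — the fraction of frames in contact — of at least
20 % of the macro-trajectory enter the interaction graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .structure_io import (
    CHARGED_GROUP_ATOMS,
    GROUP_CHARGE,
    HIS_CHARGED_ATOMS,
    HYDROPHOBIC_RESIDUES,
    BACKBONE_ATOMS,
    CAStructure,
    Ensemble,
)
from .units import nm_to_angstrom


@dataclass
class NetworkParameters:
    salt_bridge_cutoff: float = nm_to_angstrom(0.45)   # Å
    hydrophobic_cutoff: float = nm_to_angstrom(0.55)   # Å
    persistence_cutoff: float = 0.20
    include_his: bool = False          # His neutral by default
    angle_screen: bool = False         # optional N–O–C angle > 90° check

    def __post_init__(self) -> None:
        if self.salt_bridge_cutoff <= 0 or self.hydrophobic_cutoff <= 0:
            raise ValueError("distance cutoffs must be > 0")
        if not (0.0 <= self.persistence_cutoff <= 1.0):
            raise ValueError("persistence cutoff must lie in [0, 1]")


@dataclass
class InteractionRecord:
    residue_a: tuple[str, int, str]        # (chain, res_id, res_name)
    residue_b: tuple[str, int, str]
    kind: str                              # "salt-bridge" | "hydrophobic"
    contacts: np.ndarray                   # per-frame booleans
    replica_boundaries: list[int] = field(default_factory=list)

    @property
    def persistence(self) -> float:
        return float(np.mean(self.contacts))

    def replica_persistences(self) -> list[float]:
        bounds = [0, *self.replica_boundaries, len(self.contacts)]
        return [
            float(np.mean(self.contacts[a:b]))
            for a, b in zip(bounds[:-1], bounds[1:]) if b > a
        ]


def _charged_groups(structure: CAStructure, res_indices, include_his: bool):
    """(res_index, sign, atom indices) for charged side-chain groups."""
    out = []
    for i in res_indices:
        res = structure.residues[i]
        names = CHARGED_GROUP_ATOMS.get(res.res_name, ())
        if res.res_name == "HIS" and include_his:
            names = HIS_CHARGED_ATOMS
        idx = [structure.flat_atom_index(i, n) for n in names if n in res.atom_names]
        if idx:
            out.append((i, GROUP_CHARGE[res.res_name], np.array(idx)))
    return out


def _hydrophobic_groups(structure: CAStructure, res_indices):
    out = []
    for i in res_indices:
        res = structure.residues[i]
        if res.res_name not in HYDROPHOBIC_RESIDUES:
            continue
        idx = [
            structure.flat_atom_index(i, n)
            for n, e in zip(res.atom_names, res.elements)
            if n not in BACKBONE_ATOMS and (e or n[:1]).upper().startswith("C")
        ]
        if idx:
            out.append((i, 0, np.array(idx)))
    return out


def detect_contacts(ensemble: Ensemble,
                    selection_a: list[int] | tuple[int, int],
                    selection_b: list[int] | tuple[int, int],
                    kind: str = "salt-bridge",
                    params: NetworkParameters | None = None,
                    chain_a: str | None = None,
                    chain_b: str | None = None) -> list[InteractionRecord]:
    """Per-frame contact records for every qualifying residue pair.

    Selections are residue-index lists (0-based) or PDB-number ranges
    (inclusive tuples). Nothing is filtered by persistence here.
    """
    params = params or NetworkParameters()
    if kind not in ("salt-bridge", "hydrophobic"):
        raise ValueError(f"unknown interaction kind {kind!r}")
    structure = ensemble.structure

    def _resolve(sel, chain):
        if isinstance(sel, tuple) and len(sel) == 2:
            return structure.range_indices(sel[0], sel[1], chain)
        return list(sel)

    idx_a = _resolve(selection_a, chain_a)
    idx_b = _resolve(selection_b, chain_b)
    if kind == "salt-bridge":
        groups_a = _charged_groups(structure, idx_a, params.include_his)
        groups_b = _charged_groups(structure, idx_b, params.include_his)
        cutoff = params.salt_bridge_cutoff
    else:
        groups_a = _hydrophobic_groups(structure, idx_a)
        groups_b = _hydrophobic_groups(structure, idx_b)
        cutoff = params.hydrophobic_cutoff
    if not groups_a or not groups_b:
        raise ValueError(f"selection resolves to zero {kind} groups")

    records = []
    for (ia, qa, atoms_a) in groups_a:
        for (ib, qb, atoms_b) in groups_b:
            if ia == ib:
                continue
            if kind == "salt-bridge" and qa * qb >= 0:
                continue  # like charges never form a salt bridge
            pa = ensemble.frames[:, atoms_a, :]
            pb = ensemble.frames[:, atoms_b, :]
            d = np.linalg.norm(pa[:, :, None, :] - pb[:, None, :, :], axis=3)
            mind = d.reshape(len(d), -1).min(axis=1)
            contacts = mind < cutoff
            ra = structure.residues[ia]
            rb = structure.residues[ib]
            records.append(InteractionRecord(
                residue_a=(ra.chain_id, ra.res_id, ra.res_name),
                residue_b=(rb.chain_id, rb.res_id, rb.res_name),
                kind=kind,
                contacts=contacts,
                replica_boundaries=list(ensemble.replica_boundaries),
            ))
    return records


@dataclass
class InteractionGraph:
    graph: nx.Graph
    histogram: tuple[np.ndarray, np.ndarray]   # counts, bin edges
    dropped: int

    def edges(self) -> list[tuple]:
        return [
            (u, v, d["persistence"]) for u, v, d in self.graph.edges(data=True)
        ]


def filter_by_persistence(records: list[InteractionRecord],
                          params: NetworkParameters | None = None) -> InteractionGraph:
    """Drop records below the persistence cutoff and build the graph.

    Nodes are residues, arcs carry persistence weights; the persistence
    histogram is reported so the signal/noise separation can be inspected.
    """
    params = params or NetworkParameters()
    pers = np.array([r.persistence for r in records]) if records else np.array([])
    hist = np.histogram(pers, bins=20, range=(0.0, 1.0))
    g = nx.Graph()
    dropped = 0
    for rec in records:
        if rec.persistence >= params.persistence_cutoff:
            a = f"{rec.residue_a[2]}{rec.residue_a[1]}_{rec.residue_a[0]}"
            b = f"{rec.residue_b[2]}{rec.residue_b[1]}_{rec.residue_b[0]}"
            g.add_edge(a, b, persistence=rec.persistence, kind=rec.kind,
                       replica_persistences=rec.replica_persistences())
        else:
            dropped += 1
    return InteractionGraph(g, hist, dropped)


def macro_trajectory(ensembles: list[Ensemble],
                     discard: list[int] | int = 0) -> Ensemble:
    """Join the equilibrated portions of replicas into one macro-trajectory.

    ``discard`` gives the equilibration frames to drop per replica. Replica
    boundaries are recorded so per-replica and pooled persistences are both
    computable; the pooled persistence is the frame-weighted mean of the
    replica persistences by construction.
    """
    if not ensembles:
        raise ValueError("no replicas")
    if isinstance(discard, int):
        discard = [discard] * len(ensembles)
    if len(discard) != len(ensembles):
        raise ValueError("discard list length mismatch")
    ref = ensembles[0].structure
    keys = [r.key for r in ref.residues]
    blocks = []
    for ens, d in zip(ensembles, discard):
        if [r.key for r in ens.structure.residues] != keys or \
                ens.structure.n_atoms != ref.n_atoms:
            raise ValueError("incongruent replicas")
        if d >= ens.n_frames:
            raise ValueError("discard exceeds replica length")
        blocks.append(ens.frames[d:])
    boundaries = list(np.cumsum([len(b) for b in blocks])[:-1])
    return Ensemble(
        ref, np.concatenate(blocks, axis=0),
        frame_spacing=ensembles[0].frame_spacing,
        provenance="macro",
        replica_boundaries=boundaries,
    )
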