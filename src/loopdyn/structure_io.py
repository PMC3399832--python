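"""Structure, ensemble and alignment I/O.

Coordinates are in Å. Residue identity is (chain id, residue number,
insertion code, residue name) with PDB 1-based numbering; internal indices
are 0-based. Multi-model PDB is the ensemble interchange format: a frame is
one MODEL record, so any downstream tool can read the files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: side-chain atoms carrying the formal charge, per residue type
CHARGED_GROUP_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
HIS_CHARGED_ATOMS = ("ND1", "NE2")

#: formal charge sign of the side-chain group
GROUP_CHARGE = {"LYS": +1, "ARG": +1, "ASP": -1, "GLU": -1, "HIS": +1}

HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1 = set(AA3_TO_1.values())


@dataclass
class Residue:
    """One residue with its atoms; coordinates shape (n_atoms, 3) in Å."""

    chain_id: str
    res_id: int
    ins_code: str
    res_name: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_id, self.ins_code)

    def atom_index(self, name: str) -> int:
        return self.atom_names.index(name)

    @property
    def ca(self) -> np.ndarray:
        return self.coords[self.atom_index("CA")]


@dataclass
class CAStructure:
    """Parsed protein coordinates, all-atom or Cα-only.

    ``flat`` indexing concatenates atoms over residues in order; the
    residue→index mapping is a stable bijection used by every module.
    """

    residues: list[Residue]
    label: str = ""

    def __post_init__(self) -> None:
        offsets = []
        off = 0
        for res in self.residues:
            if "CA" not in res.atom_names:
                raise ValueError(f"residue {res.key} has no CA atom")
            if not np.all(np.isfinite(res.coords)):
                raise ValueError(f"residue {res.key} has non-finite coordinates")
            offsets.append(off)
            off += len(res.atom_names)
        self._offsets = offsets
        self._n_atoms = off
        # residue order must strictly increase within each chain
        prev: dict[str, tuple[int, str]] = {}
        for res in self.residues:
            mark = (res.res_id, res.ins_code)
            if res.chain_id in prev and mark <= prev[res.chain_id]:
                raise ValueError(
                    f"residue order not increasing in chain {res.chain_id!r} at {mark}"
                )
            prev[res.chain_id] = mark

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return self._n_atoms

    @property
    def is_calpha_only(self) -> bool:
        return all(res.atom_names == ["CA"] for res in self.residues)

    def flat_coords(self) -> np.ndarray:
        """All atom coordinates, shape (n_atoms, 3)."""
        return np.concatenate([res.coords for res in self.residues], axis=0)

    def flat_atom_index(self, res_index: int, atom_name: str) -> int:
        return self._offsets[res_index] + self.residues[res_index].atom_index(atom_name)

    def residue_atom_indices(self, res_index: int) -> np.ndarray:
        off = self._offsets[res_index]
        return np.arange(off, off + len(self.residues[res_index].atom_names))

    def ca_indices(self) -> np.ndarray:
        return np.array(
            [self.flat_atom_index(i, "CA") for i in range(self.n_residues)]
        )

    def ca_coords(self) -> np.ndarray:
        return np.stack([res.ca for res in self.residues])

    def residue_index(self, res_id: int, chain_id: str | None = None,
                      ins_code: str = "") -> int:
        """0-based index of the residue with the given PDB number."""
        for i, res in enumerate(self.residues):
            if res.res_id == res_id and res.ins_code == ins_code and (
                chain_id is None or res.chain_id == chain_id
            ):
                return i
        raise KeyError(f"no residue {chain_id or '*'}:{res_id}{ins_code}")

    def range_indices(self, start: int, stop: int,
                      chain_id: str | None = None) -> list[int]:
        """0-based residue indices with PDB numbers in [start, stop]."""
        out = [
            i for i, res in enumerate(self.residues)
            if start <= res.res_id <= stop
            and (chain_id is None or res.chain_id == chain_id)
        ]
        if not out:
            raise KeyError(f"empty residue range {start}-{stop} (chain {chain_id})")
        return out

    def with_coords(self, flat: np.ndarray, label: str | None = None) -> "CAStructure":
        """Copy of this structure carrying new flat coordinates."""
        if flat.shape != (self.n_atoms, 3):
            raise ValueError("coordinate shape mismatch")
        residues = []
        for i, res in enumerate(self.residues):
            sel = self.residue_atom_indices(i)
            residues.append(Residue(res.chain_id, res.res_id, res.ins_code,
                                    res.res_name, list(res.atom_names),
                                    list(res.elements), flat[sel].copy()))
        return CAStructure(residues, label if label is not None else self.label)


@dataclass
class Ensemble:
    """Ordered coordinate frames congruent with a reference structure.

    frame_spacing is the time per frame in ps, or None for ensembles with
    no time axis (NMA sampling, NMR depositions).
    """

    structure: CAStructure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_spacing: float | None = None
    provenance: str = "external"
    replica_boundaries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.structure.n_atoms:
            raise ValueError(
                f"frames shape {self.frames.shape} incongruent with "
                f"{self.structure.n_atoms} atoms"
            )
        if self.frame_spacing is not None and self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def ca_frames(self) -> np.ndarray:
        """Cα coordinates per frame, shape (n_frames, n_residues, 3)."""
        return self.frames[:, self.structure.ca_indices(), :]

    def frame_structure(self, i: int) -> CAStructure:
        return self.structure.with_coords(self.frames[i])


@dataclass
class AlignmentBlock:
    """A multiple sequence alignment over the 20 amino acids, gap and X."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        n = len(self.sequences[0])
        if any(len(s) != n for s in self.sequences):
            raise ValueError("ragged alignment: sequences differ in length")
        allowed = AA1 | {"-", ".", "X"}
        for sid, seq in zip(self.ids, self.sequences):
            bad = set(seq.upper()) - allowed
            if bad:
                raise ValueError(f"sequence {sid!r} has invalid symbols {sorted(bad)}")
        self.sequences = [s.upper().replace(".", "-") for s in self.sequences]

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def column(self, j: int) -> list[str]:
        return [s[j] for s in self.sequences]


# ---------------------------------------------------------------------------
# PDB reading / writing (biotite backend)
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD", "SOL"}


def _atoms_to_structure(arr, label: str = "") -> CAStructure:
    import biotite.structure as struc

    mask = ~arr.hetero
    mask &= ~np.isin(arr.res_name, list(_WATER_NAMES))
    arr = arr[mask]
    residues: list[Residue] = []
    starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    for beg, end in zip(starts[:-1], starts[1:]):
        sub = arr[beg:end]
        names = list(sub.atom_name)
        if "CA" not in names:
            logger.warning(
                "dropping residue %s %s%s: no CA atom",
                sub.res_name[0], sub.chain_id[0], sub.res_id[0],
            )
            continue
        ins = sub.ins_code[0] if hasattr(sub, "ins_code") else ""
        residues.append(
            Residue(
                chain_id=str(sub.chain_id[0]),
                res_id=int(sub.res_id[0]),
                ins_code=str(ins).strip(),
                res_name=str(sub.res_name[0]),
                atom_names=names,
                elements=[str(e) for e in sub.element],
                coords=np.array(sub.coord, dtype=float),
            )
        )
    if not residues:
        raise ValueError("no protein residues with CA found")
    return CAStructure(residues, label=label)


def read_pdb(path: str | Path, model_policy: str = "first") -> CAStructure | Ensemble:
    """Read a PDB file.

    model_policy "first" returns a CAStructure from the first model;
    "all" returns an Ensemble over every model (provenance "external").
    Waters and heteroatoms are excluded; altlocs resolved by occupancy.
    """
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    pfile = pdbio.PDBFile.read(str(path))
    if model_policy == "first":
        arr = pfile.get_structure(model=1, altloc="occupancy")
        return _atoms_to_structure(arr, label=path.stem)
    stack = pfile.get_structure(altloc="occupancy")
    first = _atoms_to_structure(stack[0], label=path.stem)
    # congruent frames: keep the same atom mask for every model
    import biotite.structure as struc
    mask = ~stack.hetero & ~np.isin(stack.res_name, list(_WATER_NAMES))
    sub = stack[..., mask]
    # drop atoms of residues that were discarded (no CA)
    kept = np.zeros(sub.array_length(), dtype=bool)
    keys = {r.key for r in first.residues}
    ins = sub.ins_code if hasattr(sub, "ins_code") else [""] * sub.array_length()
    for i in range(sub.array_length()):
        key = (str(sub.chain_id[i]), int(sub.res_id[i]), str(ins[i]).strip())
        kept[i] = key in keys
    frames = np.array(sub.coord[:, kept, :], dtype=float)
    return Ensemble(first, frames, frame_spacing=None, provenance="external")


def _to_atom_array(structure: CAStructure):
    import biotite.structure as struc

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    i = 0
    for res in structure.residues:
        for name, elem, xyz in zip(res.atom_names, res.elements, res.coords):
            arr.chain_id[i] = res.chain_id or "A"
            arr.res_id[i] = res.res_id
            arr.ins_code[i] = res.ins_code
            arr.res_name[i] = res.res_name
            arr.atom_name[i] = name
            arr.element[i] = elem or name[0]
            arr.hetero[i] = False
            arr.coord[i] = xyz
            i += 1
    return arr


def write_structure(structure: CAStructure, path: str | Path) -> None:
    import biotite.structure.io.pdb as pdbio

    pfile = pdbio.PDBFile()
    pfile.set_structure(_to_atom_array(structure))
    pfile.write(str(path))


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    template = _to_atom_array(ensemble.structure)
    stack = struc.stack([template] * ensemble.n_frames)
    stack.coord = np.asarray(ensemble.frames, dtype=np.float32)
    pfile = pdbio.PDBFile()
    pfile.set_structure(stack)
    pfile.write(str(path))


# ---------------------------------------------------------------------------
# Alignment reading
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, format: str = "fasta") -> AlignmentBlock:
    """Read a FASTA or Clustal multiple alignment."""
    from Bio import AlignIO

    if format not in ("fasta", "clustal"):
        raise ValueError("format must be 'fasta' or 'clustal'")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise ValueError(f"unreadable or ragged alignment {path}: {exc}") from exc
    return AlignmentBlock(
        ids=[rec.id for rec in aln],
        sequences=[str(rec.seq) for rec in aln],
    )


def write_alignment(block: AlignmentBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(block.ids, block.sequences):
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Atom-group selection
# ---------------------------------------------------------------------------

def select_group(
    structure: CAStructure,
    res_range: tuple[int, int] | None = None,
    chain_id: str | None = None,
    atom_class: str = "calpha",
    include_his: bool = False,
) -> np.ndarray:
    """Resolve a residue-range + atom-class spec to flat atom indices.

    atom_class: "calpha" | "sidechain" | "charged-group" | "all".
    charged-group resolves to the formally charged side-chain atoms
    (NZ; NE/NH1/NH2; OD1/OD2; OE1/OE2; His ND1/NE2 behind include_his)
    plus the chain termini (backbone N of the first residue, OXT of the
    last when present).
    """
    if atom_class not in ("calpha", "sidechain", "charged-group", "all"):
        raise ValueError(f"unknown atom class {atom_class!r}")
    if res_range is None:
        res_indices = list(range(structure.n_residues))
    else:
        res_indices = structure.range_indices(res_range[0], res_range[1], chain_id)
    if chain_id is not None:
        res_indices = [
            i for i in res_indices if structure.residues[i].chain_id == chain_id
        ]

    out: list[int] = []
    chain_first: dict[str, int] = {}
    chain_last: dict[str, int] = {}
    for i, res in enumerate(structure.residues):
        chain_first.setdefault(res.chain_id, i)
        chain_last[res.chain_id] = i

    for i in res_indices:
        res = structure.residues[i]
        if atom_class == "all":
            out.extend(structure.residue_atom_indices(i))
        elif atom_class == "calpha":
            out.append(structure.flat_atom_index(i, "CA"))
        elif atom_class == "sidechain":
            for name in res.atom_names:
                if name not in BACKBONE_ATOMS and not name.startswith("H"):
                    out.append(structure.flat_atom_index(i, name))
        else:  # charged-group
            names = CHARGED_GROUP_ATOMS.get(res.res_name, ())
            if res.res_name == "HIS" and include_his:
                names = HIS_CHARGED_ATOMS
            for name in names:
                if name in res.atom_names:
                    out.append(structure.flat_atom_index(i, name))
            if i == chain_first[res.chain_id] and "N" in res.atom_names:
                out.append(structure.flat_atom_index(i, "N"))
            if i == chain_last[res.chain_id] and "OXT" in res.atom_names:
                out.append(structure.flat_atom_index(i, "OXT"))
    if not out:
        raise ValueError(
            f"empty selection: range={res_range} chain={chain_id} class={atom_class}"
        )
    return np.array(sorted(set(out)), dtype=int)


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Least-squares superpose mobile onto reference; return (fitted, RMSD)."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("shape mismatch")
    if weights is None:
        weights = np.ones(len(mobile))
    w = weights / weights.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    A = mobile - mc
    B = reference - rc
    H = (w[:, None] * A).T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    fitted = A @ R + rc
    rmsd = float(np.sqrt(((fitted - reference) ** 2).sum(axis=1).mean()))
    return fitted, rmsd
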