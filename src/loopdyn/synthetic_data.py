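"""Synthetic fixtures with known ground truth.

Every analysis stage in the package has a generator here whose planted
truth it must recover: Cα chains with known geometry, Gaussian ensembles
with planted correlations, trajectories with contacts present in a planted
fraction of frames, loop trajectories with planted closed/semi-open/open
populations, backbone stretches with designed φ/ψ, and toy alignments with
designed column composition. All randomness flows through a single seeded
generator per call; outputs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import AlignmentBlock, CAStructure, Ensemble, Residue
from .conservation import AMINO_ACIDS


# ---------------------------------------------------------------------------
# Cα chains
# ---------------------------------------------------------------------------

CA_BOND = 3.8  # Å, virtual Cα-Cα bond


def _ca_structure(coords: np.ndarray, res_names: list[str] | None = None,
                  label: str = "chain") -> CAStructure:
    residues = [
        Residue("A", i + 1, "", (res_names[i] if res_names else "GLY"),
                ["CA"], ["C"], np.array([xyz], dtype=float))
        for i, xyz in enumerate(coords)
    ]
    return CAStructure(residues, label=label)


def make_chain(n_residues: int, geometry: str = "extended", seed: int = 0,
               jitter: float = 0.0) -> CAStructure:
    """Ideal Cα chain: extended zig-zag (exact 3.8 Å bonds), α-helical
    trace, or a two-strand hairpin. Optional Gaussian jitter (seeded)."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if geometry == "extended":
        # non-planar extended trace: unit steps precess about x so the ANM
        # Hessian is non-degenerate; consecutive distances stay exactly 3.8
        alpha = math.radians(30.0)
        steps = np.array([
            [math.cos(alpha),
             math.sin(alpha) * math.cos(k * math.pi / 2),
             math.sin(alpha) * math.sin(k * math.pi / 2)]
            for k in range(max(n_residues - 1, 1))
        ]) * CA_BOND
        coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])[:n_residues]
    elif geometry == "helix":
        radius, rise, twist = 2.3, 1.5, math.radians(100.0)
        t = np.arange(n_residues)
        coords = np.stack([
            radius * np.cos(t * twist),
            radius * np.sin(t * twist),
            rise * t,
        ], axis=1)
    elif geometry == "hairpin":
        half = (n_residues + 1) // 2
        alpha = math.radians(30.0)
        sx, sy = CA_BOND * math.cos(alpha), CA_BOND * math.sin(alpha)
        coords = []
        for i in range(half):
            coords.append([i * sx, (i % 2) * sy, 0.0])
        for k in range(n_residues - half):
            i = half - 1 - k
            coords.append([i * sx, (i % 2) * sy + 4.8, 0.0])
        coords = np.array(coords)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    if jitter > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    return _ca_structure(coords, label=f"{geometry}-{n_residues}")


# ---------------------------------------------------------------------------
# Backbone builder (for secondary-structure fixtures)
# ---------------------------------------------------------------------------

_BOND_N_CA, _BOND_CA_C, _BOND_C_N = 1.458, 1.525, 1.329
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of the next atom."""
    # +180° aligns the local frame with the IUPAC dihedral sign convention
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg + 180.0)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_backbone(phi_psi: list[tuple[float, float]],
                  label: str = "backbone") -> CAStructure:
    """All-backbone (N, CA, C) chain with the given per-residue φ/ψ.

    The first residue's φ and the last residue's ψ are unused; ω = 180°.
    """
    n = len(phi_psi)
    if n < 2:
        raise ValueError("need at least 2 residues")
    atoms = []  # flat [(res, name, xyz)]
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANG_N_CA_C)
    C0 = CA0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    atoms.append([N0, CA0, C0])
    for i in range(1, n):
        Np, CAp, Cp = atoms[-1]
        psi_prev = phi_psi[i - 1][1]
        N = _place(Np, CAp, Cp, _BOND_C_N, _ANG_CA_C_N, psi_prev)
        CA = _place(CAp, Cp, N, _BOND_N_CA, _ANG_C_N_CA, 180.0)
        C = _place(Cp, N, CA, _BOND_CA_C, _ANG_N_CA_C, phi_psi[i][0])
        atoms.append([N, CA, C])
    residues = [
        Residue("A", i + 1, "", "GLY", ["N", "CA", "C"], ["N", "C", "C"],
                np.array(triplet))
        for i, triplet in enumerate(atoms)
    ]
    return CAStructure(residues, label=label)


# ---------------------------------------------------------------------------
# Planted-covariance ensembles
# ---------------------------------------------------------------------------

def make_planted_covariance_ensemble(
    n_atoms: int,
    planted: list[tuple[int, int, float]],
    n_frames: int = 10_000,
    seed: int = 0,
    sigma: float = 0.5,
) -> tuple[Ensemble, np.ndarray]:
    """Gaussian ensemble whose displacement correlation carries planted ρ.

    Each Cartesian axis is drawn independently from N(0, σ²R) with R the
    planted correlation matrix (nearest-PD repair applied when needed), so
    the DCCM of the ensemble converges to R. Returns (ensemble, realized R).
    """
    R = np.eye(n_atoms)
    for (i, j, rho) in planted:
        if not (-1.0 < rho < 1.0):
            raise ValueError("planted correlation must lie in (-1, 1)")
        R[i, j] = R[j, i] = rho
    evals, evecs = np.linalg.eigh(R)
    if evals.min() < 1e-10:
        evals = np.maximum(evals, 1e-6)
        R = evecs @ np.diag(evals) @ evecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        evals, evecs = np.linalg.eigh(R)
    L = evecs @ np.diag(np.sqrt(np.maximum(evals, 0.0)))
    rng = np.random.default_rng(seed)
    base = make_chain(n_atoms, "extended").ca_coords()
    disp = np.empty((n_frames, n_atoms, 3))
    for axis in range(3):
        disp[:, :, axis] = rng.standard_normal((n_frames, n_atoms)) @ L.T * sigma
    structure = _ca_structure(base, label="planted-covariance")
    ens = Ensemble(structure, base[None, :, :] + disp, provenance="NMA")
    return ens, R


# ---------------------------------------------------------------------------
# Planted-contact trajectories
# ---------------------------------------------------------------------------

_ASP_ATOMS = {
    "N": (-2.8, 1.2, 0.0), "CA": (-2.4, 0.0, 0.0), "C": (-3.2, -1.2, 0.0),
    "O": (-4.3, -1.2, 0.0), "CB": (-1.2, 0.0, 0.8), "CG": (-0.6, 0.0, 0.2),
    "OD1": (0.0, 0.0, 0.0), "OD2": (-0.8, 1.1, -0.4),
}
_ARG_ATOMS = {
    "N": (2.8, 1.2, 0.0), "CA": (2.4, 0.0, 0.0), "C": (3.2, -1.2, 0.0),
    "O": (4.3, -1.2, 0.0), "CB": (1.6, 0.0, 0.8), "CG": (1.2, 0.4, 0.4),
    "CD": (0.9, 0.2, 0.3), "NE": (0.6, 0.0, 0.2), "CZ": (0.4, 0.5, 0.1),
    "NH1": (0.0, 0.0, 0.0), "NH2": (0.3, 1.1, -0.2),
}
_LEU_ATOMS = {
    "N": (-2.8, 1.2, 0.0), "CA": (-2.4, 0.0, 0.0), "C": (-3.2, -1.2, 0.0),
    "O": (-4.3, -1.2, 0.0), "CB": (-1.2, 0.0, 0.6), "CG": (-0.6, 0.2, 0.3),
    "CD1": (0.0, 0.0, 0.0), "CD2": (-0.7, 1.2, -0.3),
}
_ILE_ATOMS = {
    "N": (2.8, 1.2, 0.0), "CA": (2.4, 0.0, 0.0), "C": (3.2, -1.2, 0.0),
    "O": (4.3, -1.2, 0.0), "CB": (1.4, 0.0, 0.5), "CG1": (0.7, 0.2, 0.2),
    "CG2": (1.6, 1.1, -0.3), "CD1": (0.0, 0.0, 0.0),
}


def _residue_from_table(name: str, table: dict, chain: str, res_id: int,
                        shift: np.ndarray) -> Residue:
    names = list(table)
    coords = np.array([table[a] for a in names]) + shift
    elements = [a[:1] for a in names]
    return Residue(chain, res_id, "", name, names, elements, coords)


def make_planted_contact_trajectory(
    contact_fraction: float,
    n_frames: int = 1000,
    seed: int = 0,
    kind: str = "salt-bridge",
    contact_distance: float = 4.0,
    apart_distance: float = 8.0,
) -> tuple[Ensemble, dict]:
    """Two-residue trajectory with a contact in an exact fraction of frames.

    The closest inter-group atoms (Asp OD1 / Arg NH1 for salt bridges,
    Leu CD1 / Ile CD1 for hydrophobic) sit at ``contact_distance`` in
    round(f·n) frames and at ``apart_distance`` otherwise. Ground truth
    (the contact frame mask) is returned alongside.
    """
    if not (0.0 <= contact_fraction <= 1.0):
        raise ValueError("contact fraction must lie in [0, 1]")
    if kind == "salt-bridge":
        res_a = _residue_from_table("ASP", _ASP_ATOMS, "A", 1, np.zeros(3))
        res_b = _residue_from_table("ARG", _ARG_ATOMS, "B", 1,
                                    np.array([contact_distance, 0.0, 0.0]))
    elif kind == "hydrophobic":
        res_a = _residue_from_table("LEU", _LEU_ATOMS, "A", 1, np.zeros(3))
        res_b = _residue_from_table("ILE", _ILE_ATOMS, "B", 1,
                                    np.array([contact_distance, 0.0, 0.0]))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    structure = CAStructure([res_a, res_b], label="planted-contact")

    n_contact = round(contact_fraction * n_frames)
    rng = np.random.default_rng(seed)
    mask = np.zeros(n_frames, dtype=bool)
    mask[rng.permutation(n_frames)[:n_contact]] = True

    base = structure.flat_coords()
    b_atoms = structure.residue_atom_indices(1)
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    shift = apart_distance - contact_distance
    far = np.where(~mask)[0]
    frames[far[:, None], b_atoms[None, :], 0] += shift
    ens = Ensemble(structure, frames, frame_spacing=1.0, provenance="external")
    truth = {"fraction": n_contact / n_frames, "contact_mask": mask}
    return ens, truth


# ---------------------------------------------------------------------------
# Two-population loop trajectories
# ---------------------------------------------------------------------------

STATE_BANDS = {  # Å; gaps around the 6 Å / 10 Å class boundaries
    "closed": (3.0, 5.5),
    "semi-open": (6.5, 9.5),
    "open": (10.5, 15.0),
}


def make_two_state_loop_trajectory(
    fractions: tuple[float, float, float] = (0.65, 0.09, 0.26),
    n_frames: int = 10_000,
    seed: int = 0,
    n_residues: int = 30,
    cys_residue: int = 5,
    loop_range: tuple[int, int] = (10, 22),
) -> tuple[Ensemble, dict]:
    """Loop trajectory with planted closed/semi-open/open populations.

    Per frame the loop Cα block is rigidly placed so that the loop
    centre-of-mass sits at a sampled distance from the Cys Cα, drawn
    uniformly inside the state's band. Exact per-state frame counts are
    round(p·n); truth labels are returned.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    chain = make_chain(n_residues, "extended")
    coords = chain.flat_coords().copy()
    res_names = [r.res_name for r in chain.residues]
    res_names[cys_residue - 1] = "CYS"
    structure = _ca_structure(coords, res_names, label="two-state-loop")

    n_closed = round(fractions[0] * n_frames)
    n_semi = round(fractions[1] * n_frames)
    n_open = n_frames - n_closed - n_semi
    labels = (["closed"] * n_closed + ["semi-open"] * n_semi + ["open"] * n_open)
    order = rng.permutation(n_frames)
    labels = [labels[i] for i in order]

    cys_idx = structure.residue_index(cys_residue)
    cys_ca = coords[structure.flat_atom_index(cys_idx, "CA")]
    loop_idx = structure.range_indices(*loop_range)
    loop_atoms = np.array([structure.flat_atom_index(i, "CA") for i in loop_idx])
    loop_base = coords[loop_atoms]
    loop_centered = loop_base - loop_base.mean(axis=0)
    direction = np.array([0.0, 0.0, 1.0])

    frames = np.repeat(coords[None, :, :], n_frames, axis=0)
    distances = np.empty(n_frames)
    for f, lab in enumerate(labels):
        lo, hi = STATE_BANDS[lab]
        d = rng.uniform(lo, hi)
        distances[f] = d
        frames[f, loop_atoms, :] = loop_centered + cys_ca + d * direction
    ens = Ensemble(structure, frames, frame_spacing=1.0, provenance="external")
    truth = {
        "labels": labels,
        "fractions": {
            "closed": n_closed / n_frames,
            "semi-open": n_semi / n_frames,
            "open": n_open / n_frames,
        },
        "distances": distances,
        "cys_residue": cys_residue,
        "loop_range": loop_range,
    }
    return ens, truth


# ---------------------------------------------------------------------------
# Toy alignments
# ---------------------------------------------------------------------------

CLASS_MEMBERS = {"h": "AVLIMFWCY", "u": "AGS", "n": "DE"}


def make_toy_alignment(n_seqs: int, column_design: list[tuple], seed: int = 0
                       ) -> AlignmentBlock:
    """Alignment with designed per-column composition.

    Column specs: ("literal", "I") — invariant column;
    ("class", "n", 0.75) — the class members fill an exact 75 % of rows,
    the rest drawn outside the class; ("freq", {"D": 0.8, "E": 0.2}) —
    exact largest-remainder counts; ("random",) — uniform residues.
    """
    rng = np.random.default_rng(seed)
    columns = []
    for spec in column_design:
        kind = spec[0]
        if kind == "literal":
            col = [spec[1]] * n_seqs
        elif kind == "class":
            members, frac = CLASS_MEMBERS[spec[1]], spec[2]
            n_in = round(frac * n_seqs)
            outside = [a for a in AMINO_ACIDS if a not in members]
            col = [members[i % len(members)] for i in range(n_in)]
            col += [outside[int(x)] for x in
                    rng.integers(0, len(outside), n_seqs - n_in)]
        elif kind == "freq":
            freqs = spec[1]
            counts = _largest_remainder(freqs, n_seqs)
            col = [a for a, c in counts.items() for _ in range(c)]
        elif kind == "random":
            col = [AMINO_ACIDS[int(x)] for x in
                   rng.integers(0, len(AMINO_ACIDS), n_seqs)]
        else:
            raise ValueError(f"unknown column spec {spec!r}")
        columns.append([col[i] for i in rng.permutation(n_seqs)])
    seqs = ["".join(columns[j][i] for j in range(len(columns)))
            for i in range(n_seqs)]
    return AlignmentBlock(ids=[f"seq{i}" for i in range(n_seqs)], sequences=seqs)


def _largest_remainder(freqs: dict[str, float], n: int) -> dict[str, int]:
    raw = {a: f * n for a, f in freqs.items()}
    base = {a: int(math.floor(x)) for a, x in raw.items()}
    short = n - sum(base.values())
    order = sorted(raw, key=lambda a: raw[a] - base[a], reverse=True)
    for a in order[:short]:
        base[a] += 1
    return base
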