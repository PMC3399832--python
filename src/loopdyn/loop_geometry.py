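"""Omega-loop and catalytic-cleft conformational classification.

The catalytic cleft of family-3 E2 enzymes opens and closes as the acidic
L7 loop swings over the catalytic cysteine. Two independent classifiers
label every frame:

* distance — |CoM(Cys) − CoM(loop)|: closed < 0.6 nm, semi-open 0.6–1.0 nm,
  open > 1.0 nm (boundaries go to semi-open);
* accessibility — relative side-chain solvent accessibility of the Cys:
  closed < 20 %, semi-open 20–35 %, open > 35 % (all-atom frames only).

The omega-loop test follows the classical geometric criteria: hinge Cα
distance in 3.7–10 Å and below 2/3 of the largest Cα–Cα span across the
segment, ~6–16 residues, no regular secondary structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import BACKBONE_ATOMS, CAStructure, Ensemble


# ---------------------------------------------------------------------------
# Shrake–Rupley solvent-accessible surface area
# ---------------------------------------------------------------------------

VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
}
DEFAULT_VDW = 1.70
PROBE_RADIUS = 1.4


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ], axis=1)


def shrake_rupley_sasa(structure: CAStructure, probe: float = PROBE_RADIUS,
                       n_points: int = 960) -> dict:
    """Shrake–Rupley solvent-accessible surface area.

    Returns per-atom and per-residue SASA in Å². Requires an all-atom (or
    at least multi-atom) structure; for Cα-only input use the distance
    classifier instead.
    """
    if structure.is_calpha_only:
        raise ValueError(
            "SASA needs an all-atom structure; use the distance classifier "
            "for CA-only ensembles"
        )
    coords = structure.flat_coords()
    elements = [e for res in structure.residues for e in res.elements]
    radii = np.array([VDW_RADII.get(e.upper()[:1] if e else "C", DEFAULT_VDW)
                      for e in elements]) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    per_atom = np.zeros(len(coords))
    rmax = radii.max()
    for a in range(len(coords)):
        pts = coords[a] + radii[a] * unit
        neighbors = [b for b in tree.query_ball_point(coords[a], radii[a] + rmax)
                     if b != a]
        if neighbors:
            nb = np.array(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[a] = 4.0 * np.pi * radii[a] ** 2 * frac
    per_residue = np.array([
        per_atom[structure.residue_atom_indices(i)].sum()
        for i in range(structure.n_residues)
    ])
    return {"atom": per_atom, "residue": per_residue}


def _sidechain_mask(structure: CAStructure, res_index: int) -> np.ndarray:
    res = structure.residues[res_index]
    return np.array([
        structure.flat_atom_index(res_index, name)
        for name in res.atom_names
        if name not in BACKBONE_ATOMS and not name.startswith("H")
    ], dtype=int)


def relative_sidechain_accessibility(structure: CAStructure, res_index: int,
                                     probe: float = PROBE_RADIUS,
                                     n_points: int = 960) -> float:
    """Side-chain SASA relative to a Gly-X-Gly reference context.

    The reference is the residue's own atoms plus the backbone of the two
    flanking residues (neighbours reduced to glycine), carved from the same
    coordinates and scored with the identical algorithm, so numerator and
    denominator share every numerical convention.
    """
    side = _sidechain_mask(structure, res_index)
    if len(side) == 0:
        raise ValueError("residue has no side-chain atoms")
    sasa = shrake_rupley_sasa(structure, probe, n_points)
    observed = sasa["atom"][side].sum()

    from .structure_io import Residue
    ref_res: list[Residue] = []
    for i in (res_index - 1, res_index, res_index + 1):
        if i < 0 or i >= structure.n_residues:
            continue
        res = structure.residues[i]
        if i == res_index:
            keep = list(range(len(res.atom_names)))
        else:
            keep = [k for k, nm in enumerate(res.atom_names) if nm in BACKBONE_ATOMS]
            if not keep:
                continue
        ref_res.append(Residue(
            res.chain_id, res.res_id, res.ins_code,
            res.res_name if i == res_index else "GLY",
            [res.atom_names[k] for k in keep],
            [res.elements[k] for k in keep],
            res.coords[keep].copy(),
        ))
    ref = CAStructure(ref_res, label="gxg-reference")
    ref_idx = next(k for k, r in enumerate(ref.residues)
                   if r.key == structure.residues[res_index].key)
    ref_side = _sidechain_mask(ref, ref_idx)
    ref_sasa = shrake_rupley_sasa(ref, probe, n_points)["atom"][ref_side].sum()
    if ref_sasa <= 0:
        raise ValueError("degenerate reference SASA")
    return float(observed / ref_sasa)


# ---------------------------------------------------------------------------
# Conformational-state classification
# ---------------------------------------------------------------------------

@dataclass
class StateThresholds:
    """Cutoffs in Å (distances) and fractions (accessibility)."""

    closed_distance: float = 6.0       # < closed (0.6 nm)
    open_distance: float = 10.0        # > open (1.0 nm)
    closed_access: float = 0.20
    open_access: float = 0.35
    deep_buried_access: float = 0.10   # reported sub-fraction of closed

    def __post_init__(self) -> None:
        if not (0 < self.closed_distance < self.open_distance):
            raise ValueError("distance cutoffs must be strictly ordered")
        if not (0 < self.closed_access < self.open_access):
            raise ValueError("accessibility cutoffs must be strictly ordered")


STATES = ("closed", "semi-open", "open")


def _label(value: float, lo: float, hi: float) -> str:
    # strict inequalities for closed/open; boundary values are semi-open
    if value < lo:
        return "closed"
    if value > hi:
        return "open"
    return "semi-open"


@dataclass
class StatePopulations:
    distance_labels: list[str]
    distance_fractions: dict[str, float]
    distances: np.ndarray
    accessibility_labels: list[str] | None = None
    accessibility_fractions: dict[str, float] | None = None
    accessibilities: np.ndarray | None = None
    agreement: float | None = None
    deep_buried_fraction: float | None = None


def _fractions(labels: list[str]) -> dict[str, float]:
    n = len(labels)
    return {s: labels.count(s) / n for s in STATES}


def classify_states(ensemble: Ensemble, cys_residue: int,
                    loop_range: tuple[int, int],
                    thresholds: StateThresholds | None = None,
                    chain_id: str | None = None,
                    sasa_points: int = 240) -> StatePopulations:
    """Label every frame closed / semi-open / open.

    ``cys_residue`` and ``loop_range`` are PDB residue numbers. The distance
    classifier always runs (CoM of the Cys side chain, or its Cα when only
    Cα is present, versus the CoM of the loop Cα atoms). The accessibility
    classifier runs only on all-atom ensembles.
    """
    thresholds = thresholds or StateThresholds()
    structure = ensemble.structure
    loop_idx = structure.range_indices(loop_range[0], loop_range[1], chain_id)
    if not loop_idx:
        raise ValueError("empty loop range")
    cys_idx = structure.residue_index(cys_residue, chain_id)

    cys_atoms = _sidechain_mask(structure, cys_idx)
    if len(cys_atoms) == 0:
        cys_atoms = np.array([structure.flat_atom_index(cys_idx, "CA")])
    loop_atoms = np.array([structure.flat_atom_index(i, "CA") for i in loop_idx])

    cys_com = ensemble.frames[:, cys_atoms, :].mean(axis=1)
    loop_com = ensemble.frames[:, loop_atoms, :].mean(axis=1)
    distances = np.linalg.norm(cys_com - loop_com, axis=1)
    d_labels = [_label(d, thresholds.closed_distance, thresholds.open_distance)
                for d in distances]

    a_labels = None
    accessibilities = None
    agreement = None
    deep = None
    all_atom = not structure.is_calpha_only and len(_sidechain_mask(structure, cys_idx))
    if all_atom:
        acc = []
        for f in range(ensemble.n_frames):
            frame = ensemble.frame_structure(f)
            acc.append(relative_sidechain_accessibility(
                frame, cys_idx, n_points=sasa_points))
        accessibilities = np.array(acc)
        a_labels = [_label(a, thresholds.closed_access, thresholds.open_access)
                    for a in accessibilities]
        agreement = float(np.mean([x == y for x, y in zip(d_labels, a_labels)]))
        deep = float(np.mean(accessibilities < thresholds.deep_buried_access))
    return StatePopulations(
        distance_labels=d_labels,
        distance_fractions=_fractions(d_labels),
        distances=distances,
        accessibility_labels=a_labels,
        accessibility_fractions=_fractions(a_labels) if a_labels else None,
        accessibilities=accessibilities,
        agreement=agreement,
        deep_buried_fraction=deep,
    )


# ---------------------------------------------------------------------------
# Simplified secondary structure
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def _phi_psi(structure: CAStructure) -> list[tuple[float, float]]:
    out = []
    res = structure.residues
    for i in range(len(res)):
        try:
            n_i = res[i].coords[res[i].atom_index("N")]
            ca_i = res[i].coords[res[i].atom_index("CA")]
            c_i = res[i].coords[res[i].atom_index("C")]
        except ValueError:
            out.append((np.nan, np.nan))
            continue
        phi = psi = np.nan
        if i > 0 and "C" in res[i - 1].atom_names:
            c_prev = res[i - 1].coords[res[i - 1].atom_index("C")]
            phi = _dihedral(c_prev, n_i, ca_i, c_i)
        if i < len(res) - 1 and "N" in res[i + 1].atom_names:
            n_next = res[i + 1].coords[res[i + 1].atom_index("N")]
            psi = _dihedral(n_i, ca_i, c_i, n_next)
        out.append((phi, psi))
    return out


def _basin(phi: float, psi: float) -> str:
    # chain termini miss one dihedral; classify on the one available
    if np.isnan(phi) and np.isnan(psi):
        return "c"
    phi_ok = np.isnan(phi) or (-100 <= phi <= -30)
    if phi_ok and not np.isnan(psi):
        if -80 <= psi <= -35:
            return "a"          # alpha
        if -35 < psi <= -5:
            return "g"          # 3-10
    if np.isnan(psi) and -100 <= phi <= -30:
        return "a"
    beta_phi = np.isnan(phi) or (-170 <= phi <= -70)
    beta_psi = np.isnan(psi) or (psi >= 90 or psi <= -150)
    if beta_phi and beta_psi and not (np.isnan(phi) and np.isnan(psi)):
        # require at least the defined angle to sit in the beta region
        if (not np.isnan(phi) and -170 <= phi <= -70) or \
           (not np.isnan(psi) and (psi >= 90 or psi <= -150)):
            return "b"
    return "c"


def _ca_basin(tau: float, d13: float) -> str:
    """Cα-only surrogate basins from the pseudo-dihedral τ(i−1..i+2) and
    the i−1 → i+1 distance (helix ~ +50°/5.4 Å; strand ~ ±180°/6.6 Å).
    The distance guard keeps tightly curved loop traces out of the strand
    basin even when they are locally planar (|τ| ≈ 180°)."""
    if np.isnan(tau):
        return "c"
    if 35 <= tau <= 80 and d13 <= 6.0:
        return "a"
    if abs(tau) >= 140 and d13 >= 6.0:
        return "b"
    return "c"


def simple_secondary_structure(structure: CAStructure) -> list[str]:
    """Per-residue label H | E | G | T | C.

    Uses φ/ψ basins when backbone N/CA/C atoms are present: runs of ≥4
    alpha-basin residues → H, ≥3 of the 3₁₀ basin → G, ≥3 beta → E;
    shorter basin runs are turns (T), the rest coil (C). Cα-only input
    falls back to pseudo-dihedral basins (helix vs extended only).
    """
    backbone = all(
        {"N", "CA", "C"} <= set(res.atom_names) for res in structure.residues
    )
    n = structure.n_residues
    if backbone and n >= 2:
        basins = [_basin(phi, psi) for phi, psi in _phi_psi(structure)]
    else:
        ca = structure.ca_coords()
        basins = []
        for i in range(n):
            if 1 <= i <= n - 3:
                tau = _dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
                d13 = float(np.linalg.norm(ca[i + 1] - ca[i - 1]))
            else:
                tau, d13 = np.nan, 0.0
            basins.append(_ca_basin(tau, d13))
    labels = ["C"] * n
    i = 0
    while i < n:
        j = i
        while j < n and basins[j] == basins[i]:
            j += 1
        run, kind = j - i, basins[i]
        if kind == "a":
            mark = "H" if run >= 4 else ("G" if run == 3 else "T")
        elif kind == "g":
            mark = "G" if run >= 3 else "T"
        elif kind == "b":
            mark = "E" if run >= 3 else "T"
        else:
            mark = "C"
        for k in range(i, j):
            labels[k] = mark
        i = j
    return labels


# ---------------------------------------------------------------------------
# Omega-loop classification
# ---------------------------------------------------------------------------

@dataclass
class OmegaCriteria:
    hinge_distance_range: tuple[float, float] = (3.7, 10.0)  # Å
    span_ratio: float = 2.0 / 3.0
    length_bounds: tuple[int, int] = (6, 16)

    def __post_init__(self) -> None:
        lo, hi = self.hinge_distance_range
        if not lo < hi:
            raise ValueError("hinge distance range lower bound must be < upper")
        if not (0 < self.span_ratio < 1):
            raise ValueError("span ratio must lie in (0, 1)")


@dataclass
class OmegaReport:
    hinge_pair: tuple[int, int]              # PDB residue numbers
    hinge_distances: np.ndarray              # per frame, Å
    max_span: np.ndarray                     # per frame, Å
    fraction_distance_ok: float
    fraction_ratio_ok: float
    criterion_distance: bool                 # median frame
    criterion_ratio: bool
    criterion_length: bool
    criterion_secondary: bool
    secondary_summary: str
    verdict: bool
    all_pairs: dict = field(default_factory=dict)


def classify_omega_loop(ensemble_or_structure, loop_range: tuple[int, int],
                        hinge_candidates: list[tuple[int, int]] | None = None,
                        criteria: OmegaCriteria | None = None,
                        chain_id: str | None = None) -> OmegaReport:
    """Decide whether a loop classifies as an omega loop.

    ``loop_range`` and hinge pairs are PDB residue numbers; hinge pairs
    default to (loop start, loop end). The verdict uses the median frame;
    per-frame pass fractions are reported alongside. The best hinge pair is
    the one satisfying the distance criterion in the largest fraction of
    frames.
    """
    criteria = criteria or OmegaCriteria()
    if isinstance(ensemble_or_structure, Ensemble):
        ensemble = ensemble_or_structure
    else:
        st = ensemble_or_structure
        ensemble = Ensemble(st, st.flat_coords()[None, :, :], provenance="external")
    structure = ensemble.structure
    lo, hi = loop_range
    if hinge_candidates is None:
        hinge_candidates = [(lo, hi)]
    if not hinge_candidates:
        raise ValueError("no hinge candidate pair")

    loop_idx = structure.range_indices(lo, hi, chain_id)
    ca = ensemble.ca_frames()
    loop_ca = ca[:, loop_idx, :]
    # largest pairwise Cα-Cα span across the segment, per frame
    diff = loop_ca[:, :, None, :] - loop_ca[:, None, :, :]
    span = np.sqrt((diff**2).sum(axis=3)).max(axis=(1, 2))

    seg_len = len(loop_idx)
    d_lo, d_hi = criteria.hinge_distance_range

    results = {}
    for (a, b) in hinge_candidates:
        ia = structure.residue_index(a, chain_id)
        ib = structure.residue_index(b, chain_id)
        dist = np.linalg.norm(ca[:, ia, :] - ca[:, ib, :], axis=1)
        frac_dist = float(np.mean((dist >= d_lo) & (dist <= d_hi)))
        frac_ratio = float(np.mean(dist < criteria.span_ratio * span))
        results[(a, b)] = (dist, frac_dist, frac_ratio)
    best = max(results, key=lambda p: results[p][1])
    dist, frac_dist, frac_ratio = results[best]

    med = int(np.argsort(dist)[len(dist) // 2])
    crit_dist = bool(d_lo <= dist[med] <= d_hi)
    crit_ratio = bool(dist[med] < criteria.span_ratio * span[med])
    crit_len = bool(criteria.length_bounds[0] <= seg_len <= criteria.length_bounds[1])
    ss = simple_secondary_structure(ensemble.frame_structure(med))
    loop_ss = "".join(ss[i] for i in loop_idx)
    crit_ss = not any(c in ("H", "E") for c in loop_ss)

    return OmegaReport(
        hinge_pair=best,
        hinge_distances=dist,
        max_span=span,
        fraction_distance_ok=frac_dist,
        fraction_ratio_ok=frac_ratio,
        criterion_distance=crit_dist,
        criterion_ratio=crit_ratio,
        criterion_length=crit_len,
        criterion_secondary=crit_ss,
        secondary_summary=loop_ss,
        verdict=crit_dist and crit_ratio and crit_len and crit_ss,
        all_pairs={p: {"fraction_distance_ok": r[1], "fraction_ratio_ok": r[2]}
                   for p, r in results.items()},
    )
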