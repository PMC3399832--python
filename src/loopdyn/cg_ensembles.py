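"""Coarse-grained conformational sampling of Cα elastic networks.

Three samplers share one network construction:

* ANM normal modes — diagonalization of the 3N×3N Hessian of the harmonic
  network with distance-dependent Kovacs force constants
  K(r0) = C (r*/r0)^6, C = 40 kcal mol^-1 Å^-2, r* = 3.8 Å.
* Brownian (Langevin) dynamics — BAOAB splitting with friction
  0.4 ps^-1, 1 fs step, bead mass 100 Da, on the same harmonic potential.
* Discrete molecular dynamics — event-driven ballistic motion inside
  infinite square wells of half-width σ around r0 (σ = 0.1, consecutive
  pairs 0.05), pairs defined inside an 8 Å native cutoff.

All three emit an :class:`~loopdyn.structure_io.Ensemble` so downstream
analyses consume them interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import CAStructure, Ensemble
from .units import kbt_dyn, kbt_kcal, KCAL_TO_DA_A2_PS2


@dataclass
class CGParameters:
    stiffness: float = 40.0        # C, kcal mol^-1 Å^-2
    reference_distance: float = 3.8  # r*, Å
    mass: float = 100.0            # Da per bead
    temperature: float = 300.0     # K

    def __post_init__(self) -> None:
        if self.stiffness <= 0 or self.reference_distance <= 0 or self.mass <= 0:
            raise ValueError("CG parameters must be positive")


@dataclass
class BDParameters:
    friction: float = 0.4          # ps^-1
    time_step: float = 1.0         # fs
    n_steps: int = 5_000_000
    snapshot_stride: int = 1000    # steps between stored frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.friction <= 0:
            raise ValueError("friction must be > 0")
        if self.n_steps < 1:
            raise ValueError("step count must be >= 1")


@dataclass
class DMDParameters:
    sigma: float = 0.1             # well half-width, fractional
    sigma_consecutive: float = 0.05
    cutoff: float = 8.0            # r_c, Å
    total_time: float = 100.0      # simulated time budget (ps-like units)
    max_events: int = 10_000_000
    frame_interval: float = 0.1    # time between stored frames
    temperature: float = 300.0     # K, velocity initialization
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sigma < 1) or not (0 < self.sigma_consecutive < 1):
            raise ValueError("sigma must lie in (0, 1)")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class ElasticNetwork:
    """Pair list with equilibrium distances and force constants / wells."""

    coords: np.ndarray                 # (N, 3) equilibrium positions
    pairs: np.ndarray                  # (P, 2) int indices i < j
    r0: np.ndarray                     # (P,) equilibrium distances, Å
    k: np.ndarray                      # (P,) force constants, kcal/mol/Å^2
    sigma: np.ndarray | None = None    # (P,) DMD well half-widths, or None
    method: str = "nma"

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def connectivity(self) -> np.ndarray:
        """Kirchhoff connectivity Γ: −1 for connected pairs, degree on diag."""
        n = self.n_nodes
        g = np.zeros((n, n))
        for (i, j) in self.pairs:
            g[i, j] = g[j, i] = -1.0
        np.fill_diagonal(g, -g.sum(axis=1))
        return g


@dataclass
class ModeSet:
    """ANM eigensystem; rigid-body modes discarded."""

    eigenvalues: np.ndarray      # non-rigid, ascending, kcal/mol/Å^2
    eigenvectors: np.ndarray     # (3N, n_modes), orthonormal columns
    n_rigid_discarded: int
    coords: np.ndarray           # equilibrium (N, 3)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def covariance(self, temperature: float = 300.0) -> np.ndarray:
        """Thermal covariance k_B T H^+ in Å^2 (pseudo-inverse over modes)."""
        kt = kbt_kcal(temperature)
        V = self.eigenvectors
        return kt * (V / self.eigenvalues) @ V.T


def kovacs_force_constant(r0: float | np.ndarray,
                          params: CGParameters | None = None) -> float | np.ndarray:
    """Distance-dependent stiffness K(r0) = C (r*/r0)^6."""
    params = params or CGParameters()
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 <= 0):
        raise ValueError("r0 must be > 0")
    out = params.stiffness * (params.reference_distance / r0) ** 6
    return float(out) if out.ndim == 0 else out


def build_network(structure: CAStructure, params: CGParameters | None = None,
                  method: str = "nma",
                  dmd_params: DMDParameters | None = None) -> ElasticNetwork:
    """Build the elastic network for a sampling method.

    NMA/BD: every pair carries the continuous Kovacs constant (no cutoff).
    DMD: only native pairs with r0 < r_c carry square wells; consecutive
    residues get the narrow well (σ = 0.05).
    """
    if method not in ("nma", "bd", "dmd"):
        raise ValueError(f"unknown method {method!r}")
    params = params or CGParameters()
    coords = structure.ca_coords()
    n = len(coords)
    if n < 3:
        raise ValueError("need at least 3 residues")
    ii, jj = np.triu_indices(n, k=1)
    d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    if np.any(d <= 0):
        raise ValueError("coincident CA positions")
    if method == "dmd":
        dmd = dmd_params or DMDParameters()
        keep = d < dmd.cutoff
        ii, jj, d = ii[keep], jj[keep], d[keep]
        sig = np.where(jj - ii == 1, dmd.sigma_consecutive, dmd.sigma)
        k = kovacs_force_constant(d, params)
        return ElasticNetwork(coords, np.stack([ii, jj], axis=1), d, np.asarray(k),
                              sigma=sig, method="dmd")
    k = kovacs_force_constant(d, params)
    return ElasticNetwork(coords, np.stack([ii, jj], axis=1), d, np.asarray(k),
                          sigma=None, method=method)


# ---------------------------------------------------------------------------
# ANM
# ---------------------------------------------------------------------------

def anm_hessian(network: ElasticNetwork) -> np.ndarray:
    """Analytic 3N×3N Hessian of V = 1/2 Σ k_ij (|r_ij| − r0_ij)^2 at r = r0."""
    n = network.n_nodes
    H = np.zeros((3 * n, 3 * n))
    for (i, j), r0, k in zip(network.pairs, network.r0, network.k):
        d = network.coords[j] - network.coords[i]
        block = -(k / r0**2) * np.outer(d, d)
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return H


def anm_modes(network: ElasticNetwork, rigid_tol: float = 1e-8) -> ModeSet:
    """Diagonalize the ANM Hessian; flag the six rigid-body modes."""
    H = anm_hessian(network)
    evals, evecs = np.linalg.eigh(H)
    tol = rigid_tol * evals[-1]
    n_rigid = int(np.sum(evals < tol))
    if n_rigid > 6:
        raise ValueError(
            f"disconnected network: {n_rigid} near-zero eigenvalues (expected 6)"
        )
    return ModeSet(
        eigenvalues=evals[n_rigid:],
        eigenvectors=evecs[:, n_rigid:],
        n_rigid_discarded=n_rigid,
        coords=network.coords,
    )


def nma_ensemble(modes: ModeSet, params: CGParameters | None = None,
                 n_frames: int = 1000, seed: int = 0,
                 structure: CAStructure | None = None) -> Ensemble:
    """Sample frames with per-mode Gaussian amplitudes of variance k_B T / λ.

    The sampled covariance converges to the thermal covariance k_B T H^+.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    params = params or CGParameters()
    rng = np.random.default_rng(seed)
    kt = kbt_kcal(params.temperature)
    std = np.sqrt(kt / modes.eigenvalues)           # (M,) Å
    xi = rng.standard_normal((n_frames, modes.n_modes))
    disp = (xi * std) @ modes.eigenvectors.T        # (F, 3N)
    frames = modes.coords[None, :, :] + disp.reshape(n_frames, -1, 3)
    if structure is None:
        structure = _ca_only_structure(modes.coords)
    return Ensemble(structure, frames, frame_spacing=None, provenance="NMA")


def _ca_only_structure(coords: np.ndarray) -> CAStructure:
    from .structure_io import Residue

    residues = [
        Residue("A", i + 1, "", "GLY", ["CA"], ["C"], np.array([xyz]))
        for i, xyz in enumerate(coords)
    ]
    return CAStructure(residues, label="cg-network")


# ---------------------------------------------------------------------------
# Brownian / Langevin dynamics
# ---------------------------------------------------------------------------

def _harmonic_forces(coords: np.ndarray, network: ElasticNetwork) -> np.ndarray:
    """Forces in kcal mol^-1 Å^-1 of the Kovacs harmonic network."""
    f = np.zeros_like(coords)
    if len(network.pairs) == 0:
        return f
    i, j = network.pairs[:, 0], network.pairs[:, 1]
    d = coords[j] - coords[i]
    r = np.linalg.norm(d, axis=1)
    with np.errstate(invalid="ignore", over="ignore"):
        # divergence is caught by the integrator's stability check
        mag = network.k * (r - network.r0) / r   # pull toward r0
    fij = mag[:, None] * d
    np.add.at(f, i, fij)
    np.add.at(f, j, -fij)
    return f


def bd_simulate(network: ElasticNetwork, params: BDParameters | None = None,
                cg: CGParameters | None = None,
                structure: CAStructure | None = None) -> Ensemble:
    """Langevin dynamics on the harmonic network (BAOAB splitting).

    Snapshots are taken every ``snapshot_stride`` steps; frame spacing is
    stride × dt. Raises if coordinates diverge (unstable dt).
    """
    params = params or BDParameters()
    cg = cg or CGParameters()
    rng = np.random.default_rng(params.seed)
    dt = params.time_step * 1e-3  # fs -> ps
    m = cg.mass
    kt = kbt_dyn(cg.temperature)  # Da Å^2 ps^-2
    c1 = np.exp(-params.friction * dt)
    c2 = np.sqrt((1.0 - c1**2) * kt / m)

    x = network.coords.copy()
    v = rng.standard_normal(x.shape) * np.sqrt(kt / m)
    f = _harmonic_forces(x, network) * KCAL_TO_DA_A2_PS2  # Da Å ps^-2

    span = max(np.ptp(network.coords), 1.0)
    frames = []
    for step in range(1, params.n_steps + 1):
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(v.shape)
        x += 0.5 * dt * v
        f = _harmonic_forces(x, network) * KCAL_TO_DA_A2_PS2
        v += 0.5 * dt * f / m
        if step % params.snapshot_stride == 0:
            if not np.all(np.isfinite(x)) or np.ptp(x) > 100 * span:
                raise RuntimeError(
                    f"unstable BD integration at step {step}: "
                    f"coordinates diverged (dt = {params.time_step} fs)"
                )
            frames.append(x.copy())
    if structure is None:
        structure = _ca_only_structure(network.coords)
    return Ensemble(structure, np.array(frames),
                    frame_spacing=dt * params.snapshot_stride, provenance="BD")


# ---------------------------------------------------------------------------
# Discrete molecular dynamics
# ---------------------------------------------------------------------------

def _pair_event_time(r: np.ndarray, w: np.ndarray, r_in: float,
                     r_out: float) -> tuple[float, int]:
    """Earliest positive wall-crossing time for one pair.

    Returns (t, wall) with wall = +1 outer, −1 inner; t = inf if none.
    Solves |r + w t| = wall radius (ballistic closed form).
    """
    a = float(w @ w)
    if a == 0.0:
        return np.inf, 0
    b = 2.0 * float(r @ w)
    c_out = float(r @ r) - r_out**2
    best_t, best_wall = np.inf, 0
    disc = b * b - 4.0 * a * c_out
    if disc >= 0.0:
        # outward crossing is the larger root (distance increasing there)
        t = (-b + np.sqrt(disc)) / (2.0 * a)
        if t > 0.0:
            best_t, best_wall = t, +1
    c_in = float(r @ r) - r_in**2
    if r_in > 0.0 and b < 0.0:
        disc = b * b - 4.0 * a * c_in
        if disc > 0.0:
            t = (-b - np.sqrt(disc)) / (2.0 * a)
            if 0.0 < t < best_t:
                best_t, best_wall = t, -1
    return best_t, best_wall


def dmd_simulate(network: ElasticNetwork, params: DMDParameters | None = None,
                 cg: CGParameters | None = None,
                 structure: CAStructure | None = None,
                 return_diagnostics: bool = False,
                 velocities: np.ndarray | None = None):
    """Event-driven square-well dynamics.

    Particles move ballistically; at each wall crossing the radial component
    of the relative velocity is elastically reflected, conserving total
    momentum and kinetic energy exactly. Pair distances stay within
    [(1−σ) r0, (1+σ) r0].
    """
    params = params or DMDParameters()
    cg = cg or CGParameters()
    if network.sigma is None:
        raise ValueError("network has no square wells; build with method='dmd'")
    rng = np.random.default_rng(params.seed)
    m = cg.mass
    kt = kbt_dyn(params.temperature)

    x = network.coords.copy()
    if velocities is not None:
        v = np.array(velocities, dtype=float)
    else:
        v = rng.standard_normal(x.shape) * np.sqrt(kt / m)
        v -= v.mean(axis=0)  # zero net momentum

    pairs = network.pairs
    r_in = (1.0 - network.sigma) * network.r0
    r_out = (1.0 + network.sigma) * network.r0

    t_now = 0.0
    next_frame = 0.0
    frames = []
    n_events = 0
    eps = 1e-12
    p_ref = m * v.sum(axis=0)
    ke_ref = 0.5 * m * (v**2).sum()
    momentum_drift = 0.0
    energy_drift = 0.0
    while t_now < params.total_time and n_events < params.max_events:
        # next event over all pairs
        best_t, best_p, best_wall = np.inf, -1, 0
        for p, (i, j) in enumerate(pairs):
            r = x[j] - x[i]
            w = v[j] - v[i]
            t, wall = _pair_event_time(r, w, r_in[p], r_out[p])
            if t < best_t:
                best_t, best_p, best_wall = t, p, wall
        if best_p < 0:
            raise RuntimeError("no future event found for an interacting system")
        t_event = t_now + best_t
        # store frames that fall before the event
        while next_frame <= min(t_event, params.total_time):
            frames.append(x + v * (next_frame - t_now))
            next_frame += params.frame_interval
        if t_event >= params.total_time:
            break
        # advance to just before the wall and reflect
        x = x + v * (best_t - eps)
        t_now = t_event - eps
        i, j = pairs[best_p]
        r = x[j] - x[i]
        nrm = r / np.linalg.norm(r)
        w_n = float((v[j] - v[i]) @ nrm)
        # reflect only if actually moving through the wall
        if (best_wall > 0 and w_n > 0) or (best_wall < 0 and w_n < 0):
            v[i] += w_n * nrm
            v[j] -= w_n * nrm
        n_events += 1
        momentum_drift = max(
            momentum_drift, float(np.abs(m * v.sum(axis=0) - p_ref).max())
        )
        energy_drift = max(
            energy_drift, abs(0.5 * m * (v**2).sum() - ke_ref)
        )

    if not frames:
        raise RuntimeError("no frames stored; increase total_time")
    if structure is None:
        structure = _ca_only_structure(network.coords)
    ensemble = Ensemble(structure, np.array(frames),
                        frame_spacing=params.frame_interval, provenance="DMD")
    if return_diagnostics:
        return ensemble, {
            "n_events": n_events,
            "momentum_drift": momentum_drift,
            "energy_drift": energy_drift,
            "kinetic_energy": ke_ref,
        }
    return ensemble


def dmd_wall_violation(ensemble: Ensemble, network: ElasticNetwork) -> float:
    """Max over frames/pairs of the distance outside the square wells (Å)."""
    ca = ensemble.ca_frames()
    i, j = network.pairs[:, 0], network.pairs[:, 1]
    d = np.linalg.norm(ca[:, j, :] - ca[:, i, :], axis=2)  # (F, P)
    r_in = (1.0 - network.sigma) * network.r0
    r_out = (1.0 + network.sigma) * network.r0
    over = np.maximum(d - r_out[None, :], 0.0)
    under = np.maximum(r_in[None, :] - d, 0.0)
    return float(max(over.max(), under.max()))
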