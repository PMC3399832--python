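"""Flexibility and correlation analysis of conformational ensembles.

Implements the per-residue RMSF/B-factor machinery (including PCA-filtered
trajectories), essential-dynamics diagnostics (cosine content, RMSIP),
windowed dynamical cross-correlation matrices (DCCM), breadth-first chained
correlation search from root residues, and B-factor slope-change hinge
prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Ensemble, superpose
from .cg_ensembles import CGParameters, ModeSet
from .units import B_FACTOR_PREFACTOR, kbt_kcal


# ---------------------------------------------------------------------------
# Superposition helpers
# ---------------------------------------------------------------------------

def superpose_frames(frames: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Least-squares fit every frame onto the running average, iterated."""
    fitted = np.array(frames, dtype=float)
    ref = fitted.mean(axis=0)
    for _ in range(iterations):
        for f in range(len(fitted)):
            fitted[f], _ = superpose(fitted[f], ref)
        ref = fitted.mean(axis=0)
    return fitted


# ---------------------------------------------------------------------------
# Flexibility profiles
# ---------------------------------------------------------------------------

@dataclass
class FlexibilityProfile:
    """Per-residue RMSF (Å) and B-factor (Å^2); B = (8π²/3) RMSF²."""

    rmsf: np.ndarray
    provenance: str = "ensemble"
    smoothing_window: int = 0

    @property
    def bfactor(self) -> np.ndarray:
        return B_FACTOR_PREFACTOR * self.rmsf**2

    def __len__(self) -> int:
        return len(self.rmsf)


def rmsf_profile(ensemble: Ensemble, fit: bool = True,
                 filter_fraction: float = 0.70) -> FlexibilityProfile:
    """RMSF on the PCA-filtered trajectory.

    The trajectory is projected onto the leading principal components that
    jointly explain at least ``filter_fraction`` of the variance before the
    fluctuations are measured; filter_fraction = 1 reproduces the raw RMSF.
    """
    if not (0.0 < filter_fraction <= 1.0):
        raise ValueError("filter_fraction must lie in (0, 1]")
    ca = ensemble.ca_frames()
    if len(ca) < 2:
        raise ValueError("need at least 2 frames")
    if fit:
        ca = superpose_frames(ca)
    n_frames, n_res, _ = ca.shape
    flat = ca.reshape(n_frames, -1)
    mean = flat.mean(axis=0)
    dev = flat - mean
    if filter_fraction < 1.0:
        cov = dev.T @ dev / (n_frames - 1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        frac = np.cumsum(evals) / evals.sum()
        n_keep = int(np.searchsorted(frac, filter_fraction) + 1)
        proj = dev @ evecs[:, :n_keep]
        dev = proj @ evecs[:, :n_keep].T
    msf = dev.reshape(n_frames, n_res, 3)
    msf = (msf**2).sum(axis=2).mean(axis=0)
    return FlexibilityProfile(np.sqrt(msf), provenance="ensemble")


def anm_bfactors(modes: ModeSet, cg: CGParameters | None = None) -> FlexibilityProfile:
    """Thermal fluctuations from normal modes: <Δr_i²> = kT Σ_m |v_m,i|²/λ_m."""
    cg = cg or CGParameters()
    if modes.n_modes == 0:
        raise ValueError("no non-rigid modes")
    kt = kbt_kcal(cg.temperature)
    V = modes.eigenvectors.reshape(-1, 3, modes.n_modes)  # (N, 3, M)
    msf = kt * ((V**2).sum(axis=1) / modes.eigenvalues).sum(axis=1)
    return FlexibilityProfile(np.sqrt(msf), provenance="modes")


def replica_consistency(profiles: list[FlexibilityProfile]) -> dict:
    """Pairwise Pearson r between replica RMSF profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    n = len(profiles[0])
    if any(len(p) != n for p in profiles):
        raise ValueError("profiles differ in length")
    k = len(profiles)
    r = np.full((k, k), np.nan)
    undefined = []
    for i in range(k):
        r[i, i] = 1.0
        for j in range(i + 1, k):
            a, b = profiles[i].rmsf, profiles[j].rmsf
            if a.std() == 0 or b.std() == 0:
                undefined.append((i, j))
                continue
            r[i, j] = r[j, i] = float(np.corrcoef(a, b)[0, 1])
    off = r[np.triu_indices(k, 1)]
    off = off[~np.isnan(off)]
    return {
        "matrix": r,
        "min": float(off.min()) if len(off) else np.nan,
        "mean": float(off.mean()) if len(off) else np.nan,
        "undefined_pairs": undefined,
    }


# ---------------------------------------------------------------------------
# PCA / essential dynamics
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending, Å^2
    eigenvectors: np.ndarray         # (3N, M) columns
    variance_fractions: np.ndarray   # cumulative
    cosine_content: np.ndarray       # first 3 projections
    rmsip_halves: float
    mean: np.ndarray                 # (3N,)
    projections: np.ndarray          # (F, M) for the leading modes


def cosine_content(projection: np.ndarray, order: int = 1) -> float:
    """Hess cosine content of a principal-component projection in [0, 1].

    A projection that is a pure half-period cosine of the given order has
    content 1; converged sampling gives values well below 1.
    """
    p = np.asarray(projection, dtype=float)
    T = len(p)
    t = np.arange(T)
    cos = np.cos(order * np.pi * (t + 0.5) / T)
    num = (p * cos).sum() ** 2
    den = (cos**2).sum() * (p**2).sum()
    if den == 0:
        return 0.0
    return float(num / den)


def rmsip(basis_a: np.ndarray, basis_b: np.ndarray, n_vec: int = 10) -> float:
    """Root mean square inner product of two eigenvector sets (columns)."""
    k = min(n_vec, basis_a.shape[1], basis_b.shape[1])
    A, B = basis_a[:, :k], basis_b[:, :k]
    return float(np.sqrt(((A.T @ B) ** 2).sum() / k))


def pca(ensemble: Ensemble, fit: bool = True) -> PCAResult:
    """Essential dynamics of the Cα trajectory with convergence diagnostics.

    Beads share one mass, so the mass-weighted covariance reduces to the
    plain positional covariance. Reports the cosine content of the first
    three projections and the RMSIP between ensemble halves (top 10 modes).
    """
    ca = ensemble.ca_frames()
    if len(ca) < 3:
        raise ValueError("need at least 3 frames for PCA")
    if fit:
        ca = superpose_frames(ca)
    flat = ca.reshape(len(ca), -1)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / (len(flat) - 1)
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = np.maximum(evals[::-1], 0.0), evecs[:, ::-1]
    total = evals.sum()
    cumfrac = np.cumsum(evals) / total if total > 0 else np.zeros_like(evals)
    proj = dev @ evecs
    cc = np.array([cosine_content(proj[:, i], order=i + 1)
                   for i in range(min(3, proj.shape[1]))])
    half = len(flat) // 2
    if half >= 2:
        def _basis(block: np.ndarray) -> np.ndarray:
            d = block - block.mean(axis=0)
            _, vecs = np.linalg.eigh(d.T @ d / max(len(block) - 1, 1))
            return vecs[:, ::-1]
        r = rmsip(_basis(flat[:half]), _basis(flat[half:]))
    else:
        r = np.nan
    return PCAResult(evals, evecs, cumfrac, cc, r, mean, proj[:, :10])


# ---------------------------------------------------------------------------
# DCCM
# ---------------------------------------------------------------------------

@dataclass
class DCCMatrix:
    """Windowed and averaged normalized cross-correlation matrices."""

    window_matrices: list[np.ndarray]
    averaged: np.ndarray
    window_frames: int
    window_ps: float | None
    threshold: float = 0.35
    seq_sep: int = 10

    def significant_long_range(self) -> np.ndarray:
        """Boolean mask of |C| > threshold and |i − j| > seq_sep."""
        n = len(self.averaged)
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        return (np.abs(self.averaged) > self.threshold) & (np.abs(i - j) > self.seq_sep)

    def window_consistency(self) -> np.ndarray:
        """Frobenius distance of each window matrix from the average."""
        return np.array([
            np.linalg.norm(w - self.averaged) for w in self.window_matrices
        ])


def _window_dccm(block: np.ndarray, do_superpose: bool) -> np.ndarray:
    if do_superpose:
        block = superpose_frames(block)
    dev = block - block.mean(axis=0)
    inner = np.einsum("fid,fjd->ij", dev, dev) / len(block)
    var = np.diag(inner).copy()
    # relative floor: numerically frozen residues count as zero variance
    zero = var <= max(var.max(), 0.0) * 1e-12
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-variance residues in a DCCM window; "
            "their correlations are set to 0"
        )
        var[zero] = 1.0
    C = inner / np.sqrt(np.outer(var, var))
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, np.where(zero, 0.0, 1.0))
    return np.clip(C, -1.0, 1.0)


def dccm(ensemble: Ensemble, window_frames: int | None = None,
         threshold: float = 0.35, seq_sep: int = 10,
         fit: bool = True) -> DCCMatrix:
    """Windowed DCCM: C(i,j) = <Δr_i·Δr_j> / sqrt(<Δr_i²><Δr_j²>).

    Δr is taken relative to the window mean (after least-squares
    superposition when ``fit``); the trailing partial window is dropped and
    the averaged matrix is the mean over windows. The default window for
    time-based ensembles mirrors a 1-ns window at 4-ps storage (250 frames).
    """
    ca = ensemble.ca_frames()
    if window_frames is None:
        window_frames = min(250, len(ca))
    if window_frames < 2:
        raise ValueError("window_frames must be >= 2")
    n_windows = len(ca) // window_frames
    if n_windows == 0:
        raise ValueError("ensemble shorter than one window")
    mats = [
        _window_dccm(ca[w * window_frames:(w + 1) * window_frames], fit)
        for w in range(n_windows)
    ]
    avg = np.mean(mats, axis=0)
    ps = ensemble.frame_spacing * window_frames if ensemble.frame_spacing else None
    return DCCMatrix(mats, avg, window_frames, ps, threshold, seq_sep)


# ---------------------------------------------------------------------------
# Chained correlations
# ---------------------------------------------------------------------------

@dataclass
class ChainEdge:
    parent: int
    child: int
    depth: int
    correlation: float


@dataclass
class ChainGraph:
    roots: list[int]
    edges: list[ChainEdge]
    threshold: float
    max_depth: int

    def depths(self) -> dict[int, int]:
        d = {r: 0 for r in self.roots}
        for e in sorted(self.edges, key=lambda e: e.depth):
            d[e.child] = e.depth
        return d

    def long_range_partners(self, depth_min: int = 3) -> list[int]:
        """Residues first reached at depth >= depth_min (Fig-2A convention)."""
        return sorted(c for c, d in self.depths().items() if d >= depth_min)


def chained_correlations(matrix, roots, threshold: float = 0.5,
                         max_depth: int = 5) -> ChainGraph:
    """Breadth-first chained-correlation search.

    Residues are connected when |C(i,j)| >= threshold; a residue's depth is
    the minimum number of such edges from any root; expansion stops at
    ``max_depth``. Parent ties at equal |C| resolve to the lower index.
    """
    C = matrix.averaged if isinstance(matrix, DCCMatrix) else np.asarray(matrix)
    n = len(C)
    roots = sorted(set(int(r) for r in roots))
    if not roots:
        raise ValueError("empty root set")
    if any(r < 0 or r >= n for r in roots):
        raise ValueError("root index outside matrix")
    depth = {r: 0 for r in roots}
    frontier = list(roots)
    edges: list[ChainEdge] = []
    for d in range(1, max_depth + 1):
        discovered: dict[int, tuple[float, int]] = {}
        for p in frontier:
            for c in range(n):
                if c == p or c in depth:
                    continue
                corr = float(C[p, c])
                if abs(corr) >= threshold:
                    prev = discovered.get(c)
                    # prefer stronger |C|; tie -> lower parent index
                    if prev is None or (abs(corr), -p) > (abs(prev[0]), -prev[1]):
                        discovered[c] = (corr, p)
        if not discovered:
            break
        for c, (corr, p) in sorted(discovered.items()):
            depth[c] = d
            edges.append(ChainEdge(parent=p, child=c, depth=d, correlation=corr))
        frontier = sorted(discovered)
    return ChainGraph(roots, edges, threshold, max_depth)


# ---------------------------------------------------------------------------
# Hinge prediction
# ---------------------------------------------------------------------------

@dataclass
class HingeResult:
    hinges: list[int]            # residue indices (0-based)
    scores: list[float]          # |discrete slope| at each hinge
    n_terminal: int | None       # hinge flanking the loop start
    c_terminal: int | None       # hinge flanking the loop end
    detected: bool = True


def predict_hinges(profile: FlexibilityProfile,
                   loop_range: tuple[int, int] | None = None,
                   smoothing_window: int = 3) -> HingeResult:
    """B-factor slope-change hinge prediction.

    The smoothed B profile is split at the median into fixed (low-B) and
    floppy (high-B) runs; hinge residues sit at the point of maximal
    |discrete slope| at each fixed↔floppy boundary. When a loop range
    (0-based, inclusive) is given, the boundaries flanking it are reported
    as the N- and C-terminal hinge candidates.
    """
    b = profile.bfactor.astype(float)
    if np.ptp(b) < 0.05 * max(b.mean(), 1e-12):
        return HingeResult([], [], None, None, detected=False)
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        bs = np.convolve(np.pad(b, pad, mode="edge"), kernel, mode="valid")
    else:
        bs = b
    floppy = bs > np.median(bs)

    def centered_slope(m: int) -> float:
        lo, hi = max(m - 1, 0), min(m + 1, len(bs) - 1)
        return float((bs[hi] - bs[lo]) / max(hi - lo, 1))

    hinges, scores = [], []
    for k in range(len(floppy) - 1):
        if floppy[k] != floppy[k + 1]:
            # residue with the sharper local slope on either side of the step
            pick = max((k, k + 1), key=lambda m: (abs(centered_slope(m)), -m))
            hinges.append(pick)
            scores.append(abs(centered_slope(pick)))
    # dedupe, keep order
    seen = {}
    for h, s in zip(hinges, scores):
        if h not in seen or s > seen[h]:
            seen[h] = s
    hinges = sorted(seen)
    scores = [seen[h] for h in hinges]
    n_term = c_term = None
    if loop_range is not None and hinges:
        lo, hi = loop_range
        before = [h for h in hinges if h <= lo + 1]
        after = [h for h in hinges if h >= hi - 1]
        n_term = max(before) if before else None
        c_term = min(after) if after else None
    return HingeResult(hinges, scores, n_term, c_term, detected=True)
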