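# Methods

This note documents the models implemented in loopdyn, the parameter
conventions, the numerical choices that were genuinely open, and what the
synthetic-data closure tests do and do not demonstrate.

## Units and coordinate conventions

Lengths are Å, energies kcal/mol, masses Da, times ps, temperatures K.
Thresholds conventionally quoted in nm (0.45, 0.55, 0.6, 1.0 nm) are
converted once at the parameter layer (`units.nm_to_angstrom`) and stored
in Å. For dynamics, 1 kcal/mol = 418.4 Da Å² ps⁻²; k_B = 1.9872×10⁻³
kcal mol⁻¹ K⁻¹. Residues keep PDB 1-based numbering (insertion codes kept
in the identity); internal indices are 0-based; all reports use PDB
numbers. Multi-model PDB is the ensemble interchange format: text,
tool-agnostic, 10⁻³ Å round-trip precision.

## Elastic network and samplers

The Cα network uses the harmonic pair potential
V = ½ Σ K_ij (|r_ij| − r⁰_ij)² with the Kovacs distance-dependent
stiffness K(r⁰) = C (r*/r⁰)⁶, C = 40 kcal mol⁻¹ Å⁻², r* = 3.8 Å (the mean
consecutive Cα–Cα distance). The continuous decay replaces a hard cutoff,
so **NMA and BD networks include every pair**; only DMD restricts the
pair list to native distances below r_c = 8 Å. Bead mass is 100 Da
(average residue), default temperature 300 K.

**ANM.** The 3N×3N Hessian is assembled from the standard per-pair
super-elements −(K_ij/r⁰_ij²)(r_ij ⊗ r_ij) and diagonalized with `eigh`.
Eigenvalues below 10⁻⁸ × the largest are rigid-body modes (scale-free
tolerance); a connected 3D network yields exactly six, and more than six
raises a disconnected-network error. The thermal covariance is
k_B T H⁺ = k_B T Σ_m v_m v_mᵀ/λ_m over internal modes. Mode-based
ensembles draw per-mode Gaussian amplitudes of variance k_B T/λ_m — the
convention is ours to fix since only the sampler's target distribution is
physically determined; the sampled covariance converges to k_B T H⁺ by
construction.

**BD.** Langevin dynamics with the BAOAB splitting (exact for the O-step,
second-order for the rest), γ = 0.4 ps⁻¹ (water-like friction), dt = 1 fs.
The BD potential is the same harmonic Kovacs network as NMA — the
quasi-harmonic form is an interpretation we document rather than a unique
prescription. Production lengths are configurable; the reference protocol
is 5×10⁶ steps, and tests/acceptance use scaled-down runs (10⁵–1.2×10⁶
steps) chosen to reach statistical convergence at desk scale. Divergent
coordinates raise an error naming dt.

**DMD.** Infinite square wells per interacting pair: distances confined to
[(1−σ)r⁰, (1+σ)r⁰] with σ = 0.1, and σ = 0.05 for consecutive residues to
keep virtual bonds near 3.8 Å. Between events particles are ballistic;
event times solve |r + w t| = wall exactly (quadratic closed form), and
the earliest event is found by full recomputation over pairs (O(P) per
event — correctness over speed at desk scale). Collisions elastically
reverse the radial relative velocity, conserving momentum and kinetic
energy to round-off; positions advance to the event time minus 10⁻¹² to
avoid re-processing a wall. Velocities initialize from Maxwell–Boltzmann
at 300 K with the centre-of-mass drift removed.

### Oracle-equivalence checks and the harmonic regime

The Hessian is validated against central-difference differentiation of
the pair potential (≤10⁻⁵ elementwise). Sampled covariances are compared
with k_B T H⁺ after least-squares superposition onto the equilibrium
structure (BD trajectories diffuse rigidly; the analytic covariance lives
in the internal subspace). The BD check runs on a compact helical 5-mer
at T = 100 K with γ = 2 ps⁻¹: the quadratic expansion of the Kovacs
potential is only valid for small fluctuations, and an extended 5-mer at
300 K has soft bending modes with ~6 Å amplitudes where BD correctly
samples the anharmonic potential and *should not* match the harmonic
covariance. The stronger friction shortens the energy correlation time so
the comparison converges statistically; it does not change the target
distribution.

## Ensemble analyses

**Superposition** iterates a Kabsch fit of every frame onto the running
average twice — enough for convergence at these fluctuation levels.

**RMSF/B-factors.** RMSF is measured on the trajectory projected onto the
leading principal components covering ≥ 70 % of the variance by default
(filter_fraction = 1 reproduces the raw RMSF exactly);
B = (8π²/3)·RMSF². Mode-based B-factors use ⟨Δr_i²⟩ = k_B T Σ |v_m,i|²/λ_m
and agree with mode-sampled ensembles within sampling error (5 % at
20,000 frames, asserted).

**PCA diagnostics.** Cosine content c_k of the k-th projection follows the
Hess estimator (discrete cosine against the projection; 1.0 = pure
diffusion-like drift), and RMSIP compares the top-10 subspaces of the two
ensemble halves. Beads share one mass, so the mass-weighted covariance
reduces to the positional covariance.

**DCCM.** Non-overlapping windows (trailing partial window dropped), each
superposed and centred on its own mean; the averaged matrix is the plain
mean over windows. Window length for time-based ensembles defaults to the
sample size of a 1-ns window at 4-ps storage (250 frames). Residues with
numerically zero variance in a window get correlation 0 with a warning.
Per-window Frobenius distance to the average is reported as a consistency
diagnostic without asserting a threshold (no principled cutoff exists).
The significance mask applies |C| > 0.35 and |i−j| > 10.

**Chained correlations.** Breadth-first expansion from root residues over
edges with |C| ≥ 0.5 up to depth 5; a residue's depth is its minimum edge
count from any root (ties in parentage resolve to the stronger |C|, then
the lower residue index — determinism). A brute-force shortest-path
enumeration on random 8×8 matrices is the test oracle.

**Hinge prediction** renders the under-specified "B-factor slope change"
idea concretely: smooth B with a 3-residue moving average, split at the
median into fixed (low-B) and floppy (high-B) runs, and place a hinge at
the residue with the steepest centred slope at each boundary; profiles
with < 5 % relative range report "no hinge". The smoothing window and the
median split are our choices, made to reproduce the step-profile
intuition, and are test-pinned.

## Loop geometry

**States.** Distance classifier: |CoM(Cys side chain, or Cα when only Cα
exists) − CoM(loop Cα)| with closed < 6 Å, open > 10 Å, boundary values
assigned to semi-open (the outer classes are defined by strict
inequalities). Accessibility classifier (all-atom frames only): relative
Cys side-chain accessibility with closed < 20 %, open > 35 %; the
fraction below 10 % is additionally reported because deeply buried
catalytic cysteines are flagged separately in the closed class. The
agreement rate between the two classifiers is always reported, never
assumed.

**SASA.** In-house Shrake–Rupley: 960 deterministic golden-spiral points
per atom, probe 1.4 Å, vdW radii C 1.70/N 1.55/O 1.52/S 1.80 Å. Validated
against the closed-form sphere, a Monte-Carlo rejection oracle (2 %), and
rotation invariance (0.5 % at 5,000 points). Relative side-chain
accessibility divides by the same residue's side-chain SASA in a
**carved Gly-X-Gly context**: the residue's own atoms plus the backbone
of its two neighbours, extracted from the same coordinates and scored
with the identical algorithm. A de-novo extended tripeptide would require
a full side-chain topology library; the carved context keeps numerator
and denominator exactly consistent and is the documented compromise.

**Omega loops.** Criteria: hinge Cα distance in 3.7–10 Å; hinge distance
< 2/3 of the frame's maximal Cα–Cα span across the segment; length
6–16 residues; no α/β elements by the simplified secondary-structure
assignment (3₁₀ and turns tolerated). Whether the criteria apply per
frame or on an average structure is genuinely open; the report carries
per-frame pass fractions and takes the verdict from the median-distance
frame. Among candidate hinge pairs, the best is the one meeting the
distance criterion in the most frames.

**Secondary structure** is a deliberate simplification of a hydrogen-bond
assignment: φ/ψ basins (α: φ∈[−100,−30], ψ∈[−80,−35]; 3₁₀: ψ∈(−35,−5];
β: φ∈[−170,−70], ψ≥90 or ≤−150) with run-length rules (≥4 α → H, ≥3 3₁₀
→ G, ≥3 β → E, shorter → T). Cα-only input falls back to pseudo-dihedral
basins guarded by the i−1→i+1 distance (≥6 Å for strands) so tightly
curved planar loop traces are not mislabelled as extended structure.

## Interaction networks

A frame is a contact when the **minimum inter-group atom distance** is
below the cutoff — 4.5 Å between oppositely charged side-chain groups
(NZ; NE/NH1/NH2; OD1/OD2; OE1/OE2; termini), 5.5 Å between side-chain
carbons of {A,V,L,I,M,F,W,P,Y}. His is neutral by default (protonation
unknown at standard pH; switchable). An optional geometric angle screen
exists but is off by default: no angular criterion is canonically
defined, and the distance rule is the operative definition. Persistence
is the contact fraction of frames; macro-trajectories concatenate the
equilibrated parts of replicas with recorded boundaries, so pooled
persistence is exactly the frame-weighted mean of replica persistences.
Records at or above 20 % persistence form the graph (nodes = residues,
arc weight = persistence); the persistence histogram is emitted so the
signal/noise gap is inspectable. An interaction absent from one replica
pools as persistence 0 for that replica, and reports flag this
convention.

## Conservation

Per column: Shannon entropy over observed residues (gaps excluded from
frequencies but reported; columns > 50 % gaps emit "-"); mean pairwise
substitution score under the **Karlin diagonal normalization**
M(a,b)/√(M(a,a)M(b,b)) clipped to [0,1] — chosen over min/max scaling so
an invariant column scores exactly 1; and the same similarity under
Henikoff position-based sequence weights, computed from weighted residue
frequencies so that duplicating sequences provably leaves the score
unchanged. "PET91" resolves to the Jones–Taylor–Thornton 1992
mutation-data log-odds (the PET91 matrix) as shipped with Biopython — a
documented substitute for an unrecoverable in-house variant.

Consensus symbols are evaluated literal → acidic (n = {D,E}) → tiny
(u = {A,G,S}) → two-residue pair "(A,B)" → hydrophobic
(h = {A,V,L,I,M,F,W,C,Y}) → x. Compact chemical classes precede the pair
rule so a D/E column reads "n" rather than "(D,E)", while a mixed-class
Y/F column still reads "(F,Y)". Because every rule is a ≥-threshold test
and the order is fixed, raising the threshold can only move a column to a
later, less specific symbol — the monotonicity property the tests assert.
The hydrophobic class includes C and Y (configurable); h is defined only
by usage, and this membership matches the columns it must describe.

## Synthetic data

The generators emulate the *statistical structure the analyses assume*,
each emitting its ground truth:

* Cα chains — exact 3.8 Å virtual bonds; the extended trace precesses out
  of plane so its ANM Hessian is non-degenerate; helix and hairpin
  geometries for compact/turn fixtures; a NeRF backbone builder produces
  N/CA/C chains with exact requested φ/ψ for secondary-structure tests.
* Planted-covariance ensembles — per-axis i.i.d. Gaussian draws from a
  correlation matrix carrying planted ρ (nearest-PD repair recorded), so
  the DCCM converges to the planted matrix. These frames live in the lab
  frame with no rigid-body motion; closure tests therefore run the DCCM
  without superposition, since fitting would itself perturb small
  correlations by O(1/N).
* Planted-contact trajectories — two residues whose closest charged (or
  hydrophobic) atoms sit at 4.0 Å in exactly round(f·n) frames and 8.0 Å
  otherwise: persistence recovery is exact by construction.
* Two-state loop trajectories — the loop block is rigidly placed at
  distances drawn inside bands (3.0–5.5 / 6.5–9.5 / 10.5–15.0 Å) that
  avoid the 6/10 Å class boundaries, with exact per-state counts; the
  default fractions (0.65, 0.09, 0.26) are the reference closed/semi-
  open/open populations of the study conditions.
* Toy alignments — designed column compositions (invariant,
  class-conserved at exact fractions, random) via largest-remainder
  allocation.

All randomness flows through one `numpy.random.default_rng(seed)` per
generator call; outputs are bit-reproducible.

**What closure tests do not show.** Recovering planted truth verifies the
analysis machinery, not biological claims: synthetic ensembles have no
anharmonic multi-basin landscapes, no solvent, no correlated noise across
stages, and the planted populations are inputs, not predictions. Applying
the pipeline to real E2 structures requires the PDB depositions and
(for state populations) genuine MD-scale sampling, which is outside desk
scale.

## Problem sizes and limitations

Default test/acceptance sizes: 5–20-bead networks, 10,000–20,000 sampled
frames, 1.2×10⁶ BD steps, ~10³ DMD events, 1,000–10,000-frame planted
trajectories — chosen so each check converges statistically while the
whole suite remains desk-scale. Known limitations: the BD/NMA covariance
equivalence holds only in the linear-response regime (by physics, not by
implementation); the simplified secondary-structure assignment is not a
hydrogen-bond method and will disagree with DSSP near helix termini and
bulged strands; SASA ignores hydrogens unless present; the accession-based
structural comparisons (RING-domain superposition, UBC-domain identity)
need downloaded PDB depositions and are not runnable offline.
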