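# Methods

This note records the models implemented, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Structures, trajectories, units

Coordinates are Angstroms, times picoseconds, residue numbering 1-based as
in PDB files.  PDB reading keeps one atom per alternate-location group
(highest occupancy, ties to the first conformer).  Masses are standard
atomic weights; van der Waals radii come from a single bundled Bondi table
(`mdstates.elements`); unknown elements fall back to carbon-like values
with a warning.  DCD files carry no time metadata through the writer used
here, so re-read trajectories get 1-ps spacing.

## State discovery

PCA operates on the Cartesian coordinates of a selection after
least-squares fitting (Kabsch, proper rotation enforced) of every frame to
a reference frame over that same selection.  The covariance uses the
unbiased (n−1) normalization; eigenvalues are clipped at zero and sorted
descending.  Eigenvector sign is fixed by making the largest-magnitude
component positive — the decomposition is sign-degenerate and a fixed
convention keeps projections reproducible across platforms.

k-means uses scikit-learn's k-means++ with 25 restarts and a caller-supplied
seed.  Cluster labels are mapped to states by the convention that the
cluster containing frame 0 is the "closed" state, because trajectories of
this kind start from the closed crystal-like conformation.  BSS/TSS is
1 − inertia/TSS.  Distance-threshold assignment labels a frame open when
the chosen inter-residue distance exceeds the threshold; the transition
frame is the first index of the longest open run, which is robust to
isolated threshold crossings.

Free-energy landscapes are ΔG = −ln(ρ/ρ_max) over an 80 × 80 2-D histogram
(default) of the first two projection columns, in kT; empty bins are +inf
rather than a large sentinel number, so the minimum is exactly 0 by
construction.

The hinge decomposition superposes conformer B onto conformer A over the
fixed domain, fits the mobile domain's residual rigid transform, and
converts it to screw parameters via the rotation vector; the axis point
solves (I − R)p = t_perp in the least-squares sense, giving the axis point
closest to the origin.  Rotations under 1° are reported as undefined
rather than returning a noise-dominated axis.

## Structural attributes

Hydrogen bonds are geometric: donor–acceptor distance ≤ 3.2 Å and a
D–H···A angle within 20° of linear, evaluated per frame with donors and
acceptors taken from a bundled per-residue table (backbone N/O plus the
usual side-chain donors/acceptors; the table is a module-level constant
and swappable).  Hydrogens are required by default; for hydrogen-free
crystal structures an explicitly flagged heavy-atom variant
(`require_hydrogens=False`) accepts D···A ≤ cutoff plus an
antecedent–D–A angle ≥ 90°.  Salt bridges pair any Asp/Glu carboxylate
oxygen with any Lys/Arg/His side-chain nitrogen within 3.5 Å.  Attribute
time series default to a 25-frame stride (25 ps at 1-ps frames).

SASA is Shrake–Rupley with a Fibonacci sphere lattice (default 960 points,
warning below 32) and a 1.4 Å probe.  A sample point exactly on a
coincident neighbour's sphere is counted once (the lower-index atom keeps
its surface), so duplicated atoms do not double-count area.

Dihedrals use the atan2 two-projection formula in the IUPAC sign
convention (cross-checked against MDAnalysis) with range (−180°, 180°].

Rg is mass-weighted about the centre of mass.  Dmax is the exact maximum
pairwise distance up to 10⁴ atoms and a convex-hull reduction above.  For
crystal structures both are computed over standard-residue heavy atoms,
excluding waters, ions and ligands — the bare-protein convention used by
coordinate-based scattering predictors.

## Statistics

The PHI coefficient is computed from the 2 × 2 contingency table and equals
the Pearson correlation of the two binary variables; constant inputs give
NaN ("undefined"), never 0.  Point-biserial correlation is the Pearson
correlation of the continuous variable against the 0/1 labels (scipy).
The t-test is Welch's unequal-variance form: the two conformational states
generically differ in variance, so the pooled-variance test would be
anti-conservative.  Circular attributes pass through sin(θ) before
correlation; with state means well separated on the sine scale this
preserves the bimodal signal while staying in a linear-correlation
framework.

Watson–Williams: F = K(N−2)(R₁+R₂−R)/(N−R₁−R₂) with K = 1 + 3/(8κ̂) and κ̂
from the pooled mean resultant length via the standard three-regime
rational approximation of the A(κ) inverse; p from F(1, N−2).  The
high-concentration assumption is checked (pooled R̄ ≥ 0.45) and violated
inputs warn rather than fail.  Type-I error is verified by simulation to
sit in [0.03, 0.07] at α = 0.05 for von Mises data with κ = 5.

The attribute screen scores binary attributes with PHI and continuous ones
with point-biserial r, flags |r| > 0.5, and orients the sign so that
positive means "elevated or present in the open state".  Raw statistics
are reported without multiple-testing correction (flagging is
threshold-based); a Benjamini–Hochberg q-value column is emitted for
transparency only.

## Correlated motion

The DCCM normalizes the covariance of positional deviations from the
time-mean.  RCC recomputes the pair correlation inside each length-W
window advanced one frame at a time, with window-local means — global
means would hide a mid-trajectory sign flip, which is precisely the signal
of interest.  The alternative (global means) is not offered because it
reduces to a windowed average of one global quantity.  The default window
is F/10: long enough to smooth frame-to-frame noise (sd of a
null-correlation estimate ≈ 1/√W), short enough to localize a single
transition.  Window midpoints are stored as k + (W−1)//2 (floored for even
W) so they remain frame indices.  At window = F the RCC delegates to the
full-matrix entry so the limit identity is exact, not approximate.  The
deviation map is vectorized with cumulative sums and guarded to 1000
selection atoms (O(R²F) work).

The distance-fluctuation map uses a two-pass mean/variance accumulation;
the one-pass E[d²]−E[d]² form loses about seven digits to cancellation and
visibly violates the rigid-body-zero property.

## Dynamical network

Nodes are residues centred on Cα (ligands may be given several nodes
through an explicit node map, each with a representative atom).  An edge
requires any heavy-atom pair within 4.5 Å in at least 75% of frames
("at least" read as ≥); sequence neighbours (|Δresid| ≤ 1, same chain) are
excluded, following the established dynamical-network protocol.  Edge
weight is −log|C_ij| of the representative atoms: strongly correlated
contacts are "short" for information transfer.  Girvan–Newman removes the
highest edge-betweenness edge iteratively (betweenness uses the weights as
path lengths; an unweighted variant is a one-line change at the call) and
the retained partition is the first strict maximum of modularity along the
dendrogram.  Modularity is weighted by |C_ij| — connection strength — not
by the −log lengths; using lengths as modularity weights would reward
cutting exactly the strong edges.  The dendrogram is produced by
python-igraph's C implementation; its betweenness tie-break is
deterministic for a fixed edge insertion order but is not the
"lexicographically smallest edge" rule, which matters only on exactly tied
fixtures.

Known limitation: modularity maximization has a resolution scale.  For a
~200-residue two-lobe contact network the optimum partition subdivides
each lobe into several spatial sub-communities (about ten communities in
total) instead of returning the two lobes; the recovered communities are
*refinements* of the lobes (under 10% of residues land in a community
dominated by the other lobe), and the tests assert exactly that property.
A two-way agreement score such as the adjusted Rand index against the
binary lobe assignment therefore stays low by construction, for any
realizable lobe geometry — this is a property of modularity, not of the
implementation, and matches the community counts the method produces on
real proteins of this size.

## SAXS

The Debye sum uses q-independent electron-count form factors.  The
hydration shell and excluded-volume terms of hydration-aware predictors
are deliberately not modelled: absolute χ² against real solution data will
differ, and the package's SAXS metrics are designed for coordinate-space
quantities (Rg, Dmax, P(r)) and *relative* state-to-state comparisons.
P(r) is a direct-space histogram of pairwise distances (weights 2f_i f_j,
default 1 Å bins) rather than a regularized inversion of the scattering
curve; its support ends exactly at Dmax.  The Debye curve and P(r) are
Fourier mates: rebuilding I(q) from the 0.5 Å-binned histogram matches the
direct sum within 1%, which the tests assert.  Guinier fits iterate the
range qR_g ≤ 1.3 to self-consistency and refuse non-negative slopes.
χ² = (1/(N−1))Σ[(I_exp − cI_calc)/σ]² with the closed-form least-squares
scale c; the statistic is invariant to common rescaling of I_exp and σ.
Per-state χ² strides frames (default 10) and coarse-grains to one
Cα bead per residue carrying the residue's electron count, keeping a
2000-frame pass inexpensive.

## The synthetic generator

The generator stands in for a long explicit-solvent MD run.  It emulates:
a two-lobe protein (100 residues per lobe, five atoms N/CA/C/O/H per
residue on a compact serpentine lattice, 3.8 Å Cα spacing) whose open
state is the closed state with lobe B rigidly rotated 25° about a hinge
axis through the lobe interface; a sharp single-frame transition at frame
1000 of 2000 (the real transition is fast on the trajectory timescale);
state-specific contacts (three designed pairs at 4.2 Å closed / 12 Å
open); state-specific backbone ψ angles (von Mises, κ = 50, means −60°/120°
and 150°/−30°); a designed switching correlation pair whose thermal noise
is correlated +0.8 in the closed state and −0.8 in the open state,
mirroring a contact pair that moves coherently while bonded and
anti-coherently once the interface breaks; and thermal noise of 0.3 Å per
coordinate.

Two deliberate deviations from plain iid noise, both needed for the
analyses to have the statistical structure they assume in real proteins:

1. Each lobe receives a shared rigid-body translational noise component
   (0.3 Å, `lobe_noise_sigma`).  Without it the DCCM of a finite-noise
   trajectory carries no within-lobe correlation at all and
   correlation-derived network weights are structureless; semi-rigid
   domain motion is exactly what the dynamical-network analysis assumes.
2. The four atoms defining each designed ψ angle carry the von Mises
   angular resampling *instead of* Cartesian noise.  Isotropic 0.3 Å noise
   on ~1.4 Å bond lever arms would make the measured dihedral circularly
   uniform, destroying the designed state-specific distribution the
   screen is supposed to recover.

What the generator does not emulate: force-field energetics, solvent,
anharmonic intra-lobe flexibility, gradual transitions (an optional
interpolation window exists in concept but the default is sharp), or
realistic side chains.  Tests that pass on this generator demonstrate that
the estimators recover designed signals at realistic noise levels; they do
not validate force-field-dependent behaviour on real proteins.

Problem sizes throughout the test suite (200 residues, 2000 frames, five
seeds for the recovery study, 1000 replicates for the statistical
calibrations) were chosen so the full suite and the acceptance script each
complete in a few minutes on one CPU.

## Reference structures

The SMYD3 crystal-structure checks (Rg ≈ 23.2 Å and Dmax ≈ 77.8 Å for PDB
3PDN; Cα RMSD ≈ 0.6 Å between 3PDN and 5CCL) require the deposited
coordinates, which are not bundled; `mdstates.refdata` resolves them from
a local directory and explains how to fetch them.  No synthetic stand-in
is substituted for these values.
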