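# Methods

This note documents the models implemented in lidkit, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter when comparing output
across tools.

## Elastic network model

Each residue is one unit-mass grain at its Cα. Every pair (i, j) is
connected by a harmonic spring; the Hessian is assembled from the usual
anisotropic 3×3 blocks −k_ij·r̂r̂ᵀ, and its full spectrum is computed by
dense symmetric diagonalization. A generic 3-D structure has exactly six
zero-frequency rigid-body modes (tolerance: eigenvalue < 1e-8 × largest);
more than six signals degenerate (collinear) input and is an error.

The force-constant rule is cutoff-free and two-regime, in the spirit of
network force fields fitted to MD covariance data:

* sequence-proximal pairs, |i − j| ≤ `seq_neighbor_cutoff` (default 3):
  k = `k_seq` / s², stiff and decaying with sequence separation s;
* all other pairs: k = `k_cart` · d^(−`cart_exponent`) with d the Cα–Cα
  distance in Å (default exponent 6), so no hard distance cutoff exists.

The published parameter-free variants of this family do not print a
single set of constants, and none of the derived quantities used here
depend on the overall scale: predicted B-factors are reported on an
arbitrary scale, normalized mobility is rescaled to max = 1, and the
covariance map is correlation-normalized to [−1, 1]. The defaults
(`k_seq` = 60, `k_cart` = 6·10⁴, giving distal pairs at ~10 Å a constant
~1000× softer than bonded neighbours) are therefore a documented
stand-in; only orderings and profile shapes are contractual, not absolute
mobility values.

Per-residue fluctuations come from the Hessian pseudo-inverse over
internal modes: B_i ∝ tr P_ii with P = Σ_m v_m v_mᵀ / λ_m, and the
cross-correlation map is C_ij = tr P_ij / √(tr P_ii · tr P_jj). Both are
validated against a Monte-Carlo sampling of the mode Gaussians and an
independently assembled Hessian.

## Trajectory descriptors

* **Superposition**: Kabsch (SVD, proper rotation enforced). RMSF uses
  the trajectory mean structure as reference, refined by a second
  superposition pass; this removes rigid-body drift so a rigidly tumbling
  static structure has RMSF 0.
* **Distances** are Euclidean, per frame; summary statistics use the
  sample standard deviation (ddof = 1) as MD tables conventionally do.
  The κ map (below) uses population statistics as its defining formula
  prescribes — the two conventions cancel inside a correlation, so κ is
  identical under both.
* **Aperture descriptor**: distance from a hinge Cα (default residue 140)
  to the center of mass of the lid-helix residues (default 121–131). The
  literature does not state whether that COM is all-atom or Cα-based;
  both are implemented and the default is all-atom mass-weighted, with a
  `ca_only` switch. On the toy systems the two differ by a few tenths of
  an Å, which is why the crystal worked example carries a ±0.3 Å
  tolerance.
* **Hydrogen bonds**: donor–acceptor distance ≤ 3.5 Å and, when a
  hydrogen position exists, donor–H···acceptor within 30° of linearity —
  the de-facto criterion of standard MD analysis tools, adopted because
  the source analyses do not state one. United-atom force fields carry no
  apolar hydrogens and some polar ones are absent from trajectories, so a
  distance-only mode is the documented fallback.
* **Dihedrals** follow the IUPAC torsion convention (reversal-invariant;
  matches MDAnalysis). The sidechain N-Cα-Cβ-Cγ angle of the aromatic lid
  residue is the canonical use: its sign distinguishes the inward
  (aperture-blocking) from the outward ring orientation.
* **Windows** for segment statistics are [start, end) in time (ns), or in
  frame indices when the trajectory carries no times.
* **Units**: Å internally everywhere (PDB native); nm only in report
  output, because MD summary tables print nm.

## PCA and the κ map

PCA superposes the selected (default Cα) coordinates to the iteratively
refined mean structure (first-frame reference available), diagonalizes
the population covariance of the flattened coordinates, and projects
centered frames onto the eigenvectors. A static trajectory is legal and
flagged rather than an error. κ is computed exactly as the defining
correlation between the mode-projection series and each pair-distance
series; pairs with zero distance variance (and everything in a static
trajectory) are masked as degenerate and reported as κ = 0, keeping the
matrix rectangular for heat maps. The weighted map is the elementwise
|κ|·Δd in Å. The pair set defaults to all Cα pairs (i < j) of the
selection; nothing in the sources restricts it to a subset, and subsets
remain configurable for large systems.

One deliberate interpretation: the crystal-structure 1.183 nm end-to-end
value is attributed to the detergent (LDAO N–C1), following the figure
caption that states it explicitly, although one sentence in the
surrounding text could be read as attaching it to the covalent inhibitor.
The discrepancy is documented here, not resolved.

## Lid-state classification

The classifier thresholds the primary lid distance (Cα123–Cα140
numbering by default): closed iff d ≤ 9 Å, open iff d > 12 Å, else
intermediate; boundary values deterministically resolve to the more
closed state. The defaults bracket the published reference points — a
closed homolog lid near 8.4 Å, the most closed simulated mean near
7.6 Å, and the open crystal structure near 14.9 Å — and are
configuration-exposed because no printed cutoff exists. The label is
monotone in the distance by construction.

## Aperture probe

The probe test grids the structure (default spacing 0.5 Å; a margin
extends the box beyond atoms and seeds), assigns every grid point the
clearance min_atoms(|p − x_a| − r_a) with Bondi radii by element, and
runs a widest-path (maximin-clearance) Dijkstra variant over 26-connected
neighbours between an interior and an exterior seed. Cells with
non-positive clearance are impassable; unreachable seeds return radius 0.
The search is validated against an independent threshold-sweep +
connected-component oracle on the same grid, and against an analytic
slab-with-slit geometry where the bottleneck equals slit half-width minus
the vdW radius exactly. Grid discretization means thin obstacles must be
resolved by the chosen spacing; spacings above 1 Å trigger a warning.
Seeds default-free: callers supply them (the natural choice for a lipase
is the catalytic serine Oγ vicinity inside and a point beyond the lid
outside).

## Synthetic generator: what it does and does not emulate

`simulate_modes_trajectory` draws i.i.d. Gaussian amplitudes per frame
for orthonormal displacement modes acting rigidly on residues, optionally
plus i.i.d. coordinate jitter — it reproduces the *covariance* structure
of an MD trajectory (what PCA, RMSF, κ and ENM cross-checks consume) but
not its kinetics: amplitudes carry no autocorrelation, so dwell times,
transition sharpness and friction are out of scope (the two-state
generator adds Markov dwell statistics for exactly that reason). Solvent,
ligands and anharmonicity are absent. Passing tests therefore demonstrate
that the estimators recover known statistical structure exactly or within
sampling error — not that a force field or sampling protocol is correct.

Planted constructions are exact by design: the PC-coupled pair distance
is set frame-by-frame to slope·a₁(t) + intercept (κ = ±1 up to float
error); hydrogen-bond geometries satisfy or violate the criterion per a
boolean plan (occupancy equals the plan mean exactly); two-state frames
sit exactly at the open/closed values, so a threshold classifier
separates them perfectly when those values lie outside the
intermediate band. Modes intended for recovery through
superposition-based estimators are first projected off the rigid-body
subspace (`orthogonalize_to_rigid`), because superposition removes
rigid components and would otherwise distort a planted mode that
carries them.

For the localization benchmark, the planted band (residues 121–123,
mirroring the lid numbering) moves along the outward radial direction
from the fold's center with σ = 3 Å over 2000 frames, against 0.05 Å
jitter; the radial choice guarantees every other residue's distance to
the band couples to the mode well above the jitter floor, so the
row-maxima criterion of the |κ|Δd map is sharp.

Problem sizes used in tests and in `scripts/acceptance.py` (10⁴ frames
for variance/RMSF recovery, 2·10³ for κ maps, toy chains of 25–60
residues) were chosen so sampling error sits comfortably inside the
stated tolerances while the whole suite completes in well under a minute
per stage.

## Crystal-structure checks

The worked examples on the deposited structure (PDB entry 6qe2: chain-A
residue count, the 1.493 / 1.076 nm lid distances, the 1.183 nm LDAO
end-to-end distance, the 11.9 Å aperture descriptor, and the ENM mobility
ordering of residues 123 vs 140) are implemented and run whenever a copy
of the entry is placed at `data/6qe2.pdb`. The file is not redistributed
with the package; in its absence these tests fail with a message saying
exactly that, and all synthetic-data validation is unaffected.

## Known limitations

* The ENM force constants are a documented stand-in; absolute
  eigenvalues and B-factor scales are not comparable across tools.
* `aperture_probe` recomputes clearance by looping over atoms — fine for
  the toy and single-protein scale it targets, not for large complexes.
* Multi-model PDB parsing re-extracts each model through the underlying
  reader; trajectories of many thousands of frames are better kept in
  memory (the generator) or loaded through the MDAnalysis adapter.
* PDB fixed-column output rounds coordinates to 10⁻³ Å; round-trip tests
  assert at that precision.
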