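# Methods

This note documents the models, conventions and numerical choices behind
`statescan`, and what the synthetic-data generators do and do not emulate.

## Units and constants

Coordinates are Å everywhere inside the package; the umbrella reaction
coordinate ξ is in nm (the GROMACS convention for centers, spacings and
force constants), converted explicitly at the module boundary.  Energies
are kcal·mol⁻¹ internally; bias force constants are accepted in
kJ·mol⁻¹·nm⁻² and divided by exactly 4.184.  The gas constant is
R = 0.0019872 kcal·mol⁻¹·K⁻¹ and the default temperature 310 K
(physiological, matching the simulated ensembles the analyses target).

## Activation metrics

The A100 index is an affine function of five inter-residue Cα distances
(V95–L382, D120–T160, H165–A192, Q262–C322, A346–L362) with weights
(−14.43, −7.62, +9.11, −6.32, −5.22) per Å and intercept 278.88.  The
index is only meaningful with distances in Å; the classification
thresholds 0/55 (three-state) and 25 (two-state) assume that scale.  The
published threshold definitions use strict inequalities for the lower
classes and leave the boundary values unassigned; `statescan` resolves
boundaries left-closed on the active side (a score of exactly 55 is
active, 25 is active, 0 is intermediate), which keeps classification
monotone and total.  All five index pairs are evaluated as Cα–Cα
distances.  The index's source lists two residues under the
Ballesteros–Weinstein label 4.42 (T160 and A192), evidently a label typo;
residue ids are treated as ground truth and the labels are metadata only
("4.42b" disambiguates in the toy receptor's map).

Cα distance series are computed without superposition (intramolecular
distances are rigid-motion invariant).  RMSD is mass-weighted after
Kabsch superposition over the selection by default; an unweighted and an
unsuperposed variant are exposed (the unsuperposed form satisfies the
closed-form single-displaced-atom identity used in the tests).  RMSF
optionally aligns frames to the time-averaged structure via a two-pass
scheme (align to frame 0, average, re-align to the average) before taking
fluctuations about the mean; residues with several selected atoms report
the RMS over their atoms.

Reference distance levels for "open"/"closed" overlays are caller-supplied
numbers, never hard-coded: they derive from external experimental
structures.

## Superposition

Kabsch superposition uses the SVD of the weighted covariance between
centered point sets; the reflection branch (negative determinant) is
corrected by flipping the smallest singular axis, so the returned rotation
is always proper.  Fewer than three points or a (near-)collinear reference
(second singular value ≤ 1e−8 of the first) raise a degenerate-input
error, since the rotation is then underdetermined.

## Landscape extraction

PCA diagonalizes the covariance of mass-weighted (√m·x), mean-centered
coordinates of the analysis selection.  Frames must be superposed onto a
common reference over that selection first; `superpose_trajectory`
defaults to the first frame as reference (the choice is a free gauge and
is exposed as a parameter).  The selection default excludes the six
flexible loop ranges (102–108, 179–189, 263–314, 138–145, 217–231,
347–354 — 101 of the 330 residues), which would otherwise dominate the
spectrum.  Backbone mode uses N/Cα/C/O where present; the toy receptor is
Cα-only.

Clustering runs on the 2D projection (the figures the analysis feeds are
2D; clustering in full mode space would weight tail modes that the
projection discards).  k-means uses k-means++ seeding with 10 restarts,
center-movement tolerance 1e−6, and a fixed seed; k is capped at 4
ensembles and, when not fixed by the caller, chosen by silhouette score
over k ∈ {2..4} with a floor of 0.25 below which the data are treated as
one ensemble (silhouette is undefined at k = 1).  Centroid frames are the
frames nearest each center, ties resolved to the lowest index.

The TM6 outward displacement is read out by superposing a conformation
onto the closed reference over all Cα atoms *outside* the TM6 block
(residues 315–346) and averaging the displacement magnitudes of the block
Cα atoms.  On the synthetic references this returns the constructed shift
exactly; under coordinate noise of σ it is unbiased to O(σ²/shift).

## Umbrella sampling and WHAM

`wham_solve` iterates the standard self-consistent histogram equations on
a shared uniform grid (default 200 bins over the data range; at the
production layout of ~4 nm that is ~0.02 nm per bin).  Biases are
harmonic, evaluated at bin centers; a zero force constant denotes an
unbiased window.  Window free energies start at zero (or at a warm start)
and iterate until the largest change is below tol·RT with tol = 1e−7,
capped at 100 000 iterations; non-convergence raises an error carrying
the last residual rather than returning a half-converged profile.  The
gauge is fixed by pinning F₀ = 0; the PMF is −RT ln P with empty bins
masked as NaN.  Bins are occupied-or-masked, never interpolated.

Convergence slows as window overlap shrinks (the fixed-point contraction
rate is set by adjacent-window histogram overlap); the overlap diagnostic
on `build_histograms` reports shared occupied bins per adjacent pair so
starved layouts are visible before solving.

No autocorrelation-based inefficiency correction is applied (documented
simplification): the Metropolis generator thins its chains, and for real
MD data the bootstrap over whole windows absorbs within-window
correlation into the error estimate.

**Bayesian bootstrap.**  Replicates draw flat Dirichlet weights over
complete windows and scale each window's histogram (hence its effective
sample count) by weight × n_windows; per-sample multinomial resampling is
available as an option.  Each replicate solves WHAM warm-started from the
unweighted solution.  Because every WHAM solution is defined only up to a
constant, replicates are aligned by subtracting their mean over the
occupied bins before the per-bin standard deviation is taken (ddof = 1;
a single replicate yields identically zero stderr).  Zeroing the profile
afterwards shifts the mean curve only.

**Zero-in-bulk and binding ΔG.**  `zero_to_bulk` subtracts the mean free
energy over a caller-chosen bulk interval (idempotent, gauge-invariant).
There is no universally published numeric convention for the bulk and
site intervals; the pipeline default takes the 10% of the coordinate
range farthest from the binding site as bulk and exposes the site
intervals in the config.  Binding ΔG is the profile minimum inside the
site region (bulk ≡ 0), with the bootstrap stderr at the minimizing bin.
ΔΔG between the extended and orthosteric pockets is the plain difference
of the two ΔG values; its error defaults to quadrature, with linear
summation available.  Published error entries for this quantity are
internally inconsistent (three of four match linear sums, one matches
neither), so only the ΔΔG means are treated as reproducible arithmetic.
The occupancy ratio is exp(ΔΔG/RT) with its base-10 order of magnitude
reported as floor(log₁₀ ratio).

## Synthetic data: what it emulates, and what it does not

**Toy receptor.**  330 Cα pseudo-atoms (residues 70–399) on seven ideal
helices (1.5 Å rise, 100°/turn, 2.3 Å helix radius, 14 Å bundle radius,
alternating direction so ICLs join helix bottoms and ECLs helix tops),
an eighth intracellular helix, and quadratic Bézier loop arcs, plus
0.15 Å seeded jitter so no two residues coincide.  Only topology matters:
contiguity, a distinct TM6 block (315–346), and the residue numbering the
metrics rely on.  Masses are uniform (Cα carbon), so mass-weighting is
exercised structurally but not numerically by the toy.

**Reference pair and collapse.**  The open state displaces the TM6 block
rigidly along the unit vector from residue 173's Cα to residue 318's Cα,
so the ionic-lock distance grows by exactly the requested shift (default
8 Å for fully open; 4 Å models a partially-open state).  Collapse
trajectories mix open→closed with a linear schedule λ(t) dropping from 1
to 0 at the collapse frame, plus i.i.d. Gaussian coordinate noise
(default 0.3 Å, a typical Cα thermal fluctuation scale) at 0.1 ns/frame.
Real collapses are stochastic and replica-dependent; the generator
instead exposes the collapse frame deterministically, which is what a
recovery test needs.  Because frames between λ = 0.5 and λ = 0 are
geometrically nearer the closed reference, the "generating schedule" that
a distance-based clustering can recover is the λ > 0.5 partition,
exposed as `schedule_labels`; agreement is measured against that.

**Umbrella windows.**  Samples are drawn from the biased Boltzmann
density ∝ exp(−[U(ξ) + ½k(ξ−x᷈ᵢ)²]/RT), truncated to the potential's
domain, by a Metropolis random walk: step size initialized at 2.5× the
bias width √(RT/k), adapted every 50 burn-in steps toward ~40%
acceptance and frozen afterwards (preserving detailed balance), burn-in
1000 steps, thinning 10.  Any correct sampler of this density is
equivalent for estimator testing; MD time correlation is not emulated.
The production layout mirrors the real protocol: ~40 windows, 0.1 nm
spacing, k = 1000 kJ·mol⁻¹·nm⁻², 310 K.

**Analytic potentials.**  `harmonic`, `piecewise_table`, and
`double_well` — a quartic bump of height h between two minima with
exactly flat shoulders outside them.  The flat shoulders make the domain
max−min equal the barrier parameter and model flat bulk basins, keeping
gradients gentle enough (≤ ~4 kcal·mol⁻¹·nm⁻¹ inside the wells at the
default geometry) that histogram discretization bias, RT·(sΔ/2RT)²/6 for
slope s and bin width Δ, stays below ~0.02 kcal·mol⁻¹.
`analytic_pmf` provides the ground truth on any grid, zeroed to a region
or to its minimum.

**What passing tests show.**  Recovery of the analytic PMF to
< 0.1 kcal·mol⁻¹ RMSE at the production layout demonstrates the
estimator, not force-field or sampling adequacy of any real system;
equally, landscape recovery on the synthetic collapse validates the
PCA/clustering/readout chain, not the biology of receptor activation.
Observables that require μs membrane MD (absolute well depths of real
ligand unbinding, transducer-helix affinities) are out of scope.

The recovered barrier is read off as max − min of the zeroed profile over
occupied bins; with ~200 bins the extremum over many near-flat noisy bins
carries a small positive extreme-value bias (~2–3× the per-bin stderr,
about +0.1 kcal·mol⁻¹ at the production layout), which the tolerance on
barrier recovery absorbs.

## File formats

PDB I/O (single and multi-model) goes through biotite; a pre-scan
validates ATOM records and rejects insertion codes and altlocs with the
offending line number — the toy writers never produce them, and silently
dropping them would corrupt frame congruence.  Residue numbering is taken
as-printed (70–399), never renumbered.  Trajectories also round-trip
through a flat TSV (frame, time_ns, residue_id, atom_name, x, y, z),
which is the plain-text interchange surface; no binary trajectory formats
are parsed, and no periodic-boundary unwrapping is attempted (inputs must
be pre-imaged).  Umbrella datasets load from per-window two-column TSVs
plus a metadata table.  All writers are bit-stable for fixed input;
pipeline JSON is written with sorted keys and 6-significant-digit floats.

## Pipeline defaults and problem sizes

The demo pipeline synthesizes a 400-frame collapse (collapse frame 100,
noise 0.3 Å) and a 40-window umbrella run with 500 samples/window over a
binding-shaped tabulated potential (wells −12.2 and −7.0 kcal·mol⁻¹,
flat bulk), then analyzes with 100 bins and 25 bootstrap replicates —
sizes chosen so a complete demo run stays near ten seconds while leaving
every estimator in its working regime.  The validation suite uses the
full production umbrella layout (40 × 5000 samples, 200 bins, 50
bootstrap replicates) and a 1000-frame collapse for landscape recovery.
With 500-sample windows and 0.04 nm bins the demo underestimates the
sharp tabulated well depth by a few tenths of a kcal·mol⁻¹ (binning over
a kinked minimum); this is a resolution effect, not an estimator bias,
and vanishes at the production sampling density.

## Known limitations

- 1D reaction coordinates only; no periodic coordinates, no 2D surfaces,
  no MBAR production path (an MBAR-style estimator exists in the test
  suite purely as an independent cross-check of window free energies).
- No autocorrelation correction in the error model beyond window-level
  resampling.
- The toy receptor is topological, not physical: no sidechains, no
  membrane, uniform masses, idealized helices.
- Scalar microswitch metrics beyond the A100 constituents (toggle-switch
  rotation, PIF, NPXXY stacking) are not computed; they are
  noted-for-inspection quantities on centroid structures.
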