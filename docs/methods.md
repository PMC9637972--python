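# Methods

`spidec` computes liquid–liquid coexistence (binodals) and interfacial
tension of coarse-grained model systems by letting a homogeneous system
demix spontaneously. A system initialized at a density inside the spinodal
undergoes spinodal decomposition; in a periodic rectangular box (sides
`Lx = Ly`, `Lz >= Lx`) the dense phase settles, depending on the overall
density, into one of a small set of morphologies — sphere, cylinder, slab,
hollow cylinder, hollow sphere — set by the competition between bulk and
surface free energy at finite size. The slab, with two flat interfaces
normal to the long axis, is the morphology from which coexistence densities
and tension are read off.

All quantities are in reduced units: lengths in the bead diameter sigma,
energies in the well depth epsilon, temperature in epsilon/kB, time in
tau = sqrt(m sigma^2/epsilon), density in sigma^-3, tension in
epsilon/sigma^2. All masses are 1.

## Model systems

* **LJ particles** — 12-6 Lennard-Jones truncated at `rc = 3` and shifted so
  the energy vanishes at the cutoff. The force is the bare LJ force inside
  `rc` (so it is discontinuous there; this is the standard cut-shifted
  convention and the dynamics of the source method).
* **LJ chains** — 10-bead homopolymers. Non-adjacent beads interact via a
  *force-shifted* LJ with `rc = 6` (energy and force both continuous at the
  cutoff); adjacent beads interact only through a harmonic bond
  `U = (k/2)(r - 1)^2` with `k = 75,000` by default (the 1/2 convention is
  chosen so quoted spring constants read the same as in common MD engines;
  750 and 75 are supported variants). The nonbonded term is excluded
  *only* between bonded neighbors; all other intra-chain pairs interact.
* **HP chains** — like LJ chains but with two bead types: H–H attracts via
  the force-shifted LJ, H–P and P–P are purely repulsive WCA (LJ truncated
  and shifted at its minimum 2^(1/6)). The default decamer carries P beads
  at positions 1 and 5 (one-based); a variant has them adjacent at 5 and 6.
  The interaction matrix is a per-type-pair table, so other alphabets are
  configurable.
* **Patchy particles** — Kern–Frenkel hard spheres with four circular
  patches at tetrahedron vertices and a square well of range
  `lambda = 0.5` beyond the hard core. Two particles in the well gain
  `-epsilon` for every patch pair (alpha, beta) whose cones both contain
  the inter-particle direction. The patch half-angle cosine defaults to
  **0.65** (half-angle 49.46 degrees): with tetrahedral centers the four
  caps are then exactly disjoint and cover exactly a 0.7 fraction of the
  particle surface (4 x (1 - 0.65)/2), and a pair can form at most one
  bond — the tetravalent limited-valence model. A wider published value of
  the same parameter (0.35) is inconsistent with 0.7 coverage: caps of
  half-angle arccos(0.35) = 69.5 degrees overlap so strongly that their
  union covers 99.95% of the sphere (the minimum over directions of the
  largest dot product with the four tetrahedral axes is 1/3 < 0.35), which
  would make bonding nearly isotropic with pair energies down to
  -16 epsilon; we therefore take the coverage statement as defining the
  geometry and note that 0.35 = 1 - 0.65. The parameter remains settable.

## Engines

**Langevin MD** (`spidec.md`): velocity Verlet with the BAOAB splitting of
the Langevin thermostat. Friction defaults to 0.1 m/tau; time step 0.005
tau for particle systems and 0.001 tau for chains (stiff `k = 75,000`
bonds; with the softer `k = 750` variant 0.005 is stable). With friction 0
and noise off the integrator reduces to plain velocity Verlet and conserves
energy to ~1e-5 over 1e4 steps, which the suite checks. Neighbor search is
a linked-cell half-pair list with a 0.3-sigma skin rebuilt when any
particle has moved half a skin; boxes too small for a 3x3x3 grid fall back
to an all-pairs list, and the grid dimensions are capped so binning stays
O(N) even for sub-resolution cutoffs. Random insertions may contain
overlaps; instead of rejection sampling, drift displacements are clipped to
0.05 sigma per half-step for the first 1000 steps and the thermostat
relaxes the rest (insertions also keep a 0.7-sigma minimum separation for
soft particles, 0.9 for chain beads, 1.0 for hard cores, so the capped
start never sees catastrophic forces). The diagonal pressure tensor
p_aa = (sum m v_a^2 + sum_pairs r_a f_a)/V is sampled every 10 steps by
default; bonds contribute to the virial. Gaussian thermostat noise comes
from a NumPy `Generator` seeded by the run seed, so trajectories are
bit-reproducible per seed on a fixed platform.

**Metropolis MC** (`spidec.mc`): one step is a sweep of one attempted move
per particle. Patchy particles attempt a displacement or a rotation with
equal probability: displacements uniform in a cube of side 0.09 sigma;
rotations draw a new body z axis uniformly inside a spherical cap of
half-angle 0.05 rad about the current z axis, rotate about the line of
nodes, then spin about the new z axis by an angle uniform in (-0.05, 0.05).
This proposal is symmetric, so plain Metropolis acceptance preserves
detailed balance; the suite verifies sampling against a two-particle
Boltzmann quadrature oracle. Hard-core overlaps are always rejected
(implemented with a large finite sentinel energy). LJ-particle MC uses
displacements only, with the same cube side by default. The total energy is
tracked incrementally from accepted deltas and agrees with a full
recomputation to 1e-8 over >1e4 moves. For LJ particles an MC pressure
tensor replaces the kinetic part with the ideal term rho*T; for patchy
particles the pressure tensor is undefined (discontinuous potential) and
requesting it raises.

## Analyses

* **Density profiles.** Slices of default thickness 0.1 sigma (fitting) or
  1 sigma (slab counting) along the slab normal. Each frame is recentered
  so the center of mass sits at the box middle; under periodic boundaries
  the center of mass per axis is the *circular (angular) mean*, which is
  translation invariant where the naive mean is not. When the box is close
  to cubic the slab normal may lie along x or y; the analysis axis is the
  one with the largest density contrast.
* **Interface fit.** The averaged profile's positive half is fit by least
  squares to `rho(z) = (rho_d + rho_b)/2 - (rho_d - rho_b)/2 *
  tanh((z - z0)/w)`, giving the dense and bulk densities, interface
  position and width, with standard errors from the covariance. Degenerate
  inputs (flat profile, fitted width exceeding the half box, dense < bulk)
  raise instead of returning numbers; the phase-point extractor also
  requires the coarse slice sequence to contain exactly one slab.
* **Slab counting.** Slices are labeled H above `rho_H` (default 0.55) or
  L below `rho_L` (default 0.25) — the centers of the working ranges
  0.5–0.6 and 0.1–0.4 — with intermediate slices filtered out; H/L
  transitions on the circular sequence are interfaces and slabs =
  interfaces/2.
* **Timescales.** The phase-separation time tau_PS is the first time the
  maximum slice density reaches its plateau, the plateau being the median
  of the final quarter of the series (replacing by-eye tuning with a fixed
  rule); a first crossing inside that final quarter means the system is
  still coarsening and is reported as not converged. The single-slab time
  tau_SS is the first time the slab count reaches 1 and stays there for at
  least 5 saved frames (an anti-flicker guard; a literal "first time" is
  sensitive to single-frame noise).
* **Morphology.** Frames are recentered and histogrammed on a 3-D grid of
  ~1 sigma cells, averaged over the window, and thresholded at the midpoint
  of the H/L cutoffs. Labels come from the spanning dimensionality of
  periodic connected components (BFS that detects non-zero winding):
  a dense component spanning 0/1/2 directions is a sphere/cylinder/slab;
  a dense phase percolating in all 3 directions is hollow, named by the
  largest dilute component (ball -> hollow sphere, rod -> hollow cylinder);
  a shell or tube enclosing a separate dilute pocket is likewise hollow.
  Components below 3 voxels are noise. Multiple dense components yield the
  largest one's label plus an ambiguity flag.
* **Interfacial tension.** Kirkwood–Buff: gamma = (Lz/2) <pzz - (pxx +
  pyy)/2>, averaged over the second half of the run or from tau_SS to the
  end when fusion completes late (the same windowing rule used for
  densities), with a 5-block standard error. The Lz/2 factor accounts for
  the two interfaces of a periodic slab.
* **Chain Rg.** Chains are unwrapped bond-by-bond across periodic images
  (a bond longer than a quarter box after minimum imaging is an unwrap
  ambiguity and raises); the dense-phase selector keeps chains whose
  center lies within the fitted interface position z0 of the slab center.
  Both the mean and the root mean square of the per-chain Rg distribution
  are reported; closed-form ideal-chain references use the RMS.
* **Concentration conversion.** For all-atom peptide profiles, number
  densities of molecule centers (per cubic Angstrom) convert to wt/wt as
  rho * MW / (0.602214076 * water density in kg/L).

## Phase-diagram aggregation

* **Critical point.** The binodal is fit jointly (shared T_c, rho_c) to the
  rectilinear diameter `(rho_b + rho_d)/2 = rho_c + A(T - T_c)` and the
  order parameter `rho_d - rho_b = B(T_c - T)^beta` with the 3-D Ising
  exponent beta fixed at 0.32, by least squares; standard errors come from
  the Jacobian. Temperatures within 2% of the running T_c estimate are
  excluded and the fit repeated once, because near-critical slabs in
  finite boxes bias both densities; a non-monotone width sequence warns.
* **Boundary scans.** For each (aspect, rho0) a short simulation from a
  fresh random insertion (lattice for MC) is classified after its
  phase-separation time; runs extend adaptively to about 5x tau_PS within
  a cap. The label per density is the majority over seeds; boundaries are
  midpoints between adjacent differing labels, and a density with no seed
  majority contributes itself as the boundary (tie rule). The lowest and
  highest boundaries are effective spinodal densities: on the
  spinodal-decomposition timescale, metastable initial densities stay
  homogeneous.
* **Elongation scaling.** Boundary densities follow
  `rho0 = (rho_1 + rho_inf * xi)/(1 + xi)` with `xi = Lz/Lx - 1`; the fit
  is linear after multiplying through by (1 + xi). Lower (or upper)
  transitions can share a single extrapolated density rho_inf (one joint
  design matrix) or be fit separately; both are exposed because the
  published common values could come from either protocol.
* **Closed-form references.** The van der Waals fluid (units of T_c and
  rho_c; spinodal from dP/drho = 0, binodal from a Maxwell construction
  solved by bracketing the coexistence pressure and equating chemical
  potentials to 1e-10) and the symmetric Flory–Huggins blend (spinodal
  chi = [1/phi + 1/(1 - phi)]/(2L), critical point phi = 1/2, chi_c = 2/L,
  binodal from df/dphi = 0 at phi != 1/2) provide analytically closed
  binodal/spinodal geometry for plots and tests.

## Synthetic data and oracles

The `spidec.fixtures` module generates everything the analysis tests need
without long simulations: forward-generated tanh profiles with Gaussian
noise; ideal-gas two-phase configurations with exact plateau densities;
freely jointed chains (mean-square Rg = b^2(n^2 - 1)/(6n), = 1.65 for ten
unit bonds, RMS Rg 1.2845); deterministic Fibonacci-lattice spherical
quadrature for patch coverage (union by point-in-any-cap, converged to
<1e-3 on refinement); periodic voxel masks of every morphology; a
preformed-slab initializer (classical-slab-style start used where the test
needs two-phase equilibrium without waiting out spinodal decomposition);
and a two-particle Boltzmann oracle that factorizes the patchy partition
sum into cap-count distributions (valid whenever the box holds a full
interaction shell) and refines its quadrature to prove convergence.

These fixtures emulate the *statistics* the analyses consume — plateau
densities, interface shapes, morphology topology — not the dynamics or
correlations of real trajectories; passing them shows the estimators are
correct, while the engine-level tests (energy conservation, equipartition,
detailed balance against quadrature, exact-sampler cross-checks) cover the
sampling itself.

## Problem sizes and scaled-down study conditions

The default test run and the acceptance script use desk-scale versions of
the study conditions, chosen once: boundary scans use a 10-sigma box with
3 seeds per density and runs of 0.6–1.2 x 1e5 MD steps (several times the
phase-separation time at these sizes); slab equilibria for monotonicity and
tension checks use Lx = 7–12.7 boxes with a few hundred to ~700 particles
or beads started from preformed slabs; chain checks run the soft-bond
variant `k = 750` at dt = 0.005, justified by the published insensitivity
of the binodal and of the dense-phase Rg to the spring constant; the
dense-phase Rg check uses 102 chains. Full-size binodal curves (N = 4,000,
1e7–1e8 steps, Lz/Lx up to 33) are out of desk reach and are covered
instead by scaled-down monotonicity and MD-vs-MC agreement properties.

## Known limitations

* The pressure tensor for cut-shifted LJ uses the bare force inside the
  cutoff (consistent with the dynamics); tensions therefore carry the
  truncation convention of the source method and no tail corrections.
* Configurational-temperature thermometers based on |grad U|^2 / lap U are
  exact in expectation but their sampling variance for a steep 12-6 core is
  impractical; the suite instead calibrates <U> against the exact
  Metropolis sampler to verify the thermostat's configurational ensemble.
* Curvature corrections for spherical/cylindrical interfaces, capillary-
  wave analysis and Voronoi phase assignment are out of scope; tension is
  only meaningful for slabs.
* Gelation / arrested decomposition is reachable with the engines (low T)
  but is not a tested deliverable.
* The morphology classifier needs the dense and dilute plateaus to bracket
  its threshold; systems whose coexistence densities both lie on one side
  of 0.4 need the cutoffs overridden.
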