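# Methods

This note documents the models implemented in `sopes`, the unit
conventions, the defaults that matter, and the numerical and design choices
made where more than one reasonable option existed.

## Units and conventions

All energies are wavenumbers (cm⁻¹). Toy systems live in a natural unit
system with ħ = 1: coordinates are dimensionless, energies cm⁻¹, and the
unit of mass is fixed so that the kinetic term (1/2m)∂² is also in cm⁻¹; a
harmonic well V = a q²/2 with unit mass then vibrates at √a cm⁻¹, so
curvatures of 10⁶–10⁷ cm⁻¹ give molecule-like frequencies of 800–3200 cm⁻¹.
One natural time unit is 1/(2πc·1 cm⁻¹) ≈ 5308.8 fs; trajectory time steps
are supplied in femtoseconds and converted internally. Conversion constants
(kcal/mol → cm⁻¹ = 349.755…, hartree → cm⁻¹, the
hartree/(bohr²·amu) → cm⁻¹ frequency factor) are derived from scipy's
CODATA tables once at import in `sopes.units`.

Grid indices are 0-based; coordinate ranges are closed; angles are in
radians (an angular range written as [0, 2π/2] is read as [0, π]).
Imaginary harmonic frequencies are printed as negative wavenumbers, the
quantum-chemistry table convention. Reported fit RMSEs are always the
square root of the *unweighted* mean-square residual of relative energies
(relative to the global-minimum reference geometry); the fit objective
itself is weighted and carries no square root, so χ and RMSE² differ
whenever the weights do anything.

## DVR grids

Two DVR families are implemented. The harmonic-oscillator (Hermite) DVR is
parametrized by (N, first, last): the unit Gauss–Hermite nodes (eigenvalues
of the position operator in the lowest N oscillator functions) are mapped
affinely so the outermost nodes sit exactly at the requested range — ranges
are what grid tables specify, and this mapping makes the specification
exact. The cosine DVR uses the N midpoints of the range with the
{cos(jπ(x−a)/L)} basis (Neumann boundaries), whose kinetic matrix is exact
on sampled basis functions. The stored `kinetic` matrix is the mass-free
−∂² representation; Hamiltonians divide by 2m per DOF.

The multigrid structure takes each DOF's coarse index set as the arithmetic
progression {0, k, 2k, …} (`from_first`); a variant also keeps the last
index. Published benchmark coarse-grid point counts for the 6D HONO grid
(172,800 / 51,200 / 18,432 for strides 3/4/5) are not reproducible from any
straightforward stride rule on the printed primitive grid — the original
code's subsampling convention is not documented — so coarse counts here are
always reported from the actual configuration and never asserted against
those figures.

## POTFIT and Multigrid POTFIT

Exact POTFIT forms, per DOF, the potential density matrix
ρ⁽κ⁾ = V_(κ) V_(κ)ᵀ (mode-κ unfolding), takes its leading eigenvectors as
single-particle potentials, and projects the grid tensor onto them. At full
rank the reconstruction is exact; truncating one mode loses exactly the sum
of its discarded eigenvalues in squared L2 grid norm (tested).

Bottom-up MGPF evaluates the backend only on the coarse direct-product grid
(core tensor) and, per DOF, on the partial grid that is full along that DOF
and coarse along the others. From coarse–coarse ρ⁽κ⁾ and mixed fine–coarse
ρ⁽κ⁾′ it builds γ⁽κ⁾ = ρ⁽κ⁾′·pinv(ρ⁽κ⁾); the Tucker potential is the coarse
tensor contracted with the γ factors. Design choices:

- **Pseudo-inverse.** ρ is inverted through an eigenvalue-thresholded
  pseudo-inverse, default threshold 10⁻¹² of the largest eigenvalue; the
  condition number is logged. Because ρ is a Gram matrix, components of V
  below ~√ε ≈ 10⁻⁸ of its grid norm are unrecoverable in double precision;
  for a surface whose repulsive walls reach 10⁶ cm⁻¹ that is an absolute
  floor of order 1 cm⁻¹ on the reconstruction, which sets the accuracy
  plateau seen at small strides.
- **No special contracted mode.** All DOFs are treated symmetrically (each
  gets a full-along-itself partial grid); there is no separately optimized
  contracted mode.
- **Determinism.** Backend calls are cached by full-grid index and issued in
  lexicographic order, so call counts and logs are reproducible; coarse
  points shared between the coarse and partial grids are evaluated once,
  giving n_calls = |coarse| + Σ_κ(|partial_κ| − |coarse|).
- **Error reporting.** The decomposition reports RMSE over the points it
  already evaluated (coarse + partial); independent full-grid or seeded
  random-sample RMSE is available separately, since the benchmark "global
  RMSE" sampling scheme is not specified.

## Toy surface family

The synthetic reference backend is a chain of coupled wells attached to one
periodic torsion:

V = Σ_κ a_κ(q_κ−r_κ(φ))²/2 + Σ_{κ<λ} b_κλ(q_κ−r_κ)(q_λ−r_λ)
  + c₁(1−cos φ) + c₂(1−cos 2φ),  r_κ(φ) = q0_κ + d_κ cos φ.

It emulates a cis/trans isomerizing molecule: two inequivalent torsional
wells (φ = 0, π) separated by a barrier ≈ 2c₂ + O(c₁), chain equilibria
that shift along the torsion, and bilinear mode coupling. The reference
instance draws, per seed: chain frequencies √a uniform in 800–3200 cm⁻¹,
shifts d in 0.02–0.08, couplings b at 2–6 % of √(a_κ a_λ), q0 in 1.5–2.5
(bond-length-like), and fixes c₂ = 2000 cm⁻¹ (barrier ≈ 4000 cm⁻¹, the
scale of a torsional isomerization) and c₁ = 150 cm⁻¹ (a few-hundred-cm⁻¹
well asymmetry). Parameter bounds for recovery experiments are ±50 % of the
true values — wide enough that a 20 % perturbed start is an honestly bad
surface, bounded enough that a box-constrained search is meaningful.

Because this functional form is polynomial in the chain coordinates and
low-order Fourier in φ, its Tucker rank is small (≤ 3 per DOF) and coarse
grids of four points already decompose it exactly — useless as a multigrid
stress case. The anharmonic member of the family therefore replaces the
harmonic wells by Morse wells via y_κ = (1−e^{−α_κ δ_κ})/α_κ (curvatures at
the minima are unchanged), and its reference instance amplifies the d
shifts to 0.1–0.3. The factor e^{α d cos φ} then carries an infinite
Fourier series, so the surface has no finite-rank SOP form; this is the
backend on which multigrid stride convergence is measured. What these toys
do *not* emulate: dissociation channels, multiple wells per chain
coordinate, permutational symmetry, or the curvilinear kinetic couplings of
a real molecule — conclusions from passing tests are about the fitting and
decomposition machinery, not about any specific molecule's spectroscopy.

## Reference datasets

Displacement sets follow an n-body scheme around pivot stationary points:
1D cuts (others frozen at the pivot; the pivot itself excluded), 2D product
grids per coordinate pair, seeded uniform random full-D points, and linear
interpolation in internal coordinates (LIIC) between stationary points,
with periodic DOFs interpolated along the shorter arc. Displacement
amplitudes default to the curvature-scaled value √(2E/H_κκ) with
E = 3000 cm⁻¹, i.e. points land in the chemically relevant energy window
rather than on the repulsive walls (where exponential down-weighting would
waste them). Around a LIIC path, clouds are generated by blending the
endpoint normal-mode matrices with the normalized path ordinate
X_i = i/(n−1) — normalized so the endpoints use purely their own modes —
and displacing by uniform random factors in (−s, s), default s = 0.1, with
the reaction-coordinate-like mode excludable. Energy filters are inclusive
at the cutoff. Stages are concatenations of these classes, deduplicated by
rounded-geometry hash, each emitting a ledger row (class composition and
count, which always sums to the entry count). Stage compositions are fully
configurable; no particular published stage sizes are enforced.

## Optimization protocol

The fit objective is χ₀ (two-term) or χ₁ (concatenated, default). Weight
defaults: α_E = 4000 cm⁻¹ (the barrier scale), β_E = −10⁻³ per cm⁻¹;
α_F = 100 cm⁻¹, β_F = −10⁻². Frequencies are compared mode-by-mode after
ascending sort, with no mode tracking across parameter sets. A failed
backend evaluation or stationary-point refinement inside the objective
returns a finite penalty (10⁶, flagged) so derivative-free searches
survive.

The global step is a multistart search with single-linkage clustering:
seeded uniform starts ranked by objective value, local descents launched
only from starts not within the shrinking critical radius
r_k = σ(log k/k)^{1/D} of an already-descended start. Local descents use
scipy's bound-constrained Powell method — a derivative-free quadratic-model
descent filling the same role as BOBYQA-style minimizers, chosen because it
is the strongest such method available in the scientific Python stack.
Staged fitting runs global+local on the first (small, representative)
stage and warm-started local refits on each later stage; the per-stage
ledger records counts, best χ, unweighted RMSE, and percent parameter
deviation from the start.

## Stationary points, trajectories, eigenstates

Hessians are central-difference from energies (default step 10⁻³ in native
units, optional Richardson extrapolation), symmetrized. Refinement is plain
Newton with a step cap, validated against the requested Hessian signature —
converging to the wrong index is an error carrying the point, never a
silent success. Normal-mode sampling partitions the requested energy over
modes by a uniform simplex draw (sorted-uniform spacings) and assigns each
mode a harmonic displacement/velocity at a uniform random phase; this is a
documented stand-in for the classical normal-mode sampling options of
legacy trajectory codes, whose exact distributions are unspecified.
Velocity-Verlet stores every frame including t = 0 (1 ps at 5 fs → 201
frames per trajectory). Two drift measures are reported: the max total-
energy deviation (a bounded (ωΔt)² symplectic oscillation) and the secular
drift (windowed end-vs-start mean), which is the meaningful conservation
metric; trajectory protocols at a 5 fs step use a heavy-mass (m = 100)
setting so the fastest toy mode stays within the integrator's stability
limit, as one would choose time steps below ~T/10 for a real molecule.

The eigensolver assembles H = Σ_κ T⁽κ⁾/(2m_κ) ⊗ I + diag(V) on product
grids of ≤ 3 DOFs (dimension cap 20,000; dense diagonalization below 2,500,
shift-invert-free Lanczos above). It deliberately replaces wavefunction-
contraction machinery: the 6D pipeline ends at the decomposed SOP file, and
the kinetic operator is diagonal-mass Cartesian-like — real curvilinear
kinetic couplings are out of scope. Level-comparison metrics (RMSE and
mean absolute deviation) run over all reported rows *including* the zero
ground-state row; this convention reproduces published benchmark RMSE rows
exactly, whereas the corresponding published MAD row matches no
mean/median/max convention we could identify and is therefore reported but
never asserted against. Spectra from autocorrelation functions propagate by
spectral expansion in the eigenbasis with a Hann window.

## Problem sizes

The validation suite runs 12³ decomposition grids, 10×10×12 eigensolver
grids (k = 6), three-stage fits of ~50/85/165 points in a 9-parameter
space, 10-seed recovery experiments, and 80×201-frame trajectory batches —
sizes chosen so every experiment has fully converged behavior on a single
core in seconds while exercising the same code paths a production 6D
surface would use.

## Known limitations

- MGPF accuracy bottoms out at the Gram-matrix floor (~10⁻⁸ of the grid
  norm of V); surfaces whose walls tower over the region of interest limit
  the achievable absolute accuracy there. Relevant-region weighting inside
  the decomposition is not implemented.
- The external-program adapter runs one process per geometry and caches by
  (geometry, parameter) hash; it does not batch or parallelize.
- No mode combination (logical particles), no CP/tensor-train formats, no
  IRC integration (LIIC is the path surrogate), no excited-state surfaces.
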