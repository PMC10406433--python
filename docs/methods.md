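# Methods

## The fractal scaling model

`condenscale` treats a biomolecular condensate as a statistical fractal
built by iterative association of clusters.  Two per-molecule descriptors
parameterise everything:

- **compactness** φ ∈ (0, 1] — the ratio of a chain's van der Waals volume
  to its hydrodynamic (apparent) volume; an entropic descriptor of how
  densely a disordered chain fills its own envelope;
- **valency** n > 0 — the average number of simultaneously bound partner
  chains; an enthalpic descriptor of the interaction network.  n is an
  ensemble average and is treated as continuous.

Monomers (apparent radius R₀, mass M₀) associate into clusters of n + 1
members; clusters associate again with the same valency, and at every
level the sub-clusters fill the same fraction φ of the parent's apparent
volume.  With i = 0 the monomer, iteration i has

    N_i = (n+1)^i            molecules
    V_i = V₀ ((n+1)/φ)^i     apparent volume,  V₀ = (4/3)πR₀³
    R_i = R₀ ((n+1)/φ)^{i/3} apparent radius
    M_i = M₀ (n+1)^i         mass
    C_i = C₀ φ^i             effective molar concentration, C₀ = 1/(N_A V₀)

so mass and size obey M ∝ R^{d_f} with

    d_f = 3 ln(n+1) / ln((n+1)/φ),

and the fractal prefactor is exactly k_f = 1 (N_i = (R_i/R₀)^{d_f} holds
identically, which the test suite asserts to ten significant figures).
d_f → 3 as φ → 1 (space-filling), and d_f grows monotonically with both φ
and n.  Units are fixed to nm / kDa / mM and regressions use log base 10,
which makes the intercept of the log M–log R line unit-stable.

`invert_fit` is the exact inverse of this forward map: from a fitted slope
A and intercept B plus the monomer mass and van der Waals volume it
recovers R₀ = 10^{(log₁₀M₀ − B)/A}, φ = V_vdw/((4/3)πR₀³) and
n = exp(A ln(1/φ)/(3 − A)) − 1.  The round trip
forward → regression → inverse is the identity to at least six significant
figures, property-tested over random parameter draws.

The scale-dependent concentration C(R) = C₀ (R/R₀)^{d_f−3} encodes the
defining fractal property that density falls off as a power of the length
scale (exponent d_f − d in d = 3 dimensions): a condensate can be locally
concentrated and globally dilute at the same time.  `isocurve_phi_of_n`
inverts C(R) = const for φ at fixed valency by bisection on φ ∈ (1e-4, 1]
(relative tolerance 1e-8); the monomer radius depends on φ through the
chain's van der Waals volume, estimated from the mass with the standard
protein partial specific volume 0.73 cm³/g unless given explicitly.
Percolation context is provided by the Flory–Stockmayer threshold
p_crit = 1/(n − 1), with a flag for 1 < n < 2 where the nominal threshold
exceeds 1.

## Descriptors from multi-chain coordinates

Contacts use the all-atom minimum interatomic distance between chains
under the minimum-image convention in a cubic periodic box, cutoff
0.35 nm.  Distances are computed with periodic k-d trees; every tested
random scene is asserted identical to a brute-force all-pairs oracle with
explicit minimum-image arithmetic.  Residue-pair events are deduplicated
to one event per residue pair per frame so that large residues do not
dominate the statistics; intra-chain contacts exclude neighbours closer
than two positions in sequence.  Valency is the per-frame degree of the
chain contact graph; contact probability assumes a well-mixed system,
p = ⟨valency⟩/(n_chains − 1).  Chain clusters are the connected components
of the contact graph — exactly what single-linkage clustering of the
minimum-distance matrix cut at the contact cutoff produces — and the
largest cluster's radius of gyration is evaluated after unwrapping member
chains along a spanning tree of the cluster.

Contact enrichment compares observed unordered residue-type pair
frequencies with the random expectation from sequence composition, using
f_A² for homotypic and 2 f_A f_B for heterotypic pairs so both tables
normalise to one; the symmetry factor keeps ENR = 1 as the exact null (a
uniform null with 10⁵ events reproduces 1 within 5%).  1D interaction
profiles (dynamic interaction modes) collapse position-resolved contact
counts onto the sequence; the representative mode averages the four
profiles — among chains whose rounded valency (half-to-even) matches the
rounded system mean — that maximise the summed pairwise Pearson
correlation, found exhaustively for up to 20 eligible chains and greedily
beyond, with a QC gate at Pearson R > 0.6 against the all-chain average.

Compactness is measured as φ = V_vdw/V_h: the union-of-spheres van der
Waals volume (Bondi radii, voxel grid at 0.05 nm — the volume error is
bounded by a refinement test at ~1%) over the hydrodynamic volume
(4/3)πR_h³.  The default R_h is the Kirkwood double sum
R_h⁻¹ = N⁻² Σ_{i≠j} 1/r_ij; a compact-sphere mapping R_h = √(5/3)·Rg is
available where a cruder estimate suffices, and R_h can be overridden.
The random-coil reference Rg = 0.254·N^0.522 nm uses the empirical
scaling law for disordered proteins.  Analysis windows default to the
trailing 30% of frames, where valency, compactness and cluster size
plateau in equilibrated systems.

The configurational-entropy helper normalises per internal degree of
freedom, ΔS = [S_mut/(3N_mut−6) − S_wt/(3N_wt−6)]·(3N_mut−6), and reports
T·ΔS (T = 310 K default); entropy values themselves are inputs, not
estimated here.

## Transport

Diffusion: MSD = c + 6 D_PBC τ is fitted by least squares inside a linear
window (defaults 20–40 ns for crowded multi-chain systems, 5–15 ns for a
single chain); the finite-size correction D_t = D_PBC + k_B T ξ/(6πηL)
with ξ = 2.837297 removes the hydrodynamic self-interaction of a particle
with its periodic images in a cubic box, and D_pred = D_t·η_sim/η_expt
rescales to the experimental solvent viscosity (0.69 mPa·s at 310 K;
simulated water models are typically more viscous, e.g. 0.83 mPa·s).

Viscosity: the Green–Kubo integral η = V/(k_B T)·∫C(t)dt over the
autocorrelations of the six deviatoric pressure components (P_xy, P_xz,
P_yz and the three half-differences of diagonal elements).  The ACF is
estimated by FFT with unbiased normalisation, integrated by trapezoid on
[0, 1] ps, and continued analytically with a double-exponential fitted on
[1, 5] ps (tail integral a·b·e^{−t₁/b} + c·d·e^{−t₁/d}); η is the mean
over components.  The tail fit bounds its decay constants by the fit
window's end: a slower component cannot be resolved by the window, and
letting one float makes the extrapolated integral chase correlated ACF
noise.  Unit conversion (bar²·nm³·ps/k_BT → mPa·s) is centralised and
covered by a hand-computed unit test.

## FRAP and shape

Recovery curves normalised to a pre-bleach intensity of 1 are fitted with
C(t) = 1 − a·e^{−t/τa} − b·e^{−t/τb} by bounded nonlinear least squares
(amplitudes ≥ 0, times within a window derived from the sampling range)
from eight deterministic multi-starts, keeping the best residual;
components are ordered τa ≤ τb, and fits that collapse to a single
exponential are accepted and flagged.  The half-time solves
C(t) = C(0) + ½(1 − C(0)) by bracketed root finding — half of the bleached
depth recovered — which reduces to the plain C = 0.5 crossing when
a + b = 1.  At realistic noise the amplitude/time-constant split of a
double exponential is sloppy: single-curve fits reach their global optima
yet individual amplitudes scatter beyond 10%; the bleach depth a + b and
the half-time are the per-curve identifiable quantities, and parameter
recovery is therefore validated as estimator bias over many curves.
Curves are assumed photobleaching-corrected upstream.  Circularity
4π·area/perimeter² consumes precomputed segmentation results.

## Fractal aggregate reconstruction

`build_aggregate` generates particle aggregates obeying N = k_f (R/a)^{d_f}
with k_f = 1, where the aggregate radius is defined by R² = Rg_c² + a²
(Rg_c the centre-point radius of gyration, a the mean primary-particle
radius) so a single particle satisfies the law exactly.  Construction is
hierarchical cluster–cluster aggregation: clusters merge pairwise,
smallest first (a balanced binary hierarchy for any N).  For each merge
the centre-of-mass separation Γ is solved from

    Rg_c,N² = (N₁ Rg₁² + N₂ Rg₂²)/N + (N₁N₂/N²)Γ²

so the merged cluster lands exactly on its target radius; one particle
from each cluster is brought into contact (a randomly chosen pair among
those that can geometrically realise Γ), the satellite cluster is rotated
to place its contact particle while leaving a free spin angle, and the
configuration is rejected on any sphere overlap beyond the 1e-3
tolerance.  Where the touching constraint makes the exact law infeasible
(only the smallest clusters, N ≲ 8: two touching monomers cannot be closer
than 2a), Γ is clipped to the nearest achievable value and the actual
radius recorded.  Recorded (N, R) pairs for N ≥ 16 satisfy the scaling law
exactly; regression over the records recovers d_f to within ±0.15.
Geometries are bitwise deterministic under the master seed.

`measure_df` estimates d_f from the cumulative mass profile.  The default
is the sandbox estimator: N(<r) averaged over the quarter of particles
nearest the centre of mass as reference centres, fitted on log–log axes
from 2⟨a⟩ up to 0.8 of the usable radial extent with √N weights (counts
are Poisson-like).  A single-centre profile (`method='com'`) is also
provided but is a poor estimator for k_f = 1 hierarchies: balanced merges
can leave the global centre of mass in a void between lobes, so
single-realisation COM profiles mis-measure d_f by up to ±0.5 while the
correlation (sandbox) dimension is stable to about ±0.1.  The closure
build → measure recovers d_f within ±0.2 across {1.63, 2.09, 2.42} —
chain-like, intermediate and densely packed condensate topologies.

`decorate` replaces each spherical particle by the conformer whose radius
of gyration is nearest the particle radius (random tie-breaking, mismatch
above 25% is an error), randomly rotated, centre of mass on the particle
centre.  Steric clashes between neighbouring chains are permitted, as in
visual models of condensate interiors; no energy minimisation is
attempted.

## Synthetic data: what it does and does not emulate

The fixtures module generates every input with known ground truth:

- **Polymers** are self-avoiding bead walks, 4 carbon-radius pseudo-atoms
  per residue, bond 0.38 nm.  Compact mode confines the walk to a sphere
  sized so Rg falls below the random-coil reference; extended mode uses a
  persistent walk above it.  They exercise the Rg/volume/contact code
  paths but carry no chemistry: no sequence-specific energetics, no
  secondary structure, no realistic dihedral statistics.
- **Scenes** plant an exact chain contact graph: chains are atom blobs
  whose centres are laid out by BFS-seeded, step-capped stress relaxation
  so that planted edges have minimum interatomic distance ≤ 0.3 nm and
  non-edges ≥ 0.6 nm — margins on both sides of the 0.35 nm cutoff, making
  descriptor output invariant to cutoff choices in [0.33, 0.40] nm.
  Dense planted graphs (e.g. large cliques) may be geometrically
  unembeddable and fail packing with an error.
- **FRAP curves** sample the double-exponential model on a log-spaced
  grid, 32 points to 20 min by default (a typical acquisition protocol),
  with additive Gaussian noise.
- **MSD series** are exact lines 6Dτ + c with optional Gaussian noise —
  they test the fitting chain, not Brownian-path statistics.
- **Pressure series** are Ornstein–Uhlenbeck processes whose ACF integral
  equals the planted viscosity, 40 ns at 10 fs sampling with a 1.5 ps
  decorrelation time by default: long enough that the Green–Kubo
  tail-fit estimator is statistically converged (recovery within 5%),
  with the decay inside the 1–5 ps fit window as for real pressure
  fluctuations.

Passing tests on these fixtures demonstrates the correctness of the
estimators and the internal consistency of the model chain, not the
physics of any particular protein system: no force field, hydrodynamics
or chemistry is simulated.

## Numerical choices and limitations

- Problem sizes in the test suite: 1024-particle aggregates (5 seeds ×
  3 fractal dimensions) for the builder closure, 5-chain scenes for the
  contact oracles (30 seeds), 50 FRAP curves, one 40 ns pressure series —
  sizes at which every estimator is converged while the full suite stays
  fast.
- The box-concentration formula C = N/(N_A L³) uses the nominal cubic
  edge; equilibrated constant-pressure boxes contract slightly, so
  concentrations printed from equilibrium volumes can differ in the last
  digit (6.8 vs 6.9 mM for 24 chains at 18 nm).
- Heterogeneous chain lengths are supported by the container and the I/O
  layer (decorated aggregates), but contact statistics require equal
  sequence lengths.
- PDB output switches to XYZ (with a JSON chain-map sidecar) when
  coordinates overflow the fixed-width PDB fields, as µm-scale aggregates
  do; chains beyond 62 are identified by 4-character segment ids.
- The builder's merge search is rejection sampling; pathological targets
  (d_f near 3 with strong polydispersity) can exhaust the attempt budget
  and raise, suggesting relaxation.
- `fit_frap` multi-starts are deterministic (seeded); identical inputs
  give identical fits.
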