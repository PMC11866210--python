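# Methods

This note documents the models, conventions and numerical choices behind
`advib`, and what the synthetic fixtures do and do not establish about real
data.

## Trajectory handling

A trajectory is a fixed atom set sampled at a fixed stride (default
0.25 fs, typical of surface AIMD).  All internal quantities use Å, fs, amu
and K; the derived energy unit is amu·Å²/fs² and the Boltzmann constant is
8.31446261815324×10⁻⁷ amu·Å²/fs²/K (CODATA).  Wavenumbers enter only at
the spectrum boundary through the exact speed of light,
c = 2.99792458×10⁻⁵ cm/fs; at 0.25 fs sampling the Nyquist wavenumber is
≈ 66 712 cm⁻¹, so nothing in the chemical range can alias.

Because the initial motion of any MD run is biased by its starting
geometry, analyses should discard an equilibration span first
(`trim_equilibration`; 1 ps is a common choice at a 0.25 fs step).
Averaging positions under periodic boundaries is meaningful only after
`unwrap`, which makes every frame-to-frame displacement the minimum-image
one (first frame anchored; idempotent; cells are assumed fixed over the
run and variable cells are rejected).  When files carry only positions,
`derive_velocities` uses central differences, v(t) = [x(t+Δt) −
x(t−Δt)]/2Δt, dropping the two endpoint frames; this is exact for motion
affine in time and second-order accurate otherwise, and both stored and
derived velocities are supported because archival trajectories come both
ways.

## Glide symmetry

Adsorbate overlayers can show a mirror-plus-half-lattice-translation
symmetry *on time average* that no instantaneous frame displays.  The user
supplies the candidate operation (mirror normal axis, plane offset, glide
vector); atom pairing σ is greedy nearest-image matching under a species
constraint with ties broken by smallest index, a 1 Å default distance
cutoff, and a bijection/involution check.  The translation — the in-plane
glide component and the plane offset together — is then refined by least
squares, since an approximate symmetry is only fairly judged against its
best-fit operation (`refine=False` disables this when the raw candidate
operation is the reference).

"Deviation from perfection" of atom i is |x_i − x̃_i| where x̃ is the
symmetrized structure (each atom averaged with its partner's
back-transformed image).  This measures the distance to the *nearest
exactly symmetric structure* and halves the double counting a raw
partner-image distance would incur; the same engine symmetrizes
displacement matrices, Ũ_i = ½(U_i + Rᵀ U_σ(i) R), whose output is exactly
invariant and whose partner ellipsoids are exact mirror images.  Whether
published rms values follow this convention or the partner-image one is
generally not stated; the choice here is declared, and the partner-image
number is simply twice ours for a displaced pair.

## Thermal ellipsoids

U = ⟨u uᵀ⟩ is accumulated per atom from displacements about the mean
structure of the same frames; it is symmetric positive semidefinite by
construction and its trace equals ⟨|u|²⟩.  Ellipsoid semiaxes are
scale·√λ along the eigenvectors, eigenvalues ordered descending, each
axis's sign fixed by its largest-magnitude component for deterministic
output.  The default probability scale 1.5382 draws the 50 % surface of a
trivariate Gaussian; conventions that enclose "slightly more than half"
the probability use marginally larger factors, so the scale is a plain
parameter rather than a constant.  Shape classes compare semiaxis ratios
against a tolerance (default 5 %): prolate when the two small axes agree
but the large one does not, oblate in the mirror case, spherical when all
three agree, triaxial otherwise.

ADP export writes CIF `_atom_site_aniso_U_ij` referred to the
reciprocal-axis basis (U_cart = M N U_cif Nᵀ Mᵀ with M the
fractionalisation matrix and N = diag(a_i\*)), which round-trips exactly
for cells in the standard lower-triangular orientation; arbitrarily
rotated cells are recovered in the standard frame.

## Vibrational density of states

The DOS is the one-sided PSD of mass-weighted velocity summed over atoms
and Cartesian components, Welch-averaged over non-overlapping segments,
with each atom's mean velocity (drift) removed to kill the ν = 0 artifact.
The normalisation constant is chosen so ∫S dν̃ equals the time-mean of
Σ m|v|², i.e. twice the mean kinetic energy.  Under equipartition a
thermalised mode then carries exactly k_B·T of integrated weight, so
`band_mode_count` is simply the band integral divided by k_B·T — the
device used to check that a band holds the expected number of states.

The VACF route computes the unbiased estimator of C(τ) = ⟨Σ m v(t)·v(t+τ)⟩
by FFT and cosine-transforms it on the periodogram grid.  The default
Bartlett lag window times the unbiased estimator is algebraically the
biased estimator, whose transform *is* the rectangular-window periodogram
— the discrete Wiener–Khintchine identity — so the two routes agree to
machine precision under matched windowing, and the test suite asserts
this rather than a loose tolerance.  A Hann data window is the default for
production spectra (leakage suppression at ~10 ps record lengths); the
smoothing applied in published spectra is rarely stated, so the window is
exposed rather than hard-coded.

## Local modes

For a glycinate-like NH₂–CH₂–CO₂ molecule (9 atoms, 21 internal degrees
of freedom) the basis follows the classical group-vibration constructions:
XH₂/CO₂ stretch pairs (Δr₁ ± Δr₂)/√2; scissors as the H–X–H (O–C–O)
angle; for the terminal NH₂ and CO₂ groups wag/rock as the symmetric and
antisymmetric combinations of the two flanking X–skeleton bends — except
the planar CO₂ wag, which must be the Wilson out-of-plane coordinate of
the skeletal bond against the O–C–O plane because the in-plane bend sum
has a vanishing gradient at planarity; the methylene group, having two
skeletal neighbours, uses the four flanking bends in the ± patterns
(wag ++−−, rock +−+−, twist +−−+), which also avoids the rank deficiency
of raw angle sets at C_α; torsions as the √2-normalised sum of the two
dihedrals about the named bond; plus the N–C–C skeletal scissor.  Sign
conventions are fixed by this table since the traditional definitions
admit sign ambiguity.  Exact primitive compositions vary between
laboratories; these are the standard textbook combinations.

Projection uses analytic Wilson s-vectors (stretch, bend,
Blondel–Karplus torsion, Wilson out-of-plane) recomputed from the
instantaneous geometry *every frame* — a fixed reference geometry is not
defensible for large-amplitude motion at 500 K.  Internal coordinates
annihilate rigid translations exactly and rigid rotations to first order;
both are tested.  Frames where a bend or torsion becomes numerically
collinear (sin θ < 10⁻³) are flagged and linearly interpolated, and more
than 1 % flagged frames aborts the analysis.  Per-mode spectra are
unit-area normalised (so only line *positions* and *shapes* carry
information) and averaged across molecules when several are supplied.

## Peak assignment and reconciliation

Peaks are local maxima above a prominence floor (fraction of the global
maximum) separated by a minimum distance, with half-height widths;
reported frequencies may be rounded to the nearest 5 cm⁻¹, matching the
resolution at which such tables are usually printed.  A peak's mode
contributions are each unit-area local spectrum's mass within ±25 cm⁻¹ of
the peak (half the typical crowded-fingerprint peak spacing; configurable),
listing contributors in descending order and dropping those below 10 % of
the top one — the practice that keeps printed tables to a handful of
labels.  Coverage-to-coverage shifts match rows by dominant label, pairing
repeated labels (main peak plus satellite) by descending frequency rank;
positive means blue shift.  Reference reconciliation matches by label,
never by nearest frequency, because published tables deliberately pair
some peaks against chemical judgment rather than proximity; rms statistics
are √(Σ(calc−ref)²/n) and the relative analogue ×100, reported both exact
and at the printed rounding (1 cm⁻¹, 0.1 %).

## Synthetic fixtures

The generator provides ground truth for every stage:

- **Prescribed-frequency harmonic toy.**  A 9-atom glycinate at standard
  organic geometry (N–H 1.02, C–H 1.09, C–N 1.47, C–C 1.52, C–O 1.26 Å).
  The mass-weighted local-mode directions are projected off the rigid-body
  space and Löwdin-orthonormalised — the orthonormal set closest to the
  originals, so each normal mode maximally overlaps its own local mode —
  and the Hessian is assembled as K = M^{1/2}(Σ ω_k² v_k v_kᵀ +
  Σ ω_ext² e eᵀ)M^{1/2}.  Requested wavenumbers are therefore normal-mode
  frequencies *exactly*.  Fitting bond/angle stiffnesses to 21 targets
  instead would be an ill-conditioned inverse vibrational problem; the
  designed Hessian sidesteps it without changing what is being tested.
  Default placement puts one mode at each observed 1/3 ML band position
  (gaps ≥ 25 cm⁻¹ so every mode is resolvable); six external modes at
  50–200 cm⁻¹ stand in for the frustrated translations/rotations of the
  substrate attachment.  The glide-pair layout mirrors molecule and
  Hessian through y and translates by half the cell, giving an exactly
  symmetric 18-atom fixture.
- **Integrators.**  Velocity Verlet (NVE; no secular energy drift),
  Langevin via BAOAB splitting (default thermostat — robustly ergodic for
  tiny systems, default friction 10⁻³ fs⁻¹ = 1 ps⁻¹, a line broadening of
  ~5 cm⁻¹), and a Nosé–Hoover chain (default 5 links, τ = 25 fs) provided
  because surface AIMD conventionally uses one, but documented as
  optional: NHC on few-particle systems can be weakly ergodic.  A guard
  warns when dt exceeds a tenth of the fastest period and refuses beyond
  1/π of it.  All randomness flows from one seeded generator.
- **Morse bond.**  A mobile atom Morse-bonded to a fixed site, with a
  stiff transverse cage (default 2400 cm⁻¹) keeping the stretch
  one-dimensional — a soft cage lets the atom librate and the centrifugal
  coupling contaminates the stretch band.  The default study condition is
  dissociation energy D = 10 k_B·T at 500 K with a 1000 cm⁻¹ harmonic
  fundamental: strongly anharmonic (≈5 % red shift) yet safely bound.
  `morse_bond_reference` integrates the action-angle period at energy
  k_B·T by Gauss–Chebyshev quadrature with the turning-point singularities
  absorbed analytically; for the Morse form this reproduces the closed
  form ν(E) = ν₀√(1−E/D) to 10⁻⁸, which the tests use as a cross-check
  while the quadrature remains the independent route.  Thermal spectra are
  compared against the prediction by averaging the stretch-projected PSD
  over several independent Langevin runs, because a single run's band
  maximum wanders by a few grid spacings.

What the fixtures emulate: thermostated small-adsorbate dynamics with
known mode content, known temperature, optional anharmonicity and exact
glide symmetry.  What they do not: real anharmonic *coupling* between
modes, multi-minimum hopping, substrate phonon baths, dipole activity, or
DFT-quality forces.  Passing tests therefore establish the correctness of
the *analysis chain* — axes, normalisations, symmetrization, projections,
statistics — not the fidelity of any particular simulation engine.

## Problem sizes and tolerances

Test and acceptance runs use 2¹⁶–2¹⁷ steps at 0.25 fs (16–33 ps) for
thermostated fixtures, Welch segments of 2¹³ steps (≈16 cm⁻¹ resolution),
and four-run averages for the Morse band; these lengths put sampling error
comfortably inside the asserted bounds (one grid spacing for deterministic
peak positions, 3 batch-mean standard errors for variances, 15 % for the
21-mode band count, two grid spacings for the thermal Morse peak).
Statistical assertions estimate their own uncertainty from batch means
rather than assuming one.

## Known limitations

Only the extended-XYZ dialect described above is read; cells must be
fixed; only one symmetry operation (a single mirror/glide) is supported —
no space-group detection.  The local-mode library covers the glycinate
family plus user-supplied primitive lists, not general automatic
internal-coordinate generation.  CIF ADP round-trips assume the standard
cell orientation.  Infrared intensities are out of scope: the surface
selection rule (only modes with a surface-normal dynamic dipole are
RAIRS-visible) must be applied by the user when comparing mode lists with
experiment.
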