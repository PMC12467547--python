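# Methods

This note documents the models, numerical choices and known limitations of
`headspectra`. All lengths are in mm (converted to metres internally where SI
units matter), conductivities in S/m, dipole moments unit-strength (A·m);
every relative or dB quantity is unit-invariant.

## Four-shell semi-analytical forward model

The head is four concentric spheres — brain, CSF, skull, scalp — with radii
`R1 < R2 < R3 < R4` (defaults 80/81/86/92 mm) and conductivities
σ1..σ4 (defaults 0.33/1.79/0.0066/0.33 S/m). For a current dipole at
distance `b = f·R4` from the centre, rotated onto the +z axis with moment
components `(Px, Py, Pz)`, the potential on the outer surface is

    V(θ, φ) = 1/(4π σ4 R4²) Σ_{l≥1} w_l f^(l−1)
              [ (Px cos φ + Py sin φ) P_l¹(cos θ) + Pz · l · P_l(cos θ) ]

with `w_l = (2l+1)⁴ / (l C(l))` and `C(l)` the shell coefficient built from
the conductivity ratios `k_i = σ_i/σ_{i+1}` and radius ratios. Arbitrary
dipole positions are handled by rotating dipole and evaluation points into
the canonical frame (`rotate_to_canonical`); the rotation uses the minimal
axis-angle map, and for tangential moments the azimuth is irrelevant to all
energy quantities (asserted in tests).

### Stable evaluation of C(l)

Closed-form printings of `C(l)` are easy to get wrong and naive evaluation
overflows: the boundary-value problem couples growing (`r^l`) and decaying
(`r^−(l+1)`) radial modes whose coefficients span hundreds of orders of
magnitude, and forward transfer-matrix propagation cancels catastrophically
beyond l ≈ 150. We therefore evaluate the coefficient chain directly from
the boundary-value problem with a backward Möbius recursion: the insulating
outer boundary fixes the mode ratio `μ = (A x^l)/(B x^−(l+1)) = (l+1)/l` at
the surface, `μ` is propagated inward through each interface by a 2×2
linear-fractional map, and the surface gain is then a telescoping product of
`(1+μ)` factors in which only *decaying* radius-ratio powers appear. Every
intermediate is O(1) or decaying; the evaluation is vectorized over l and
stable far beyond the l = 600 cap.

Validation (in the test suite):

- equal conductivities reduce to the homogeneous insulated sphere,
  `C(l) = (2l+1)³`, to machine precision — and the summed series then matches
  a closed-form homogeneous-sphere dipole potential built independently from
  Legendre generating functions;
- an extended-precision (mpmath, ≥80 digits) direct solve of the 7-unknown
  interface system agrees to ~1e−12 relative at every tested degree;
- closed-form term energies match Gauss–Legendre surface quadrature of the
  actual potentials to 1e−8, terms are energy-additive (orthogonality), and
  the surface mean of every potential vanishes (no spatial DC on the closed
  sphere).

### Series truncation

Per-degree surface energies have the closed form

    E_l = R4² A_l² [ (Px²+Py²) · 2π l(l+1)/(2l+1) + Pz² l² · 4π/(2l+1) ],
    A_l = w_l f^(l−1) / (4π σ4 R4²),

so truncation is driven by exact energies: the series is cut when the
remaining tail drops below `tol` (default 1e−10) of the total, with a cap at
l = 600. For the deepest-used eccentricity f = 76/92 this needs ~50–60
degrees. The pointwise truncation error near the source pole is a few orders
larger than the energy-tail bound (all Legendre terms peak coherently at
θ = 0); tests that compare potentials pointwise tighten `tol` accordingly.
The centre source (`f = 0`, with `0^0 = 1`) excites only l = 1, whose term
energy is independent of moment orientation and depth — it is the 0 dB
reference of all spherical-model spectra.

## Sensor layouts and the spatial Nyquist limit

Equidistant layouts are generated by seeded relaxation: a Fibonacci lattice
is randomly rotated and jittered (seeded), then iterated with
repulsive-only springs along the edges of the convex-hull triangulation,
projecting back to the sphere each step and stopping when the maximum vertex
movement falls below 1e−4·radius. This is the same force model as the
distmesh family of mesh generators; it reproduces the edge statistics of
equidistant EEG-style layouts closely (34 points on R = 92 mm: h_mean ≈
59.6 mm, h_max ≈ 70.9–71.5 mm depending on seed; 938 points: h_mean ≈
11.5 mm). Triangulation is the convex hull (unique and deterministic for
spherical point sets), oriented outward; closed layouts satisfy F = 2n−4,
E = 3n−6.

A mesh with maximum edge length `h_max` is assigned the worst-case spatial
Nyquist limit `k_N = π/h_max`, `ω_N = 1/(2 h_max)`, `λ_N = 2 h_max`: below
λ_N even the sparsest mesh region aliases.

Open caps are extracted as strict subcomplexes (a triangle survives only if
all three vertices lie within the angular radius), so cap meshes share
vertex coordinates with their parent and have disc topology.

## Sphara basis

The discrete Laplace–Beltrami operator uses linear FEM: the cotangent
stiffness matrix `S` (symmetric PSD, zero row sums) and the *consistent*
mass matrix `B` (per-triangle area/6 diagonal, area/12 off-diagonal). The
consistent mass is the default because it is the matrix that defines the
B-inner-product in which the basis is orthonormal and energies are computed;
a row-lumped variant is exposed (`fem_matrices(..., lumped=True)`) for
sensitivity checks — on coarse layouts it changes sampled-energy deviations
substantially (and away from the validated behaviour), which is why it is
not the default.

The generalized eigenproblem `S x = τ B x` is solved densely below 500
vertices and by shift-invert Lanczos above (shift −1e−4 of the spectral
scale keeps the factorization definite despite the constant null space). Two
reproducibility measures matter in practice: a fixed Lanczos start vector
(otherwise degenerate eigenspaces rotate between runs), and a solve buffer
of extra modes (max(8, k/8)) so that a degenerate 2l+1 cluster is never
truncated mid-cluster before sorting. Eigenvector signs are fixed so the
largest-magnitude entry is positive. Eigenvalues map to wavenumbers by
`k = √τ = 2πω = 2π/λ`.

On refined sphere meshes the eigenvalues converge to `l(l+1)/R²` from above
(equivalently, Sphara wavelengths are systematically slightly *shorter* than
the Jeans wavelengths, because the polyhedral surface on which they are
measured sags inside the sphere); the dense 2562-vertex icosphere is within
0.6% and the tests assert 5%.

For spectra, modes are grouped to spherical degrees after the DC mode in
consecutive blocks of 2l+1 — exact on the sphere's degenerate spectrum,
declared approximate on other geometries.

## Spherical harmonics

Real basis in the geodesy 4π normalization without the Condon–Shortley
phase; coefficients of scattered samplings by rank-revealing least squares
(no regularization; rank deficiency raises with a suggested
`l_up(n) = ⌊√(n/2) − 1⌋`, the inversion of the Gauss–Legendre point count
`N ≈ 2l²`). Degree energies are `4πR² Σ_m F_lm²`. The grid counts
`N_GLQ = (l+1)(2l+1)` and `N_DH = (2l+2)²` are provided for reference.

## Spectral analyses and references

All spectra are energy fractions against a declared reference
(dB = 10·log10, so 50% ≈ −3 dB):

- spherical analyses: the centre-source energy. The exact reference is
  orientation-independent; discrete routes use the mean energy of 100 seeded
  random-orientation centre sources computed through the same route (SH
  total, Sphara/mass-matrix total) so each route is normalized by its own
  systematic bias.
- open-surface (lead-field) analyses: the median energy of the 15 deepest
  sources, logged in the run summary.

The discrete "captured" energy of a sampled distribution is `f^T B f` on the
layout mesh (metre-scaled); comparing it with the exact series energy gives
the signed relative misestimation per source. On the default ensemble the
coarse 34-point layout underestimates every source (median ≈ 20%, worst
≈ 45–47%, concentrated at shallow radial sources), the 104-point layout is
in the high single digits in the median with a worst case ≈ 17–18%. The
within-depth spread of degree-grouped Sphara contributions on the dense
4000-point layout is below 0.008% of the reference — note that *individual*
modes of a degenerate group exchange energy freely between same-depth
sources (azimuthal alignment); only the 2l+1 group sums are
position-invariant, and the spread statistic is defined on those.

Depth-group envelopes default to equal-count (sextile) depth bins, and
percentile envelopes report the median/90th/99th/99.9th percentiles plus the
maximum, pointwise over frequency.

## Synthetic ensembles

The default dipole ensemble mirrors the validation design: 77 shells at
radii 0–76 mm in 1 mm steps, 100 unit sources per shell, per orientation
class. Shell positions use the same seeded relaxation as sensor layouts
(per-shell seeds spawned from the master seed); tangential azimuths and the
orientations of the 100 centre sources (where radial/tangential is
undefined) are seeded per shell and *independent of orientation class*, so
radial and tangential ensembles with the same seed share positions.
Exact random streams are a package choice — only distributional properties
(equidistribution per shell, uniform tangential azimuth, uniform centre
orientations) are meaningful.

The open-cap fixture generates a full-sphere layout, extracts a cap, and
attaches a "pseudo lead field" computed from the four-shell forward model at
the cap vertices — labelled pseudo because it stands in for an externally
computed (e.g. BEM) lead field, letting the imported-lead-field route be
cross-checked exactly against the direct analytic route on spherical
geometry. What passing those tests shows is that the *pipeline* treats an
imported bundle identically to the analytic route; it says nothing about the
fidelity of any particular BEM model.

## Problem sizes used in tests and the acceptance script

The test suite uses a scaled ensemble (20 sources per shell per class) for
the misestimation analyses and a 204-source depth-spanning subset (9 shells
× 12 positions × both classes) for the dense-layout spectral comparisons;
the acceptance script runs the full 100-per-shell ensemble for the
misestimation analyses and 100-source-per-depth sweeps for the spread
statistic. Maxima over the scaled ensemble sit within ~1–2 percentage points
of the full-ensemble values; medians are essentially unchanged.

## Known limitations

- The spherical model is isotropic and four-shell; no anisotropy, no
  realistic geometry. Realistic-geometry spectra enter only through imported
  lead fields.
- The degree grouping of Sphara modes is exact only on (nearly) spherical
  closed meshes; on open caps the DC mode carries real energy and the
  per-degree labels are approximate.
- The mesh Nyquist limit `λ_N = 2 h_max` is a conservative heuristic, not a
  theorem, for irregular triangulations.
- Least-squares SH expansion is unregularized by design; heavily
  non-uniform samplings may need a lower `l_max` than `l_up(n)` suggests.
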