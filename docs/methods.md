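# Methods

## Dose formalism

Dose rates come from the TG-43U1 2D line-source equation
Ḋ(r,θ) = Λ·S_k·[G_L(r,θ)/G_L(r₀,θ₀)]·g_L(r)·F(r,θ), with the reference
point (r₀, θ₀) = (1 cm, 90°). The geometry function is evaluated in the
numerically stable two-arctangent form β/(L·r·sinθ) with the limiting form
1/(r² − L²/4) on the source axis; it agrees with direct quadrature of the
line integral to better than 10⁻⁹ everywhere tested, and reduces to 1/r²
as L → 0. Points on the active segment are degenerate: the scalar API
raises, the gridded API stores +inf and warns.

g_L(r) is interpolated log-linearly in r (dose falls near-exponentially,
and the interpolant is exact at knots and geometric-mean-consistent at
midpoints); F(r,θ) bilinearly in (r,θ). Queries outside a table are
clamped to the nearest knot with a warning — never silently extrapolated.
θ is measured from the seed tip (+z); the packaged anisotropy fixtures are
pole-symmetric, so the tip convention has no observable effect. The
packaged g_L/F tables themselves are *synthetic-representative*: smooth,
correctly normalized values standing in for published consensus data,
which is why tests assert formalism properties rather than specific
radial-function numbers. Λ = 0.966 cGy/(h·U) (6702) and 1.109 cGy/(h·U)
(Flexisource) with L = 3.30 mm and 3.50 mm.

Multi-seed dose is the voxelwise sum over seeds, each evaluated in its own
(parallel, translated) frame. Sums and P-value products are accumulated in
a canonical order so that both are exactly permutation-invariant in
floating point.

## Seed geometry

Seeds are ordered lists of convex axisymmetric components (cylinders,
spheres, hemispherical end welds, cone frusta). Nesting is handled by a
parent-material convention: each component records the material it is
embedded in, and the attenuation along a ray is Σ (μ_comp − μ_parent)·chord,
which is exact for strictly nested convex parts and turns all path-length
queries into per-component chord computations (vectorized over rays).
Chords below 10⁻⁷ cm are treated as tangential misses.

The 6702 model reads the 0.500 mm end-weld description as a 0.400 mm-radius
hemisphere on a 0.100 mm solid cylinder at each end of a 3.60 mm central
tube (0.800 mm OD, 0.050 mm wall), with three 0.600 mm resin pellets at
1.10 mm pitch and negligible-thickness iodine coating. The Flexisource
model keeps the published outer envelope (0.85 mm OD, 4.60 mm length,
23.6° conical tip with 0.17 mm face radius, 5.0 × 0.5 mm steel cable) and
the 3.60 mm hollow section (inner radius 0.335 mm) centered on the
3.50 × 0.60 mm iridium core; the published internal section lengths do not
jointly sum to the capsule length once the tip's axial extent implied by
its half-angle is honored, so the residual axial budget forms the solid
front/rear sections. None of the tests or results depend on that residual
split. For dose queries the 6702 active region is its 3.30 mm effective
line; for transport and shadow tests it is the three pellets.

## Perturbation kernels and their combination

A P kernel stores gridded perturbation factors for one relative
active/dummy placement, in the active seed's frame, on the 0.25 cm lattice
(kernel coverage 6 cm, matching common clinical seed separations). Query
placements are snapped to the lattice (error if off by more than 0.05 cm)
and reduced to the stored dR ≥ 0, dZ ≥ 0 quadrant by azimuthal rotation
about the seed axis and mirror reflection in Z — both exact symmetries of
parallel pole-symmetric seeds. Lookups short-circuit to exactly 1.0
wherever the center-ray shadow test misses the dummy's outer envelope; an
optional flag widens the shadow test to sampled active-region points for
finite-source realism. The converse is not an invariant: a point can be
geometrically shadowed while its nearest voxel center is not, so penumbral
voxels may read 1.

P values up to 1.02 are accepted (scatter excess and Monte Carlo
statistics can push ratios slightly above unity) and are clamped only on
explicit request, so printed table entries of exactly 1 and 0.999
round-trip untouched. The neglect policy ("treat a perturbation under 4 %
as none", i.e. P ≥ 0.96 → 1) exists but defaults to off for exact table
reproduction. Products are reported at 3 decimals, half-up, matching the
published precision.

## Transport oracle

The Monte Carlo is deliberately minimal: photons sampled uniformly over
the active region with line-spectrum energies, isotropic emission, free
paths drawn from the water total cross section in a full-scattering water
sphere (radius 40 cm, density 0.998 g/cm³), photoelectric absorption or
Klein–Nishina Compton scattering (Kahn sampling) at collision sites, a
5 keV kill cutoff, and a track-length kerma tally
(weight · chord · E · μ_en/ρ of water) per voxel. No Rayleigh scattering,
binding corrections, characteristic x-rays, or electron/β transport; the
hemisphere-vs-sphere ambiguity of the reference setup is resolved as a
full sphere.

Seeds never host collisions. Each traversed component chord multiplies the
photon weight by exp(−(μ_material − μ_parent)·chord) — the attenuation in
excess of the displaced water. Because seed handling consumes no random
numbers, runs with and without dummies follow bit-identical trajectories
for one RNG seed: the with/without ratio that defines P is automatically
coupled (common random numbers), which suppresses its variance by orders
of magnitude. Ratios are estimated in batches (default 10); the standard
error is the spread of per-batch ratios, and zero-dose denominators are
flagged undefined. Runs are single-threaded and bit-reproducible for a
fixed seed.

With this construction the sequential-ratio identity
P₁·P₂ = D(A,B,C)/D(A) holds algebraically, and the coupled test verifies
it to machine precision; the *pairwise-kernel* approximation (the model
proper) is validated separately against joint runs and against the
published tables. The analytic kernel builder is the primary-beam limit:
P(voxel) = Σ w(E)·T(E)/Σ w(E) with T the narrow-beam transmission along
center-to-voxel rays, optionally averaged over sampled emission points and
medium-corrected; it matches primary-only Monte Carlo within statistics.

Desk-scale problem sizes: property and acceptance checks run 10⁵–10⁶
histories on 2–4 cm tally windows, a deliberate choice of scale. At 10⁶
full-physics histories the shadowed-point P estimates for the quadrant
configuration land within about 0.01 of the published joint-simulation
values (≈0.81 for I-125, ≈0.87 for Ir-192) — closer than the bracketing
band [0.75, 0.92] the tests assert, which allows for the reduced physics
and cross-section approximations.

## Interaction coefficients

Per-material μ/ρ and μ_en/ρ tables (5–1000 keV) are committed CSV
fixtures built once by `scripts/build_material_fixtures.py`: water, C, H,
N, O, Ti, Fe and Pb carry standard NIST-compilation values; Cl, Cr, Mn,
Ni, Si and Ir are derived by Z^4.7 scaling of an anchor element's
photoelectric part plus a Klein–Nishina Compton part, and mixtures (AISI
304 steel, C₁₂H₁₈NCl resin) use mass-fraction weighting. Interpolation is
log-log. The iridium K edge is only crudely placed and metal μ_en/ρ
columns are approximate — kerma is scored in water, so neither enters the
results beyond the percent level. The Compton/photoelectric split in
water uses the analytic Klein–Nishina cross section; coherent scatter is
counted as absorption, slightly deepening low-energy shadows.

## What the synthetic inputs do and do not show

The validation tables are transcribed printed values (including two rows
whose printed coordinates duplicate an earlier row — kept as printed and
flagged, not corrected; and "≈1" annotations stored as their numeric
products with a flag). Passing them shows the multiplicative combination
and rounding conventions are right, not that any particular transport code
is. The synthetic g_L/F tables and the reduced Ir-192 line set mean
absolute dose rates are representative rather than clinical; P and ISA
values, being ratios, are insensitive to them. Non-parallel seed
orientations, separations beyond 6 cm, tissue heterogeneity, mixed
radionuclides and DICOM-RT I/O are out of scope.

## Numerical conventions

Grid voxels are 0.25 cm cubes with centers on integer multiples of the
voxel size (81 centers per axis over ±10 cm), so every published
calculation point is a voxel center; ownership is half-open per axis.
Tangency tolerance 10⁻⁷ cm; kernel lattice slack 0.05 cm; scatter-excess
allowance 0.02 on P; table comparison at printed precision (one unit in
the third decimal before rounding). Monte Carlo variance checks use
F-statistic bands around the ideal 1/N scaling rather than exact ratios.
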