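# Methods

## The model

`arterymech` implements a three-dimensional microstructure-based
constitutive model of the coronary artery wall with active smooth muscle
contraction, and the machinery needed to exercise it: forward simulation
of biaxial distension–extension tests, transmural stress analysis, and
joint passive+active parameter estimation.

### Kinematics

The reference configuration is the zero-stress state (ZSS): the radially
cut-open sector obtained after releasing residual stresses, described by
inner/outer radii `R_i`, `R_o`, opening angle `Θ`, and length `L`.
Loading maps the sector to a closed cylinder with outer radius `r_o` at
axial stretch `λ_z`.  The deformation is assumed axisymmetric,
axially uniform, plane-section-preserving and isochoric, which fixes the
loaded radius of every material point,

    r(R) = sqrt( r_o² − (R_o² − R²)·(π − Θ)/(λ_z π) ),

and the principal stretches `λ_θ = (π/(π−Θ))·r/R`, `λ_r = ∂r/∂R`, `λ_z`,
whose product is exactly 1.  All tensors are stored in the cylindrical
basis ordered (θ, r, z); under this loading the deformation gradient is
diagonal and every shear stress component vanishes.

### Constituents and their laws

The wall is a two-layer fiber composite in a fluid-like matrix
(affine deformation; the matrix contributes only a hydrostatic
pressure).  The strain energy per reference volume is the
volume-fraction-weighted sum over constituents; each constituent's
energy is an expectation of a single-fiber law over its orientation
distribution, with the fiber strain given affinely by `e = E : N⊗N`.

* **Elastin** (and inter-lamellar, IL, elastin): linear and
  tension-only, `w = ½ k e²` for `e > 0`.
* **Collagen**: wavy; a fiber carries load only beyond its
  straightening strain `e₀`, with `w = k_C (e − e₀)^{1+M_C}/(1+M_C)`.
  The straightening strain is a random variable: beta-distributed in
  the adventitia (moment-matched to the measured mean 0.35 and SD 0.051
  on bounds [0, 1]) and uniform on [0, e₀₂] in the media.
* **Orientations**: adventitial elastin and collagen follow
  two-component truncated-normal mixtures on [0, π] (angles from the
  circumferential direction, in the θ–z plane); medial fibers and SMCs
  form symmetric families mirrored about the circumferential direction,
  realized as truncated normals on [0, π/2] (under diagonal strain both
  mirrored halves contribute identically); medial IL elastin is
  isotropic in the θ–r plane with density 1/π on (−π/2, π/2).
* **Smooth muscle (active)**: a cell generates stress along three axes.
  Longitudinally, an asymmetric bell-shaped length–tension law
  `σ = A[½ρ₁(λ_max^ρ₂ − λ^ρ₂ − 2)(λ − λ_max)² + σ_max]` peaking at
  `σ_max` at the optimal stretch `λ_max`; transversely the same law
  scaled by the ratio `τ`; radially a linear law `σ″ = A·k_SMC·λ_r`
  (the cells are radially compressed, where the bell law is far outside
  its calibrated range).  `A ∈ [0, 1]` is the activation level.  The
  SMC second Piola-Kirchhoff contribution sums the chain-rule terms
  `σ·∂λ/∂E + σ′·∂λ′/∂E + σ″·∂λ″/∂E` with `∂λ/∂E = N⊗N/λ`, averaged over
  the SMC orientation family.

Two modeling choices deserve mention, both switchable:

* the bell-shaped law can turn negative far from `λ_max`; it is clamped
  at zero by default (a contracting cell is not assigned active
  compression);
* the radial SMC law is gated by `A` like the other two axes, so fully
  passive tissue carries no active stress at all, consistent with the
  negligible passive contribution of relaxed SMCs.

Fiber material parameters are identical in both layers.  The layer is
selected by reference radius: the media occupies the inner fraction of
the wall thickness (default 2/3).

### Equilibrium of the loaded tube

With the extra Cauchy stress `σ̂ = F·S·Fᵀ`, radial equilibrium with a
traction-free outer surface gives the transmural radial stress by inward
integration and the luminal pressure and reduced axial force as

    p_i = ∫ (σ̂_θθ − σ̂_rr)/r dr,
    F   = π ∫ (2σ̂_zz − σ̂_θθ − σ̂_rr) r dr,      N = F + p_i π r_i².

The incompressibility multiplier cancels from all three (only stress
*differences* enter), and is recovered pointwise only when full Cauchy
profiles are requested.  The inverse problem (radius at prescribed
pressure) is solved by safeguarded Brent root finding on the monotone
pressure–radius relation, warm-started across a pressure sweep.

## Numerical choices

* **Quadrature.**  Orientation expectations use density-weighted
  Gauss–Legendre nodes placed on the essential-mass window μ ± 8σ
  intersected with the support (the normal mass outside 8σ is ~1e-15),
  so narrow and broad densities are resolved equally well.  Beta
  recruitment expectations use Gauss–Jacobi quadrature — the orthogonal
  family of the beta weight — with weights normalized to sum exactly
  to 1; extremely concentrated betas (shapes > 200) fall back to a
  windowed Gauss–Legendre rule.  The isotropic IL term is evaluated in
  closed form (its law is quadratic, so the tension-only angular
  integrals reduce to elementary antiderivatives between the zero
  crossings of the fiber strain); this removes the only integrand kink
  that degraded quadrature convergence.  Radial integrals use
  Gauss–Legendre per layer on the reference radius (the integrand jumps
  at the media/adventitia interface), with `dr = λ_r dR`.  Defaults:
  64 angle nodes per mixture component, 32 recruitment nodes, 32 radial
  nodes per layer; doubling any of these changes pressures and stresses
  by well under 1e-6 relative.
* **Point-mass (mean-value) mode.**  Every distribution can collapse to
  a point mass at its mean; expectations then reduce to single
  evaluations with no quadrature error, and the full model converges to
  this mean-value model as all dispersions shrink (verified to 0.1 % on
  pressure and force).
* **Degenerate inputs.**  Tension-only switches are applied per fiber
  inside the integrand; compressive fiber strains contribute nothing.
  An outer radius too small for the imposed axial stretch (negative
  squared radius) raises a dedicated invalid-configuration error.
* **Units.**  Lengths mm, stresses MPa, forces mN, pressures mmHg at
  the interfaces with a single declared conversion
  1 mmHg = 1.333224e-4 MPa.

## Parameter estimation

The objective is the studentized SSE over the full protocol grid
(n pressures × m stretches), with four channels per grid point: outer
radius and axial force, in the passive and the fully activated state,
each normalized by its measurement SD and averaged by 1/(nm).  Passive
and active parameters are fitted jointly by default: the two-stage
(passive-then-active) alternative, provided as an option, estimates
passive parameters only in the passive loading range and is therefore
biased in the low-stretch region that dominates the active response.

The global search is `scipy.optimize.differential_evolution` — a
population-based evolutionary optimizer of the same algorithmic class as
a genetic algorithm — with population 15×dim, at most 300 generations,
final local polish, and a mandatory seed making every fit
bit-reproducible.  The search terminates at the first of: the generation
cap, scipy's population-convergence test (relative tolerance 0.01), an
absolute objective floor (best noise-normalized SSE below 1e-3, i.e.
every residual far below measurement precision — a meaningful absolute
scale because the objective is studentized), or best-value stagnation
over 15 consecutive generations; the polish step then refines the best
member to the local optimum, which on smooth noiseless recovery
problems drives parameter errors well below 1 %.  Inside the objective
the forward model runs at reduced quadrature (16 angle / 8 recruitment /
8 radial nodes) with warm-started secant/Brent pressure solves (each
optimizer trial reuses the previous trial's radii as starting guesses)
and a 1e-7 mm radius tolerance; with the quadrature schemes above this
changes predicted radii by ~1e-4 relative, far below the measurement
noise, while making a full fit tractable in minutes on one core.
Infeasible parameter proposals (solver failures) are penalized rather
than raised.

Three modes mirror how the microstructure enters:

* `statistical_fixed`: geometric statistics pinned at the packaged
  population averages; only material parameters free.
* `refined_geometry`: geometric parameters also estimated, inside box
  constraints centered on the statistical means with half-width
  2 statistical SDs (configurable).  Seeding the refined run with the
  fixed-mode optimum makes the nested-model inequality
  (SSE_refined ≤ SSE_fixed) hold by construction.
* `mean_value`: point-mass microstructure; mean angles and the two
  straightening strains estimated directly.

Per-channel goodness of fit is reported as R² for radius and force per
state, plus an R² for pressure computed by forward-evaluating the
pressure at each measured radius.

## Synthetic data

The generator emulates the bench protocol: pressure 0→160 mmHg in
20 mmHg steps, axial stretches 1.3 and 1.5, one passive and one maximal
K⁺-activation pass, i.e. 36 records per replicate.  Measurement noise is
additive, zero-mean Gaussian and independent per channel, with SDs
defaulting to 2 % of each channel's noiseless range per state (the
source experiments report error bars but not rig SDs; this is a declared
assumption).  Reference geometries are drawn from documented porcine
LAD-scale ranges — ZSS outer radius 2–3 mm, wall/outer ratio 0.2–0.35,
opening angle 0.5–2.5 rad — because the source studies do not publish
their specimens' ZSS dimensions; the packaged default geometry
(R_o = 2.5 mm, R_i = 1.85 mm, Θ = 1.2 rad, L = 10 mm) is likewise a
documented synthetic assumption, as are the volume fractions
(SMC-dominant media 0.45/0.15/0.15/0.25 SMC/IL/E/C; collagen-dominant
adventitia 0.65/0.35 C/E) and the 2/3 media share of wall thickness.

What the generator does *not* emulate: preconditioning hysteresis,
temperature equilibration and washout transients, between-vessel
heterogeneity (available but off by default), non-Gaussian measurement
error, and axial-position dependence.  Passing recovery tests therefore
demonstrate identifiability and correctness of the estimation machinery
under the stated noise model, not robustness to every artifact of bench
data.

## Problem sizes used in the shipped tests

Unit tests run the forward model at 16/8/8 quadrature on reduced
pressure grids; the end-to-end recovery check refits five parameters
(k_E, k_C, λ_max, σ_max, τ) of a noiseless 36-record protocol with the
default optimizer budget, and the estimator-bias check uses ten noisy
replicates of a 5-pressure, single-stretch protocol with a small
population.  These sizes are the package's own choice of a desk-scale
experiment; all tolerances are stated in the tests themselves.

## Known limitations

* The active model is phenomenological; only `λ_max` and `σ_max` carry
  direct physical meaning, and mechano-chemical activation dynamics are
  out of scope.
* Orientation dispersion is planar (single-angle); no two-angle 3D
  dispersion.
* No shear loading, torsion, bending, perivascular constraint or
  fluid–structure interaction; the equilibrium solver covers
  axisymmetric distension–extension only.
* Adventitial mixture weights are not published; equal weights are the
  default and are configurable.
* The published refined-fit beta shapes are not reproducible from the
  published moments on standard bounds, so the package calibrates the
  recruitment beta by moment matching and exposes all four parameters
  (shapes and bounds) instead of guessing undocumented bounds.
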