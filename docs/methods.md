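# Methods

This package reimplements, at desk scale, a factor-screening study of peak
stresses in atherosclerotic carotid plaques: how much do the assumed wall
thickness (WT), the imaging slice thickness (ST), the lipid-core stiffness
(LC), the fibrous-tissue stiffness (FT) and the media anisotropy (MB) change
the computed peak plaque stress (PPS) and peak cap stress (PCS)?  The
original question arises because patient-specific plaque models are built
from uncertain inputs — segmentations at finite imaging resolution, tissue
stiffnesses spanning orders of magnitude, wall layers that endarterectomy
samples do not even contain — and the clinical quantity of interest (the
peak first principal stress in the fibrous cap, the standard vulnerability
indicator) may be dominated by those choices rather than by patient anatomy.

## Constitutive models

All tissues are modelled as incompressible hyperelastic solids (kPa, mm
units throughout).

* Isotropic tissues use the Yeoh polynomial Ψ = Σᵢ c_i0 (I₁−3)ⁱ, i ≤ 3:
  neo-Hookean lipid core (c10 = 0.1 soft … 50 hard), 2nd-order fibrous
  tissue (c10 = 2.7 soft … 342.1 hard with the strain-stiffening constant
  fixed at c20 = 20), and 3rd-order fits for the wall layers
  (media c10 = 122.3, c30 = 337.7; adventitia c10 = 88.7, c30 = 45301.4).
* The anisotropic media is a fiber-reinforced matrix with two symmetric
  collagen families at ±φ from the circumferential direction:

      Ψ = μ/2 (I₁−3) + k₁/(2k₂) (exp[k₂((1−ρ)(I₁−3)² + ρ(I₄−1)²)] − 1)

  with μ = 122.3 kPa, k₁ = 24.7 kPa, k₂ = 16.5, φ = 6.9°, ρ = 0.8, and
  I₄ = λ_θ² cos²φ + λ_z² sin²φ the shared squared fiber stretch.  For a
  general C the two families are combined through the generalized structure
  tensor H = cos²φ e_θ⊗e_θ + sin²φ e_z⊗e_z (their cross terms cancel), so
  I₄ = C : H.

Near-incompressibility in the FE context uses the isochoric split
(Ī = (det C)^(−1/3)-scaled invariants) plus a volumetric penalty
U(J) = K/2 (J−1)², K defaulting to 10⁴ × the stiffest c10/μ present in the
model, which keeps |J−1| ≲ 10⁻³–10⁻⁴ at physiological loads.  No
tension-only switch is applied to the fibers (a documented flag could add
one; the fitted φ is small, so the families are near-circumferential and
compression of the fiber direction is rare under inflation).

All stress and tangent expressions (S = 2∂Ψ/∂C, ℂ = 4∂²Ψ/∂C∂C, both in 3D
and in the plane-strain specialization) are generated symbolically with
sympy and lambdified once per model family.  This gives machine-precision
derivatives and keeps the analytic route strictly independent of the
finite-difference oracles used to verify it.

The fibrous-tissue stiffness fit mirrors how the experimental range was
reduced to a single factor: tissue responses are nearly linear, so c20 is
held fixed and only c10 is fitted to uniaxial stress–stretch data (the
model is linear in c10, so the least squares is closed form; R² is
reported and values above 0.8 are considered adequate).

## Synthetic phantom

No imaging data ships with the package; the study object is a synthetic
idealized carotid segment chosen to match the anatomy the screening design
presupposes — an advanced lesion with a large lipid pool and a locally thin
cap:

* straight segment, 4 mm long, master stations every 0.2 mm (the span at
  which per-station maxima are tabulated);
* fibrous tissue between a circular outer boundary (R = 4 mm) and an
  eccentric lumen: healthy-side lumen radius 3 mm, plaque depth 1.8 mm over
  a 140° sector;
* a large lipid core (100° sector, up to 1.9 mm thick) separated from the
  lumen by a fibrous cap of nominal thickness 0.2 mm whose axial profile
  carries a local dip to 0.08 mm (raised width 0.5 mm, centred mid-segment);
* the outer wall as a 0.5 mm equidistant offset of the tissue boundary,
  partitioned by the WT factor: outer WT/2 adventitia, next WT/2 media,
  remainder fibrous tissue, so the wall volume is always present and only
  its material assignment varies (WT = 0 reproduces the common
  "wall-omitted" shortcut of assigning plaque properties everywhere);
* a small smooth angular jitter (0.02 mm, low-order Fourier modes, seeded)
  so contours are not perfectly circular; the jitter moves lumen and core
  together, leaving the cap-thickness profile exactly as specified.

Contours are radius-vs-angle profiles on 256 rays (mirroring a 256×256
in-plane acquisition matrix), which makes every contour simple and
star-shaped and reduces all geometry processing to per-ray arithmetic.
Plaque and core flanks follow a flat-top profile with a C²-continuous
quintic-smoothstep falloff: a curvature jump at the flank would act as a
mesh-sensitive stress raiser, while the flat top preserves the full
plaque/core dimensions over the sector interior.

Slice-thickness degradation resamples every profile at axial spacing ST
(0.25–1.5 mm) and linearly interpolates back onto the master stations, as a
reconstruction from sparse images would.  Because linear interpolation
takes convex combinations, the reconstructed minimum cap thickness can
never fall below the true minimum, and on nested sampling grids the
information loss is monotone in ST.  At ST = 1.5 mm the 0.5 mm dip falls
between samples and disappears from the reconstruction.

What the phantom deliberately does not emulate: the carotid bifurcation
(near-boundary and bifurcation results were excluded from the responses in
the motivating study anyway), voxel data and segmentation noise,
calcifications as discrete inclusions (their effect enters only through the
LC stiffness range), and inter-patient shape variability.  Passing tests on
the phantom therefore demonstrate the method chain — geometry degradation,
material realization, solving, peak extraction, screening statistics — not
agreement with any particular patient's stress magnitudes.

## Cross-section meshes and material frames

Each station is meshed with a single structured polar quad grid: radial
bands for the cap (lumen → core-inner line), the core band, the outer
tissue, and the wall rings (media and adventitia two elements each, the
FT-like remainder one element per 0.125 mm).  Since every surface is
star-shaped, the grid is conforming at all material interfaces (the bonded
tissue–wall contact is realized by shared nodes).  Elements in the core
band are labelled lipid core only where the band is ≥ 0.15 mm thick; the
labelled core therefore ends in a blunt tip about one element across, which
keeps the soft-inclusion tip concentration resolvable at the default
element size.  Default resolution: 64 sectors × ~10–12 radial elements
(campaign default 32 sectors); region areas agree exactly with the polygon
areas at matched angular sampling and to < 0.5% with the full-resolution
contours.

Material frames per wall element follow the centerline construction: lumen
contour centroids define the centerline; its two points bracketing a
section give e_z; the outward normal of the element's inner face at the
element centroid gives e_r; e_θ = e_z × e_r, re-orthonormalized.  The
plane-strain solver consumes the in-plane angle of e_θ; full 3D frames and
±φ fiber vectors are computed and exportable regardless.

## Finite-element solver

The 3D pressurized-segment problem is reduced to independent plane-strain
sections per axial station — the central desk-scale modelling decision.
It is defensible here because the phantom is straight, its ends are far
from the evaluation window, and the responses are per-station maxima; it
ignores axial stress transfer along the dip, so axial gradients are
represented only through the per-station geometry (see Limitations).

* Total-Lagrangian kinematics, 4-node quads, 2×2 Gauss integration.
* F-bar-type strain projection at the energy level: at every Gauss point
  the in-plane C is rescaled to the element-centroid dilatation,
  C̄ = (J₀/J) C, before the isochoric energy is evaluated; the volumetric
  penalty acts on J₀ only.  This removes volumetric locking; the
  dilatational hourglass modes the projection leaves unconstrained are
  controlled by a small fluctuation penalty ε·10⁴·(local c10/μ)/2 ·
  Σ w (J−J₀)² with ε = 0.002.  The stabilization is scaled by the *local*
  material stiffness — scaling it by the global penalty would stiffen a
  0.1 kPa core by four orders of magnitude and lock the solution.  On the
  homogeneous tube benchmark the element converges at second order
  (0.3% hoop-stress error at 64×8).
* Residual and tangent are exact derivatives of the element energy
  (verified against finite differences to ~10⁻¹⁰), so Newton is locally
  quadratic; the follower pressure on the deforming lumen polygon
  contributes the only non-symmetric tangent block and derives from the
  potential −p·(enclosed-area change).
* Globalization: Armijo backtracking on the total potential; 5 pressure
  increments with automatic halving on divergence; penalty continuation
  (pressure stepped at 0.01×K, then K ramped 0.1× → 1× with warm restarts)
  — full-penalty Newton from zero stalls on fine meshes of very soft
  tissue because the quadratic penalty response to a physically sized step
  dwarfs the linear model.  Neighbouring stations warm-start each other,
  and geometrically identical stations (the phantom is axially uniform
  outside the dip) are solved once.
* Rigid-body modes of the self-equilibrated section are removed by three
  scalar constraints (one outer node pinned, the diametrically opposite
  one fixed perpendicular to the joining line); the constraints carry
  essentially zero reaction and the peak stresses are insensitive to the
  pin choice to < 0.1%.
* Convergence: relative residual ≤ 10⁻⁸ of the applied-load magnitude
  (pressure × lumen perimeter).

The verification oracle is the classic incompressible plane-strain
thick-wall inflation: with λ_z = 1, r² − r_i² = R² − R_i², and
p = ∫ (σ_θ − σ_r) dr/r integrated by quadrature with the inner radius found
by root bracketing; it supports layered isotropic walls and recovers the
membrane formula σ_θ ≈ p r/t in the thin-wall limit to 0.4%.

## Stress responses

Cauchy stresses σ = F S Fᵀ / J + K(J₀−1) I are recovered at element
centroids — a single recovery point per element, no nodal averaging across
region boundaries (averaging would smear the tissue/core stiffness jump).
PPS is the maximum first principal stress over the plaque search region
(fibrous tissue including the FT-like wall remainder, plus the lipid core
by default; a flag restricts to FT), PCS the same maximum over the cap set:
lumen-adjacent FT elements whose outward ray from the section centroid
crosses the lipid core, dilated by one element ring to include the
shoulders (the ray-casting definition is this package's formalization; cap
maxima typically sit at the shoulders).  Stations within an exclusion
length (default 0.6 mm) of the segment ends are skipped.

Two recovery caveats are documented rather than hidden.  First, because the
reported peak is a maximum over centroid values, uniform mesh refinement
moves the sampling points toward the lumen surface and the peak grows with
the through-thickness stress gradient; the discretization-convergence test
therefore refines in-plane resolution at fixed band element counts (PPS
changes < 5%).  Second, peak values at the core shoulder are concentration
values at a material-interface corner and converge slowly in any
discretization; the screening conclusions rest on factor *contrasts* at a
fixed discretization, not on absolute peak magnitudes.

With the stiff wall present (WT = 0.5), the soft plaque cushion is in a
near-hydrostatic compressive state and PCS can legitimately be small or
negative; the large tensile peaks appear when the wall is assigned
fibrous-tissue properties (WT = 0) and the hoop load must pass the cap/core
complex — reproducing the wall-omission overestimation that motivates the
WT factor.

## Screening design and statistics

Face-centred central composite design over the four continuous factors
(coded −1/0/+1, natural values by linear decoding of WT 0–0.5 mm,
ST 0.25–1.5 mm, LC 0.1–50 kPa, FT 2.7–342.1 kPa): 2⁴ factorial + 8 face
axial + 1 centre = 25 runs, replicated for each media behaviour (and per
geometry when several are requested; two geometries reproduce the
100-model arithmetic of the motivating study).  Stiffness factors are coded
linearly despite their 500× ranges — the standard CCD convention; a log
coding is a one-line change in the factor definition but is not the
default.  Simulations are deterministic, so the centre point is not
replicated.

Each response is fitted with the full quadratic surface on coded units
(intercept + 4 linear + 4 square + 6 interaction terms, 25 runs).
Term p-values are OLS t-tests, identical to single-degree partial-F tests;
an independent brute-force extra-sum-of-squares computation is kept as a
test oracle (agreement to 10⁻⁸).  Significance is declared at α = 0.05 and
near-significance at α = 0.1; residual normality uses the D'Agostino–
Pearson omnibus test; R² > 0.8 is the model-adequacy gate.  An optional
hierarchy-preserving backward elimination (α_out = 0.1) produces reduced
models.  The categorical media factor is assessed with a two-sided paired
t-test across the 25 matched design points (a zero-variance difference
vector is reported as degenerate, without a p-value).  Failed solves are
excluded with a warning, never imputed; a campaign with > 10% failures
aborts.

## Problem sizes

The default configuration solves one geometry: 50 runs × the stations in
the exclusion window at 64 sectors.  The reproduction script and the heavy
tests use the compact configuration: 32 sectors and the evaluation window
z ∈ [1.6, 2.4] mm around the cap dip, where all axial variation of the
phantom lives (the axially uniform remainder contributes identical
sections, which the dedupe layer would solve once anyway); a compact
50-run campaign takes roughly 10–15 minutes on one CPU.  The verification
benchmarks always run at 128×16.

## Known limitations

* Plane-strain sections cannot carry axial stress transfer along the dip;
  the ST effect is driven purely by per-station geometry degradation.
* Peak values at material-interface corners are discretization-dependent
  concentration values (see above); contrasts, ratios and significance
  flags are the meaningful outputs.
* The lipid core at 0.1 kPa is near-fluid; at the softest corners the
  solver needs the full continuation machinery and strains are large
  enough that reported peaks carry noticeable mesh sensitivity.
* One synthetic geometry family; no claim is made to reproduce any
  patient-specific stress magnitude.  Fiber dispersion, viscoelasticity,
  damage, residual stresses in the plaque, axial pre-stretch and
  fluid–structure interaction are out of scope.
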