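# Methods

This note records the models implemented in `helmetplan`, the parameter
choices that matter, and what the synthetic test bed does and does not
demonstrate.

## Tissue model and phantoms

Anatomies are cell-centered voxel label grids (x right, y anterior,
z cranial; default 4 mm isotropic — about λ/18 in the most permittive
tissue, CSF, at 500 MHz). Membership is decided by a voxel-center test
(winner-takes-all, no partial-volume weighting). Each label maps to a row
of a versioned YAML property table with dielectric values (εr, σ) at the
three discrete operating frequencies and thermal values (ρ, c_p, k_th,
perfusion in ml/min/kg). The dielectric numbers follow the IT'IS/Gabriel
database at those frequencies; tumor dielectrics are an average of
reported malignant-tissue values, and tumor thermal properties are
ρ = 1090 kg/m³, c_p = 3421 J/kg/K, k_th = 0.49 W/m/K. The table is a
package constant; users can pass their own.

Two generators exist. The *layered sphere* (for coupling experiments)
nests skin (6.3 mm), cortical bone (6.8 mm) and CSF (10.7 mm) shells under
a 96.9 mm scalp radius around a brain core, inside a spherical water
bolus. The *synthetic head* is a stack of coaxial ellipsoids with the same
shell thicknesses plus a gray/white matter split, a caudal muscle fill
standing in for the rest of the body, a pharyngeal air duct, two vitreous
eyes, and a tumor blob: a randomly oriented ellipsoid rescaled iteratively
until its voxelized volume matches the request within 5 % (default 126 mL,
a large medulloblastoma). Shells thinner than a voxel are flagged, not
rejected.

The local impedance η used by the interpolation surrogate is the
*complex* intrinsic impedance η₀/√(εr − jσ/ωε₀) (a config switch can
force the lossless form). Because the surrogate divides and later
multiplies by the same map, the choice cannot bias the round trip; it only
affects how much anatomy the surrogate factors out.

## Bolus geometry and antenna frames

The bolus is an axis-aligned ellipsoid fitted to a scalp point cloud
pushed ~5 cm outward, by linear least squares on the quadric
Ax² + By² + Cz² + Dx + Ey + Fz = 1. A caudal trim plane (7.7 cm below
center for the study geometry, giving a 22.1 cm cranial–caudal extent)
leaves a breathing opening; its polar angle bound is
θ_max = arccos(−trim/c).

An antenna at surface coordinates (θ, φ) carries the frame: W inward
along the surface normal; U (the polarization axis) tangent to the
surface in the plane spanned by the z axis and W (at the pole, where that
plane degenerates, U falls back to the x direction); V = W × U. The
origin O is retracted inward along W by the smallest distance keeping the
8.7 × 6.2 cm back plate inside the water (bisection on the corner quadric
values), and the phase center sits at O′ = O + 1.4 cm · W.

## Interpolation grid

Grid nodes are spread by minimizing Σ_pairs 1/d² — the electrostatic
energy of like charges — with chordal (3-D) distances, L-BFGS-B on
(θ, φ) with θ ≤ θ_max, from an area-uniform random start (rejection
sampling against the surface element, so starts are not pole-biased).
The objective is non-convex, so 8 independent starts are run and the
lowest-energy result kept. Nodes are triangulated by mapping them to the
unit sphere via (θ, φ) and taking the convex hull; facets whose spherical
centroid falls beyond θ_max span the caudal opening and are dropped.

Two spacing statistics are recorded: over unique triangulation edges
(max/mean edge) and over per-node nearest neighbors (max/mean NN). The
acceptance script reports the nearest-neighbor statistics as "nearby
pair" distances. The reason is geometric: the trimmed study ellipsoid has
≈1.8 · 10³ cm² of surface, so 221 points triangulate into ≤ ~440 patches
and the largest edge of *any* configuration is at least
√(4·A/(√3·n_tri)) ≈ 3.1 cm — an equilateral covering bound that no
spreading can beat — whereas nearest-neighbor distances are not coverage-
bounded. A converged spread lands at max NN ≈ 3.2 cm, which satisfies the
half-wavelength design rule (λ/2 = 3.4 cm in water at 500 MHz) that sets
the 221-point grid size. Less converged single-start runs show local
clustering and correspondingly shorter nearest-neighbor distances; the
package deliberately reports the converged multi-start optimum.

## Analytic field oracle

The oracle replaces a full-wave solver for testing and desk-scale design:

E(x) = D(ψ) · p(x) · exp(−j k₀ n̄(x) s(x)) / max(s, s₀),

with s the distance from the phase center, D(ψ) = cos²(ψ/2) a smooth
forward taper about W, p the U axis transported transversally along the
ray, and n̄ the complex refractive index √(εr − jσ/ωε₀) averaged along
the straight ray (32 samples), so phase advance and attenuation
accumulate through traversed tissues. s₀ = one voxel caps the 1/s
singularity. Fields are normalized to unit accepted power, defined as the
power absorbed in the lossy domain. The oracle is smooth in the pose,
polarized, dispersive and anatomy-dependent — the properties the
interpolation, coupling and optimization stages rely on — but it has no
diffraction, reflection or standing waves. Consequences: interpolation
errors measured here are optimistic relative to FEM fields, and coupled-
field experiments are constructed (first-order additive with a known
ground-truth coefficient) rather than emergent.

## Interpolation and its error

The field at an arbitrary pose is built in six steps: locate the
containing patch on the unit sphere (ray–facet barycentric test; queries
beyond θ_max are clamped and flagged); divide each corner field by η
(H-field surrogate — tissues are non-magnetic, so this strips most
anatomy dependence); rigidly transform each surrogate from its corner
frame to the query frame, rotating both sample positions and vector
components, resampling trilinearly (real and imaginary parts per
component; out-of-domain samples are zero and their fraction reported —
zero is conservative for SAR); multiply back by the *query-lattice* η
(the anatomy is fixed, only the antenna moves); blend with barycentric
area weights computed from the query projected onto the patch plane, so
they are exact, nonnegative and sum to 1 (edge queries resolve as limits;
at a node the stored field is returned bit-for-bit). Trilinear
resampling balances the smoothness needed by finite-difference gradients
in the arrangement refiner against cost.

Field approximation error against a reference is reported as four
fractions averaged over an evaluation mask, after both fields are 5 g
mass averaged component-wise (complex components averaged, not
magnitudes): relative magnitude of the vector difference (ε_DIS);
relative amplitude error of the U-projected component (ε_ABS); wrapped
phase difference of that projection over π (ε_ANG, 100 % = opposition);
and the angle between per-voxel amplitude vectors over π/2 (ε_DIR, 100 %
= orthogonal). Voxels with a vanishing reference denominator are excluded
and counted.

## Coupling model

A passive antenna re-radiates k_AP · E_P with k_AP = c · e_AP, where
e_AP = ⟨U_P, E_A(O′_P)⟩ is the impinging field projected on the passive
polarization axis at its phase center and c is a complex per-frequency
constant of the antenna design. k is estimated from a pair experiment by
decorrelation (least-squares fit of the remainder E_{A+P} − E_A onto
E_P), and c by a complex through-origin fit over 30 seeded random pairs
(uniform surface poses; the synthetic experiments randomize the passive
polarization through the pose frame). The array correction multiplies the
stacked individual fields by the (K−1)-th power of the matrix with unit
diagonal and c·e_ij off-diagonal (e_ij: field of antenna i at antenna j);
the exponent is read as a matrix power, which preserves the printed K = 1
identity and converges geometrically for |c·e| < 1. K = 3 is the default;
e_ii is fixed at 1 per the unit diagonal.

## Treatment planning

SAR is coherent within each frequency and incoherent across:
Σ_f ½σ_f/ρ |Σ_c χ_{f,c} E_{f,c}|², with unit-total-accepted-power
normalization Σ|χ|² = 1. It is smoothed by 5 g mass averaging: per voxel,
the smallest centered cubic kernel (grown in whole-voxel shells) whose
in-mask tissue mass reaches 5 g, mass-weighted, with out-of-mask voxels
contributing nothing. The evaluation mask excludes the first 20 mm of
tissue under the water bolus (Euclidean distance transform from the
water/air contact), modeling surface cooling. Tail sizes use nearest-rank
counts on voxel volumes with mass-weighted tail means; q = p·|T|/|R|
holds exactly by construction, and with uniform voxels the two tails
contain the same number of voxels.

The steering optimizer iterates a time-reversal-flavoured scheme (the
update rule is this package's own design): per frequency, the steering
vector maximizing cold-tail target SAR against hot-tail healthy SAR is
the dominant generalized eigenvector of the two tail covariance matrices
(ridge-regularized); tails are re-identified from the current best plan
each sweep and frequency weights re-balanced over a small candidate set
(single frequencies, uniform, seeded Dirichlet draws, current weights);
only improvements are accepted (tolerance 1e−4 on HCQ, ≤10 sweeps). The
search is initialized with uniform-phase equal-amplitude steering (all
frequencies and each alone), 200 seeded random steerings, and any
caller-supplied plans, so the result is never worse than its best
initialization. HCQ is scale-invariant, so the absolute power level is
deferred entirely to the thermal stage.

## Arrangement optimization

Candidate arrays of n_c antennas are drawn area-uniformly with rejection
until feasible: pairwise clearance |L| − l_i − l_j > 0 (l = the 43.5 mm
enclosing-circle radius projected on L in each antenna's UV plane;
coincident antennas take the limit l = r) and eye avoidance (eyes
projected radially onto the bolus as discs inflated by the antenna
radius; chordal distances). The candidate count is round(n_patches/n_c),
n_patches being the triangle count of the interpolation grid — more
antennas mean more permutation redundancy among layouts, so fewer
candidates are needed. Because channel order is semantically redundant,
population-based global optimizers are a poor fit; candidates are instead
scored by the full pipeline (interpolate each channel, apply the K = 3
coupling correction, optimize steering), sorted, and refined locally by
SLSQP on (θ, φ) with 0.5° forward finite differences, φ unbounded with
modular wrapping, under the same constraints. Refinement walks the sorted
list and stops at the first candidate whose refined cost exceeds the best
refined cost so far; a diverging or infeasible refinement falls back to
its unrefined candidate with a warning. Ties between equal refined costs
break toward the more compact layout.

## Bioheat evaluation

The steady-state Pennes equation ∇·(k∇T) − ρ_b c_b ω (T − 37 °C) + PLD = 0
is discretized with a 7-point finite volume over patient voxels
(harmonic-mean face conductivities), Robin conditions on exterior faces
(h = 100 W/m²/K to 30 °C water at the bolus contact, 8 W/m²/K to 20 °C
air elsewhere, assembled as half-cell conduction in series with the film
coefficient; lattice-boundary faces adiabatic), and a direct sparse
solve. The water bolus is not meshed — its entire effect is the Robin
condition. ρ_b c_b = 3.6 · 10⁶ J/m³/K; perfusion is constant per tissue
(no thermoregulation). Verification: the 1-D slab with constant source
matches its parabolic closed form with the expected O(h²) wall-closure
error, and flux balance holds cell by cell.

The deposited power PLD = κ Σ_f ½σ_f |E_f|² (no averaging, no masking)
is scaled so the maximum healthy-tissue temperature equals 42 °C. T is
affine in κ, so two solves fix the response and κ is bisected on the
cached affine maximum to ±0.01 °C — the same fixed point a gradient
search would find, but guaranteed by the monotonicity of max T in κ.
T50/T90 are the minimum temperatures within the hottest 50 %/90 % of the
target distribution (nearest rank).

## Validation metrics

Approximated and reference SAR maps are compared after normalization to
unit mean over the evaluation domain (mask metrics are invariant to any
monotone rescaling): mean relative absolute difference ε_DIS, and the
overlap fractions of hot-spot (q-tail of remaining tissue) and cold-spot
(p-tail of target) masks derived independently from each map. A location
sweep interpolates at poses marching from a patch corner to the opposite
edge midpoint and reports the field error metrics per step and frequency;
error vanishes at the corner by grid-node exactness and peaks mid-patch.

## Problem sizes and determinism

The test bed runs layered-sphere phantoms at 8–10 mm and the synthetic
head at 4 mm, grids of 15–221 nodes, and one to three frequencies —
sizes chosen so the full suite exercises every stage end-to-end at desk
scale. All stochastic steps (phantom blobs, grid starts, random
steerings, candidate sampling, noise) are driven by explicit integer
seeds through `numpy.random.default_rng` and are bit-reproducible.

## Known limitations

- The ray-based oracle omits diffraction, multiple scattering and
  standing waves; passing tests bound the machinery's correctness, not
  the fidelity of any full-wave field. With FEM exports in the same
  container, every downstream stage applies unchanged.
- Tissue properties are tabulated only at the three operating
  frequencies; no Cole–Cole evaluation at arbitrary frequency.
- Constant perfusion (no thermoregulation) and no transient thermal
  dynamics or CEM43 dose.
- The eye-exclusion projection and the SAR normalization convention are
  reasonable choices among several; both are isolated behind single
  functions and configurable.
- Antenna rotation about W (polarization angle) is not a design variable.
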