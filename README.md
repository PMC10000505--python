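# helmetplan

Design tools for ultra-wide-band (250–500 MHz) **helmet applicators** for
deep microwave hyperthermia of brain tumors.

Conformal phased arrays heat deep-seated tumors by constructive
interference of microwave fields, while hot spots in healthy tissue —
typically in poorly perfused, highly conductive cerebrospinal fluid —
limit the deliverable power. For brain targets, a semi-spherical "helmet"
arrangement with freely placed antennas can outperform the classical
equally spaced ring, but searching over arrangements requires evaluating
thousands of candidate arrays, each of which would normally need a
full-wave electromagnetic simulation per antenna. This package implements
the fast design loop that makes that search tractable:

1. **Anatomy** (`helmetplan.anatomy`): voxel tissue phantoms (layered
   sphere; synthetic layered head with an embedded tumor blob of
   prescribed volume) with per-tissue dielectric and thermal properties at
   {250, 375, 500} MHz.
2. **Geometry** (`helmetplan.geometry`): least-squares bolus-ellipsoid
   fitting, antenna frames `(U, V, W)` on the bolus surface, and
   repulsion-spread surface grids (minimizing Σ 1/d², the energy of like
   charges) with their Delaunay triangulation.
3. **Field oracle** (`helmetplan.fieldsim`): an analytic, ray-based
   polarized antenna field `E = D(ψ) p(x) e^{-jk̃s}/s` with tissue-dependent
   complex phase accumulation — a smooth, dispersive, anatomy-aware
   stand-in for a full-wave solver (FEM exports can be carried through the
   same HDF5 container).
4. **Interpolation** (`helmetplan.interp`): the E-field of an antenna at an
   *arbitrary* surface pose from the three nearest grid fields —
   impedance-normalize (H-field surrogate), rigidly transform frames,
   restore, and blend with barycentric area weights; error metrics
   ε_DIS/ε_ABS/ε_ANG/ε_DIR.
5. **Coupling** (`helmetplan.coupling`): per-frequency complex coupling
   coefficient `c` fitted from two-antenna experiments
   (k_AP = c·⟨U_P, E_A(O′_P)⟩) and the array correction
   `Ê = M^(K−1) E` with unit diagonal and `c·e_ij` off-diagonal (K = 3
   propagations by default).
6. **Planning** (`helmetplan.planning`): multi-frequency SAR
   `Σ_f ½σ_f/ρ |Σ_c χ_{f,c} E_{f,c}|²`, 5 g mass averaging, 20 mm
   surface-exclusion masks, and minimization of the hot-to-cold spot
   quotient `HCQ_p = SAR̄_R^q / SAR̄_T^p` (q = p·|T|/|R|) over the complex
   steering parameters χ by an iterated generalized-eigenvector
   (time-reversal-style) scheme.
7. **Arrangement optimization** (`helmetplan.arrayopt`): constrained random
   search (round(n_patches/n_c) candidates, non-overlap and eye-avoidance
   constraints) followed by local SQP refinement with sorted early
   stopping.
8. **Bioheat** (`helmetplan.bioheat`): steady-state Pennes solver
   (7-point finite volume, convective boundaries: 8 W/m²/K to 20 °C air,
   100 W/m²/K to 30 °C water), power scaling κ to a 42 °C healthy-tissue
   limit, and the target T50/T90 indexes.

## Worked example

A two-antenna toy on the layered sphere phantom — build the phantom and
masks, generate per-channel fields, optimize the steering, and evaluate
the thermal outcome:

```python
import numpy as np
import helmetplan as hp

spec = hp.PhantomSpec(outer_radius=96.9, bolus_thickness=30.0,
                      tumor=hp.TumorSpec(center_mm=(0, 0, 0), volume_ml=30.0))
model = hp.build_layered_sphere_phantom(spec, spacing=8.0)
masks = hp.build_evaluation_masks(model, p=50.0, exclusion_depth_mm=20.0)
print(f"target {masks.n_target} voxels, remaining {masks.n_remaining} voxels, "
      f"q = {masks.q:.2f}%")

bolus = hp.Ellipsoid(radii=(116.9, 116.9, 116.9))
fields = hp.FieldSet(spacing=model.spacing, origin=model.origin)
poses = [hp.antenna_frame(bolus, np.pi / 2, 0.0),
         hp.antenna_frame(bolus, np.pi / 2, np.pi)]
for c, pose in enumerate(poses):
    fields.add(c, 500e6, hp.oracle_antenna_field(model, pose, 500e6))

plan = hp.optimize_steering(fields, model, masks, seed=1)
print(f"optimized HCQ = {plan.hcq:.2f}")

thermal = hp.scale_power_to_limit(model, fields, plan.chi, limit_c=42.0)
print(f"kappa = {thermal.kappa:.3f}, max healthy T = {thermal.max_healthy_t:.2f} C, "
      f"T50 = {thermal.t50:.2f} C, T90 = {thermal.t90:.2f} C")
```

Output:

```
target 60 voxels, remaining 3804 voxels, q = 0.79%
optimized HCQ = 180.81
kappa = 1.954, max healthy T = 42.00 C, T50 = 37.01 C, T90 = 37.01 C
```

The optimizer finds the symmetric excitation (equal amplitudes, zero phase
offset) for the mirror-symmetric pair. The large HCQ and the barely warmed
deep target are the expected physics of this deliberately hard toy: two
antennas cannot focus past the superficial hot spot, and the power scaling
stops at the 42 °C healthy-tissue ceiling long before the centrally seated
target heats — exactly the failure mode that denser, well-arranged helmet
arrays (and the HCQ objective) are designed to overcome.

A command-line interface mirrors the library
(`helmetplan phantom/grid/bank/plan/design/thermal/validate`); run
`helmetplan --help`.

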