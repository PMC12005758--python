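# Methods

This note documents the physical model, the numerical choices, the
synthetic-data assumptions and the known limitations of `magassembly`.

## Physical model

### Magnetic force chain

The permanent magnet is modeled as a uniformly axially magnetized
cylinder.  Its exterior flux density is evaluated in closed form
(Derby–Olbert solution) through Bulirsch's generalized complete elliptic
integral `cel`, implemented in `magassembly.magnet` and validated in the
suite against (a) the on-axis closed form, (b) a numerical
magnetic-surface-charge quadrature, and (c) the point-dipole limit at 20×
the magnet size (1%).

The force on one superparamagnetic nanoparticle is
F = μ₀ V_NP f(|H|) (H·∇)H with the two-branch magnetization factor
f(H) = min(3, M_NP/|H|).  M_NP converts the mass saturation magnetization
(60 emu g⁻¹) to volumetric units with the magnetite density
ρ_NP = 5180 kg m⁻³; ρ_NP is configurable because it also sets the total
particle count N_NPtot = m_NPtot/(V_NP ρ_NP).  In the current-free
exterior (H·∇)H ≡ ½∇|H|², an identity the tests assert at 10⁻⁶; the
production path exploits it by precomputing |H| and ½∇|H|² on an
axisymmetric (ρ, z) grid (768 × 512 over the well footprint, bilinear
interpolation, verified against direct evaluation to ~0.2% median error).
A spheroid feels N_NP,i times the single-particle force at its center.

The magnet's vertical position is not a free dial: the top face is placed
below the well floor at the gap for which the on-axis floor field equals
the measured 0.4 T maximum (≈1.04 mm with Br = 1.48 T, solved by Brent's
method).  Both the nominal-remanence and gap-calibrated placements are
available.

### Contact mechanics and dynamics

Sphere–sphere and sphere–well contacts use Hertz repulsion
F_H = (4/3)E*√r̂ δ^{3/2} with 1/E* = (1−ν²)/E_a + (1−ν²)/E_b and ν = 0.5
for both tissue and well material (standard DEM convention; the published
table gives only the two moduli, 120 and 1000 Pa).  The well is an
analytic cylinder (floor plane + lateral wall, r̂ = rᵢ at the wall).  The
tabulated spheroid–well adhesion energy density (10⁻²⁰ N m⁻¹) appears in
no force law and is numerically negligible at these scales; it is stored
for fidelity but no adhesion force is applied.  Rotational motion is
ignored throughout.

Because the dynamics are overdamped, velocities solve C v = F with
3×3 blocks: diagonal 6πηrᵢI plus the damping tensors
S[c_t I + (c_n−c_t)n̂n̂ᵀ] of every contact at spheroid i, off-diagonal the
negated pair tensor.  C is sparse, symmetric and positive definite
(Cholesky-checked in tests on randomized crowded states), and is solved
by Jacobi-preconditioned conjugate gradients to relative residual 10⁻¹⁰
(configurable), warm-started from the previous step's velocities and
verified against dense solves to 10⁻⁸.

Semi-implicit stepping: for implicitness λ > 0 the operator becomes
C + λΔt Σ g′(δ) n̂n̂ᵀ (diagonal) / −λΔt g′ n̂n̂ᵀ (off-diagonal) with
g′ = d|F_H|/dδ, which only adds positive semidefinite terms.  The
published parameterization uses λ = 0, so the implicit branch is
config-gated and tested but inert by default.  A thermal term
√(2DΔt)·N(0,1) is implemented for D > 0 and off by default (the text's
own argument: spheroids above 100 µm radius make stochastic forces
negligible).

### Stability guard

With soft contacts (E ~ 10² Pa) and strong near-field magnetic forces,
explicit steps can overshoot.  Each step is therefore sub-divided
adaptively so no spheroid moves farther than 0.1 × r_min per sub-step,
with forces and the mobility system recomputed per sub-step.  This guard
is what keeps the late, densely packed stage stable without shrinking the
global timestep.

### Engines

`run()` drives either a numba-compiled kernel (production; O(n²) in-kernel
contact sweep, matrix-free CG, field-table lookup) or a pure-numpy
reference path (KD-tree contact candidates, explicit sparse assembly).
Both implement the identical algorithm — including the interpolation
arithmetic, bit for bit — and the suite asserts trajectory agreement with
a naive dense-solve reference at 10⁻⁶ over 1000 steps.  A sharp-interface
caveat: packed contact dynamics amplify last-bit differences
exponentially, so cross-engine agreement is asserted on a horizon before
dense pile-up; per-step equivalence holds throughout.

## Readouts

* **Coverage**: area of the union of equatorial disks projected on the
  floor, rasterized (default pixel r_min/10), clipped to a circular ROI
  of 2.5 mm radius — the magnet footprint, which is also the final
  implant's size.  Validated against exact polygonal unions.
* **Assembly time**: first time coverage reaches 95% of its final plateau
  (linear interpolation between snapshots).  The threshold convention is
  ours — published kinetics plots of this process do not define their
  "time coefficient" — so the threshold is configurable and a saturating-exponential time
  constant is reported alongside.
* **Rate profile**: per-interval speed normalized by spheroid radius,
  binned by distance from the magnet axis.
* **Stress profiles**: per-spheroid body force (magnetic + gravity;
  gravity contributes ~10⁻⁵ N m⁻² and is retained for completeness,
  toggleable) over the cross-section πrᵢ², projected on the outward
  radial unit vector (radial) or ẑ (vertical); negative = compressive.
  Contact forces are excluded from these profiles by design; they remain
  available from trajectory exports.  Binning domain defaults to the
  magnet footprint, matching the extent over which the construct forms.

## Synthetic data

The generators provide every input the pipeline consumes:

* **Populations**: lognormal radii (default mean 100 µm, CV 0.1 —
  measured size distributions are not published; defaults
  correspond to ~250-cell microtissues), positions uniform in the well
  with overlap rejection, fully contained at init.  Default population
  1200 (≈300,000 cells/well ÷ 250 cells each); the study protocol uses
  300 (below).
* **NP counts**: Normal(µᵢ, µᵢ/2) as published; negative draws are
  truncated to zero then rounded (the published sampling rule leaves
  negative draws unspecified).  Expected allocated total = α·N_NPtot,
  verified by Monte Carlo at 1%.
* **Hysteresis curves**: Langevin-shaped, m = m_Fe·M_sat·L(B/B_scale)
  with fixture scale B_scale = 0.05 T (a shape parameter, not a measured
  quantity), odd in the field, flat when m_Fe = 0 — the control-tissue
  signature.
* **Fiber images**: sinusoidal stripe textures at a prescribed angle plus
  Gaussian noise.

What the generators do **not** emulate: real microtissue size outliers and
doublets, field inhomogeneity from neighboring magnets in a multi-well
grid, instrument drift/coercivity in magnetometry, and the speckled,
partially curved fiber morphology of real second-harmonic images.  Tests
passing on these fixtures therefore validate the algorithms' correctness,
not their robustness to every artifact of real acquisitions.

## Study protocol and scale

The canonical reproduction study (`magassembly.study`) uses n = 300
spheroids, 6 s of simulated time at Δt = 10⁻⁴ s, output every 50 ms, and
five seeds per loading condition.  These sizes were chosen so a full
two-condition, five-seed study runs in minutes on one core; the
time-step-halving test (final positions change <1% when Δt is halved)
supports the resolution, and 6 s comfortably brackets the coverage
plateau (assembly completes by ~2.5 s in both conditions).  Because the
total added nanoparticle mass is divided among the spheroids present,
per-spheroid loads at n = 300 are larger than at the experiment's ~1200
microtissues per well; assembly times are insensitive to this (transport
is rate-limited by the far-field, where timing scales weakly), while
stress magnitudes scale ∝ 1/n.

## Known limitations

* **Radial stress magnitude.** With a single axially magnetized cylinder
  calibrated to 0.4 T at the floor, the lateral gradient of |H| within
  the assembled construct (radius ≲ 2 mm, inside the 2.5 mm magnet rim)
  is small: the radial body-force stress peaks at only a few N m⁻², and
  its magnitude *grows* toward the rim (it vanishes on-axis by symmetry).
  The published radial-stress quantification (−30 / −52 N m⁻²,
  decaying away from the center) are an order of magnitude larger and
  shaped differently; they are consistent with a field carrying much
  stronger lateral gradients (e.g. the measured multi-magnet grid map) or
  with an internal-stress measure that includes contact forces.  This
  package reports what the specified single-magnet body-force model
  produces.
* **Vertical stress flatness.** Vertical stress is nearly constant over
  the construct interior (CV ≈ 0.1 across interior bins) but drops in the
  outermost occupied bin, so the coefficient of variation over all
  occupied bins is ≈ 0.5.
* Hydrodynamic interactions between spheroids, lubrication, rolling
  friction and history-dependent tangential friction are not modeled.
* Multi-magnet grids are only available as naive superposition of
  cylinder fields and are not calibrated against measured maps.
* The FFT directionality analysis assumes roughly uniform illumination;
  strong low-frequency shading should be removed before analysis.
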