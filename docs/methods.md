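# Methods

This note records the models, conventions and design choices behind
`mgdrqa`, in the spirit of a methods appendix: enough detail to reproduce or
challenge any number the package prints.

## Coordinate and geometry conventions

Patient coordinates are millimetres: x to the patient's left, y anterior,
z superior. A voxel's position is its center; voxel indices are 0-based;
the grid extent is the half-open box `[origin − spacing/2,
origin + (shape − 1/2)·spacing)`. Gantry angles follow IEC 61217 (0° =
source anterior, increasing toward the patient's left); the source sits at
distance SAD (default 1000 mm) from the isocenter in the isocenter's axial
plane. The beam's in-plane axes are the cross-plane direction in the axial
plane (u) and the superior direction (v), rotated about the beam axis by
the collimator angle. Structure masks use voxel-center inclusion (even–odd
rule for contour rasterization), not partial-volume weighting, so the
voxel-counting DVH downstream is consistent with the masks by construction.
Structures are evaluated on the dose grid, not on a separate imaging grid.

## The reconstruction chain

The error map is the ratio of measured to planned planar dose at each
detector node, with nodes below `min_dose_fraction` (default 0.05) of the
planned planar maximum masked invalid. Node coordinates are rescaled from
the measurement plane to the isocenter plane by the projective factor
SAD / source-plane distance; scaling is applied to node coordinates first,
then the map is interpolated (the alternative order differs only by the
interpolation lattice and is not observable at 5 mm node pitch).

The error is applied **multiplicatively**. A ratio map makes two properties
exact, and the test suite enforces both bitwise: measured ≡ planned implies
predicted ≡ planned, and scaling every measurement by k scales every
covered predicted voxel by exactly k. (Internally the map is interpolated
as a deviation from the neutral ratio 1, so bilinear weight rounding cannot
break the identity.) An additive difference mode (`mode="additive"`) exists
for sensitivity studies; it does not satisfy the homogeneity property and
is not the default.

Rays that miss the detector extent, and map cells touching an invalid
node, contribute the neutral ratio — measurement error is never
extrapolated beyond detector coverage; both event counts are reported.
Interpolated ratios are clamped to [0.5, 2.0] by default so detector noise
over near-zero planned dose cannot explode the prediction; clamps are
counted and logged, and the bound is configurable.

## Gamma analysis

Global normalization only (the per-organ/3D analysis the package exists for
is defined with global criteria). The normalization dose defaults to the
maximum of the reference distribution, the common array-QA convention; a
prescription-dose normalization is available. Reference/evaluated roles:
the measurement is the reference for detector-plane 2D QA; the planned dose
is the reference for the predicted-vs-planned 3D analysis. The roles matter
(gamma is asymmetric) and are fixed in configuration, not guessed.

The evaluated distribution is linearly interpolated on an offset lattice of
step `interp_step_fraction × DTA` out to `search_radius_factor × DTA`
(defaults DTA/10 and 3×DTA; beyond 3×DTA a gamma value has no further
clinical meaning). Offsets are processed in radius-sorted shells and a
point leaves the search once the spatial term alone exceeds its current
best — an exact bound, so the result equals a dense exhaustive search at
the same step; the suite checks this against an independent brute-force
oracle on random lattice pairs. Gamma exactly 1.0 passes. Points below the
lower threshold (10% of the normalization dose in 2D, 3% in 3D) are
excluded from passing rates; a passing rate over an empty evaluated set is
reported as undefined, never as 0 or 100.

For 3D runs the orchestration layer uses an interpolation step of DTA/5:
on a 2 mm dose grid this is sub-voxel sampling and changes passing rates
by less than the reporting precision relative to DTA/10.

## DVH and radiobiological models

DVHs are voxel-counting histograms (default bin width 0.01 Gy in the
library, 0.05 Gy in the report orchestration). Each bin stores the mean of
the voxel doses that fell into it; generalized means (EUD) and the NTCP
product therefore evaluate exactly on piecewise-uniform dose
distributions instead of acquiring half-bin bias. `D_x%` uses the "≥" on
cumulative volume convention with linear interpolation between bin edges;
`V_xGy` interpolates the cumulative curve.

TCP is evaluated at the EUD of the target DVH (the standard EUD-based
formulation): a voxelwise logistic cannot yield one TCP per plan without an
aggregation rule, and the EUD is that rule. For EUD with negative
exponents, zero-dose bins are clamped to a 0.01 Gy floor — the a < 0
generalized mean is otherwise annihilated by a single empty voxel, which is
numerically correct but clinically meaningless. NTCP follows the relative
seriality model exactly as written over the differential DVH bins; the
uniform-dose identity NTCP(D50) = 1/2 holds to ~1e−14 for any seriality s
because the product is accumulated with `log1p`/`expm1`.

### Parameter registry

The shipped registry (`mgdrqa/data/radiobio_params.yaml`):

| structure | endpoint | parameters |
|---|---|---|
| PTV | local control | EUD exponent a = −7.23, γ50 = 0.89, TCD50 **configurable** (default 45 Gy) |
| ipsilateral lung | pneumonitis | D50 = 26.16 Gy, γ = 0.97, s = 0.012 |
| heart | late cardiac mortality | D50 = 52.3 Gy, γ = 1.28, s = 1.0 |

Two caveats are deliberately loud. First, published parameter tables for
breast local control list −7.23 in the dose-parameter column; a negative
dose is meaningless, and −7.23 is a textbook EUD volume-effect exponent for
tumors, so it is stored as `a` and TCD50 must come from configuration. The
45 Gy default is a placeholder in the plausible range for conventionally
fractionated breast control; TCP values are meaningful for
planned-vs-predicted *comparison*, not absolute outcome prediction.
Second, the lung row's printed form is typographically ambiguous (a stray
leading digit); the registry stores the parse consistent with a strongly
parallel organ (s = 0.012) and is overridable by a user YAML file.

## Beam-profile metrics

Region boundaries: exactly 80% of CAX is central ("80% or over"), exactly
20% is out-of-field ("up to 20%"); the partition is exhaustive and
exclusive. The penumbra DTA defaults to the 50% iso-level averaged over
both field edges; the level is configurable because published tables do
not always state whether one or several levels were averaged.

## The synthetic study conditions

The generator emulates two tangentially opposed 6 MV beams (gantry
50°/230°, SAD 100 cm, aperture half-widths 32 × 45 mm, 50 Gy total at the
isocenter) on a 64×64×48 grid at 2 mm — sizes chosen so the full chain runs
in seconds while keeping ≥10⁵ evaluated voxels. The phantom holds a PTV
ellipsoid at the isocenter, a large ipsilateral lung posterior-lateral to
it whose anterior surface *grazes the posterior field edge by ≈5 mm* (the
realistic tangential-breast feature that makes lung V20Gy constraints
necessary), and a small heart carved out of the lung region by priority
(PTV > heart > lung, all clipped to the body).

The beam model is analytic, not a transport calculation: exponential
attenuation (μ = 0.005/mm water-equivalent, lung density 0.25) along
radiologically marched rays, a 10 mm buildup, inverse-square divergence,
and a lateral profile per axis made of a sharp logistic penumbra (80–20%
width ≈ 6 mm), a low-amplitude broad shoulder (8%, 12 mm scale) feeding the
near-field region, and a 2% out-of-field plateau. Per-beam 3D doses are
normalized so the trilinear dose at the isocenter equals the requested
output exactly. Planar "measurements" sample the same lateral model in a
water slab at 5 cm depth on the 5 mm detector lattice (detector plane at
the isocenter distance); injected errors transform the planned planar dose
(global scale, multiplicative Gaussian ratio blob, rigid field-edge shift),
with optional multiplicative Gaussian detector noise (off by default; all
generation is bit-deterministic for a fixed spec and seed).

The default *decoupling scenario* places a +20% Gaussian blob (σ = 12 mm)
10 mm outside each beam's posterior field edge, centered where the planar
dose sits near the 10% lower threshold. Its tail reaches the in-field lung
sliver: the per-beam 2D GPR at 3%/3 mm stays above 95% (the blob core is
threshold-excluded, and penumbra nodes are rescued by the distance term),
while in the reconstruction the lung shelf accumulates dose errors above
3% of the global maximum in a flat region — so the predicted lung 3D GPR
drops below the PTV's, and lung V5Gy/V20Gy/NTCP shift upward with PTV
D95% essentially unchanged. This reproduces the direction of the
2D-vs-per-organ-3D decoupling; the magnitudes are properties of the
synthetic conditions, not of any clinical cohort.

What the synthetic data does **not** emulate: CT-number heterogeneity
beyond the single lung density, MLC segment sequences and leaf-end effects,
detector angular response, setup error, or breathing motion. Passing tests
therefore demonstrate the correctness of the QA chain's computations and
their stated invariants on controlled inputs — not clinical accuracy of any
TPS or detector.

## Numerical choices and degenerate inputs

* Gamma search: exact early exit (no approximation); offsets outside the
  evaluated lattice are skipped; an all-below-threshold reference is a
  degenerate-input error.
* Error map: ratio is neutral (1.0) outside coverage and at invalid nodes;
  covered voxels are those whose ray hit lands in a cell with four valid
  nodes.
* Rays at or behind the source plane are a geometry error naming the voxel.
* DVH: differential sums to 1 within 1e−9 by construction; an emptied mask
  raises rather than returning an empty curve.
* DICOM RT Dose: 32-bit stored values with DoseGridScaling chosen from the
  grid maximum; non-uniform frame offsets or a missing scaling attribute
  raise a format error naming the attribute.
* Reports round floating values to 6 decimals and carry a config digest,
  package version and seed, so byte-identical reproduction is a provenance
  check.

## Known limitations

* The reconstruction perturbs only the planned dose along source rays;
  scatter-path changes from delivery errors are not modeled (inherent to
  the MGDR approach, not just this implementation).
* Local-normalization gamma and interpolation-free analytic gamma variants
  are out of scope; global normalization only.
* No EQD2/fractionation correction in TCP/NTCP; parameters are for total
  physical dose under conventional fractionation.
* The 2D analysis of real detector exports is supported via the portable
  planar format; proprietary vendor file formats are not parsed.
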