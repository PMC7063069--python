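# Methods

This note records the models, conventions, parameters and design choices
behind the package, and what the synthetic testbed does and does not show
about clinical data.

## Coordinate conventions

World coordinates are patient coordinates in mm; the gantry rotates about
the world z axis (patient superior–inferior).  At gantry 0° the source is
on +y and the beam travels toward −y; the angle increases toward +x at
90° (IEC-61217).  The beam frame has its origin at the isocenter with +z
toward the source (source at (0, 0, SAD)), x/y spanning the field; the
frame is right-handed and co-rotates with the gantry.  Collimator and
couch rotations are not modeled (the collimator field exists and is
validated to 0).  Grids are axis-aligned, 0-based, with `origin` the world
position of the center of voxel (0, 0, 0); lengths are mm and angles
degrees at every interface.

## Deformation fields

A DVF stores, per voxel, the displacement from planning to daily anatomy
(`x` → `x + v(x)`); consumers needing the opposite direction invert
explicitly.  Analytic families: zero, constant translation, isotropic
scaling about a center (`v = (f−1)(x−c)`), an isotropic Gaussian bump, and
*windowed* translation/scaling — the affine field multiplied by a radial
smoothstep that is 1 inside `r_inner` and 0 beyond `r_outer`.  The
windowed families model a localized organ deformation: a global affine
field would move the body outline and change every radiological path,
conflating fluence adaptation with dose-scale shifts the method does not
claim to correct.

Inversion is fixed-point iteration `u ← −v(x + u)` (default 20 sweeps,
tolerance 0.01 mm, composition residual logged; a warning, not an error,
on poor convergence).  The windowed fields have displacement gradients
approaching 1 in the falloff shell, so pipeline code that inverts them
requests 80 sweeps.  Out-of-bounds samples return zero displacement —
rays and warps routinely touch the volume border.

Volume warping is backward mapping through the inverted field with
trilinear interpolation.  Structure propagation uses the same backward
map, sampling the binary indicator trilinearly and thresholding at 0.5
(≥ resolves the tie): the propagated surface is then localized to
sub-voxel accuracy, where nearest-neighbour sampling (available via
`interp="nearest"`) carries a half-voxel classification band that is
visible at 4 mm voxels.

## Beam's-eye-view reduction

Each plane pixel's ray is traversed through the voxel grid by a
parametric (Siddon-type) sweep: boundary-crossing parameters are merged
and each sub-interval assigned to the voxel containing its midpoint.
Chord lengths below 10⁻⁹ mm count as grazing contacts and are dropped;
the retained lengths sum to the box chord to float precision.  The pixel
vector is the unweighted mean of the projected displacements of the ROI
voxels crossed (division by the plain count *n*); a chord-length-weighted
mean is available behind a flag for sensitivity checks, and one central
ray per pixel is used (no sub-pixel supersampling).

Pixels whose rays miss the ROI can be filled three ways: `zero` (leave
them undeformed — the standalone default, preserving fluence far from the
target), `nearest` (copy the nearest covered vector), `smooth` (Laplace
interpolation with covered pixels as Dirichlet data).  The *scenario
harness* defaults to `nearest`, because the one-pixel aperture rim just
outside the ROI silhouette carries planned intensity that must travel
with the target; pixels with zero intensity are unaffected by any fill.

## Fluence warping

`push` splats each pixel's intensity forward with bilinear weights; it
conserves the total (up to what leaves the plane) and reproduces
whole-pixel shifts exactly, but dilutes the pattern under expansion and
carries a first-order sub-pixel aliasing ripple: its round trip with the
exact inverse map recovers a smooth map only to a few percent L1.  `pull`
samples the input at `center − vector` (the small-deformation
approximation of the inverse map); it transports intensity *values* — an
adapted aperture keeps each ray's intensity at its displaced position —
cannot leave holes, gives the moved edge a clean sub-pixel penumbra, and
its round trip is second-order accurate (<1 % L1 on smooth maps).  The
adaptation pipeline therefore warps with `pull` (combined with
nearest-fill so leading-edge destinations have vectors); `push` remains
the standalone default and is the right tool when intensity mass, not
value, must be conserved.  `conserve_total` rescales the output sum to
the input sum exactly when requested (off by default — MU renormalization
is a plan-level decision).

## MLC sequencing

The map is quantized to `levels` uniform intensity levels (default 10,
step = max/levels) and decomposed row-wise by the classical
unidirectional sweep: per leaf row the exposure window [s_j, e_j) of each
pixel is scheduled so both leaf trajectories are monotone, the exposed
set at any instant is provably a single interval, and the delivered MU
equals the sweep bound — the maximum over rows of the summed positive
gradients.  Reconstruction (weight × aperture indicator, pixel centers
strictly between leaves and inside jaws) reproduces the quantized map
exactly for *all* profiles; for unimodal rows the segment count is at
most `levels`, for multimodal rows it may exceed it (flagged in the plan
metadata) — exactness was preferred over capping the count.  Leaf rows
align with fluence rows (leaf width an integer multiple of the row
spacing; grouped rows deliver their maximum).  Jaws are the tightest
pixel-snapped rectangle around pixels above 1 % of the maximum, plus an
optional margin.  Leaf travel and interdigitation constraints are not
enforced.

## Contours

Filling rasterizes each slice's polygons with the even-odd rule (nested
polygons are holes) testing voxel centers; extraction runs per-slice
marching squares at iso-level 0.5 on the padded binary mask, so every
polygon is closed and refilling recovers the mask except at most a
one-voxel boundary band (fill ∘ extract is idempotent after one round
trip).

## Dose engine

Per beam and voxel:

    dose = I(x′, y′) · exp(−μ · d_rad) · (SAD / (SAD − z))²

with I sampled bilinearly at the voxel's plane projection, d_rad the
water-equivalent path from the grid entry point (midpoint rule, 64
samples), and the squared magnification the inverse-square correction
(fluence is defined at the plane, distance SAD from the source).  Before
sampling, the fluence is convolved with a Gaussian of
`penumbra_sigma_mm` (default 3 mm, a typical megavoltage source penumbra
scale).  The penumbra matters beyond realism: with an ideally sharp edge,
calibrating a plan to "D95 = prescription" pins a large voxel population
exactly at the prescription isodose, and every dose-volume quantile
becomes a discontinuous function of geometry — sub-percent radiological
changes then swing V100 by several points, a regime real plans do not
exhibit.  μ defaults to 0.005 /mm (≈ 6 MV in water).  The engine is
exactly linear in the fluence, geometrically faithful and deterministic;
it has no scatter kernel, no buildup and no electron transport, which is
acceptable because the package's claims concern fluence adaptation, not
absolute dosimetry.

Metrics: Dq is the linear-interpolated percentile of the structure's
voxel doses (minimum dose to the hottest q %); Vx the percent volume at
or above x Gy; HI = D5/D95.  Curves are exported on a uniform dose grid;
point metrics never pass through bins.

## Synthetic thorax and study conditions

Default scene: 64³ grid at 4.0 mm voxels (256 mm field of view — large
enough for a thorax-scale cross-section, the reason 4 mm was preferred
over a finer grid of smaller extent); an elliptical-cylinder body
(110 × 90 mm), two lungs (relative density 0.26), a 22 mm-radius tumor
(1.05) centered in the left lung 60 mm from the nearest body surface, a
posterior cord; CTV = tumor + 5 mm, PTV = CTV + 5 mm (margins realized by
Euclidean-distance dilation with a half-voxel surface allowance, which
makes the dilated volume track the analytic radius instead of
undershooting by ~0.4 voxel); five coplanar beams every 72°, SAD
1000 mm, prescription 60 Gy.  The reference plan is a uniform conformal
field over each beam's PTV shadow, globally calibrated so PTV D95 equals
the prescription (the clinical prescription statement; with the penumbra
this leaves the CTV fully covered with ≈ 2 Gy of headroom, as deliverable
plans have).

Daily anatomies apply a windowed affine transform about the tumor center
(`r_inner` 44 mm, `r_outer` 58 mm < 60 mm, so the body surface and cord
never move).  The daily tumor is re-rasterized from the transformed
sphere; the daily CTV/PTV are the *exact affine images of the planning
masks* — margins deform with the tissue, exactly as registration-based
contour propagation produces them — and the lungs, which intersect the
falloff shell, are propagated through the exact field.  The ground-truth
field and the daily masks are therefore mutually consistent by
construction, which the tests verify (Dice ≥ 0.95 through the generic
propagation path).  The two study deformations are an 8 mm tumor
translation and a ×1.25 isotropic tumor expansion; optional seeded
Gaussian density noise is off by default.

The scenario harness evaluates, on the daily anatomy: the original plan
as-is; the original plan with the isocenter moved by the
overlap-maximizing couch shift (exhaustive translation search, 2 mm
steps within 15 mm, ties to the smaller then lexicographically smaller
shift); and the adapted plan (projection ROI = planning PTV, the
structure the aperture conforms to; nearest fill; pull warp; 10-level
re-sequencing).  All scenarios are evaluated as sequenced segment plans.

Test problem sizes: the closed-form and oracle tests use 8³–26³ grids and
10×10–24×24 planes with brute-force or dense-sampling oracles; the
end-to-end comparisons run the full 64³ phantom with all five beams.

## Known limitations

* The dose engine's primary-only model understates out-of-field dose;
  OAR metrics are comparative, not absolute.
* Covering a target that has genuinely grown costs integral dose: under
  the ×1.25 expansion the adapted portal area grows ×1.56 and mean lung
  dose rises by several Gy over repositioning.  No fluence-adaptation
  method can restore coverage of a larger target without this cost; the
  package reports it rather than renormalizing it away.
* The pull warp uses the negated forward field as an approximate inverse;
  exact only for translations, second-order accurate otherwise.
* The phantom has no CBCT artifacts, no registration error (the DVF is
  ground truth, standing in for a deformable-registration output), no
  breathing motion and no multi-modal fluence from a real optimizer, so
  passing tests demonstrate geometric correctness of the adaptation
  chain, not robustness to registration noise or clinical plan
  complexity.
* Coplanar beams only; collimator and couch rotations unmodeled.
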