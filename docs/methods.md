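# Methods

This note records the model implemented by `planecast`, the choices made
where the design was genuinely open, and what the test suite does and does
not demonstrate.

## Volume model and classification

A volume is a regular vertex grid `(Ex, Ey, Ez)` with strictly positive
per-axis spacing in mm and its world origin at vertex `(0, 0, 0)`; all
coordinates are 0-based. The transfer function is a piecewise-linear map
from gray value to color and opacity, clamped outside its control-point
range. Color is a single luminance channel by default; all samplers and
the compositor are channel-agnostic, so RGB control points work unchanged.

Classification order is configurable. *Pre-classification* (the default)
assigns optical properties to every vertex and interpolates those fields
along rays — the literal assign-then-sample pipeline. *Post-classification*
interpolates gray and classifies each sample. The two commute exactly
wherever the transfer function is linear across the gray values spanned by
a voxel, and differ near control-point kinks; tests pin the commuting case.

## Camera and ray enumeration

The source material for this renderer never defines a camera, so one had
to be chosen: orthographic, one ray per pixel, ray origins on a regular
grid (`pixel_pitch` mm) on a plane outside the volume box, centred on the
box centre. The in-plane frame is deterministic: `u = normalize(ζ × a)`
with `a = +z` unless `|ζ·z| > 0.9` (near-axial view) in which case
`a = +x`, and `v = ζ × u`. Ray directions are normalized at construction
so ray distances are metric (mm). Rays are clipped to the box by the slab
method; `t_enter` is clamped to ≥ 0 and a miss is a value, not an error.
Sample positions form the arithmetic progression `t_enter + n·δ` up to and
including `t_exit` (ties resolve to "inside", absorbed by a 1e-9 relative
tolerance). The default sampling distance is δ = 0.3 mm, matching the
spacing regime of the clinical geometry the phantoms mimic.

## Trilinear backend

Voxel location per axis is `i = ⌊x/Δx⌋`, `x_i = iΔx`, `x_n = (x − x_i)/Δx`,
with points exactly on the upper box boundary clamped to the last voxel
with local coordinate 1 (the bare floor rule would index a voxel that does
not exist there). The corner labels I0..I7 follow the unique layout
consistent with the interpolation chain — F1..F4 lerp along z, F5/F6 along
x, F along y. The scalar implementation is deliberately plain arithmetic
so the operation counter can execute it on counting cells; the renderer
uses an equivalent vectorized path, and a test asserts the two agree to
1e-12.

## Plane-cluster backend

The cluster axis is the dominant component of ζ (ties break x → y → z);
this is always valid — when direction components vanish the dominant axis
is by construction nonzero — and gives the densest plane bracketing. A
config override can force a specific axis, e.g. the y-cluster. For rays
travelling against the axis the per-plane distances decrease with plane
index; the intersection list is sorted by `t`, so entry/exit roles follow
ray order, not plane order.

Face interpolation uses exactly three vertexes — the base vertex of the
face and its two in-plane neighbours. This is a planar reconstruction, not
bilinear: the diagonal corner is unused, which drops the in-plane cross
term. Consequences, both pinned by tests against a bilinear oracle kept in
the suite:

* exact on fields affine in the face plane;
* at a face centre of the field `g·xz` (y-cluster), the error is exactly
  `g/4`, while trilinear sampling remains exact.

Whether the three-vertex formula is an approximation by intent or a
truncated bilinear is not decidable from its source; the literal formula
is implemented and its error characterised.

Between consecutive intersections, sample values come from the section
(definite-proportion) formula — linear interpolation in ray distance. A
sample landing exactly on an intersection takes the face value (the
formula's endpoint; no tie ambiguity). Sample positions keep the global
arithmetic progression from ray enumeration and are bracketed
independently; they are **not** re-phased per segment. Positions in the
sliver between the box boundary and the first (or last) plane crossing
clamp to that nearest intersection's value: the choice is continuous and
cheap, affects only sub-plane-spacing slivers at the box edge, and is the
one place the plane sampler is not exact on affine fields — which is why
the sampler-identity tests use axis-aligned views (where hitting rays
enter through a cluster plane and no sliver exists). A clipped segment so
short it crosses no plane at all falls back to trilinear sampling for
those few samples.

Because the three-vertex formula is not a convex combination, interpolated
opacities can overshoot [0, 1] marginally near edges; the renderer clips
opacity after sampling.

## Compositing

The compositor implements the front-to-back sum
`c_out = Σ c_i Π_{j<i} (1 − a_j)` with index 0 the viewer-nearest sample,
evaluated in one pass with an accumulated transparency product; an O(n²)
literal double loop is kept as an independent oracle and equality to 1e-12
is asserted on seeded random sequences. The prose convention "cast the ray
back to front" conflicts with this formula (whose first sample is
undimmed, i.e. nearest); the formula wins because it is the checkable
artifact, and a `back_to_front` flag reverses sample order for
experimentation. No opacity correction for sampling distance is applied,
so changing δ shifts the brightness of semitransparent media — documented
behaviour, exercised by no test as "correct brightness" for that reason.
Early termination (skip samples once accumulated transparency < 1e-4)
exists but defaults off so outputs and operation counts match the literal
loop.

## Operation counting

Convention: subtraction = addition, division = multiplication; floor,
comparisons and assignments are free. This is the unique simple convention
under which the traditional pathway's per-point cost enumerates to
17 additions / 16 multiplications with 3/9 for voxel location, and the
section formula to 4/2 per evaluation — the anchored figures. Counts exist
in two independent forms: *structural* closed-form tallies, and
*instrumented* tallies from running the real sampler code on counting-cell
scalars; tests assert the two agree and that tallies are invariant across
random inputs and spacings (structure-determined).

Per plane intersection this package's enumeration gives 9 additions /
8 multiplications (distance 1/2, cross coordinates 2/2, owning-voxel
quotients 0/2, face formula 6/2 — the quotients `V_i/Δx`, `V_k/Δz` are
computed once and reused in the face formula; the reuse policy is a
package decision). The published pairing of 15 additions /
19 multiplications for an entry/exit pair does not decompose under any
enumeration tried (natural variants give 18/16, 18/20, 18/12), so that
pair — and the 39/31 totals built on it — is echoed in the CLI table as a
descriptive reference only and asserted nowhere. Wall-clock timings and
acceleration ratios are hardware-bound and out of scope; the cost table is
the comparison surface.

## Phantoms

All test data is synthetic, generated from closed forms so samplers can be
checked against ground truth at arbitrary off-grid points: constant,
affine, general trilinear (the discriminating fixture — exact for the
trilinear sampler, quarter-cross-term error for the face formula), binary
sphere, ellipsoidal shell, Gaussian blob (the smooth image-similarity
fixture), and a `head_like` composition (bone-like ellipsoidal shell,
smooth soft-tissue interior with seeded low-frequency texture) that has no
closed form and exists for qualitative/IO exercises. Default geometry is
64×64×37 vertexes at 0.486×0.486×0.700 mm — clinical head-CT spacing at
reduced extent, so anisotropic-spacing behaviour is exercised at test
scale; gray values follow CT-like magnitudes (0–3000) so default transfer
functions are meaningful. Phantom generation is deterministic given the
spec (the seed is part of it).

What phantoms do not show: CT physics (noise, beam hardening, partial
volume), anatomical structure, or the 512×512×295-scale memory/throughput
regime. Image-similarity results on the smooth blob (normalised RMSE
< 0.02 between backends, measured ≈ 0.001) bound the samplers' disagreement
on smooth fields only; sharp-edged data concentrates face-formula error at
boundaries and the RMSE threshold is a package decision standing in for a
qualitative "almost the same" claim, not a clinical-equivalence statement.

## Numerical choices

* Box-membership and segment-membership tests use 1e-9 relative
  tolerances; local coordinates are clipped to [0, 1] after the tolerance
  admits a point.
* Intersection plane coordinates are set exactly to `jΔ` (not recomputed
  from `O + tζ`) so the plane-equation residual is zero by construction;
  the ray-equation residual is asserted < 1e-9.
* `np.interp` performs the bracketing and endpoint clamping for the
  section formula along a ray; it is algebraically identical to the scalar
  segment formula and is tested against it.
* Renders are bit-deterministic for a fixed config: no randomness exists
  anywhere in the render path, and the run log carries a config hash to
  make accidental config drift visible.

## Problem sizes

Tests and the acceptance script run at reduced scale — phantoms up to
64×64×37 vertexes, 64×64-pixel images, δ = 0.3·min(spacing) ≈ 0.146 mm
(≈ 500 k samples per render) — chosen so the full suite completes in
seconds while still exercising anisotropic spacing, oblique views and
multi-hundred-sample rays. Counting results are size-independent by
construction.

## Known limitations

* No perspective camera, no lighting/gradient shading, no 2D transfer
  functions, no empty-space skipping or bounding-volume acceleration.
* No DICOM parsing; raw-plus-sidecar and slice stacks are the input
  formats.
* The three-vertex face formula's error grows with in-plane curvature of
  the optical field; δ smaller than the plane spacing does not recover
  trilinear accuracy, it only densifies the section formula between the
  same face values.
* Opacity is not resampling-corrected (see Compositing).
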