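# Methods

## Scope and model

`portaledge` estimates and verifies rigid patient setup errors from
orthogonal portal-image pairs. The measurement model is deliberately
minimal: each view (anteroposterior at gantry 0°, lateral at gantry 90°)
sees a 2D rigid motion — in-plane translation in detector pixels plus an
in-plane rotation about the image centre — and the two views share the
cranio-caudal (row) axis. A 3D couch error (tx, ty, tz in mm; rx, rz in
degrees) is therefore observable as: AP columns ← tx, LAT columns ← ty,
both rows ← tz, AP rotation ← rz, LAT rotation ← rx. Rotation about the
anterior–posterior axis is outside the model, matching the convention of
reporting only two rotation axes for orthogonal pairs.

Detector-plane pixel shifts are converted to isocenter millimetres by
`mm = px · pitch / (SDD/SID)`; the reference geometry is a 0.39 mm pitch
panel at SDD 1400 mm and SID 1000 mm (magnification 1.4), giving
0.27857 mm per pixel at the isocenter.

## Mutual-information registration

Each DRR/EPID pair is aligned by maximising
`I(A,B) = H(A) + H(B) − H(A,B)` in bits. Intensities are min–max
rescaled and hard-binned into 64 bins (a bias/variance compromise at
256² images; both marginals are taken from the joint histogram so
`I(A,A) = H(A)` holds exactly). The optimiser is deterministic:

* a coarse exhaustive grid — integer-pixel translations over
  ±10 mm (isocenter scale, converted to pixels) and rotations over ±3°
  in 0.5° steps. For each rotation the reference is resampled once
  (bilinear); integer translations are then scored by pure array
  shifts, so the grid stage involves no further interpolation;
* Powell refinement of (t_col, t_row, θ) from the best grid node,
  bounded to the grid box, relative tolerance 1e-3.

Pixels resampled from outside the frame are excluded from the joint
histogram rather than zero-filled — zero fill manufactures mutual
information at large shifts. Candidates retaining less than 25 % overlap
are rejected outright.

One numerical artifact is worth knowing: bilinear resampling creates new
intermediate intensity levels, which raises the marginal entropy of the
warped image, so the binned MI at a small subpixel warp of an image
against itself can slightly exceed `H` of the unwarped image. The
optimum can therefore sit a fraction of a pixel away from the exact
alignment; empirically this bias stays well under a quarter pixel on the
phantom projections, which is the recovery tolerance asserted in the
tests.

## Bone-edge extraction and hybrid refinement

The gradient image is the forward-difference sum
`dx(i,j) = I(i+1,j) − I(i,j)`, `dy(i,j) = I(i,j+1) − I(i,j)`; the last
row/column, which have no forward neighbour, are set to zero so shapes
are preserved (image borders never contain anatomy). Detection and
optimisation use the polarity-free form `|dx| + |dy|` by default: the
signed sum cancels on edges of opposite polarity, which would make the
maximisation depend on which side of the bone is brighter. The literal
signed form remains selectable.

A border point on an axis-aligned profile is the profile pixel of
maximal polarity-free gradient; ties are broken toward the seed point,
then toward the smaller index, so the output is deterministic. The
profile is kept axis-aligned (a direction flag chooses vertical or
horizontal) rather than rotating with the local edge.

Four markers are fitted with the unique interpolating cubic. The
orientation is chosen by span: row = f(col) when the markers cover at
least as many columns as rows, else col = f(row) — a cubic in the column
coordinate is single-valued and fails on near-vertical edges. The
objective samples the curve at every integer abscissa between the A and
D markers and evaluates the gradient image by bilinear interpolation.
The default objective is the per-sample mean rather than the raw sum:
the sum grows with the A-to-D span, which would bias the optimiser
toward widening the curve as the end markers move during optimisation.
The raw sum is available as `objective_mode="sum"`.

The refinement box is ±3 mm per coordinate, converted to whole detector
pixels (`round(3/pitch)`) — the search happens in the image, not at the
isocenter. The global stage is a particle swarm (30 particles, 50
iterations, inertia 0.7, cognitive = social = 1.5, box clipping, the
initial marker positions seeded as particle 0 so the refined objective
can never fall below the starting one) with positions rounded to integer
pixels during evaluation, reproducing a single-pixel search step. Powell
then refines the best swarm position in continuous coordinates with
tolerance 1e-3 px. A user seed is mandatory and makes the whole
procedure bit-reproducible. On images small enough to enumerate, the
hybrid matches exhaustive integer-grid search (asserted in the tests
both for two free markers at the full ±3 px radius and for all four
markers at ±1 px).

The verification readout overlays the refined DRR and EPID curves on the
fused frame and reports their mean point-to-curve distance in pixels
over the common domain; identical curves score 0.

## Synthetic phantom

The generator emulates a head phantom — a skull with lower-density
filling of the cranium and the oral/nasal cavities — as an ellipsoidal
bone shell (outer semi-axes 70/85/95 mm, 8 mm shell) around soft tissue,
with two air cavities in the lower anterior region. The default volume
is 128³ voxels of 2 mm (256 mm extent, matching a 2 mm-slice planning
CT); unit tests use a 48³/4 mm variant for speed. Projection is
parallel-beam exp-attenuation along the view axis with per-tissue linear
attenuation: kV-like coefficients (bone 0.060 /mm, soft 0.020 /mm,
ratio 3.0) for the DRR surrogate and MV-like coefficients (bone
0.008 /mm, soft 0.005 /mm, ratio 1.6) for the EPID surrogate — the
ordering of these ratios is the low-contrast property of megavoltage
imaging and is asserted as an invariant on every generated pair. Beam
divergence is folded into the magnification, so the projection pixel
pitch is `voxel · magnification / upsample` (1.4 mm on the detector,
i.e. 1 mm at the isocenter, for the defaults with 2× upsampling to 256²
frames).

EPID degradation is a Gaussian detector point-spread (σ = 1 px) followed
by seeded additive Gaussian noise with σ = 2 % of the dynamic range,
clipped to the input range. These are stated choices — portal-image
noise depends on monitor units and dose rate, which are not modelled.

Setup errors are applied as the per-view 2D motions listed above
(bilinear resampling; integer translations are lossless), which makes
recovery well-posed: a 2D rigid registration can in principle recover
the truth exactly. A secondary `apply_volume_motion` rigidly moves the
label volume before projection for qualitative realism; out-of-plane
components then have no recovery guarantee and the evaluation does not
use this mode.

What passing tests therefore demonstrate is that the pipeline recovers
per-view rigid motion from low-contrast, blurred, noisy projections of a
skull-like object — not that it handles scatter, beam hardening,
anatomy deformation, breathing motion, or the out-of-plane geometry of a
real couch displacement.

## Evaluation protocol

The ten study displacements (±7 mm translations, ±3° rotations) are
replayed end to end: simulate → register both views → fuse → signed
residual (estimated − applied) per axis. Summaries are the minimum,
maximum and mean of the absolute residuals per axis; Z residuals use the
two-view average rather than pooling the views. Case k's noise stream is
seeded as `seed·1009 + 2k` (AP) and `+1` (LAT), so a single seed fixes
the whole experiment. The paired t-test helper (two-sided, n−1 degrees
of freedom) raises on zero-variance differences rather than returning an
undefined statistic.

The human traditional-vs-new comparison of the original study is not
reproducible in software; in its place the package offers a noise sweep
(`noise_sweep`, checking that error statistics do not improve by more
than one effective pixel as noise grows) and an ablation hook
(`with_edge_check=True`) that reports the bone-edge coincidence score of
each registered view alongside the MI-only residuals.

## Problem sizes and runtime

Defaults were chosen for desk-scale execution: the full ten-case replay
(default phantom, 256² projections, twenty registrations) completes in
roughly 80 s on one CPU; the exhaustive-search equivalence tests
enumerate 7⁴ and 3⁸ marker-offset combinations on a 64² fixture in
about a second each.

## Known limitations

* Parallel-beam projection with divergence absorbed into a global
  magnification; no cone-beam geometry.
* Per-view 2D motion as the ground-truth model; true 3D couch rotations
  project with out-of-plane components the method cannot observe.
* Axis labelling of the two in-plane rotations (rx/rz) is a reporting
  convention, exposed as a parameter of `fuse_views`; projection
  geometry alone cannot fix it unambiguously.
* Marker placement is manual by design (`detect_border_point` assists
  with single profiles); only the refinement is automatic.
* No scatter, beam hardening, dose-rate or detector-lag modelling.
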