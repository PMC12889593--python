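# Methods

## The measurement model

The assay exposes hydrogel microcaps in a flow cell to a constant
concentration of FITC-labelled nanodextran until equilibrium (confirmed by
a single-plane time-lapse plateau check), then images three channels of a
confocal z-stack: Calcofluor White (hydrogel shell), an AF594-like channel
(embedded polystyrene microspheres), and FITC (tracer everywhere, plus a
specular reflection of the coupon surface). The quantity of interest is the
microcap partition coefficient K_P, the ratio of the mean FITC signal in
the microcap interior (hydrogel ∪ microsphere voxels) to the mean in the
surrounding water. K_P < 1 indicates exclusion; comparing K_P across
conditions tests three candidate transport barriers — size exclusion by the
hydrated mesh, volume exclusion by impermeable inclusions, and
electrostatic attachment.

Equilibrium levels are *set*, not simulated: the phantom prescribes a
piecewise-constant concentration field per domain. Diffusion kinetics,
photochemistry and optical physics beyond Gaussian blur are out of scope.

## The phantom

Geometry is analytic: a hemisphere of radius R resting on the coupon plane
(the physical caps are dome-like; a hemisphere is the simplest consistent
shape and is isolated behind one function so other shapes can be plugged
in), spheres placed by rejection sampling entirely inside the cap and above
the coupon, pairwise non-overlapping, with a 10% volume-fraction guard so
placement terminates. Voxel membership uses a voxel-center point test with
no partial-volume weighting — boundary voxels are therefore assigned whole,
and voxelization error shrinks quadratically with the grid; a 50 μm
hemisphere on a 1 μm grid matches (2/3)πR³ to 0.1%.

Rendering: the CW channel is nonzero only in hydrogel within the
penetration depth of the cap's outer spherical surface (default 10 μm;
clamped if the depth exceeds the radius); AF594 only inside spheres; FITC
carries each domain's equilibrium level, the coupon solid carries none, and
the reflection is additive in exactly the one voxel layer at the coupon
surface — which is what gives the z-edge detector a transition to find.
Noise is applied last: default Poisson–Gaussian (shot noise at configurable
gain plus additive read noise), seeded; negative intensities are clipped to
zero. With noise off and no blur the render is piecewise-constant and
bit-deterministic.

Default scene values (intensity units are arbitrary detector counts):
water 100, interior level = K_P × 100, CW shell 150, spheres 200, coupon
reflection 300. The reflection is set 3× the water level so the edge drop
(≥ 200 counts) dominates noise-induced drops at the 10–30 count level;
detector noise magnitude and reflectivity are not reported for the physical
system, so they are parameters, not assertions.

## Segmentation choices

* **Otsu** is implemented over a 256-bin histogram of min-max-scaled
  intensities (reproducible across bit depths; affine-invariant), with the
  between-class variance maximized over interior bin edges and ties broken
  toward the lowest edge. A brute-force scan over all edges is kept as a
  test oracle, and scikit-image's implementation is cross-checked to within
  one bin.
* **Sphere plausibility gate.** Otsu cannot isolate a foreground class
  occupying ~10⁻⁴ of the volume once the background carries read noise:
  splitting the background yields higher between-class variance than
  isolating the rare bright class. Since the spheres are a ≪1% minority
  phase by construction (0.01 wt% loading), a threshold labeling more than
  `max_sphere_fraction` (default 10%) of voxels as sphere is taken as "no
  genuine sphere class" and the detector returns an empty mask with a
  warning — the same fallback as a dark channel. The lost sphere voxels are
  recovered as hydrogel by the region fill, which leaves K_P unchanged
  because the phantom's interior levels coincide.
* **Region filling** runs per z-slice in 2-D (4-connectivity): a
  hemisphere's open top would defeat naive 3-D hole filling, and the
  original analysis filled slices in a 2-D image tool. Components smaller
  than `min_region_voxels` (default 64; "very small" is otherwise
  unquantified) are discarded with 26-connectivity, the convention for
  confocal blobs.
* **Coupon detection** finds, per (x, y) column, the strongest
  positive-to-negative FITC transition along z within the lower half of the
  stack (window configurable). Columns whose best drop is below 25% of the
  global best fall back to the modal detected plane. The detected layer,
  everything below, and `coupon_bias_layers` above (default 1) are labeled
  coupon — the bias deliberately sacrifices coupon accuracy to keep the
  water and hydrogel means clean. Precedence on overlap: coupon >
  microsphere > hydrogel.
* The sphere threshold is computed over the full volume (a per-slice
  variant is conceivable but unstated in the original protocol).

## Quantification

Domain means are arithmetic, voxel-count weighted; the microcap mean is
taken over the union Ω_I ∪ Ω_O, not as an average of the two domain means.
The water mean excludes the topmost coupon-labeled layer plus a one-voxel
guard band above it, because the specular reflection would bias the water
reference upward (the biased coupon segmentation implies the same intent).
An optional radial-shell restriction of the water domain is available for
stacks where the water reference should be local to the cap; the default is
the whole water domain. Background subtraction is supported but off by
default. Saturated voxels are flagged in diagnostics, never clipped.

The plateau check fits a least-squares line to the last quarter of a
time-lapse trace and declares equilibrium when |slope| / mean ≤ 1%/min
(both the window and tolerance are parameters; at least 5 tail samples are
required).

## Statistics

Welch's unequal-variance t statistic with Welch–Satterthwaite degrees of
freedom and a one-sided alternative per effect direction; "one-way" is read
as one-tailed, since only one direction constitutes evidence for each
hypothesized effect. No multiple-testing correction is applied (fidelity to
the original analysis); the result table carries the comparison count so
users can correct afterwards. Shapiro–Wilk uses the exact n = 3 closed form
(W from a₁ = 1/√2, p = (6/π)(asin√W − asin√0.75)) and Royston's
approximation for 4 ≤ n ≤ 50, matching scipy to ~10⁻⁴. Normality failures
warn and proceed by default; a strict mode aborts. The 95% CIs on condition
means use the t quantile with n − 1 degrees of freedom.

With n = 3 per sample the Welch test is intrinsically conservative: its
true one-sided size at nominal α = 0.05 is ≈ 0.039 for normal
equal-variance samples (the estimated degrees of freedom fluctuate below
the pooled value). Monte-Carlo calibration checks must therefore expect
rejection rates slightly below α, with sampling spread on top.

## Synthetic study generator

The default per-condition true K_P values are the study's own measured
equilibrium levels, 10^(−pBCF) of the eleven published study rows (e.g.
0.685 for the neutral 150 kDa tracer with plain spheres, 0.480 for the
2 MDa tracer — the 30% size effect). Noise is multiplicative and
two-level: a batch term shared by a coupon's microcaps and an independent
per-microcap term, each zero-mean normal with CV 0.05 by default (the
batch-level CV is the scale at which the size-exclusion test is expected to
reach ≥80% power; per-microcap spread is set equal in the absence of a
reported value). Fast mode draws K_P directly; full mode renders a phantom
per microcap and runs the image pipeline end to end.

The full-mode phantom is a scaled-down cap — 12 μm radius on a 64³ stack at
0.5 μm voxels, 4 μm stain penetration, 15 spheres — chosen so the unstained
core still exercises region filling while a simulated 99-cap study stays
cheap; proportions, not absolute sizes, match the physical assay. What the
generator does *not* emulate: partial-volume effects at domain boundaries,
spatially varying background, optical attenuation with depth, cap-shape
irregularity, and sphere aggregation. Passing recovery tests on these
phantoms therefore validates the pipeline's logic and its noise robustness,
not its performance on real optics.

## Bioconcentration conventions

Study rows convert with pBCF = −log₁₀ K_P; this is the only sign choice
that reproduces the published 30% decrease from the printed pair
(10^(0.164−0.319) = 0.700) and keeps the pore-water inequality's "greater
by log 2" statement consistent. Published literature values are shipped
verbatim (ranges kept as printed strings) and never re-derived; merged
tables carry an explicit `pbcf_convention` column because one log scale
cannot honestly mix study ratios below 1 with literature mass ratios far
above 1. The dry→wet conversion divides by a configurable 100:1 wet/dry
mass ratio. The pore-water correction assumes the pore water is in
equilibrium with the bulk; its log-scale shift log₁₀((m_b+m_w)/m_b) depends
only on the pore-to-solid mass ratio.

## Known limitations

* Sub-voxel spheres (0.35–0.45 μm radii on ≥0.5 μm grids) occupy so few
  voxels that the sphere channel is unusable by thresholding; the
  plausibility gate then deliberately reports no spheres.
* The coupon edge detector assumes the coupon at low z with a single
  reflective interface; tilted or curved substrates are out of scope.
* K_P aggregation treats the three microcaps per coupon as exchangeable
  technical replicates; no mixed-effects model of the batch hierarchy is
  attempted.
* The literature comparison is bookkeeping, not re-analysis: kinetic
  parameters (characteristic times) are carried as strings.
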