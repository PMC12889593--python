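# microcap

Quantification of nanomaterial accumulation in synthetic biofilm analogs
("microcaps"): hemispherical nanocellulose hydrogel deposits on a reflective
polycarbonate coupon, loaded with 0.7–0.9 μm polystyrene microspheres that
stand in for bacterial cells, and bathed in water carrying a FITC-labelled
nanodextran tracer. The package is for researchers studying transport
barriers in biofilms and hydrogels who need a tested, reusable version of
the whole measurement chain — from confocal z-stack to hypothesis test to
cross-study bioconcentration bookkeeping — plus a synthetic phantom
generator so every stage can be validated against exact ground truth
without raw microscope data.

## What it computes

**Four-domain segmentation.** Every voxel of a 3-channel confocal z-stack
is assigned to the water domain Ω_L, the hydrogel (interstitial) domain Ω_I,
the microsphere domain Ω_O, or the solid coupon Ω_S: spheres by Otsu
thresholding of the AF594 channel; hydrogel by Otsu thresholding of the
Calcofluor White channel followed by per-slice region filling (the stain
only decorates an outer ~10 μm shell) and small-region discard; the coupon
by an edge detector along z on the FITC channel, deliberately biased toward
the coupon; remaining voxels are water.

**Partition coefficient.** For each microcap's accumulation image

    K_P = [FITC]_microcap / [FITC]_water,

with [FITC]_microcap the voxel-weighted mean over Ω_I ∪ Ω_O and
[FITC]_water the mean over Ω_L (excluding the reflective coupon-adjacent
layer). Normalizing by the local water signal makes K_P comparable across
microcaps and imaging sessions.

**Hypothesis battery.** Technical replicates (3 microcaps per coupon) are
averaged; 3 hydrogel batches form each condition's sample (n = 3). Six
one-tailed Welch t-tests at α = 0.05 probe three biofilm-mimicry effects:
size exclusion (2 MDa < 150 kDa tracer), volume exclusion (spheres <
no spheres) and attachment (each oppositely charged tracer/sphere pairing >
its two controls). Samples are screened with Shapiro–Wilk.

**Ecotox conversions.** K_P ↔ pBCF (study convention pBCF = −log₁₀ K_P),
dry→wet BCF rescaling (100:1 wet/dry mass), the pore-water-corrected BCF
(counting pore water in the denominator lowers BCF by log₁₀((m_b+m_w)/m_b) —
exactly log₁₀ 2 at equal masses), and a merged comparison table against a
shipped survey of published biofilm pBCF values.

## Worked example

`examples/02_segment_and_quantify.py` renders a noisy phantom with known
K_P = 0.70 and pushes it through the full pipeline:

```
segmented counts: {'water': 214543, 'hydrogel': 27121, 'microsphere': 0, 'coupon': 20480}
voxel-wise agreement with ground truth: 98.4%
water mean 99.92, microcap mean 69.90
recovered KP = 0.6995  (truth 0.7000)
```

The microcap interior sits at 69.9% of the bulk water signal, so the
recovered partition coefficient is 0.6995 — within 0.1% of the phantom's
true value despite shot + read noise at 10% of the water signal.
`examples/03_hypothesis_battery.py` simulates the full 99-microcap study
around the measured equilibrium levels and prints the six-test battery
(the 30% size-exclusion effect rejects at p ≈ 2.5 × 10⁻⁵); the other
examples cover phantom rendering and the bioconcentration conversions.

A thin CLI mirrors the stages: `microcap simulate | segment | quantify |
analyze | report` (see `microcap --help`).

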