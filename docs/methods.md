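# Methods

## Measurement model

The unit of measurement is a calibrated multi-channel field
(`FieldImage`): co-registered drug, vessel and optional nuclear /
exclusion rasters with square pixels. Camera resolution is not part of
the protocol, so the pixel pitch is derived from the printed field area
per magnification — ×40 → 6.82 mm², ×100 → 1.09 mm², ×200 → 0.27 mm²
(these scale as the inverse square of magnification within rounding).
A 1024×1024 raster of a ×100 field therefore implies ≈1.0196 µm/px.
Channels of differing dimensions are aligned by nearest-neighbor
resampling onto the drug channel's grid; no sub-pixel registration is
attempted (the channels image the same physical section).

Vessel masks use the "any non-zero pixel is vessel" rule, appropriate for
channels that arrive pre-masked by the staining software; raw intensity
channels are thresholded by Otsu's method or a fixed calibrated value.
Both drug spots and vessels are 8-connected components; components
smaller than 4 px (configurable) are treated as noise. Each spot is
reduced to the unweighted centroid of its component, the fractional
centroid is rounded half-away-from-zero to a pixel, and the penetration
distance is the Euclidean distance transform of the vessel mask at that
pixel, in µm. Distance is measured to the nearest vessel *pixel center*
(vessel interiors are 0), not to a sub-pixel boundary contour; together
with centroid rounding this produces a small positive systematic offset
relative to the continuous spot-to-vessel-surface distance, bounded at
roughly half a pixel (≈0.4 µm at ×100 resolution) in the simulator tests.

A field's penetration is the mean over its spots and an animal's value is
the mean over exactly three fields. Fields without vessels or without
detectable drug are *flagged and excluded*, never scored as 0 µm (a zero
would bias penetration downward); an animal with fewer than three usable
fields is reported flagged with NaN measurements.

Field selection mirrors the imaging protocol. Drug-evaluation fields:
1.09 mm² windows scanned over the section (stride = window/4, plus
flush-end positions), scored by summed drug intensity over non-excluded
pixels; windows more than 50 % excluded are ineligible; the three
highest-scoring pairwise-disjoint windows win, ties in raster order.
MVD: the vessel mask is scanned the same way with 0.27 mm² windows scored
by microvessel count (components re-labelled within the crop, as an
observer sees through the eyepiece); the animal's MVD is the mean of the
three disjoint top windows. Greedy disjoint selection can stall below
k = 3 when the window side exceeds a third of the grid, so selection
restarts greedily from each top candidate until a full set is found.
Components touching the exclusion mask are not counted.

## Statistics

Cells are summarized as mean ± sample SD (n−1). The two sacrifice-time
subgroups have equal n by design, and their Total row is the exact pooled
sample summary reconstructed from subgroup sufficient statistics:

    m = (m1 + m2)/2
    s^2 = [ (n-1)(s1^2 + s2^2) + n((m1-m)^2 + (m2-m)^2) ] / (2n-1)

Arms are compared by one-way fixed-effects ANOVA — available both from
raw values and from (n, mean, sd) summaries, which agree to floating-point
precision — followed by Fisher's LSD-t on the within-group mean square.
LSD is by definition unadjusted for multiplicity; output metadata says so.
Report tables round half-away-from-zero to 2 decimals (computed on the
decimal representation so exact halves round up); internal files keep full
precision. Field-within-animal nesting is averaged out before statistics,
matching the protocol; no mixed-effects modelling is attempted.

## The forward simulator

`generate_field` renders one field from an explicit generative model:

* **Vessels** — a Poisson point process with mean density
  `vessel_density_per_mm2` (default 30 mm⁻², chosen so that 0.27 mm²
  hotspot windows count ≈12–14 microvessels), linearly enriched
  `edge_enrichment`-fold (default 3) toward one image edge to emulate
  peripheral tumor vascularization; disks with radius ~N(4, 1) µm.
* **Spots** — count ~Poisson(`spot_rate`); each spot picks a perfused
  vessel uniformly, a uniform direction, and a distance from the vessel
  surface drawn from the configured law (exponential with scale λ by
  default; half-normal optional). Spots landing outside the grid, inside
  any vessel, in the avascular patch or in necrosis are rejected and
  redrawn. A fraction of vessels (default 5 %) is unperfused and seeds no
  drug.
* **Ground truth** — for every accepted spot the *continuous* distance to
  the nearest vessel surface, min over all vessels, is recorded. At large
  λ this is substantially below λ because the nearest vessel is often not
  the seeding vessel; recovery is therefore always validated against the
  recorded truth, not against λ.
* **Intensity** — spot peak I(d) = I₀·e^(−d/τ) (defaults I₀ = 180,
  τ = 100 µm) clipped below at a detectability floor of 30, on a Gaussian
  background (mean 5, sd 2), all in arbitrary 16-bit-safe units. The
  floor encodes that a "spot" is by definition detectable fluorescence.
  Spots are rendered as filled disks of radius 1.3 px — the smallest
  radius that guarantees ≥4 rendered pixels at any sub-pixel offset (so
  every spot survives the default component-size filter) while keeping
  adjacent spots from fusing into one component at realistic densities.
* **Structure** — an optional avascular disk patch (no vessels, hence no
  drug) and a necrosis disk covering `necrosis_fraction` of the area,
  exported as the exclusion channel. No PSF, bleed-through or vignetting
  is simulated.

`generate_study` renders 4 arms × 2 sacrifice times × 4 animals, with
per-(arm, time) parameters (λ, spot rate per 1.09 mm² field) defaulting to
the observed arm summaries: λ = 12.14/7.36, 40.54/32.68, 76.29/72.37,
38.21/81.16 µm and rates 235.75/75, 2070.5/1137, 3130.75/3190,
1912/3681.5 for groups 1–4 at 10 min / 4 h. A per-animal log-normal
multiplier (σ = 0.20 on the log scale, median 1) on both λ and the rate
reproduces between-animal spread approximately; per-animal raw
distributions were never published, so this spread cannot be validated
further. Every (arm, time, animal, field) coordinate derives its own
31-bit sub-seed from the master seed through a `SeedSequence` keyed on the
integer indices, so any single field is regenerable in isolation and the
whole study is byte-reproducible.

Because a simulated study knows its own calibration, `run_simulate`
writes a config with a *fixed* drug threshold midway between the
background mean and the dim-spot floor (≈6 SD above background). Per-field
Otsu — the default for real, uncalibrated images — settles above the
dim-spot floor on fields with strong intensity decay and censors the
far-from-vessel spots, biasing measured penetration downward; the shipped
calibrated config avoids this.

## Problem sizes and numerical choices

* Simulated sections default to the 6.82 mm² scan area at 2 µm/px
  (1306² px), a raster size that keeps a full 32-animal study in the low
  minutes on one CPU; single-field validation runs use the full derived
  1.0196 µm/px pitch.
* Penetration-recovery checks use 2560² px fields (the full scan area at
  full resolution) with ~1000 spots: large enough that component fusion
  stays below ~10 % and the measured-vs-truth offset stays within 3
  standard errors of the ground-truth mean at λ = 10, 40 and 75 µm.
* The arm-ordering replicate check uses pre-selected 1.09 mm² fields at
  2 µm/px with spot rates scaled by 0.25 — a problem-size reduction only;
  the per-arm penetration scales are the observed values untouched.
* Empty histogram bins report count 0 and NaN means; hotspot ties break
  in raster order (row, then column); stride scans always include the
  flush-end window so the scan covers the full grid; distance lookups
  clamp rounded centroids to the grid.
* The Otsu threshold refuses constant channels (`DegenerateHistogram`);
  callers fall back to the nonzero rule with a logged warning.

## Known limitations

* Distances are 2-D; out-of-section vessels are invisible, so penetration
  is overestimated relative to the 3-D truth. No multi-section
  reconstruction is attempted.
* Spot fusion at high density biases the measured mean slightly upward
  (fusions concentrate where spots crowd, near vessels); the simulator's
  small spot footprint keeps this below the statistical noise in the
  tested regimes, but very dense real fields would need marker-based
  splitting that is out of scope here.
* Necrosis segmentation is not performed; exclusion masks are inputs.
* The simulator's noise model is additive Gaussian only; detector shot
  noise, PSF blur and channel bleed-through are not emulated, so passing
  recovery tests demonstrates estimator correctness on clean spot/vessel
  geometry, not robustness to real acquisition artifacts.
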