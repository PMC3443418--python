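# Methods

## Scores

### Agatston score (volume form)

The search region is the set of voxels whose centers lie within a
trajectory's search radius (default 8 mm) of any reader-traced coronary
centerline, with distance taken to polyline *segments* (not vertices) so
sparse centerline sampling cannot open gaps. Lesions are connected
components of voxels with HU ≥ 130 inside the region; contiguity is
26-connectivity by default (6 available) because coronary lesions span
slices and the permissive convention is the safer default when the
reading-software convention is unknown. Components under 4 voxels are
discarded. Each lesion scores `n_voxels · dx·dy·dz × c` with the
coefficient `c ∈ {1,2,3,4}` binned on the lesion's maximum HU at
130/200/300/400. This is deliberately the *volume × coefficient* form; the
classic per-slice area scoring is out of scope. Anisotropic spacing is
respected throughout — volumes are never resampled, matching acquisition at
2.5/3.0 mm slices with sub-millimetre in-plane pixels.

An interactive analyst review of candidate plaques is replaced by an
optional exclusion mask. Per-participant scores are the arithmetic mean
over the available (1 or 2) scans.

### Spatially weighted calcium score

The published description of the SWCS fixes its two-step structure —
phantom-derived per-voxel weights, then a neighbour-dependent per-voxel
score — but the exact functional forms appear only in a supplementary
appendix that is not available. The forms used here are therefore this
package's own design, chosen to satisfy every property the main text
states, and both are pluggable:

1. **Weight.** `w = Φ((HU − μ_c)/σ_c)`, the probability that a voxel drawn
   from the phantom-implied attenuation distribution at the criterion
   calcium density shows at most the observed HU. Smooth, threshold-free,
   strictly increasing, strictly positive, and fully parameterised by the
   scan's own phantom, so scores are comparable across scanners.
   - μ and σ are both fitted linearly in density by OLS over the phantom
     inserts (≥ 2 distinct densities required; 4 in the reference design,
     so both fits are overdetermined and residual RMS values are kept for
     QC). A constant-σ model was rejected in favour of the 2-parameter line
     because it costs nothing and absorbs density-dependent noise.
   - The criterion density defaults to `c = (130 − a_μ)/b_μ` clipped to
     [0, max insert density]: the density whose fitted mean attenuation is
     130 HU. This anchors the continuous score to the conventional
     detection threshold so supra-threshold scores stay comparable to the
     AS.
   - `σ_c` is clamped below at `sigma_floor` (default 1 HU) so noise-free
     synthetic scans cannot degenerate into a step function.
2. **Neighbour adjustment.** `s(v) = w(v) · mean(w over the 3×3×3
   neighbourhood including v)`, truncated (no padding) at volume borders.
   Multiplying by the neighbourhood mean up-weights spatially coherent
   attenuation and suppresses isolated single-voxel noise with no free
   parameters. A 6-neighbour (face-adjacent) variant is available.

`SWCS = κ Σ s(v)·voxel_volume` over the search region, κ = 1 by default. A
utility fits κ by through-origin regression of AS on SWCS over AS > 0
scans if a user wants the two scores on a comparable scale.

Whether the original software applied the phantom adjustment by
recalibrating the image before thresholding is unclear from the main text;
an affine HU recalibration mapping the fitted phantom line onto a nominal
line is provided but **off** by default.

Whether the 8 mm constraint was applied in 3D or per slice is also not
stated; 3D Euclidean distance is the default, with a per-slice ("2d") mode
that clips centerline segments to each slice slab and measures in-plane
distance.

## Numerical choices

- **Weight floor.** Φ underflows to exactly 0 in double precision near
  z = −38. Weights are clamped to `[1e-150, 1 − eps]`: the floor is small
  enough never to matter in the informative range (z = −26 corresponds to
  Φ ≈ 1e-150) yet large enough that `w · w̄` — the smallest product the
  neighbour adjustment can form — stays strictly positive, so an all-air
  region still receives a positive SWCS. Consequences: exact strict
  monotonicity in HU holds only inside the numerically resolvable band
  (roughly μ_c ± 26σ_c below, μ_c + 8σ_c above, where Φ saturates at 1);
  the tests exercise strictness there and non-decrease globally.
- **Determinism.** Connected-component labeling order never affects
  scores; lesions are reported sorted by their lexicographically smallest
  voxel index. The neighbourhood mean is computed by correlation with a
  constant kernel divided by an in-volume neighbour count, which is
  bit-reproducible.
- **Degenerate inputs.** An empty search region raises a dedicated error
  (distinct from a zero score); a phantom with non-increasing attenuation
  versus density, overlapping inserts, regions under 8 voxels, or fewer
  than 2 distinct densities is rejected; percent difference is undefined at
  x1 + x2 = 0 and such participants are excluded and counted.

## Synthetic cohort generator

The generator stands in for the non-distributable study images. It
emulates: a soft-tissue background (30 HU), the four-insert calibration
phantom under the thorax, a reader-style coronary centerline, spherical
calcified plaques within 8 mm of it, additive Gaussian scanner noise, and
two replicate scans per participant differing by independent noise plus
sub-voxel jitter of the centerline points and plaque positions.

Key defaults (all overridable on `SyntheticCohortConfig`):

| parameter | default | rationale |
|---|---|---|
| volume shape / spacing | 64×64×16 at 0.68×0.68×3.0 mm | sub-millimetre in-plane pixels with 3 mm slices, the coarser of the two acquisition protocols; small enough to score hundreds of scans in seconds |
| density→HU map | HU = 10 + 1.2·d | places the 130 HU operating point at ~100 mg/mL, inside the phantom range, so the auto criterion density is interior |
| noise_sd | 15 HU | typical soft-tissue noise for unenhanced chest CT |
| jitter_sd | 0.25 mm | sub-voxel inter-scan displacement for consecutive same-table acquisitions |
| fraction_zero_as | 0.5 | roughly half of a screening cohort scores zero |
| detectable plaques | 1–4 per participant, radius 1.2–4 mm, density 150–400 mg/mL | spans coefficient bins 1–4 and three decades of score |
| zero-stratum plaques | 1–8 per participant, radius 0.65–1.0 mm | see below |

**The AS = 0 stratum.** Real zero scores arise mostly from calcifications
that fail the detection minimum — fewer than 4 contiguous voxels — rather
than from low attenuation alone, and the normal-CDF weight makes this the
only regime in which a zero-score stratum carries a volume-ordered SWCS:
below the criterion the Gaussian tail is so steep that any spread in plaque
*density* would dominate the score. Zero-stratum participants therefore
carry up to eight small high-density foci sized at the voxel scale (radius
0.65–1.0 mm ≈ the in-plane pixel), each rasterised to 1–3 voxels.
Placement keeps plaque separations above the 26-neighbourhood physical
diagonal so footprints can never merge into a detectable ≥ 4-voxel
cluster, and when per-scan jitter pushes a footprint across the minimum the
scan's displacement for that plaque is redrawn (jitter conditioned on the
stratum), with radius shrinkage only as a bounded last resort.
Sub-criterion-density plaques remain available through the density-range
fields and are used in the threshold-contrast tests.

Plaques are solid uniform-density spheres rasterised by voxel-center
sampling; the recorded true volume is the voxelised volume of the base
(unjittered) geometry — the calcium the scanner's grid actually resolves.
There is no partial-volume blur, PSF, beam hardening, cardiac motion or
vendor noise texture, and replicate-scan variation has no
table-repositioning component. Passing cohort tests therefore demonstrate
the *scoring pipeline's* properties (oracle equivalence, threshold
contrast, positivity, ordering, calibration recovery), not robustness to
those physical effects. One visible consequence: with only noise and
sub-voxel jitter between replicates, both scores are far more reproducible
here than in real test–retest data, and the thresholded score is not
systematically noisier than the weighted one — the direction test for the
paired reproducibility comparison uses a score-level simulation with the
noise asymmetry planted explicitly.

Determinism: every scan derives from per-participant/per-scan RNG
substreams of a single seed; fixed seed ⇒ byte-identical volumes, tables
and reports.

## Reproducibility statistics

Percent difference `|x1−x2| / ((x1+x2)/2) × 100` (symmetric,
scale-invariant, range [0, 200]) is the primary measure; the two methods
are compared on identical participant subsets via the per-participant
paired difference (AS% − SWCS%), summarised by median and mean with seeded
bootstrap percentile CIs (default 2000 resamples of participants) — chosen
for distribution-freeness since no interval method is prescribed. Subset
filters mirror the published analysis: AS > 0 on either scan, on both
scans, and optional AS < cutoff on both. The ICC defaults to the one-way
random-effects form ICC(1,1) = (MSB − MSW)/(MSB + MSW) for k = 2, because
scan order within a participant is exchangeable under a randomised reading
protocol; the two-way absolute-agreement form ICC(2,1) is available behind
a flag. Reader-based noise exclusions have no algorithmic definition and
are exposed only as an explicit exclusion list.

## Problem sizes

Cohort-level checks use 200 participants × 2 scans on 64×64×16 grids
(~15 s end to end); oracle-equivalence checks use exhaustive naive
reference implementations on grids ≤ 16³; Monte-Carlo recovery checks use
200–300 calibration replicates and 5000 ICC pairs. These sizes make the
full suite and the acceptance script comfortably reproducible on a laptop
while leaving the statistical assertions well-powered.

## Known limitations

- The weighting and neighbour-score forms are this package's
  reconstruction of a two-step description, not the original appendix
  algorithm; both are isolated behind small functions so alternative forms
  can be swapped in.
- The SWCS scale (κ = 1) is arbitrary; published per-cohort regressions of
  one score on the other are not reproducible without the original data.
- Double-precision saturation of Φ bounds the resolvable attenuation band
  (see numerical choices); scores remain well-defined and positive
  everywhere, but perturbations far outside the band are numerically
  invisible.
- The generator's realism limits are listed above; in particular it is not
  a tool for estimating real-world reproducibility magnitudes.
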