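# Methods

## Scope and data model

All image analysis operates on 2D maximum-intensity projections; 3D stacks
are projected before any measurement (the generator renders projections
directly). Coordinates are 0-based (x, y) with the pixel-center convention;
physical pixel size is carried in μm/px and every output table suffixes its
columns with units (px², μm², %, min).

## À trous wavelet spot filter

The transform is the undecimated B3-spline pyramid: at level j the 1D kernel
(1, 4, 6, 4, 1)/16 with 2^{j−1}−1 zeros inserted between taps is applied
separably to c_{j−1} (c_0 = input), and w_j = c_{j−1} − c_j. Summation of
all detail planes plus the residual reconstructs the input exactly (floating
point only); the suite verifies ≤ 1e−9 relative error together with
linearity, shift equivariance away from borders, and variance monotonicity
of the smooth planes.

Choices that the method itself leaves open, fixed here:

* **Boundary handling** — symmetric reflection (`scipy` `mode="reflect"`),
  fixed so outputs are bit-stable.
* **Levels** — default J = 4; an image must satisfy min(dim) > 2^J·4 so the
  level-J kernel support fits, and the error message names the feasible
  maximum.
* **Noise threshold** — per plane, hard threshold at k·σ_j with k = 3 and
  σ_j = MAD/0.6745 by default (plane SD available). MAD is robust to the
  sparse bright spots sitting in each plane. On pure Gaussian noise ≤ 1% of
  coefficients survive k = 3.
* **Scale selection** — j* = round(log₂(d_px)) for an expected spot diameter
  d_px, clamped below at 1; a diameter needing a scale beyond J raises with a
  suggestion. A σ = 1.5 px Gaussian spot (FWHM ≈ 3.5 px, d_px ≈ 4) selects
  j* = 2. Single-plane output is the default; an opt-in multiscale sum over
  j*±1 trades selectivity for robustness.
* Negative coefficients are kept during thresholding and clipped only in the
  spot response (spots are bright).

## Spot segmentation

The response is binarized by one image-wide threshold — by default
`response > 0`, which is meaningful precisely because coefficients were
already noise-thresholded; Otsu and fixed thresholds exist for raw responses.
Components are 8-connected and no size gate is applied by default (optional
`min_area`/`max_area` flags exist but are off).

Declumping splits components containing several regional intensity maxima by
a seeded watershed. The markers are found on the wavelet spot response itself
with no extra smoothing and a minimum peak separation of 1 px, and centroids
are response-weighted. This was settled empirically on the generator's study
conditions: marker detection on the Gaussian-smoothed raw image (σ_d = 1 px,
2-px separation) left close spot pairs merged and capped pooled recovery
F1 near 0.89, while the band-pass response — already smooth at exactly the
spot scale — resolves pairs down to the physical limit (~2.5 px at
σ = 1.5 px) and yields pooled F1 ≈ 0.92 at precision ≈ 0.99. Both the declump
image and the parameters remain exposed. The split conserves foreground
pixels exactly, so cumulative spot area is invariant to declumping. Per-spot
mean/max intensity is measured on the raw FISH channel, not the response.

## Regions and enrichment

Polygons are rasterized by pixel-center membership under a half-open rule:
centers exactly on an edge are resolved by nudging the test point +1e−9 px in
x and +2e−9 px in y, so the rule is deterministic, adjacent polygons do not
double-claim centers, and an axis-aligned w×h rectangle on half-integer
vertices rasterizes to exactly w·h pixels. Self-intersecting polygons,
duplicate names and overlapping regions are rejected; out-of-frame vertices
are clipped with a warning.

A spot belongs wholly to the region containing its centroid (area-weighted
splitting was rejected for determinism and simplicity), so per-region
cumulative spot areas sum exactly to the total. The enrichment index is the
density ratio (region spot-area fraction over outside spot-area fraction),
making E = 1 the no-enrichment point; the raw-area variant
(A_spot(R)/A(R))/A_spot(out) is also emitted for completeness, since either
normalization is defensible when comparing vessel ROIs against surrounding
tissue. A zero outside spot area flags E undefined rather than returning
infinity.

## Morphometry conventions

* TD spans are merged (union of intervals) before summation, so duplicated
  or overlapping annotation spans cannot inflate the extent; the defect
  classes are {0} → absent, (0, 20) → "<20%", [20, 50) → "20–50%",
  [50, 100] → "≥50%".
* All protrusion thresholds are strict: a 15.0-μm protrusion does not count
  as "longer than 15 μm", nor a 5.0-μm filopodium as "longer than 5 μm".
* Sprout connection time is (contact frame − first frame strictly above
  threshold) × frame interval (20 min default); tracks that never cross
  report "no sprout" and tracks without a contact frame "no contact".
* The cortical band is the cell mask minus its erosion by a disk of radius
  `cortex_width`. The reported enrichment is cortex/middle (> 1 = cortical
  accumulation), with the reciprocal emitted alongside because both
  orientations of this ratio appear in common use. The ratio is invariant
  under positive intensity scaling; on a discrete disk the band boundary
  costs a few percent, hence the 5% tolerance on the generator's exact ring
  contrast.

## Group statistics

Implementations are thin, documented dispatchers over scipy/statsmodels:

* Mann–Whitney U uses the exact null when n+m ≤ 12 with no ties (a compute
  cutoff; the exact path is verified against full enumeration over all
  C(n+m, n) assignments for every n+m ≤ 10 in the suite) and otherwise the
  normal approximation with tie and continuity corrections. Two-sided
  everywhere by default.
* Kruskal–Wallis applies the tie correction; an all-identical input returns
  H = 0, p = 1 flagged degenerate instead of erroring.
* The 2×2 χ² uses the Yates continuity correction and requires positive
  margins; pairwise proportion tests build all pairwise Yates tables and
  Holm-adjust (step-down: sorted raw p, p̃_(i) = max_{j≤i} min(1, (m−j+1)
  p_(j))). Degenerate all-or-nothing identical pairs get p = 1.
* The dotplot summary reports percent = 100·#(value > 0)/n per (group, gene)
  and the mean over expressing cells by default (an all-cells mean is an
  option); a group with no expressing cells reports mean 0 with an
  undefined flag.

## Synthetic data: what it emulates and what it does not

The FISH generator renders two parallel vessel bands (default 37 px wide at
fixed fractional heights of a 256×256, 0.2 μm/px frame), plants round
σ = 1.5 px Gaussian spots (truncated at 4σ) at region-specific densities
(default 10/1000 px² in DA and PCV, 2/1000 px² outside), and applies Poisson
noise followed by additive Gaussian read noise (SD 2), the standard camera
model. The defaults give peak SNR ≈ 7–8 (amplitude 30 over
√(background + read²)). Per-region counts are Poisson draws with an
exact-count mode for bookkeeping tests; every planted center lies strictly
inside its polygon, and the "true spot area" reference uses the
disk-of-radius-2σ convention (π(2σ)² px²). Real projections differ in ways
the generator does not model — non-uniform background, vessel curvature,
autofluorescence, anisotropic PSFs, annotation error — so passing tests
demonstrate correctness of the computations at realistic densities and
noise, not field performance on any particular microscope.

Spot size and SNR of real data are not constrained by the source material;
σ = 1.5 px with the noise levels above is this package's choice of a
realistic diffraction-limited regime.

The cortical-cell generator renders a disk whose outer ring is exactly
`ring_ratio`-fold brighter than the interior before noise; the protrusion
track generator places the first strict threshold crossing at a named frame;
the expression generator draws Bernoulli expressing cells with
Gamma(2, mean/2) values and records the realized percent-expressing; the
measurement-table generator covers normal, shifted-normal, lognormal and
binomial families for type-I/power exercises.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data:
100 random 256×256 images across J = 1..5 for reconstruction, 30 seeds for
detection F1 (pooled over seeds) and 30 per planted density ratio for
enrichment recovery, 5000 replicates for the null rejection rate, 200 random
small samples for the enumeration check — sizes chosen so the whole suite
completes in well under a minute while keeping Monte-Carlo error far from
each margin. All randomness flows from explicit seeds; a fixed seed gives
bit-identical images, tables and pipeline CSVs (verified byte-for-byte).

## Known limitations

* No sub-pixel spot localization and no 3D or time-lapse tracking.
* Vessel ROIs are inputs (manual or simulated); there is no automatic vessel
  segmentation from the GFP channel.
* ImageJ ROI import covers rectangle and polygon types with an approximation
  of ImageJ's boundary semantics (exact for rectangles); other ROI types are
  rejected.
* The exact Mann–Whitney path requires tie-free data; tied small samples fall
  back to the corrected normal approximation.
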