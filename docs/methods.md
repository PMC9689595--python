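# Methods

This note documents the model, the defaults and why they were chosen,
what the synthetic data does and does not emulate, and the numerical
edge cases. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Imaging model and conventions

A B-scan is a 2-D array of 8- or 16-bit unsigned intensities, row-major,
origin top-left, indexed 0-based as (row, col); every stage inherits this
single convention so tiles, probes and contours cannot drift out of
register. RGB inputs (viewer exports, screenshots) are converted by the
arithmetic mean of the first three channels rather than rejected.
Clinician grades are stored as floats {0, 0.5, 1, 2, 3, 4} so the
calibration arithmetic needs no special ordinal handling. Physical pixel
spacing is never used: every rule in the pipeline (tile size, probe
size, thresholds) is defined in pixels or in fractions of image size.

## Binarization and denoising

The white-pixel threshold is Otsu's method on the full image by default,
with a fixed-threshold override (`threshold_mode: fixed`). Otsu is used
because the source device's reflectance scaling is not standardized
across exports, and the B-scan histogram is strongly bimodal (dark
aqueous vs bright anatomy). The boundary convention is strict: a pixel
equal to the threshold is black. A constant image makes Otsu
meaningless; the code falls back to the fixed threshold and logs a
warning instead of crashing.

Denoising is a morphological opening with the 3×3 **square**
neighborhood (radius 1). The square element is the identity on solid
blocks and on any spot at least 3×3 in extent, while erasing isolated
single-pixel speckle — which is exactly the separation wanted between
speckle noise and multi-pixel cell spots. (A radius-1 *disk* footprint
is the 3×3 cross; it clips convex corners and erases 5-pixel cross
spots, so it is not used.) Opening is anti-extensive and idempotent;
both properties are asserted by tests.

The fixation target leaves a thin bright vertical line at the scan
center. It is removed by an explicit rule rather than left to the
opening: any column in the central third of the image whose longest
vertical white run exceeds H/2 is an artifact candidate; contiguous
candidate bands at most `artifact_max_width` (default 3) columns wide
are zeroed whole. Wider full-height bands are left alone — they are
anatomy or fibrin, and judging them is the exclusion gate's job.

## Chamber segmentation

The anterior chamber is found on a *structure-scale* view of the
binarized scan:

1. a closing with radius `seal_radius` (default 2 px) seals slits up to
   ~4 px wide — in particular the zeroed artifact column, which would
   otherwise cut the cornea and iris bands and topologically connect
   the cavity to the background;
2. an opening with radius `structure_radius` (default 8 px) erases all
   white features thinner than ~17 px — cell spots and fibrin flecks —
   leaving only the anatomical bands;
3. dark 4-connected components of the result are candidate cavities.
   A candidate must touch neither the top nor the bottom image row,
   have area ≥ `min_area` (100 px), and be bounded by bright structure
   both above and below in at least 95% of the central 80% of its
   columns (fully enclosed regions qualify trivially). The largest
   candidate wins; an exact area tie goes to the higher centroid, since
   the AC sits directly under the cornea;
4. the final AC mask is the **column-wise vertical closure** of the
   winning component — every row between its upper and lower envelope —
   so intra-cavity content (cell spots, fibrin) lies inside the mask by
   construction; it is then eroded by `boundary_margin` (2 px) so the
   mask does not annex cornea/iris edge pixels, and reduced to its
   largest 4-connected piece if the erosion splits it.

The 8-connectivity-for-white / 4-connectivity-for-dark pairing is the
standard duality for border following and is used consistently. The
margin is deliberately small and decoupled from the structure radius: an
erosion at the structure scale would cost ~13% of a realistic cavity's
area and visibly depress overlap with the true cavity, for no gain once
the envelope is computed from the opened mask.

A scan with no qualifying dark region raises a segmentation error and is
reported unanalyzable — a distinct outcome from fibrin-gate removal,
though both exclude the eye.

Contour tracing is a Suzuki–Abe border-following implementation
(raster scan with border numbering, outer and hole borders, containment
hierarchy). It exists both as the chamber's outline provider and as a
general operation. One caveat discovered during testing and frozen into
the test oracle: the *ordered point set* of a border cannot always be
re-filled into the original mask — a border that weaves diagonally
around an interior white pixel is indistinguishable, as a point set,
from one that encloses it. Random-mask tests therefore check a complete
labeling-based characterization (contour counts per component and per
hole; border sets sandwiched between 4- and 8-adjacency to background;
fill-reconstruction exact away from the one-pixel border band), and
exact fill round-trip is asserted on weave-free fixtures.

## Fibrin gate and spot counting

Two probe rectangles of `region_width` × `region_height` (defaults
W/8 × H/8, floored) are anchored symmetrically about the AC centroid at
horizontal offsets ∓W/8, clipped to the mask's bounding box. The white
fraction is pooled over both probes intersected with the AC mask — the
20% criterion is read as a pooled criterion, not per-region — and the
scan is removed iff the fraction **strictly exceeds** 0.20. Probe
placement is the package's choice (the anchor rule is not dictated by
the underlying method); the centroid is the most defensible
anatomy-free anchor for sampling aqueous.

Counting partitions the image into non-overlapping 5×5 tiles anchored
at (0,0); partial tiles at the right/bottom edges participate. A tile
contributes 1 iff it contains ≥ 1 pixel that is white *and* inside the
AC mask. Tiles, not connected components, are the counting unit: a
clump of adherent cells in one tile counts once, and a large cell
spanning two tiles counts twice — an accepted, deliberate property of
the method. The count is bounded by ⌈W/5⌉·⌈H/5⌉ and is monotone in the
white-pixel set; both are tested against a brute-force enumeration
oracle.

Per eye, the four scan counts are summed. If *any* scan is gate-removed
or unanalyzable the eye is excluded as a whole (totals from fewer than
four scans would not be comparable across eyes); excluded eyes are
always carried to the output with a flag. The sum (not the mean) is
used; with all four scans present the two differ only by a constant
factor, which the monotone calibration absorbs.

## Calibration and evaluation

The count-to-grade curve y = a·ln(x) + b is fit by OLS of grade on
ln(count) — the natural reading of a "logarithmic approximation curve".
Counts below 1 are outside the domain of ln; they are dropped from the
fit with a warning, and a count of 0 predicts grade 0.0 by convention.
Fewer than two usable points, or all counts identical, raise a fit
error. Predictions are unclipped by default (rank correlation is
unaffected by clipping for in-range data); an optional clip constrains
them to [0, 4].

Spearman's rho uses average ranks with the t-approximation p-value
(n − 2 df) — adequate at the cohort sizes involved, and the rho itself
is what the evaluation reports. Zero rank variance raises an error
rather than returning NaN. Kruskal–Wallis uses the tie-corrected H with
a χ² p (k − 1 df); all-identical observations return H = 0, p = 1.
Both statistics are delegated to scipy and cross-checked in the tests
against hand-computed rank formulas, including a tie-corrected case.

The train/test split is seeded and stratified by grade with
largest-remainder allocation, so a 48-eye cohort splits exactly 26/22
and each grade stratum is represented proportionally (±1). LOOCV fits n
models, each leaving one eye out, and reports the Spearman rho between
observed grades and the held-out predictions; predictions are
order-invariant and the fold count equals n.

## Synthetic data

`generate_scan` renders the geometry the pipeline relies on, not OCT
physics: a parabolic corneal band (apex at 0.10·H, sag 0.23·H,
thickness ≈ 0.067·H), a flat iris/lens band at 0.73·H, dark aqueous
between them, disk-shaped cell spots (radius 1 ≙ a 3×3 block, which the
denoising opening preserves exactly), optional fibrin, an optional 1-px
fixation line at W/2, and additive Gaussian noise standing in for
multiplicative speckle. Default size is 800×600 so the W/8 × H/8 probes
(100×75) and the 5×5 tiling behave as exact integers. By default spot
centers snap to centers of distinct 5×5 tiles with a minimum center
separation of 2·(radius+3); this makes the ground-truth tile count equal
the number of spots placed, so end-to-end fidelity is exactly testable.
Clumping scenarios are produced by turning the alignment off.

Fibrin is rendered as dense bright flecks of 3–6 px radius covering a
target fraction of the chamber. The scale matters: flecks sit below the
structure-opening scale, so they remain *inside* the segmented chamber
and raise the gate's white fraction to about the coverage fraction —
the phenotype the 20% rule was designed to catch. Anatomy-scale blobs
would instead merge into the structure mask and be segmented *around*,
which can never trip a gate that measures white content inside the
chamber.

`generate_cohort` inverts the calibration curve: an eye of grade g
targets a total count of exp((g − b)/a) multiplied by lognormal noise
of dispersion `count_noise` (default 0.4), floored at 1 spot — even
clinically quiet eyes show occasional hyperreflective specks — and
distributes it multinomially over the four scans. The default grade
census (13, 6, 12, 10, 7 eyes for grades 0–3+ in 48 eyes) mirrors the
reference cohort's analyzable eyes; fibrin eyes are generated as
grade 4 with 50% fleck coverage in every scan.

What passing tests on this data do **not** show: robustness to real
OCT speckle statistics, intensity inhomogeneity across the chamber,
eyelid/lens reflections, pseudophakic anatomy, or the true reflectance
distribution of cells vs pigment (the method cannot distinguish those
even on real data). The synthetic cohort demonstrates that the
*pipeline* is faithful — counts equal ground truth, exclusions hit
exactly the fibrin eyes, calibration recovers the generating curve —
not that the clinical correlations would reproduce on another cohort.

## Problem sizes

Default test and acceptance runs use: 100 noise-free and 100 noisy
scans for count fidelity, 50 scans for segmentation overlap (Dice ≥
0.90 against ground truth), 1000 random masks for the tiling oracle,
200 replicates of the 26-point calibration recovery, and one 51-eye
cohort (204 scans at 800×600) for the end-to-end exclusion and LOOCV
check. These sizes were chosen to exercise every rule at full image
scale while keeping a complete run in the low minutes on one core.

## Known limitations

- The Otsu threshold is global; severe flare brightens the aqueous and
  shifts the threshold, which can depress spot detection before the
  gate fires (the underlying method shares this limitation).
- Probe placement assumes the chamber centroid lies in aqueous; an eye
  with an extremely shallow or fragmented chamber may gate-error and be
  reported unanalyzable.
- The Suzuki–Abe tracer is pure Python; it is fast enough for one
  contour per scan but is not optimized for dense contour soups.
- Grades are calibrated on ln(count); eyes with zero counts carry no
  information for the fit and are predicted 0.0 by convention.
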