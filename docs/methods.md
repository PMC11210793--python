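# Methods

This note documents the models, procedures and numerical choices behind
`chemotax`, in the order data flows through the pipeline.

## Coordinate system and arena geometry

Each behavioral arena is a foam-bounded lane with two apices on the gradient
axis; the test compound sits at the notched apex, the solvent reference at
the other.  Worm positions are measured in pixels along the gradient axis
from the test apex and mapped to a centered millimeter coordinate

    z = (w/2 − x) · 25.4 / dpi

where `w` is the apex-to-apex span in pixels (measured per arena from the
insert's interior extrema) and `dpi` the scan resolution.  Positive `z` is
toward the test compound.  The printed form of this transform in the
literature does not itself re-center the origin; we apply the origin shift
explicitly so that the full range is symmetric (±w·25.4/(2·dpi), about
±32.2 mm at the nominal 3,041 px / 1,200 dpi geometry).  The *nominal*
arena half-width is 32.5 mm and is used wherever a fixed physical bound is
needed (position-model truncation, default index segmentation); the
*measured* per-arena `w` overrides it for pixel→mm conversion.

## Imaging

The imaging path is deterministic (no randomness anywhere):

1. **Otsu threshold.**  Computed over the full 0..255 histogram with exact
   integer arithmetic: between-class variances are compared as integer
   fractions `(S₀W₁ − S₁W₀)²/(W₀W₁)`, so the returned threshold is the true
   argmax even when two splits differ by less than float precision, and
   ties resolve deterministically to the smallest maximizing threshold.
   Foreground is *strictly* above the threshold.  A constant image has no
   defined threshold: the mask is empty and a warning is issued.
2. **Closing.**  One pass with a 3×3 square.  The defect-repair element is
   deliberately minimal: anything larger starts merging neighboring worms.
3. **Labeling.**  8-connected components (diagonal-touching worm bodies
   stay whole), with centroid, area and bounding box per object.
4. **Arena detection.**  Insert candidates are objects above an area floor
   (50× the maximum worm area, scaled by `(dpi/1200)²`) that enclose an
   interior; the interior's horizontal extrema give the apices and `w`.
   The notch tab makes the test-side half of the insert heavier, which is
   how the test side is recognized.  Detections are ordered row-major
   across the scan; consecutive groups of `wells_per_plate` share a scanner
   slot.
5. **Area filter.**  Worm-like objects satisfy `min < area < max`
   (defaults 50 and 2,500 px at 1,200 dpi, strict on both bounds,
   idempotent).  Aggregated worms exceed the upper bound and are excluded,
   not split; the small-object bound removes eggs, debris and the rare
   background-noise speck.  At reduced resolutions callers pass bounds
   scaled by `(dpi/1200)²` — there is no hidden scaling inside the filter.
   Objects touching the arena-mask border are kept if their centroid is
   inside the mask.

## Chemotaxis metrics

The gradient axis is divided into nine equal segments.  `p` counts worms in
the four test-side segments, `q` the four control-side segments; the central
ninth is the starting zone where worms were dispensed and is excluded from
the index `CI = (p − q)/(p + q)`.  When every worm is still in the starting
zone the index is undefined (`nan` with a flag), never silently zero.  A
worm exactly on a segment boundary is assigned to the segment nearer the
test side — a deterministic tie-break that is measure-zero on real data.
The mean worm position is the plain average of `z` over *all* worms,
starting zone included.  On unimodal endpoint distributions the two metrics
are essentially interchangeable (the test suite checks R² > 0.9 across a
drift sweep).

QC: arenas with fewer than 150 worms are excluded from pooling.  The
threshold is where the variance of the null-condition index stops shrinking
appreciably in the 1/n law (see the variance-curve simulation); the bound is
inclusive (exactly 150 passes).

## Estimation statistics

Responses are quantified as effect sizes, not test statistics:

* **Mean difference.**  `mean(test) − mean(control)` over per-worm positions
  pooled across replicate arenas.  The point estimate is exact; only the
  interval is bootstrapped (5,000 resamples with replacement, each group
  independently).  The default interval is the percentile interval — it is
  transparent and directly checkable against a brute-force reimplementation;
  the bias-corrected accelerated (BCa) interval is available via
  `method="bca"`.  Point estimates are identical either way.
* **CI → p.**  `p = 2·min(F̂(0), 1 − F̂(0))` from the bootstrap ECDF at
  zero, floored at `2/(B+1)` — one cannot claim more resolution than B
  resamples provide — and capped at 1.  Calibration at the study's
  conditions (truncated-normal positions, σ = 10 mm, 250 worms/group) gives
  95% CI coverage within 95 ± 2% and a null rejection rate within 5 ± 2%
  over 1,000 replicates (measured by the acceptance suite).
* **FDR.**  Benjamini–Hochberg step-up at 5%, applied within each
  (strain, null-reference) family of comparisons.
* **Two-factor contrasts.**  `Δ₁ = mean(G1,C) − mean(G2,C)`,
  `Δ₂ = mean(G1,T) − mean(G2,T)`, `ΔΔ = Δ₁ − Δ₂`, CI by jointly resampling
  all four groups.  The second contrast is between the two *test*
  conditions, the form consistent with a two-way-ANOVA interaction; a
  `strict_literal` switch reproduces the alternative reading in which Δ₂
  contrasts G1's test response with G2's control.  `ΔΔ` is exactly linear:
  adding a constant to all four groups leaves it unchanged.
* **Reproducibility.**  One top-level seed; each comparison derives its
  stream from `SeedSequence((seed, crc32(label)))`, so any subset of a run
  reproduces bit-for-bit.  Percentile edges use `numpy.percentile` with its
  default linear interpolation.

## Classification

Valence: a compound is chemoactive when its CI excludes zero against at
least one of the two null references (symmetric DMSO:DMSO, asymmetric
DMSO:water); the valence sign comes from the symmetric comparison.  If the
two significant comparisons disagree in sign the call is flagged ambiguous
and the symmetric sign wins.  Compounds that lose significance after FDR
correction stay in the output flagged as putative false positives rather
than being dropped — weak responders can be genuine.

Channel dependence uses the |ΔΔ| panel of five genotype-pair comparisons
(each single mutant and the double vs wild type; each single vs the double).
The pooled |ΔΔ| distribution over every compound × pair comparison in the
run is binned into quartiles, and the pooled median is the
substantial/modest threshold (strictly above = substantial).  The classes:

| class | rubric |
|---|---|
| `tax4_primary` | tax-4 vs wt substantial; tax-4 vs double modest; osm-9 vs wt modest |
| `osm9_primary` | mirror image |
| `both_required` | both singles differ from wt but phenocopy the double |
| `redundant` | both singles phenocopy wt; the double differs from wt |
| `partial` | both singles differ from wt without phenocopying the double |
| `unclassified` | anything else |

The verbal notions of "requires both" and "either suffices" have no
canonical numeric form; reusing the single median threshold keeps the whole
rubric on one scale.  That choice has a known sensitivity: the median is a
quantile of whatever pool the run computed, so in very small screens (few
compounds) it can land inside a cluster of genuinely-large or
genuinely-small values and flip borderline calls.  With screen-scale pools
this is immaterial.  Valence inversion is flagged when wild type and a
single mutant both respond significantly with opposite signs.

## Synthetic data

The generator emulates the study conditions, not arbitrary imagery:

* **Scans.**  8-bit grayscale, nominal 1,200 dpi, apex-to-apex span
  3,041 px (the measured geometry of the real arenas); background 30,
  worm 200, insert 230 intensity with Gaussian noise (σ = 6) added before
  quantization and clipping — the foreground-background gap is ≥28 noise
  SDs, far above the ≥3σ separability floor the generator enforces.  Worms
  are filled ellipses with random orientation and aspect ratio 2.5–5,
  target areas 150–900 px (an adult worm's ~1 mm × 60–80 µm footprint at
  1,200 dpi), placed with a ≥4 px gap so that a single 3×3 closing pass can
  never merge neighbors; the rendered label image records the exact painted
  pixels, so ground-truth areas are pixel-exact.  Reduced-dpi canvases
  scale lengths by `dpi/1200` and areas by its square, for cheap multi-plate
  layout tests.  Multi-plate scans stack plates vertically so row-major
  ordering groups lanes by plate.
* **Positions.**  Endpoint coordinates are drawn from
  `Normal(μ_drift, σ)` truncated to ±32.5 mm.  Defaults: σ = 10 mm (the
  spread of real endpoint distributions is of this order), drift 7.5 mm for
  an attractant-strength effect, 250 worms per arena (the typical dispense).
  Drift is a phenomenological endpoint model — it does not simulate runs,
  pirouettes or weathervaning, worm clumping, or the scanner's photometric
  transfer.  Consequently, passing tests demonstrate the correctness of the
  measurement and statistics pipeline given worm-sized bright objects and
  drift-shaped endpoint data; they do not validate segmentation against
  real-scan artifacts (uneven illumination, condensation, gel texture).
* **Rendering positions.**  When a screen run renders sampled positions
  into images, positions within ~1.5 mm of an apex are pulled inward (a
  worm body cannot center on the apex point) and the drift model is
  truncated slightly tighter; this biases recovered drift a few percent
  low, which the recovery checks tolerate.

## Problem sizes

Defaults in the test and acceptance suites: 20 full-resolution scans of
200 worms for recovery; 1,000 random histograms / p-vectors for the
exactness checks; 600 replicates per point of the variance curve over
n = 50..350; 1,000 replicates at 250 worms/group for bootstrap calibration
(5,000 resamples each); rendered mini-screens use 2–3 arenas of 200–250
worms per condition.  These sizes give stable estimates at the stated
tolerances while keeping a full run in a couple of minutes on one core.

## Known limitations

* Clumps are excluded by area, so counts are biased low where worms
  aggregate; mean position is robust to this but extreme aggregation near
  one apex would bias it.
* The insert detector assumes ring-shaped inserts with an enclosed
  interior and a mass asymmetry marking the test side; damaged or touching
  inserts are not recovered.
* Pooling ignores biological-replicate structure (by design, matching the
  screen's pooled analysis); hierarchical replicate models are out of
  scope.
* The reproduction module (`chemotax.reproduce`) recomputes published
  screen-level numbers only when the deposited per-worm position tables are
  supplied locally; they are not redistributed with the package.
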