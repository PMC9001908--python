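# Methods

## Problem and pipeline

Endometrial thickness (ET) is measured on longitudinal transvaginal
ultrasound sections as the maximal anteroposterior extent of the
endometrial band. The pipeline automates the two steps a sonographer
performs: delineating the endometrium (semantic segmentation) and placing
the caliper at the thickest point (largest inscribed circle). All geometry
is done on the pixel grid in 0-based (row, column) coordinates, row 0 at
the top; physical units enter only through a single isotropic pixel spacing
(mm/px).

## Thickness from the largest inscribed circle

Given a binary mask, the largest 8-connected foreground component is kept
(4-connectivity is available as a flag; 8 is the default because speckle
fragments masks along diagonals). For every foreground pixel the Euclidean
distance to the nearest background pixel is computed, with everything
outside the image frame counted as background so a border-touching region
cannot claim a circle extending past the frame. The circle's centre is the
pixel with maximal distance; its radius is that distance.

Conventions, chosen once and used everywhere:

- **Radius.** Distance from the (integer) centre pixel to the nearest
  background pixel. A single isolated pixel has radius 1.
- **Thickness.** `thickness_px = 2 * radius_px - 1`, so a 1-px region
  measures 1 and an odd-height strip of height *h* measures exactly *h*.
  Even heights are reported one pixel low; this is within the pipeline's
  stated ±1 px measurement tolerance and is the price of an integer-centred
  circle. `thickness_mm = thickness_px * spacing`.
- **Tie-breaking.** Both the component choice (among equal-sized
  components) and the circle centre (among equal distances) take the
  candidate whose first pixel comes earliest in row-major order, making
  results deterministic and implementation-independent.

Two implementations are provided and tested for exact agreement (centre and
radius) on random-mask sweeps and handcrafted edge cases (border-touching
shapes, 1-px lines, donuts, ties): a brute-force search that minimises over
all background pixels, O(foreground × background), kept as the reference
oracle; and the production route via the exact Euclidean distance transform
(`scipy.ndimage.distance_transform_edt` on a mask padded with one
background ring — any exterior pixel beyond the ring is farther than the
ring pixel on the same ray, so one ring suffices for exactness).

## Segmentation network

SegNet-pattern encoder–decoder with a residual backbone, built on a
self-contained NumPy layer engine (convolutions via im2col, instance
normalisation, ReLU, 2×2 max-pooling that records argmax indices, the
matching max-unpooling, residual basic/bottleneck blocks, Adam). Using
instance rather than batch statistics makes inference independent of batch
composition; using NumPy end to end makes runs bit-reproducible for a fixed
seed.

Layout: a 3×3 convolutional stem, four residual stages, and a 2×2 max-pool
after the stem and after each stage — five halvings, hence input sizes must
be divisible by 32 (other sizes are symmetrically zero-padded for
prediction and cropped back, preserving the pixel grid for the geometry
step). The decoder mirrors the five poolings with index-based unpooling,
each followed by one 3×3 convolution (five decoder convolutions in all),
and a 1×1 sigmoid head yields per-pixel foreground probabilities;
binarisation is strictly-greater-than a threshold (default 0.5).

Presets:

- `full` — the standard ResNet-50 stage layout (bottleneck blocks in counts
  3/4/6/3, output widths 256/512/1024/2048). Two classification-specific
  pieces are deliberately absent: the global 7×7 average pooling (a
  segmentation encoder must keep its spatial grid) and the 7×7 stem (the
  engine supports 1×1 and 3×3 kernels; a 3×3 stem is functionally
  equivalent at segmentation scale). No pretrained weights are bundled;
  `pretrained_encoder=True` is rejected with a clear error.
- `tiny` — same topology with basic blocks, widths 8/16/24/32, one block
  per stage (~10⁵ weights). This is the variant all experiments and tests
  train; it fits a CPU-minute budget.

Training minimises binary cross-entropy plus soft Dice loss (selectable:
either alone or their sum, the default — the Dice term counters the heavy
class imbalance of a thin band, the cross-entropy term keeps gradients
well-scaled early on) with Adam at learning rate 10⁻³, batch size 5.
`train()` re-initialises weights from the training seed, so (data, config)
fully determines the run; per-epoch mean minibatch loss is recorded as the
history.

## Phantom generator

The generator emulates the one property of clinical TVUS frames the
pipeline depends on: a single bright, gently curved band of controllable
maximal thickness on a darker speckled background. A quadratic centreline
spans the image width (curvature parameter bends it; amplitude is bounded
so the band stays in frame); the band is all pixels within
`(t − 1) / 2` of the rasterised centreline, which for odd targets *t*
renders exactly *t* px thick and for even targets *t* − 1 px (inside the
±1 px tolerance). The ground-truth mask is the exact band support before
noise. Intensities are two-level (foreground mean 0.75, background 0.2 by
default) under multiplicative speckle, `image = base × (1 + s·(R − E[R]))`
clipped to [0, 1] with *R* Rayleigh-distributed — the standard first-order
ultrasound speckle model. Each phantom stores a `true_thickness_px`
re-measured on its own mask by the inscribed-circle search, so the
reference value shares the pipeline's conventions. Cohorts derive
per-phantom seeds as `master_seed + index`.

Defaults: 128×160 px frames at 0.1 mm/px — a desk-scale analogue of
clinical frames (852×1136 px at sub-0.1-mm spacing), sized so that a full
train-and-evaluate cycle runs in about a minute on one CPU. The standard
experiment trains the tiny preset on 50 phantoms with thicknesses uniform
in 5–40 px and curvatures in [0, 1] for 20 epochs and evaluates on 10 fresh
phantoms; held-out Dice is ≈ 0.87–0.92 depending on seed.

What the phantoms do **not** emulate: acoustic shadowing, attenuation,
ambiguous boundaries, neighbouring echogenic structures (e.g. the
myometrial interface), probe-angle variation, or pathology-distorted
shapes. Passing phantom tests therefore demonstrates that the pipeline's
machinery is correct and that the network can learn a bright-band
segmentation — not that clinical-grade accuracy (published Dice ≈ 0.8,
MAE ≈ 2 mm on real cohorts) would be reached; that requires clinical data
outside this package's scope.

## Evaluation statistics

- **Dice** 2·TP/(2·TP + FP + FN); two empty masks score 1.0 by convention.
- **MAE** mean of |yᵢ − xᵢ| over cases (y automated, x reference, mm).
- **Acceptable rate** 100 × #{|yᵢ − xᵢ| within tolerance}/n. The tolerance
  and its strictness are parameters (default 2.0 mm, strict) because
  clinical margins of both ±2 and ±3 mm are in use; the stratified report
  defaults to ±3 mm inclusive.
- **Stratified report** groups by *reference* ET with closed-left bounds
  exactly as the labels read: ET ≤ 3; 3 < ET ≤ 10; ET > 10 mm, plus a Total
  row. Counts are conserved (strata sum to Total; within + over = cases per
  row). Rates are kept at full precision and rendered at 1 d.p., em dash
  for empty strata.
- **Pathology comparison** on signed errors y − x between N/P/EC groups:
  per-group mean and variance, pairwise unpaired Welch t-tests (groups are
  independent patients with unequal sizes and no variance homogeneity
  guarantee), one- and two-tailed p, and a single Bonferroni-corrected
  p = min(1, m · min p) over the m ≤ 3 pairwise comparisons. A Shapiro–Wilk
  statistic per group serves as the normality diagnostic. Identical groups
  give t = 0, p = 1; a pair in which both groups have zero variance is
  reported as a degenerate-test error rather than a number.

A calibration check draws all three groups from one normal distribution
(sizes 127/43/10, matching a realistic clinical imbalance) and verifies the
corrected test rarely rejects: its long-run non-rejection rate is ≈ 95.9%
(the Bonferroni bound is conservative for correlated pairwise tests). Note
that a 100-replicate sample of that rate carries a binomial standard
deviation of ≈ 2 percentage points, so individual 100-replicate runs
scatter roughly between 92 and 99.

## Published-table replication and source discrepancies

The stratified report reproduces published acceptable-rate tables from
their printed (cases, within) counts. Reference tables of this kind are
not always internally consistent; the one this package's fixtures follow
carries two arithmetic slips, which the package surfaces rather than
hides:

- its third stratum prints 98.3% where its own counts give
  61/62 = 98.387… → 98.4 at 1 d.p. (no rounding convention yields both
  95.4 from 124/130 and 98.3 from 61/62);
- its Total row's within-count (191, rate 89.3%) is not the sum of the
  per-stratum counts (12 + 124 + 61 = 197, rate 92.1%).

`stratified_report` stays arithmetically exact and conserves counts; the
Total rate 89.3% is reproduced from the Total row's own counts (191 of
214). Similarly, an accompanying prose figure of 55.3% for the thin
stratum is superseded by the tabulated 12/22 = 54.5%.

## Degenerate inputs and numerical choices

Empty masks raise a dedicated error (segmentation failure must not be
silently measured as zero). Non-positive spacing, out-of-range thresholds,
non-two-valued masks, and malformed tables raise validation/format errors
naming the violated constraint. Probability maps are produced by a
numerically stable sigmoid; losses use ε = 10⁻⁷ clipping inside logs and
+1 smoothing in the soft-Dice ratio. All float comparisons in the
equivalence tests are exact because both circle searches compute the same
square-root-of-integer distances.

## Known limitations

- Thickness is the inscribed-circle diameter on the pixel grid: no
  sub-pixel centres, no anisotropic spacing, no double-layer caliper
  emulation; the circle-derived value is reported as ET directly.
- Even-width regions measure 1 px low (convention above).
- The exhaustive circle search is quadratic and intended only as an oracle
  for small masks.
- The `full` preset is provided for architectural fidelity and parameter
  count; training it in NumPy on a CPU is impractical and untested.
- Phantom realism limits are listed above; clinical performance claims are
  out of scope.
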