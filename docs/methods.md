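# Methods

This note documents the models and numerical choices behind `raybok`: what
each operator computes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Intensity convention

All processing happens on real intensities in [0, 1]; 8-bit files map via
`v/255` on read and `round(v·255)` on write.  This makes the two
scale-sensitive parameters — the CLAHE clip fraction (0.01) and the
NL-means filter strength (h = 0.05) — independent of bit depth.
Coordinates are row-major, 0-based, origin top-left.

## CLAHE

The image is partitioned into an 8×8 tile grid (tiles of `⌊H/8⌋ × ⌊W/8⌋`,
edge tiles absorbing remainders).  Per tile: a 256-bin histogram; bins
clipped at `⌈clip_limit · n_tile⌉`; the clipped excess redistributed
uniformly over all bins, iterating because redistribution can push bins
over the limit again, until the residual excess is below one count (the
residual is then spread uniformly without clipping, so histogram mass is
conserved exactly).  The mapping is the cumulative distribution scaled to
the full [0, 1] output range; each pixel bilinearly interpolates the
mappings of its ≤ 4 surrounding tile centers, with clamped replication
outside the outer ring of centers.  A pathological clip limit below
`1/n_bins` leaves insufficient capacity; redistribution then stops after a
bounded number of iterations and conserves mass at the expense of the clip
bound (this cannot occur with the default parameters).

The "distribution parameter" 0.4 is stored but inert under the default
uniform target shape; a Rayleigh-shaped target (CDF mapped through the
Rayleigh quantile function, renormalized to [0, 1]) is implemented for
completeness.

With a 1×1 tile grid and clip limit 1.0 the operator reduces exactly to
global histogram equalization — one of the test oracles.

## Non-local means

Output at pixel *i* is `Σ_j w(i,j)·v(j) / Σ_j w(i,j)` over the
`(2·window_radius+1)²` search window clipped at the image border, with
`w(i,j) = exp(−d²(i,j)/h²)` and `d²` the Gaussian-weighted mean squared
difference between the `(2·kernel_radius+1)²` patches around *i* and *j*
(patch weights: Gaussian with σ = kernel_radius/2, normalized to sum 1;
patches near the border come from the mirror-extended image).  The self
weight `w(i,i)` is set to the maximum of the other window weights — the
standard guard against the zero self-distance dominating the average — and
to 1 when the window holds only *i*.

The kernel and window radii are absolute half-widths in pixels (radius 4
gives 9×9 patches and 9×9 windows); a fractional-of-image-size reading
would make the filter's behaviour depend on image size, which nothing else
in the chain does.

The implementation computes, per window offset `d`, the full patch-distance
field as a separable Gaussian convolution of the squared shifted
difference, and exploits the symmetry `w(i, i+d) = w(i+d, i)` to process
each offset pair once.  It agrees with a per-pixel triple-loop reference to
≤ 1e-6 and fixes constant images exactly.

## Repetition padding

The image is rescaled (bilinear, aspect preserved) so its long side equals
512, then the deficient axis is filled by cyclically repeating the rescaled
content from its first row/column, cropping the last copy; output is
exactly 512×512, content anchored top-left.  Square 512×512 input passes
through bit-identically, which makes the operator idempotent.  A figure can
show repetition but not anchoring; top-left is the simplest reproducible
convention.

## Layering and input modes

`layered` stacks original / CLAHE / NL-means as R/G/B — a fixed, documented
channel order (none is canonical).  `padded_layered` pads **first** and
computes both enhancement layers on the padded image: enhancing first would
compute CLAHE tile statistics on a geometry that no longer exists after
padding.  Six input modes (original, clahe, nlmeans, layered, padded,
padded_layered) form the rows of the evaluation report.

## Bag-of-Keypoints

* **Dense SIFT.** Gradient-orientation descriptors (4×4 spatial cells × 8
  orientation bins = 128 dims) on a 4-px grid at cell sizes {4, 6, 8, 10},
  the usual multi-resolution dense-SIFT ladder.  Gradients by central
  differences; orientations soft-assigned to the two nearest bins; cell
  sums via integral images.  Descriptors are L2-normalized, clamped at 0.2,
  re-normalized, and stored on the conventional integer scale (×512,
  clipped at 255) so they round-trip losslessly through uint8 — a uniform
  scaling that leaves all nearest-neighbour geometry unchanged.  Frames
  whose support has mean gradient magnitude below 1e-4 are flagged
  low-contrast and excluded from sampling and quantization.  Multi-channel
  (layered) input is collapsed to the channel mean before extraction.
* **Codebook.** Lloyd k-means, centers initialized from k distinct random
  data points, at most 20 iterations, empty clusters re-seeded from the
  farthest points, within-cluster sum of squares recorded per iteration.
  Each training image contributes at most 1,000 randomly sampled
  descriptors to the clustering pool (subsampling keeps clustering
  tractable; histograms still use every descriptor).
* **Quantization.** Nearest center under L2.  The default path is exact
  brute-force assignment via a single matrix product — in 128 dimensions
  this outruns kd-tree traversal at desk-scale codebook sizes — with ties
  broken toward the lowest center index.  A kd-tree route
  (`mode="kdtree"`, `approx_eps` for approximate pruning; 0 = exact) is
  provided for large codebooks and verified equal to brute force at exact
  settings.
* **Spatial histogram.** 2×2 equal quadrants (extra pixels to the
  right/bottom), per-quadrant k-bin word counts concatenated row-major:
  4·k dims, 4,000 at k = 1,000.  Histograms are L1-normalized by default:
  with image areas varying several-fold, raw totals dominate the PCA
  variance and measurably depress class signal; raw counts remain available
  (`normalize=False`).
* **PCA.** Fit on training histograms only (no test leakage), reduced to
  100 dims (clamped to `min(100, n_train−1, 4k)` for small runs), no
  whitening; component signs fixed so the largest-magnitude loading is
  positive, making the model deterministic.

## Classification and the experiment harness

One Random Forest per scheme: bagged trees grown to purity, `√d` features
per split (the standard heuristic; only the tree count is prescribed),
majority vote with ties to the lexicographically smallest label, plain
votes with no class weighting.  The harness prepares inputs per mode, fits
codebook and PCA on training images only (asserted by checksumming the fit
inputs), trains and evaluates per scheme, and reports exact-match accuracy
per (mode, scheme) cell with the canonical row labels and ordering.  Class
universes are derived from the training table; unseen test labels are
counted and reported, never silently added.  A single run seed fans out to
per-stage seeds (CRC32 of `seed:stage`), so stages are independently
reproducible and a rerun reproduces the report byte-for-byte.

## Synthetic data generator

The generator emulates the properties of a radiograph annotation corpus
that the pipeline actually exercises: variable aspect ratios (height and
width sampled independently from [200, 512], so padding occurs along both
axes), smooth radial vignetting, additive Gaussian read-out noise
(σ = 0.05), and four class-discriminative factors wired one-to-one onto the
IRMA axes — A (4 values) picks the foreground shape family (ellipse / bar /
three blobs / ring), D (3 values) the in-plane rotation of shape and
texture, T (2 values) the acquisition regime (smooth vs. fine
concentric-ring overlay with a different level pair), B (2 values) the
interior texture pattern (stripes vs. dot lattice).  The texture's spatial
period tracks the A family — texture and region are correlated, as organ
systems are with body regions — and textures are near-square-wave with
amplitude 0.22 so their gradients clear the noise floor at the descriptor
level.  Per-image randomness is a pure function of (code, seed).

Deliberate simplifications: Gaussian rather than Poisson noise, no
anatomical realism, no long-tailed class imbalance, and vocabulary sizes
chosen so A is the hardest single axis and T the easiest — mirroring the
difficulty ordering of real multi-axial annotation without claiming to
reproduce any corpus's absolute accuracies.  Passing the synthetic
benchmark therefore shows that the chain carries class signal end to end
and is reproducible; it does not predict accuracy on clinical data.

## Benchmark problem sizes

The standing benchmark uses 300 images, an 80/20 split stratified by full
code (never emptying a class's training side), four input modes, all five
schemes, k = 50 words and 100 trees — dimension contracts all scale with k,
so the desk-scale codebook exercises the same code paths as k = 1,000.

## Known limitations

* Dense SIFT lacks the Gaussian spatial weighting of detector-based SIFT;
  for bag-of-words quantization this has no practical effect.
* The ANN route exposes kd-tree `eps`-style approximation rather than a
  max-comparisons budget.
* CLAHE requires images at least as large as the tile grid; tiny images
  should use fewer tiles.
* The full IRMA terminology is not bundled; axis decoding needs a
  user-supplied TSV dictionary.
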