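# Methods

This note documents the models and procedures implemented in `organoidq`,
the parameters that matter, the synthetic data the tests run on, and the
limits of what those tests show.

## Segmentation model

Brightfield organoids present as a dark epithelial rim enclosing a brighter
lumen on a bright background, imaged as a z-stack because objects float at
different depths in the matrix. The pipeline therefore detects *edges* per
plane and combines them, rather than thresholding intensity:

autoscale → per-plane Canny → per-plane small-component removal → minimal
projection (union) of the edge maps → contour bridging and filling →
boundary calibration → marker-based watershed splitting.

**Autoscale** (`autoscale_p_low=1`, `autoscale_p_high=99`): linear stretch
of each plane to 8-bit between its 1st and 99th intensity percentiles,
clipped. Robust percentiles suppress specular outliers (bubbles, dust). A
constant plane maps to zero.

**Edge detection** (`canny_sigma=2` px): Gaussian smoothing, Sobel
gradient, non-maximum suppression, double-threshold hysteresis. Thresholds
are computed *once per stack*, not per plane: the high threshold is Otsu's
threshold on the pooled gradient-magnitude histogram of all planes,
re-applied to the above-threshold population (a second Otsu pass), floored
at `canny_floor_mult=3` times the pooled median gradient; the low threshold
is half the high one. Rationale: every object is sharp in one plane and
casts progressively wider, weaker halo edges into the others. Per-plane
adaptive thresholds dutifully report those halos, and the union then
inflates every contour by several pixels. One stack-level threshold keeps
the sharp rims and rejects the halos; the median floor keeps object-free
stacks (pure noise) from yielding edges at all. Fixed thresholds can still
be supplied in the config (`canny_low`, `canny_high`).

**Small-component removal** (`min_edge_component_px=10`): 8-connected edge
components below 10 px are noise speckle; removing them before projection
keeps the union clean.

**Contour filling** (`close_radius=3`, `min_object_area=200`): gaps up to
2·`close_radius` in the projected contours are bridged by
dilate → fill-holes → erode. Plain morphological closing cannot reconnect
a broken one-pixel contour (the erosion half removes the bridge again),
while dilate/fill/erode reduces exactly to hole filling when the contour is
already closed. Hole filling uses 4-connected background so a diagonal
pinhole does not drain a lumen. Components below `min_object_area` are
dropped; increasing this threshold can only decrease the object count.

**Boundary calibration** (`boundary_erosion_px=2`): the filled contour
reaches the *outer envelope* of the projected edge band, which straddles
the physical boundary (the band is 1–3 px wide: pixel quantization, the
finite rim width relative to the smoothing scale, and residual
near-focus-plane union). The boundary is pulled back by a fixed 2 px
erosion, calibrated on the synthetic benchmark at the default detector
scale and plane spacing — the same kind of hand calibration any such
pipeline carries for its microscope. With it, mean absolute area error on
the benchmark drops from ~9% to ~1–2%.

**Watershed splitting** (`min_peak_separation=15`, `min_peak_height=5`):
per object, local maxima of the Euclidean distance transform become
markers; the object is partitioned by watershed on the negated distance
transform. Candidate maxima are found at small scale and then thinned
greedily in order of decreasing height until accepted peaks are pairwise
≥ `min_peak_separation` apart — window-based non-maximum suppression at
that radius would silently drop a genuine second organoid whenever the
rising slope toward its taller neighbour enters the window. Candidates
below half the tallest peak are rejected (`rel_height=0.5`): budding lobes
produce shallow secondary maxima at roughly a third of the body's depth,
while a genuinely overlapping neighbour of comparable size peaks at a
comparable height. Children smaller than `min_object_area` are merged back
into their largest sibling, so splitting never changes the total
foreground.

**Object center**: arg max of the distance transform (the pixel furthest
from the object edge); plateau ties break toward smaller row, then smaller
column, so centers are deterministic.

Objects touching the image border are kept but flagged `on_border`;
summaries can exclude them.

## Morphology classification

Each object is extracted as a 120×120 8-bit crop from the
minimum-intensity projection of the autoscaled stack (the same raster the
segmentation saw): non-object pixels are set to white, the object is
isotropically rescaled so its longer side is 116 px and centered, leaving
a ≥2 px white margin. Because everything off the object is white, a
context margin around the bounding box would be invisible; the scale is
therefore anchored to the object's own bounding box.

Shape descriptors per object mask: area, perimeter, circularity
(4πA/P², capped at 1.1 for rasterization), solidity (area / convex-hull
area), eccentricity, radial variance (squared coefficient of variation of
the centroid-to-boundary distance), and a lobe count = number of
convexity defects — 8-connected components of (hull − mask) — whose depth
exceeds `defect_depth_frac=0.1` times the equivalent radius √(A/π).

The default classifier is a deterministic rule cascade:

- **junk** if area < `junk_area_px=700` or solidity < 0.5;
- else **spheroid** if circularity ≥ `spheroid_circularity=0.86` and
  lobe count ≤ 1;
- else **budding**.

The two cut-offs are calibrated to the *measured-area scale of this
segmentation*: rendered debris of ≤250 true px measures up to ~550 px
after defocus-halo inflation while the smallest organoids measure ≥~900 px,
so 700 px splits them; segmentation smoothing (contour bridging plus the
boundary calibration) raises segmented budding circularity to ≤0.85 while
segmented spheroids measure ≥0.88, and the ground-truth populations sit at
≤0.786 vs ≥0.899, so 0.86 separates both domains. Probabilities come from
sharp logistic scores on the decisive margins, chained
(junk gate × spheroid-vs-budding split) so they always sum to 1; the label
is the arg max, with exact ties broken conservatively junk > budding >
spheroid.

Two trainable backends share the interface: `features` (multinomial
logistic regression on the descriptor vector; deterministic given the
seed) and `mlp` (a small scikit-learn neural network on 24×24 downsampled
crop pixels; requires ≥50 examples per class). Training records a seeded
20% stratified hold-out accuracy. The original workflow's image classifier
was a convolutional network trained on manually labeled crops that are not
available; the rule cascade is the default precisely because it is exactly
reproducible and auditable.

## Blinded correction

The interactive correction editor is replaced by a CSV round-trip with the
same information content. `export_review` writes crops named only by
blinded IDs (`B00001.png`, …) in a seed-determined permuted order, plus a
template table; no condition or field identifier appears in anything the
reviewer sees, and the keyfile resolving blinded IDs is written separately.
`apply_corrections` deletes, relabels (flagged `human_labeled`), and
re-splits: any foreground region that a correction touched and that holds
two or more corrected centers is repartitioned by a watershed seeded
exactly at those centers. Untouched objects keep their IDs, labels and
pixels; center corrections never change the foreground pixel set, and an
empty correction table is the identity.

## Quantification and statistics

Per-well summaries exclude junk by default; budding/spheroid percentages
are over non-junk objects and sum to 100 when everything is classified. A
well with zero non-junk objects yields a flagged summary, not an error.
Condition normalization divides every well's metric by the mean of the
control condition's wells (within an experiment), so the control's
normalized mean is exactly 1 and the values are invariant to rescaling.

Mann–Whitney U: exact p by the full count distribution of U (Gaussian
binomial coefficients, computed by the exact polynomial product) whenever
n₁+n₂ ≤ 20 and there are no ties; otherwise mid-ranks with the
tie-corrected normal approximation and 0.5 continuity correction. The
two-sided p is twice the smaller tail, capped at 1 — the convention under
which complete separation gives 2/252 = 0.0079 at n = 5 per group and
2/70 = 0.0286 at n = 4. One-way ANOVA uses scipy's F statistic with
Bonferroni (pairwise t-tests × number of comparisons, capped at 1) or
Tukey HSD (studentized-range distribution) post-hocs; groups with zero
within-variance but different means report F = ∞, p = 0. The one-tailed
Fisher test sums hypergeometric point masses at least as extreme as the
observed top-left count, in the direction of the observed association
(ad ≥ bc → "greater").

## Synthetic scenes

The generator renders what the segmentation needs to be tested against,
with exact ground truth; it does not model real optics. Defaults define
the benchmark conditions: 512×512 px fields at 3 µm/px, 6 spheroids
(ellipses, axis ratio 1–1.3, mean radius 18–36 px), 5 budding organoids
(body plus 2–5 lobes of 0.18–0.26 body radius), 4 debris specks (5–9 px),
5 planes, per-object random focal plane, defocus blur 1.2 px·|Δz|,
background 205 with a ±5 grey illumination gradient, Gaussian noise
σ = 3, dark rim (70) of 3 px around a brighter lumen (160). Objects are
placed with a ≥10 px gap so that scenes intended as disjoint cannot be
bridged by the default closing radius; `overlap_fraction` instead forces
pairs (spheroid-first) to overlap 10–40% of the smaller member's area,
with the center distance solved by bisection on the two-disc lens area.
Everything is drawn from a single `numpy.random.default_rng(seed)` stream,
so a config is bit-reproducible.

The benchmark matches predictions to truth by nearest centers within half
the truth object's equivalent radius; unmatched non-junk predictions count
as false positives. Count recovery and area errors are reported over
non-junk truth objects — debris is deliberately rendered near or below the
detectability scale, and the stack-level thresholds may drop it entirely
in organoid-rich fields, which is the desired behaviour.

**What passing does and does not show.** The renderer exercises the
pipeline's failure modes (defocus, noise, illumination gradients, touching
objects, debris) with homogeneous rim contrast and clean elliptical
geometry. Real wells have heterogeneous contrast, organoids far out of
focus in *every* plane, matrix texture, and overlaps worse than 40%; the
measured 100% recovery and ~1% area error are properties of the benchmark
conditions, not of arbitrary real data. The boundary-calibration constant
and the two classifier cut-offs are calibrated at the default synthetic
scale and should be re-tuned (they are all in the config) for a different
microscope, magnification, or rim morphology.

## Known limitations

- Distance-transform watershed cannot split overlapping pairs whose union
  has no distance dip (near-total overlap of similar-size objects); the
  blinded correction round exists for exactly those cases.
- The edge band's outward offset is corrected by a constant, not estimated
  per object; gross changes in plane spacing or smoothing scale shift it.
- The rule classifier sees silhouettes only; morphologies distinguished by
  internal texture rather than outline need the trainable backends and
  real labels.
- No proprietary microscope formats (ND2/CZI) and no OME metadata beyond
  pixel size; plane order is TIFF page order.
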