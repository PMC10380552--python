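# Methods

`leafseg` implements a few-shot pipeline for phenotyping high-resolution
flatbed leaf scans: two iterative CNN segmenters (boundary tracing for the
leaf body, region growing for the visible venation), a tiled U-Net
baseline, trait extraction in physical units, and broad-sense heritability
from clonal replicates. This note records the models, their assumptions,
the numerical choices, and what the synthetic benchmark does and does not
establish.

## Boundary tracing (leaf body)

A leaf scan contains exactly one leaf on a near-white background. Rather
than classifying every pixel, a CNN looks at a 256×256 tile centered on the
leaf boundary — RGB plus a fourth channel marking the recently traced path
— and regresses the next N = 128 boundary positions as (row, col)
displacements from the tile center. Inference walks the boundary: commit
the first 32 predicted pixels, re-center, repeat; stop when the trace
returns to within 10 px of its own earlier contour (ignoring a guard
window of recent pixels so it cannot terminate against itself), join the
gap with a straight rasterized line, and fill the closed contour. The
filled mask is simply connected by construction — no holes or speckle, the
property that motivates tracing over per-pixel classification.

The regression loss is a weighted MSE, `L = (1/N) Σ ω_i ‖y_i − ŷ_i‖²`,
with `ω_i = 1 + (1 − tanh(α i + β))/2`, `α = 8/N`, `β = −4`, `i = 1..N`
(the index convention matters only in the 4th decimal; we use 1-based).
The weights fall smoothly from ≈2 at the tile center to ≈1 at the tile
edge: predictions near the center are the ones actually committed, but the
model must still see far enough ahead to skip damaged boundary segments.

Initialisation uses Otsu thresholding on grayscale (darker-than-threshold,
largest connected component): it provides the start pixel (topmost rough
boundary point, i.e. the leaf tip) *and* the initial direction — a short
stretch of the rough-mask boundary behind the start pixel seeds the
path-overlay channel. Without that seed the first tile carries no
directional information and the L2-optimal prediction degenerates toward
the midpoint of the two possible directions, stalling the trace; with it,
the first prediction continues unambiguously. Training mirrors this by
randomly truncating the overlay (never below a quarter of its full
length). Trace direction is randomized during training so the model is
direction-agnostic.

Training targets are built per contour pixel: displacements are sampled at
equal arc-length spacing (cumulative 1/√2 steps, linear interpolation,
rounded to integer pixels) from the center to where the contour first
leaves the tile. Augmentation applies 90° rotations and flips (with exact
off-by-one displacement corrections — the center pixel of an even-sized
tile moves under `np.rot90`), uniform center jitter, and per-channel color
gain. One target exists per contour pixel per direction; batches sample
them lazily.

## Region growing (venation)

The vein CNN maps a 128×128 RGB tile to a 3×3×2 softmax: vein/lamina
probabilities for the center pixel and its 8 neighbors. Inference is a
flood fill seeded with 10,000 random leaf-interior pixels: classify each
frontier pixel, accumulate all nine probabilities into a per-pixel running
sum and visit count, and enqueue neighbors whose instantaneous vein
probability exceeds 0.5 (never re-using a center). Because a pixel is
visited from up to nine directions, the final mask thresholds the
*average* probability; the threshold is chosen from a grid (0.05…0.95,
step 0.05) to minimise the number of 8-connected components, since the
vasculature is a single network and fragmentation is biological error. An
empty mask counts as +∞ components so the selector cannot win by
predicting nothing; ties break toward the smaller threshold.

Training draws one positive tile per vein pixel and up to 10× as many
leaf-interior negatives. The default objective is the focal loss
`−α(1−p)^γ log p` (vein) / `−(1−α)p^γ log(1−p)` (lamina) with α = 0.25,
γ = 2; plain BCE is available for comparison and equals the focal loss at
γ = 0, α = 0.5 rescaled by 2 (verified to 1e−12). Probabilities are
clamped at ε = 1e−7 inside logs.

Focal gradients are strongly attenuated near uninformative predictions,
and α = 0.25 under-weights the vein class when veins are not actually rare
(inside the synthetic leaf the imbalance is only ~2:1, versus the extreme
rarity of vein pixels in full scans). Training therefore initialises the
class-logit bias at the empirical positive rate — the standard companion
to the focal loss — clips gradients by global norm, and relies on
best-validation checkpointing under a stepped learning-rate schedule. At
desk scale the selected grower checkpoints favour recall over precision:
they capture the vein network plus a halo, the right trade for the
connectivity-based threshold selection that follows (and the reason the
demo's vein Jaccard is far below its vein recall).

## U-Net baseline

The baseline shares each task's encoder exactly; a decoder mirrors the
widths in reverse with 2×2 transposed-convolution upsampling, concatenated
skip connections from the pre-pooling activations, three-convolution
residual blocks per stage (mirroring the encoder depth, which the source
architecture leaves open), and a final 1×1 convolution with sigmoid.
Whole-image prediction tiles the image at half-tile stride (the last
row/column flush with the image edge), averages per-pixel probabilities
across overlapping tiles, and thresholds: fixed 0.5 for leaf,
connectivity-minimising for veins (same selector as the grower). Training
samples tiles from anywhere in the leaf with per-pixel loss; padded pixels
of edge tiles are masked out.

## Network implementation

No deep-learning framework is used: `leafseg.nn` is a compact NHWC numpy
layer library (3×3 zero-padded convolutions as per-offset matrix products,
batch normalization, LeakyReLU(0.1), 2×2 max pooling, 2×2 transposed
convolution, dense heads, Adam) with hand-written reverse-mode gradients,
each verified against float64 finite differences in the test suite.
Residual connections add the input back after the second and third
convolution of each block. All initialisation and batch sampling flow from
explicit `numpy.random.Generator` seeds, so training runs are
bit-reproducible.

## Trait extraction

From a leaf mask and a vein mask (veins plus petiole):

* **Leaf morphology** — area (cm²), boundary-walk perimeter with √2
  diagonal steps (cm), circularity `4πA/P²`, solidity `A / hull area`, and
  mean R, G, B, hue, saturation, brightness over leaf pixels (petiole
  excluded). The staircase arc-length perimeter is biased high on curved
  outlines (a rasterized disk scores ≈0.91 rather than 1.0) but is
  consistent across leaves; circularity values are comparable within the
  pipeline, not across estimators.
* **Vein architecture** — veins are restricted to the leaf interior,
  skeletonized, and measured: total length as the sum of skeleton
  adjacency arcs (each 8-neighbor edge of length 1 or √2 split between its
  endpoint pixels, so per-class lengths sum exactly to the total); local
  diameter as twice the Euclidean distance transform at each skeleton
  pixel; three diameter classes <0.25 mm, [0.25, 0.80) mm, ≥0.80 mm
  (approximating third/second/first-order veins); vein density as vein
  area over leaf area.
* **Petiole** — the largest connected component of vein pixels outside the
  leaf mask. Length is the longer side of the minimum-area rotated
  bounding rectangle (shapely); width averages 2×EDT over the central 20%
  of the medial axis (arc-length positions 0.4–0.6), matching how calipers
  are placed mid-petiole; volume stacks local cylinder slices π(d/2)²Δs
  along the skeleton.

All conversions use 25.4/DPI mm per pixel (300 DPI default).

## Evaluation and heritability

Jaccard (both-empty = 1), recall (undefined for empty truth), connected
component counts (8-connectivity everywhere, the convention that keeps
1-px diagonal vein runs connected), per-model component-count comparison
with Tukey's HSD at α = 0.05 and compact-letter grouping, and OLS
validation (R², slope, intercept) of digital against manual measurements.

Broad-sense heritability uses one-way random-effects ANOVA on clonal
replicates: σ²_E = MS_within, σ²_G = max(0, (MS_between − MS_within)/k̄)
with the standard effective clone number k̄ = (Σk − Σk²/Σk)/(g−1) for
unbalanced designs, and H² = σ²_G/(σ²_G + σ²_E). Negative genetic-variance
estimates truncate to zero, keeping H² in [0, 1]. An optional MAD
pre-filter (scaled by 1.4826, default cutoff 6) removes gross outliers
before fitting.

## Synthetic data: what it emulates and what it does not

The generator renders one leaf per scan from an analytic polar outline — a
low-order random Fourier perturbation of an ellipse plus a signed
triangular serration term — with a recursively branching vein tree
(polylines with linearly tapering stamped width, one connected network by
construction), a petiole protruding below the lamina, a near-white
background (≥0.93), smooth value-noise color heterogeneity on the lamina,
and optional artifacts: a dark fold crease, a vertical near-white stripe
(failing scanner pixel), dust specks, and a blurred patch. Artifacts
perturb only the rendered image; masks stay clean. Branch levels draw from
per-level generators, so deepening the tree only adds segments (skeleton
length is monotone in branch depth). "True" traits are computed from the
analytic curves, never from the rasters, which is what makes
parameter-recovery tests meaningful.

Defaults correspond to a full 3510×2550 scan at 300 DPI. Tests and the
demo run desk-scale versions (canvases 192×144 to 320×240 px with
proportionally shrunk geometry; 64-px tracer tiles with 3 conv blocks and
N = 32 displacements; 32-px grower/U-Net tiles; hundreds of gradient steps
rather than the full schedule of up to 1000 epochs with batch 256/1024 and
early-stopping patience 20 — the training loop itself is identical). The
tracer's desk canvas is the largest so the tile:leaf ratio stays near the
full-scale geometry. The model-comparison images carry the full artifact
set and a third of training leaves carry artifacts, mirroring a field
campaign's imperfect scans and the deliberate inclusion of artifact
examples during dataset refinement; on artifact-free synthetic images all
models converge to ~1 component and the fragmentation comparison is
uninformative.

Synthetic leaves lack real venation topology (loops, anastomoses), texture
at scanner resolution, specular effects, and genuine partial observability
of higher-order veins. Passing the synthetic benchmark therefore
demonstrates that the algorithms and plumbing are correct and learnable at
small scale — not that the trained desk-scale weights transfer to real
scans.

## Degenerate inputs and tie-breaks

Otsu with empty foreground raises a "no object" error; masks with several
components must be reduced before contour tracing; an all-background
grower halts after the seed pass (the center set is finite, so growing
always terminates); contour orientation is stored counter-clockwise and
mask filling is orientation-invariant; a single-pixel contour fills to a
single pixel; empty vein masks yield zero-valued vein traits; a petiole
thinner than one pixel after skeletonization reports missing width.
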