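# Methods

This note documents the models and procedures implemented in
`mpmtools`, the parameters that matter, the numerical choices made
where the design was open, and what the synthetic-fixture validation
does and does not demonstrate.

## Cell coverage

Pixel intensities inside the well are modelled as a two-component 1D
Gaussian mixture fitted by EM (k-means initialisation, fixed seed,
200 iterations, tolerance 1e-4). The component with the larger mean is
the foreground (cells). The binary cell mask is

    pixel >= mu_fg + lambda * sigma_fg

with the comparison inclusive, so `lambda = 0` places the cutoff
exactly at the foreground mean. `lambda` is a user dial: negative
values admit more pixels, positive values fewer. Coverage is the
masked pixel count inside the well boundary divided by the boundary
interior area. The mixture is fitted to well-interior pixels only, so
out-of-well plastic does not perturb the background component.

**Unimodal wells.** An empty or a fully covered well has no bimodal
intensity structure; a forced two-component fit splits the single mode
and the cutoff lands inside it, which is meaningless. When Ashman's D
of the fit (`sqrt(2)|mu1 - mu2| / sqrt(s1^2 + s2^2)`) is below 4 the
well is instead called entirely empty or entirely covered by comparing
the interior median against the out-of-well median plus ten robust
sigmas. Both paths are relative comparisons, so coverage is invariant
under affine intensity rescaling.

**Choice of lambda for the fixture suite.** The fixture foreground is
a symmetric Gaussian component, so the cutoff at its mean counts
exactly half of it; validation therefore runs at `lambda = -3`, which
counts the entire foreground component while remaining more than ten
background sigmas above the background mean. This follows from the
generative model, not from tuning. Real images typically have
right-skewed foregrounds, for which `lambda = 0` is the natural
default.

**Well boundary.** The well footprint is separated from the dark
plastic by multi-Otsu candidate thresholds (3- and 4-class, plus plain
Otsu); each candidate's binary image is opened and hole-filled, and
the largest resulting component over all candidates is taken as the
footprint. The superellipse `|x/a|^n + |y/b|^n = 1` is then fitted by
bounded least squares on the implicit form to the *outermost* Canny
edge point in each of 180 angular bins — fitting *around* the edges,
which makes the fit indifferent to interior cell edges. The fit is
rejected (RMS implicit residual > 0.05, or fewer than 100 edge points)
in favour of a centred circle of radius `0.95 * min(H, W) / 2`. A
single-pass least-squares fit on all Canny edges, the obvious simpler
estimator, proved non-robust whenever cell edges outnumber rim edges
and is not used.

## Invasion depth

Each Z-plane is scored by a binary classifier for the presence of
in-focus (invaded) cells. The classifier is a residual CNN: stages of
channel-preserving residual blocks separated by 2x max-pooling, global
average pooling, and a dense logit head. The reference design in this
method family is a 50-layer residual network; the desk-scale default
used throughout the tests is stages (8, 16) with one block each on
32 x 32 inputs, because adequacy is judged behaviourally (fixture
accuracy), not by weight count. Training uses Adam on binary
cross-entropy with dihedral augmentation (random flips and 90-degree
rotations), a stratified 20% held-out split, and normalisation
statistics frozen from the training split.

A plane with probability >= 0.5 (inclusive) is invaded. Depth is
`deepest_invaded_index * z_step_um`, index 0 being the top plane where
cancer cells are seeded; a stack with no invaded plane has depth 0.
Non-monotone call vectors are resolved by the literal rule: the
deepest invaded plane governs. Accuracy, sensitivity and specificity
are computed from confusion counts with the invaded class positive;
ratios with empty denominators are reported as undefined, never
silently zero.

## Vessel segmentation

Two routes produce the refined 2D vesselness image the graph extractor
consumes.

**Model route (projections).** A U-Net-style encoder/decoder with
separable-convolution blocks (depthwise 3x3 + pointwise 1x1, twice per
level) predicts per-pixel vessel probability. Reference configuration:
filters (64, 128, 256, 512), learning rate 1e-3, 320 x 320 inputs,
50 epochs of floor(1500/batchsize) training and floor(500/batchsize)
validation steps. The desk-scale configuration trained in the test
suite is filters (8, 16, 32, 64) on 64 x 64 inputs, 5 epochs of
75 steps at batch 4, which reaches validation Dice >= 0.8 on tube
fixtures in about a minute on one CPU. Training uses BCE with a
positive-class weight of 3 and two seeded restarts keeping the best
validation Dice: with thin structures (~8% foreground) an unlucky
initialisation otherwise stalls in the all-background minimum.
Augmentation (random rotation p=0.5, 512-crop p=1, flips p=0.25 each,
brightness/contrast p=0.7, multiplicative noise p=0.4 XOR blur+noise
p=0.4 with a seeded coin when both fire, elastic p=0.85, resample to
the model input size) applies geometric transforms identically to
image and mask and photometric ones to the image only. Full-resolution
prediction tiles the image into overlapping 512-pixel patches
(stride 256), resamples each to the model input, and averages
overlapping predictions; edges are reflection-padded.

Refinement of the probability map: threshold at 0.5, label connected
components, remove components with circularity `4*pi*A/P^2 > 0.8`
(blobs) or whose 1-px skeleton has no junction (a junction is a
skeleton pixel with >= 3 skeleton neighbours, 8-connected), mask the
probability map with the survivors, and multiply by the medial-axis
weight `d_bg / (d_bg + d_medial)` — 1 on the medial axis, 0 at the
border — so vessel centrelines become the bright ridges the extractor
assumes. Perimeter is measured as marching-squares contour length with
a cyclic 5-point smoothing of the contour polygon; without the
smoothing a rasterised disk scores ~0.90 rather than ~1.0, i.e. the
0.8 cutoff would not behave as the continuum formula intends.

**Sato route (Z-stacks).** Per plane: Sato tubeness at scales
sigma = 1, 2, 4 px followed by an unsharp mask (radius 5, amount 1);
then a max-intensity projection to 2D. A vasculature mask is grown
from Canny edge seeds (sigma 2, gradient-quantile hysteresis
0.85/0.95, seeds additionally required to sit above 0.25 of the
maximum vesselness), adding 8-connected neighbours while the intensity
gradient into the region is non-negative (queue-free iterative
implementation with a minimum-filter acceptance test), closed with a
radius-3 disk, and circularity-filtered (> 0.8 removed). The mask is
applied to the projection and the result rescaled to [0, 1]. The Canny
parameters are package defaults chosen by measuring seed precision on
fixtures; the original method publishes none.

## Graph extraction (Morse skeleton)

The vesselness image is treated as a terrain and its ridge graph
extracted by a native discrete-Morse construction (no external
filament-extraction binary):

1. The field is pre-smoothed with a Gaussian (`smooth_sigma`, default
   1 px). This is the counterpart of the peak-merging smoothing the
   ridge-extraction approach requires: without it, pixel noise on the
   vessel ridge spawns hundreds of spurious critical pairs and the
   extracted length overshoots by an order of magnitude.
2. Pixels are swept in decreasing (intensity, index) order — the index
   tie-break gives a strict total order — with a union-find over the
   processed set (8-connectivity). A pixel with no processed neighbour
   is a local maximum; a pixel joining k >= 2 components is a saddle
   and records one merge event per absorbed component with persistence
   `f(dying peak) - f(saddle)`.
3. Each event contributes an arc: steepest-ascent paths from the
   saddle into both merging components, joined at the saddle.
4. Cancellation in increasing persistence order, below the cutoff: a
   peak whose only arc is its death edge is a noise spur and vanishes
   with it; a degree-2 peak is dissolved by splicing its two arcs, so
   ridge geometry survives; peaks supporting >= 3 arcs are kept.
5. The domain is restricted to pixels above `support_floor`
   (default 0). Masked vesselness backgrounds are exact zeros —
   no data — and including them lets merge events join disjoint
   network pieces with arcs wandering across empty background
   (measured: ~60% length overcount on Z-stack fixtures).

The persistence cutoff defaults to `max(2 * sigma_MAD, 0.005 * max)`
with `sigma_MAD = 1.4826 * median|I - median(I)|`, configurable.
Vertices are retained maxima; edges are pixel polylines along ridges.

**Simplification.** Leaf branches shorter than `min_branch_um`
(default 10 um) are pruned, with degree-2 chains merged between passes
and the pruning iterated to a fixed point (chain merging can expose
new short leaves). Optionally all but the largest component (by total
length) is dropped. Each branch polyline is then smoothed by a centred
moving average (window 5, shrunk symmetrically near the ends so
endpoints and collinear runs are fixed): raw arcs are grid-aligned
(horizontal/vertical/45-degree steps) and the staircase overestimates
Euclidean length.

## Branch decomposition by persistent homology

The network is filtered by `f(x) = -d(x, r)` where `r` is the network
centre, operationalised as the vertex of minimum geodesic eccentricity
in the largest component (ties to the smallest vertex id). Because the
barcode of this filtration only decomposes *trees* into branches, a
cyclic network is first reduced to its shortest-path tree from `r`
(Dijkstra with deterministic tie-breaking by smallest predecessor id).
Sublevel sets grow from the leaves toward the root; each leaf births a
bar at minus its distance to the root, at every merge vertex the bars
of all but the deepest-reaching sub-branch die (elder rule, ties to
the smaller leaf id), and the deepest leaf's bar dies at 0. Bar
persistences are branch lengths, so for a tree they sum exactly to the
tree length (verified to 1e-9 relative on 100 random trees). Reported
statistics: branch count (number of bars), total network length (sum
of *graph* edge lengths; for cyclic networks the tree length is
reported alongside), and mean branch length (mean bar persistence).

## Synthetic fixtures

The generators emulate the statistical and geometric structure of the
assay, not its photorealism; all are bit-reproducible under a seed and
their ground truth is exact by construction.

* **Well fixtures**: a circular well (radius 0.9 of the half-frame) on
  dark plastic; the cell region is the top-k set of a smoothed random
  field with k chosen for the requested coverage exactly; intensities
  background N(25, 5), cells N(180, 12), plastic N(8, 3).
* **Invasion fixtures**: 48 x 48 planes of binary cell speckle
  (N(200) on N(20), 25% cover, noise sigma 8), sharp down to the true
  deepest invaded index and defocus-blurred (sigma 3) below it.
* **Vessel fixtures**: random planar trees grown by stochastic
  branching (heading jitter 6 degrees per 4-px step, bifurcation
  angles 25-55 degrees, rejection resampling of self-intersecting or
  out-of-frame trees over successive seeds; branches of different
  lineages must stay 10 px apart). Tubes render with Gaussian
  cross-section (sigma = width/2.5) plus brighter bead cells every
  12 px and emphasised tip/junction cells — microvessels image as
  strings of labelled endothelial cells of non-uniform brightness, and
  those bright cells are precisely what ridge extraction keys on.
  Additive Gaussian noise at 1/SNR.

**Validation conditions.** The 25-fixture end-to-end recovery suite
uses 256-px frames at 2.5 um/px (640 um field), 5-15 branches of
30-150 um at SNR 5, rendered as projections and analysed through the
refinement route; success means branch count within +/-1 and total
length within 10%, required in >= 80% of fixtures (measured: 88-100%
across seeds, mean length error 0.5-2%). Branch lengths are capped at
150 um because a 15-branch tree of 300-um branches cannot fit one
microscope field. The Sato Z-stack route is validated on sparse 1-3
tube stacks at high SNR (20): at SNR 5 its Canny-seeded mask loses
~25% of centreline coverage and breaks tubes apart — a genuine
limitation of edge-seeded region growing on noisy stacks, and the
reason projections are the preferred input for dense noisy networks.

**What passing does not show.** Fixtures have uniform tube width,
additive Gaussian noise, and no out-of-focus haze, autofluorescence
gradients, or touching parallel vessels; classifier and segmenter
results on them bound nothing about real staining variability. The
invasion classifier in particular learns the fixture's sharp/blurred
contrast and must be retrained on annotated planes for real data.

## Known limitations

* Graph extraction is 2D; overlapping vessels at different depths are
  collapsed and only the most prominent branch of a crossing pair is
  retained.
* The per-plane invasion rule ignores between-plane context; a single
  misclassified deep plane sets the depth (the fixture suite bounds
  this at one plane, 90% of stacks).
* Training at full reference scale (320-px inputs, 64-512 filters,
  50 x 375 steps) is supported by the same code paths but is not
  exercised by the test suite, which runs the desk-scale
  configurations stated above.
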