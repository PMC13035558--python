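# Methods

## Model and assumptions

The pipeline assumes that (i) frame descriptors of a procedure video form
clusters in embedding space, each dominated by one semantic scene type, and
(ii) the scene type is piecewise constant in time — scenes persist for many
consecutive frames. Under those assumptions a nearest-centroid classifier
over human-labeled K-means centroids, followed by temporal filtering, is
sufficient to partition a video; no per-frame annotation is ever required,
only one label per cluster.

Distances are **squared** Euclidean throughout: the per-class distance is
d_L = min_n ‖x − c_Lⁿ‖₂², and the ratio rule d₁ < d₂·R is applied to these
squared distances as defined. d₂ is the second-smallest distance **over
classes** (not over centroids), so a frame near two centroids of the same
class is not penalized. Descriptors are used raw — no normalization — since
the centroids live in the same space as the descriptors that produced them.

## Parameters

| name | default | unit | role |
|---|---|---|---|
| k | 100 | clusters | K-means size; trades annotation effort against cluster purity |
| max_iter | 300 | iterations | K-means cap |
| n_init | 10 | restarts | k-means++ restarts against bad local minima |
| R | 0.95 | ratio ∈ (0,1] | rejection strictness; R=1 rejects only exact ties |
| M | 40 | frames | centered mode-filter window |
| P | 80 | frames | minimum segment length; shorter runs → Uncertain |
| W | 400 | frames | surgery moving-average window |
| t | 6.3 | squared distance | surgery threshold — specific to the embedding space and dataset the model was built on |
| stride | 10 | frames | temporal subsampling (all positions downstream refer to the subsampled stream) |
| side | 224 | px | frame resolution after center crop |

## Numerical and procedural choices

* **Windows are centered and truncated** at video boundaries (both the mode
  filter and the moving average); no padding values are invented. Whether
  the moving average should be centered or trailing was an open choice;
  centered keeps detected intervals aligned with their cause.
* **The mode filter is pure**: every output label is the mode of the
  *original* labels in its window, with no in-place cascading. A tied mode
  becomes Uncertain, consistent with Uncertain's role as the label for
  unclear cases, and deterministic.
* **Short-segment suppression is a single pass**: segments shorter than P
  are relabeled Uncertain, adjacent equal labels are merged, and merged
  Uncertain runs are not re-tested (no fixpoint iteration).
* **Surgery smoothing is threshold-centered**: the implementation averages
  (d_Surgery − t) and tests < 0. Mathematically identical to averaging
  d_Surgery and testing < t, but exact at the decision boundary — a constant
  signal equal to t can never drift below threshold through summation
  rounding.
* **Crop offsets**: for an odd margin the extra pixel goes to the trailing
  side (offset = floor(diff/2)). Resize interpolation is fixed bilinear;
  the choice is a documented convention — determinism across runs matters
  more than which interpolator is used.
* **K-means** is scikit-learn's Lloyd implementation with k-means++ init and
  n_init restarts, deterministic given the seed; its empty-cluster
  relocation (reseeding to the points farthest from their centroids) is the
  standard remedy and is used as-is.
* **Ties in exemplar export** (equidistant members) resolve to the lower
  frame index. Ties in the ground-truth mode during segment evaluation
  resolve to the earliest label occurring in the segment; both rules exist
  only to make outputs deterministic.
* **Percent rounding** in reports is nearest integer, ties away from zero.
  Division by zero (a class never predicted, or absent from the ground
  truth) yields an undefined value reported as null, never 0.

## Evaluation conventions

Predicted-Uncertain segments carry no class claim: they are excluded from
confusion matrices and reported as a separate count, so matrix totals plus
the excluded count always equal the number of predicted segments.

On the published binary segment confusion matrix (true Informative: 113
correct / 16 wrong; true Non-informative: 8 / 104), standard definitions give
Informative precision 93% and recall 88% — matching the published pair — but
Non-informative precision 87% and recall 93%, whereas the published pair is
92%/87% (it appears transposed). This package uses the standard definitions
(precision = column-wise, recall = row-wise on a rows-true matrix) and does
not reverse-fit the discrepant pair.

## Synthetic generator

The generator emulates the two assumptions above and nothing more. Planted
centroids are drawn isotropically at scale `separation·max(σ,1)` (so the
geometry does not collapse in the small-noise limit) and rejection-sampled
until all pairwise distances are ≥ `separation·σ` (default 8σ: emissions
essentially never overlap, so downstream errors come from the temporal
filters, not descriptor ambiguity). Scene labels follow a Markov chain with
uniform transitions to the other classes and geometric durations
(mean `mean_run` = 600 frames, roughly matching the scale at which the
temporal filters operate: runs ≫ P). Each segment emits around a single
centroid of its class; the centroids of a class are cycled in seeded random
order across that class's segments so occupancy stays even. Three long
Surgery runs (500–1200 frames, i.e. ≥ W) are planted on top of the chain so
interval metrics have guaranteed targets; chain-generated Surgery runs
shorter than W are legitimately smoothed away and give the Recall@1 <1 seen
on "all intervals".

Default stream size is 20,000 frames at D = 64 — large enough for ~30 scene
segments and stable statistics, small enough that the full pipeline runs in
seconds on one CPU.

For the synthetic space the surgery threshold is the analytic midpoint
`t = σ²(dim + separation²/2)`: a surgery frame's squared distance to its own
centroid is σ²·χ²_dim (mean dim·σ²), a non-surgery frame adds at least
separation²·σ². This is derived from the generator's geometry, not tuned.

**Centroid-recovery tolerance.** The sample mean of m isotropic Gaussian
points in d dimensions deviates from the true center by ≈ σ√(d/m) in norm
(‖mean − c‖² ~ σ²χ²_d/m), so recovery tests require each discovered centroid
to lie within 4σ√(d/m) of a distinct planted centroid. A √m-only bound
without the √d factor would be a per-coordinate bound and is wrong for
d = 64. Recovery is checked against the clusters actually *realized* in the
stream (a rare seed can leave a cluster with zero segments; K-means cannot
recover a cluster with no members), with k set to the realized count.

## What passing synthetic tests does and does not show

Passing shows the machinery is correct: distances, the rejection rule, the
filters, interval extraction and all metrics behave exactly as specified,
end to end, and the pipeline recovers a planted partition whose assumptions
it matches. It does not show that a given real embedding satisfies those
assumptions — real descriptor clusters overlap, noise is anisotropic and
class-dependent, scene transitions are not uniform, and t must be calibrated
per embedding space (the default 6.3 came from one labeled sequence in its
original space). The baseline 96-d featurizer is a plumbing device, not a
substitute for a domain-trained embedding.

## Known limitations

* The class hierarchy and label map are inputs; nothing validates that a
  human's labels are semantically right, only that they are complete.
* The ratio rule has no probabilistic calibration; R is a heuristic
  rejection knob.
* Offline only: the temporal filters are centered, so the partition is not
  computable in a streaming, bounded-delay fashion.
* Video container decoding is out of scope; frames come from image
  directories or manifests.
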