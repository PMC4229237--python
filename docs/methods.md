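# Methods

## Data model

A *proximity matrix* is one subject's square, symmetric, zero-diagonal
table of non-negative dissimilarities over an ordered item set — pixel
distances when the data come from spatial arrangement (SpAM) trials,
rating units when they come from pairwise Likert judgments.  A
*proximity stack* aligns several subjects' matrices over the identical
item order; item order is canonicalized lexicographically (or by an
explicit order) so that matrices, coordinates and classification tables
are reproducible across runs.  SpAM placements are converted to
distances center-to-center; only relative distances matter downstream,
so the screen-pixel origin convention (top-left, y down) is internal.

Long-format input files may list each unordered pair once or in both
orientations; mirrored entries must agree to a relative tolerance of
1e-9 — arrangement distances are deterministic, so any larger asymmetry
indicates a corrupt file and is rejected rather than averaged.

## Scaling model and fitting

The scaling model is the weighted Euclidean (three-way) model: a group
configuration `X` (n items x k dimensions) shared by all subjects, and
per-subject non-negative dimension weights `w_s`, giving subject
distances `d_ij(s) = sqrt(Σ_a w_sa (x_ia − x_ja)²)`.  Dissimilarities
are ratio-level: each subject's data δ_s enters through a disparity
`d̂_s = b_s δ_s` with `b_s ≥ 0` fitted per subject (matrix-conditional),
because each participant's use of the screen sets an arbitrary unit.

The loss is taken in the **squared-distance domain**,
`Σ_s Σ_{i<j} (d̂² − d²)²`, the classic formulation for
alternating-least-squares three-way scaling.  This choice is structural,
not cosmetic: with a free ratio slope, a squared-error loss on *raw*
distances admits quasi-degenerate solutions — near-constant-distance
configurations whose stress-1 is far below what any generic three-way
data set genuinely supports — and an early prototype of this fitter
converged to exactly those.  The squared-domain loss weights large
distances heavily and does not reward collapsing the configuration.

Each alternation performs:

1. **Optimal scaling.**  For ratio data with the standard per-matrix
   normalization `Σ d̂² = n(n−1)/2`, the slope is absorbed by the
   normalization, fixing `d̂_s = δ_s · sqrt(P / Σ δ_s²)` once.  The
   normalization also pins the solution's scale; without it the triple
   (b, X, W) can jointly shrink toward zero while the normalized fit
   stalls.
2. **Configuration update.**  One sweep of exact coordinate-wise
   minimization: the loss is a quartic polynomial in any single
   coordinate `x_ia`, its stationary points solve a cubic, and the real
   root with the lowest loss is taken.
3. **Weight update.**  `d²` is linear in `w_s`, so each subject's
   non-negative weights solve an exact NNLS problem.

Termination follows the three standard criteria, applied to the
normalized squared-domain stress that the updates minimize: improvement
≤ `stress_delta_tol` (default .001), value < `stress_floor` (default
.005), or `max_iter` (default 30) alternations.  Kruskal stress-1 is
monitored every iteration and the best-stress-1 iterate is returned, so
the reported (accepted) stress sequence is non-increasing by
construction.

**Reporting conventions.**  Stress-1 per matrix is
`sqrt(Σ(d̂−d)²/Σd²)` with the disparity slope refitted in the distance
domain (least squares through the origin), which is how stress formula 1
is conventionally evaluated against a final model; the headline value is
the root-mean-square over matrices, and R² is the per-matrix squared
disparity–distance correlation averaged arithmetically — the two
averaging conventions of the classic three-way scaling programs.  The
per-matrix vectors are also exposed, so a pooled stress can be formed if
preferred.

**Initialization and restarts.**  `X` starts from classical (Torgerson)
metric MDS of the subject-averaged squared dissimilarities (each
subject's vector normalized to unit RMS first so arbitrary pixel scales
contribute equally); weights start at 1.  `n_restarts − 1` additional
seeded random starts are available as an escape hatch from local minima;
the best final stress-1 wins.  The default is the single deterministic
start.

**Normalization of the solution.**  Columns of `X` are centered and
scaled to unit mean square, the scale is absorbed into `W`, and columns
are ordered by mean subject weight, so dimension 1 is the primary
dimension and weights are comparable across subjects and
dimensionalities.

**Degenerate inputs.**  An all-zero matrix is rejected (stress
undefined).  A stack in which every pair is equally dissimilar carries
no ordinal information; the fitter returns a seeded random
configuration with uniform weights and a warning rather than failing.

## Weirdness

Weirdness summarizes how unusual a subject's dimension-weight profile
is.  Each row of `W` is reduced to its direction (unit vector); the
group reference is the mean of these directions.  A subject's score is
the angle to the reference divided by the largest angle any
non-negative vector can make with it (attained on the coordinate axis
with the smallest reference component), clipped to [0, 1].  Properties:
zero exactly when the subject's profile is proportional to the group
direction; invariant to rescaling any single subject's row (using the
raw column mean as reference would break this, since rescaling one row
moves the mean); symmetric axis profiles receive equal scores; scores
are undefined for k = 1, where every profile is trivially proportional
to the group's.  This is one reasonable formalization of an "angle from
the group profile" index; other programs' weirdness values may differ
numerically while agreeing on these qualitative contracts.

## Classification products

Pair and centrality tables are computed in the *group* space (unit
weights): the products describe the aggregate configuration, not any
one subject's stretch of it.  Ranks ascend with distance; exact ties
break by canonical item order so classifications are stable.  The
ternary split puts `floor(N/3)` in each class and assigns the 1–2
leftover slots to the first class (close/inner) then the second, so 136
pairs split 46/45/45 and 17 items split 6/6/5.  Agreement curves
correlate a dimensionality's pair-distance vector (or per-item mean
distance) with each other dimensionality's and average; ordinal mode
uses fractional ranks, making the correlation a Spearman coefficient.
Zero-variance vectors are excluded from the average with a warning.

## Monte Carlo null models

The generators emulate structureless data under the two collection
procedures at the reference design: 20 simulations per method, 20
simulated subjects each, 17 items.

* **spam** — per subject, 17 points i.i.d. uniform on a
  1366 x 768 plane (the monitor geometry of the emulated task), with no
  minimum-separation constraint; the matrix is the pairwise Euclidean
  distance table.  These matrices are genuine 2-D embeddings and never
  violate the triangle inequality.
* **pairwise** — per subject, each unordered pair receives an
  independent uniform integer in 1–9, oriented as a dissimilarity
  (larger = less similar) for consistency with distance semantics.  The
  1–9 support follows the standard Likert illustration for pairwise
  similarity collection; it is an assumption, as the scale used in the
  original simulations is not recorded.  Independent ratings violate
  the triangle inequality with probability approaching 1 as the item
  count grows — the internal-consistency damage that pairwise
  collection permits and arrangement on a plane prevents, and the
  mechanism behind its higher stress.

A structured generator (planted `X*`, `W*`, truncated-at-zero Gaussian
noise on the distances) backs parameter-recovery tests: with zero noise
the fitter reproduces the generating distances to within 1e-3 relative
error and stress ≤ 1e-3.

Batches are deterministic: a master seed spawns independent
per-replicate streams, so replicates are reproducible in any execution
order.  Each replicate runs the full pipeline (profile over dims 1–5,
weirdness for dims 2–5, pair/centrality tables, all four agreement
curves); summaries report means and standard errors over replicates.

What these nulls do *not* emulate: real subjects' correlated structure
across participants, category-specific geometry, item-pinning effects
of real screens (images cannot overlap), or rating biases.  Passing the
null-study checks therefore validates the machinery and the
noise-floor behavior of the estimator, not its behavior on human data.

## Problem sizes and runtime

The full validation study (2 methods x 20 replicates x 5
dimensionalities of 20 x 17 stacks, 200 fits) completes in well under a
minute on one CPU; unit tests use smaller stacks (5–10 items, 3–8
subjects) chosen to exercise the same code paths at negligible cost.

## Known limitations

* The fitter shares the model, loss domain, update structure and
  termination rules of the classic three-way ALS programs, but its
  per-iteration steps (exact cubic coordinate solves, exact NNLS) are
  stronger than historical implementations, so on structureless data it
  tends to converge to slightly better-fitting solutions — somewhat
  lower stress on hard (triangle-violating) data and somewhat more
  idiosyncratic subject weights at high dimensionality.  Group-level
  *orderings* (arrangement nulls beat pairwise nulls on stress and R²;
  weirdness higher for arrangement nulls; agreement bowing at middle
  dimensionalities) are robust to this.
* Non-metric (ordinal) scaling and Bayesian dimensionality selection
  are out of scope.
* One-dimensional scaling is multi-modal for any local algorithm; the
  classical-MDS start mitigates but does not eliminate local minima
  (use `n_restarts` for hard cases).
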