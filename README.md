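# spamscale

Individual-differences multidimensional scaling (MDS) for similarity
data collected with the **spatial arrangement method** (SpAM), plus the
Monte Carlo null-model machinery needed to judge whether a fitted
"psychological space" reflects shared structure rather than noise.

## Who this is for

Researchers in perception, categorization, and memory often need
stimulus sets with controlled similarity: exemplars of a category that
are close or far in "psychological space".  A fast way to measure
similarity is SpAM: show all items of a category at once and let each
subject drag them around the screen so that spatial proximity expresses
subjective similarity; the pairwise Euclidean pixel distances between
the final placements form that subject's dissimilarity matrix.  This
package turns such matrices (or classical pairwise Likert ratings) into
group spaces, individual-difference diagnostics, and item/pair
classifications ready to use for stimulus selection.

## The model

Given dissimilarity matrices from `S` subjects over `n` items, the
weighted-Euclidean (three-way / INDSCAL-family) model assumes one group
configuration `X` (n x k) that every subject stretches along its axes
with personal non-negative weights:

    d_ij(s) = sqrt( Σ_a  w_sa (x_ia − x_ja)² )

Dissimilarities are treated as ratio-level (pixel distances have a true
zero), entering through per-subject disparities `d̂_s = b_s δ_s`.  The
fit alternates least-squares updates in the squared-distance domain —
ratio optimal scaling with per-matrix normalization, exact per-coordinate
configuration updates, and exact non-negative least-squares weight
updates — and stops when stress fails to improve by more than .001,
falls below .005, or 30 iterations are reached.  Reported per solution:

* **Kruskal stress-1** `sqrt( Σ(d̂−d)² / Σd² )` (RMS over subjects),
* **R²** — squared correlation of disparities with model distances,
  averaged over subjects (variance accounted for),
* **weirdness** — per subject, the angle between the subject's weight
  profile and the group-average profile direction, normalized by the
  largest angle a non-negative profile can attain; 0 means the subject
  weights dimensions like the group, values near 1 mean a one-dimension
  subject,
* **pair-similarity continuum** — all `n(n−1)/2` pair distances in the
  group space ranked and ternary-split into close / mid / far,
* **prototypicality** — per-item mean distance to the other items,
  ranked and split inner / mid / outer,
* **agreement curves** — mean Pearson correlation between a
  dimensionality's distance (or rank) vector and those of the other
  fitted dimensionalities.

The Monte Carlo module provides two null generators at the reference
design (20 simulations x 20 subjects x 17 items): random uniform
placements on a 1366x768 plane ("spam") and independent uniform 1-9
Likert ratings per pair ("pairwise").  Plane placements always satisfy
the triangle inequality; independent ratings usually violate it, which
scaling must absorb as stress — so the two baselines bracket what
"structureless" data look like under each collection procedure.

## Worked example

`examples/scale_arrangements.py` builds five synthetic subjects who
arrange nine mugs around a shared 3x3 screen layout with placement
noise, converts the placements to pixel distances, and scales them:

```
dim  stress-1   R^2
  1    0.296   0.783
  2    0.072   0.964
  3    0.064   0.971
  4    0.057   0.979
  5    0.052   0.983
```

Stress collapses from one to two dimensions and then plateaus — the
scree elbow correctly recovers that the arrangements live on a 2-D
plane — while R² climbs toward 1.  `examples/classify_space.py` shows
the derived products on a planted 2-D space (most/least similar pairs,
inner/mid/outer items, per-subject weirdness), and
`examples/null_baselines.py` runs a scaled-down null study:

```
spam      stress=0.506  R^2=0.119  weirdness=0.403  pair-agreement=0.521
pairwise  stress=0.530  R^2=0.034  weirdness=0.200  pair-agreement=0.494
```

Random arrangements scale better (lower stress, higher R²) than random
pairwise ratings; a real data set should beat both baselines before its
group space is interpreted.

## Command line

```bash
spamscale scale --input ratings.tsv --format long --dims 1-5 --out run/
spamscale simulate --method both --n-sims 20 --seed 1 --out sim/
spamscale report sim/
```

`scale` writes coordinates, weights (+weirdness), stress/R² summaries,
pair and centrality tables, scree data, agreement curves, and a
manifest; `simulate` writes per-method batch summaries and a
spam-vs-pairwise comparison.  Every flag can come from a YAML config
file (`--config`), with explicit flags taking precedence.

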