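"""Monte Carlo null models and the batch validation experiment.

Low stress alone does not prove that a group-level MDS space reflects a
shared sense of similarity: scaling algorithms can accommodate pure
noise surprisingly well.  The null models here generate structureless
data under the two standard collection procedures so that real results
can be benchmarked against them:

* ``spam`` — each simulated subject places the items uniformly at
  random on a plane proportional to a 1366x768 monitor; the matrix is
  the pairwise Euclidean pixel distances.  Being genuine 2-D distances,
  these matrices always satisfy the triangle inequality.
* ``pairwise`` — each unordered item pair receives an independent
  uniform integer Likert rating (1-9, larger = more dissimilar).
  Independent ratings routinely violate the triangle inequality, which
  is exactly the internal-consistency damage that pairwise collection
  permits and spatial arrangement prevents; it surfaces as higher
  stress.

A structured generator (planted configuration + weights + noise) backs
parameter-recovery tests, and :func:`run_batch` runs the full study:
replicate stacks, scaling at dimensionalities 1-5, weirdness at 2-5,
classification tables and agreement curves, aggregated as means and
standard errors over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from spamscale.classify import agreement_curves, centrality_table, pair_table
from spamscale.proximity import ItemSet, ProximityMatrix, ProximityStack
from spamscale.scaling import ScalingConfig, ScalingProfile, profile, weirdness

__all__ = [
    "NullSpec",
    "StructuredSpec",
    "BatchSummary",
    "gen_spam_subject",
    "gen_pairwise_subject",
    "gen_null_stack",
    "gen_structured_stack",
    "run_batch",
    "compare_batches",
    "triangle_violations",
]

METHODS = ("spam", "pairwise")


@dataclass(frozen=True)
class NullSpec:
    """Study conditions for one null-model batch.

    Defaults reproduce the reference design: 20 simulations of 20
    simulated subjects arranging (or rating) 17 items, the SpAM plane
    proportional to a 1366x768 px monitor, Likert ratings on 1-9.
    """

    method: str = "spam"
    n_items: int = 17
    n_subjects: int = 20
    n_sims: int = 20
    plane_width: float = 1366.0
    plane_height: float = 768.0
    likert_min: int = 1
    likert_max: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if min(self.n_items, self.n_subjects, self.n_sims) < 1:
            raise ValueError("counts must be positive")
        if not self.likert_min < self.likert_max:
            raise ValueError("likert_min must be below likert_max")
        if self.plane_width <= 0 or self.plane_height <= 0:
            raise ValueError("plane dimensions must be positive")

    def item_set(self) -> ItemSet:
        width = len(str(self.n_items))
        return ItemSet(tuple(f"item{str(i + 1).zfill(width)}" for i in range(self.n_items)))


@dataclass(frozen=True)
class StructuredSpec:
    """A planted configuration/weights generator for parameter recovery."""

    X: np.ndarray
    W: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        X = np.asarray(self.X, float)
        W = np.asarray(self.W, float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "W", W)
        if X.ndim != 2 or W.ndim != 2 or W.shape[1] != X.shape[1]:
            raise ValueError("X (items x k) and W (subjects x k) must share k")
        if np.any(W < 0):
            raise ValueError("planted weights must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.W.shape[0]

    def item_set(self) -> ItemSet:
        n = self.X.shape[0]
        width = len(str(n))
        return ItemSet(tuple(f"item{str(i + 1).zfill(width)}" for i in range(n)))


def gen_spam_subject(
    spec: NullSpec, rng: np.random.Generator, subject_id: str = "sim01"
) -> ProximityMatrix:
    """One random-arrangement subject: uniform placements, pixel distances."""
    coords = np.column_stack(
        [
            rng.uniform(0.0, spec.plane_width, size=spec.n_items),
            rng.uniform(0.0, spec.plane_height, size=spec.n_items),
        ]
    )
    return ProximityMatrix(subject_id, spec.item_set(), squareform(pdist(coords)))


def gen_pairwise_subject(
    spec: NullSpec, rng: np.random.Generator, subject_id: str = "sim01"
) -> ProximityMatrix:
    """One random-rating subject: independent uniform Likert per pair."""
    n = spec.n_items
    n_pairs = n * (n - 1) // 2
    ratings = rng.integers(spec.likert_min, spec.likert_max + 1, size=n_pairs).astype(float)
    return ProximityMatrix(subject_id, spec.item_set(), squareform(ratings))


def gen_null_stack(spec: NullSpec, rng: np.random.Generator) -> ProximityStack:
    """One replicate stack of ``n_subjects`` null matrices."""
    gen = gen_spam_subject if spec.method == "spam" else gen_pairwise_subject
    width = len(str(spec.n_subjects))
    mats = tuple(
        gen(spec, rng, subject_id=f"sim{str(s + 1).zfill(width)}")
        for s in range(spec.n_subjects)
    )
    return ProximityStack(spec.item_set(), mats)


def gen_structured_stack(spec: StructuredSpec, rng: np.random.Generator | None = None) -> ProximityStack:
    """Stack of weighted-Euclidean distances from a planted (X*, W*).

    Subject ``s`` sees the distances of the shared configuration
    stretched by its planted weight row, plus Gaussian noise truncated
    at zero (dissimilarities cannot be negative).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    items = spec.item_set()
    diffs2 = (spec.X[:, None, :] - spec.X[None, :, :]) ** 2
    width = len(str(spec.n_subjects))
    mats = []
    for s in range(spec.n_subjects):
        D = np.sqrt(np.tensordot(diffs2, spec.W[s], axes=([2], [0])))
        if spec.noise_sd > 0:
            noise = rng.normal(scale=spec.noise_sd, size=D.shape)
            noise = np.triu(noise, 1)
            D = np.maximum(D + noise + noise.T, 0.0)
            np.fill_diagonal(D, 0.0)
        mats.append(ProximityMatrix(f"sub{str(s + 1).zfill(width)}", items, D))
    return ProximityStack(items, tuple(mats))


def triangle_violations(m: ProximityMatrix) -> int:
    """Count ordered triples (i, j, k) with d(i,k) > d(i,j) + d(j,k).

    Genuine 2-D pixel-distance matrices never violate the triangle
    inequality; independently rated pairs usually do.
    """
    D = m.values
    n = D.shape[0]
    count = 0
    for i, j, k in combinations(range(n), 3):
        a, b, c = D[i, j], D[j, k], D[i, k]
        if c > a + b + 1e-9 or a > b + c + 1e-9 or b > a + c + 1e-9:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Batch experiment
# ---------------------------------------------------------------------------

DIMS = (1, 2, 3, 4, 5)
WEIRD_DIMS = (2, 3, 4, 5)

#: metric -> whether it is indexed by dimensionality
METRICS = (
    "stress",
    "rsq",
    "weirdness",
    "agreement_pairs_raw",
    "agreement_pairs_ordinal",
    "agreement_centrality_raw",
    "agreement_centrality_ordinal",
)


@dataclass
class BatchSummary:
    """Aggregated results of one null-model batch.

    ``per_replicate`` is tidy: one row per (replicate, metric,
    dimensionality) value; ``summary`` aggregates mean and standard
    error of the mean over replicates.  Headline scalars (grand means
    over dimensionalities, and the dims 1->5 stress reduction) are
    exposed as properties.
    """

    spec: NullSpec
    config: ScalingConfig
    per_replicate: pd.DataFrame
    profiles: list[ScalingProfile] = field(default_factory=list, repr=False)

    @property
    def summary(self) -> pd.DataFrame:
        g = self.per_replicate.groupby(["metric", "dimensionality"])["value"]
        out = g.agg(["mean", "sem", "count"]).reset_index()
        out = out.rename(columns={"sem": "se", "count": "n"})
        out.insert(0, "method", self.spec.method)
        return out

    def _replicate_means(self, metric: str) -> np.ndarray:
        df = self.per_replicate
        sub = df[df["metric"] == metric]
        return sub.groupby("replicate")["value"].mean().to_numpy()

    def grand_mean(self, metric: str) -> float:
        """Mean over dimensionalities and replicates."""
        return float(self._replicate_means(metric).mean())

    def grand_se(self, metric: str) -> float:
        """SE of the replicate-level means (replicates are the unit)."""
        vals = self._replicate_means(metric)
        return float(vals.std(ddof=1) / np.sqrt(len(vals)))

    def stress_reduction(self) -> float:
        """Mean stress(k=1) - stress(k=5) over replicates."""
        return float(self._stress_reductions().mean())

    def stress_reduction_se(self) -> float:
        vals = self._stress_reductions()
        return float(vals.std(ddof=1) / np.sqrt(len(vals)))

    def _stress_reductions(self) -> np.ndarray:
        df = self.per_replicate
        sub = df[df["metric"] == "stress"].pivot(
            index="replicate", columns="dimensionality", values="value"
        )
        lo, hi = min(sub.columns), max(sub.columns)
        return (sub[lo] - sub[hi]).to_numpy()

    def write(self, csv_path, json_path=None) -> None:
        """Tidy summary CSV plus an optional JSON manifest of the spec."""
        self.summary.to_csv(csv_path, index=False)
        if json_path is not None:
            import dataclasses
            import json

            manifest = {
                "spec": dataclasses.asdict(self.spec),
                "config": dataclasses.asdict(self.config),
            }
            with open(json_path, "w") as fh:
                json.dump(manifest, fh, indent=2)


def run_batch(
    spec: NullSpec,
    cfg: ScalingConfig | None = None,
    dims: tuple[int, ...] = DIMS,
    keep_profiles: bool = False,
) -> BatchSummary:
    """Run the full Monte Carlo study for one null method.

    For each of ``spec.n_sims`` replicates: generate a stack, scale it
    at every dimensionality, compute weirdness (k >= 2), pair and
    centrality tables, and all four agreement curves.  Per-replicate
    streams are spawned from the master seed, so the batch is
    deterministic regardless of execution order.
    """
    cfg = cfg or ScalingConfig()
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_sims)
    rows = []
    profiles = []
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        stack = gen_null_stack(spec, rng)
        rep_cfg = replace(cfg, seed=int(ss.generate_state(1)[0] % (2**31)))
        prof = profile(stack, dims=dims, cfg=rep_cfg)
        if keep_profiles:
            profiles.append(prof)
        for k in dims:
            sol = prof.solutions[k]
            rows.append((rep, "stress", k, sol.stress1))
            rows.append((rep, "rsq", k, sol.rsq))
            if k >= 2:
                rows.append((rep, "weirdness", k, float(weirdness(sol.W).mean())))
            # classification products are computed for every solution so a
            # batch exercises the full pipeline, not just the fit
            pair_table(sol, stack.items)
            centrality_table(sol, stack.items)
        for basis in ("pairs", "centrality"):
            for mode in ("raw", "ordinal"):
                curve = agreement_curves(prof, mode=mode, basis=basis)
                for k, v in curve.values.items():
                    rows.append((rep, f"agreement_{basis}_{mode}", k, v))
    per_replicate = pd.DataFrame(
        rows, columns=["replicate", "metric", "dimensionality", "value"]
    )
    return BatchSummary(spec=spec, config=cfg, per_replicate=per_replicate, profiles=profiles)


def compare_batches(a: BatchSummary, b: BatchSummary) -> pd.DataFrame:
    """Tabulate per-metric grand means of two batches side by side.

    Returns one row per headline metric with each batch's mean, their
    difference (a - b), and which method scored lower.  Inferential
    tests are deliberately not included.
    """
    dims_a = sorted(a.per_replicate["dimensionality"].unique())
    dims_b = sorted(b.per_replicate["dimensionality"].unique())
    if dims_a != dims_b:
        raise ValueError(f"dimensionality mismatch: {dims_a} vs {dims_b}")
    rows = []
    for metric in METRICS:
        ma, mb = a.grand_mean(metric), b.grand_mean(metric)
        rows.append(
            {
                "metric": metric,
                a.spec.method + "_a": ma,
                b.spec.method + "_b": mb,
                "difference": ma - mb,
                "lower": (a.spec.method + "_a") if ma < mb else (b.spec.method + "_b"),
            }
        )
    ra, rb = a.stress_reduction(), b.stress_reduction()
    rows.append(
        {
            "metric": "stress_reduction_1_to_5",
            a.spec.method + "_a": ra,
            b.spec.method + "_b": rb,
            "difference": ra - rb,
            "lower": (a.spec.method + "_a") if ra < rb else (b.spec.method + "_b"),
        }
    )
    return pd.DataFrame(rows)
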