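"""Metric individual-differences MDS by alternating least squares.

The model is the weighted Euclidean (three-way) distance model: all
subjects share one group configuration ``X`` (n_items x k), and subject
``s`` stretches its axes by personal non-negative weights ``w_s``::

    d_ij(s) = sqrt( sum_a  w_sa * (x_ia - x_ja)^2 )

Dissimilarities are treated as ratio-level data (SpAM distances are
pixel measurements, so a zero means identity and the unit is arbitrary):
each subject's raw dissimilarities delta_s enter the fit through a
disparity  dhat_s = b_s * delta_s  with a per-subject slope b_s >= 0.
Following the classic three-way alternating-least-squares formulation,
the loss is taken in the squared-distance domain,

    L = sum_s sum_{i<j} ( dhat_ij(s)^2 - d_ij(s)^2 )^2,

which makes two of the three updates closed-form and — unlike a loss on
raw distances with a free ratio slope — does not admit quasi-degenerate
near-constant-distance solutions.  Each alternation performs

1. slope update      b_s^2        (least squares through the origin,
                                   squared domain, clamped at 0),
2. configuration     X            (one sweep of exact coordinate-wise
                                   minimisation: each x_ia solves a
                                   cubic stationarity equation),
3. subject weights   W >= 0       (per-subject non-negative least
                                   squares; d^2 is linear in w),

and stops when the normalised squared-domain stress fails to improve by
more than ``stress_delta_tol``, falls below ``stress_floor``, or
``max_iter`` iterations are reached — the standard termination rules of
alternating-least-squares scaling programs.  Kruskal stress-1 is
monitored throughout and the iterate with the best stress-1 is the one
returned, so the accepted (reported) stress-1 sequence is
non-increasing by construction.

Fit quality is reported as pooled Kruskal stress-1 and as R^2 — the
squared product-moment correlation between disparities and model
distances, computed per subject and averaged.  Individual differences
are summarised by "weirdness" scores measuring how far each subject's
dimension-weight profile points away from the group-average profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import pdist, squareform

from spamscale.proximity import ProximityStack

__all__ = [
    "ScalingConfig",
    "ScalingSolution",
    "ScalingProfile",
    "model_distances",
    "stress1",
    "fit",
    "rsq",
    "weirdness",
    "profile",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class ScalingConfig:
    """Tuning knobs for one alternating-least-squares fit.

    The three termination criteria are the classic ones: a stress-1
    improvement below ``stress_delta_tol``, stress-1 below
    ``stress_floor``, or ``max_iter`` alternations.
    """

    dims: int = 2
    stress_delta_tol: float = 0.001
    stress_floor: float = 0.005
    max_iter: int = 30
    n_restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dims < 1:
            raise ValueError("dims must be >= 1")
        if self.stress_delta_tol <= 0 or self.stress_floor <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class ScalingSolution:
    """Result of one fit at one dimensionality.

    ``X`` columns are normalised to unit mean square and ordered by the
    variance they account for (dimension 1 is the primary dimension);
    the scale lives in the subject weights ``W``.  ``stress1`` is the
    headline value: the root-mean-square of the per-matrix stress-1
    values in ``stress_per_subject`` (the convention of the classic
    three-way scaling programs); ``rsq`` is the per-subject squared
    disparity-distance correlation averaged over subjects.
    """

    X: np.ndarray
    W: np.ndarray
    disparity_slope: np.ndarray
    stress1: float
    rsq: float
    stress_per_subject: np.ndarray
    n_iter: int
    stop_reason: str
    stress_path: list[float] = field(default_factory=list)

    @property
    def dims(self) -> int:
        return self.X.shape[1]

    @property
    def n_items(self) -> int:
        return self.X.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.W.shape[0]

    def group_distances(self) -> np.ndarray:
        """Condensed inter-item distances in the unweighted group space."""
        return pdist(self.X)


@dataclass
class ScalingProfile:
    """Solutions across a range of dimensionalities for one stack."""

    solutions: dict[int, ScalingSolution]

    @property
    def dims(self) -> list[int]:
        return sorted(self.solutions)

    @property
    def stress_by_dim(self) -> dict[int, float]:
        return {k: s.stress1 for k, s in sorted(self.solutions.items())}

    @property
    def rsq_by_dim(self) -> dict[int, float]:
        return {k: s.rsq for k, s in sorted(self.solutions.items())}


def model_distances(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Euclidean distances for one subject, as a square matrix.

    ``d_ij = sqrt(sum_a w_a (x_ia - x_ja)^2)`` with ``w >= 0``.
    """
    X = np.asarray(X, float)
    w = np.asarray(w, float)
    if w.shape != (X.shape[1],):
        raise ValueError(f"weight vector of length {w.shape} does not match k={X.shape[1]}")
    if np.any(w < 0):
        raise ValueError("subject weights must be non-negative")
    return squareform(pdist(X * np.sqrt(w)))


def stress1(disparities: np.ndarray, model_dists: np.ndarray) -> float:
    """Kruskal's stress formula 1 on matched (pooled) pair vectors.

    ``sqrt( sum (dhat - d)^2 / sum d^2 )``; undefined when all model
    distances are zero.
    """
    dhat = np.asarray(disparities, float).ravel()
    d = np.asarray(model_dists, float).ravel()
    if dhat.shape != d.shape:
        raise ValueError("disparity and distance vectors differ in length")
    denom = float(np.sum(d**2))
    if denom <= 0:
        raise ValueError("stress-1 is undefined for all-zero model distances")
    return float(np.sqrt(np.sum((dhat - d) ** 2) / denom))


def weirdness(W: np.ndarray) -> np.ndarray:
    """Per-subject deviation of the dimension-weight profile from the group.

    The score is the angle between a subject's weight vector and the
    group-average weight vector, normalised by the largest angle any
    non-negative vector can make with that average (attained on a
    coordinate axis).  Hence scores lie in [0, 1]; a subject whose
    weights are proportional to the group average scores exactly 0, and
    a subject loading a single dimension that the group spreads over
    many approaches 1.  Undefined for one-dimensional solutions, where
    every weight profile is trivially proportional to the average.
    """
    W = np.asarray(W, float)
    if W.ndim != 2 or W.shape[1] < 2:
        raise ValueError("weirdness needs a weight matrix with k >= 2 dimensions")
    if np.any(W < 0):
        raise ValueError("subject weights must be non-negative")
    norms = np.linalg.norm(W, axis=1)
    if np.any(norms <= 0):
        bad = np.nonzero(norms <= 0)[0]
        raise ValueError(f"all-zero weight row(s): {bad.tolist()}")
    # each subject's weight profile is a direction; the group reference is
    # the mean of the unit profiles, which makes every score invariant to
    # rescaling any single subject's row
    unit = W / norms[:, None]
    mean = unit.mean(axis=0)
    mean = mean / np.linalg.norm(mean)
    cos_s = np.clip(unit @ mean, -1.0, 1.0)
    theta = np.arccos(cos_s)
    # Largest possible angle from the mean direction over the non-negative
    # orthant is to the axis with the smallest mean weight.
    cos_max = np.clip(np.min(mean), -1.0, 1.0)
    theta_max = np.arccos(cos_max)
    if theta_max <= 0:
        return np.zeros(W.shape[0])
    return np.clip(theta / theta_max, 0.0, 1.0)


def rsq(solution: ScalingSolution, stack: ProximityStack) -> float:
    """Proportion of variance accounted for by the solution.

    Squared Pearson correlation between each subject's dissimilarities
    and their model distances, averaged across subjects.  Subjects with
    a zero-variance dissimilarity vector cannot be correlated and are
    excluded with a warning.
    """
    delta = stack.condensed()
    dist = _subject_distances(solution.X, solution.W)
    return _rsq_from_vectors(delta, dist)


def _rsq_from_vectors(delta: np.ndarray, dist: np.ndarray) -> float:
    vals = []
    for s in range(delta.shape[0]):
        if np.std(delta[s]) <= 0 or np.std(dist[s]) <= 0:
            warnings.warn(
                f"subject index {s} has a zero-variance vector; excluded from R^2",
                stacklevel=2,
            )
            continue
        r = np.corrcoef(delta[s], dist[s])[0, 1]
        vals.append(r * r)
    if not vals:
        return 0.0
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Alternating least-squares fitter
# ---------------------------------------------------------------------------


def _subject_distances(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """(n_subjects, n_pairs) weighted distances, condensed pair order."""
    diffs = _pair_diffs(X)
    d2 = W @ (diffs**2).T
    return np.sqrt(np.maximum(d2, 0.0))


def _pair_diffs(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return X[iu] - X[ju]


def _coordinate_sweep(
    X: np.ndarray, W: np.ndarray, Dhat2: np.ndarray
) -> np.ndarray:
    """One pass of exact coordinate-wise updates of the configuration.

    For each coordinate ``x_ia`` in turn, the squared-domain loss is a
    quartic polynomial in that coordinate alone; its stationary points
    solve a cubic, and the real root with the lowest loss is taken.
    ``Dhat2`` holds the per-subject squared disparities in square form
    (S, n, n).
    """
    n, k = X.shape
    for i in range(n):
        mask = np.arange(n) != i
        for a in range(k):
            w = W[:, a]                      # (S,)
            sw2 = float(np.sum(w**2))
            if sw2 <= _EPS:
                continue
            diff = X[i] - X[mask]            # (n-1, k)
            # contribution of the other dimensions to each subject's d^2
            other = W @ (diff**2).T - np.outer(w, diff[:, a] ** 2)  # (S, n-1)
            c = Dhat2[:, i, mask] - other    # (S, n-1)
            xj = X[mask, a]
            wc = w @ c                       # (n-1,)
            a3 = sw2 * (n - 1)
            a2 = -3.0 * sw2 * np.sum(xj)
            a1 = 3.0 * sw2 * np.sum(xj**2) - np.sum(wc)
            a0 = -sw2 * np.sum(xj**3) + np.sum(wc * xj)
            roots = np.roots([a3, a2, a1, a0])
            cand = roots[np.abs(roots.imag) < 1e-9].real
            if cand.size == 0:
                continue
            # pick the root with the lowest loss
            y2 = (cand[:, None] - xj[None, :]) ** 2          # (R, n-1)
            resid = c[None, :, :] - w[None, :, None] * y2[:, None, :]
            losses = np.sum(resid**2, axis=(1, 2))
            X[i, a] = cand[np.argmin(losses)]
    return X


def _classical_init(delta: np.ndarray, n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Classical (Torgerson) metric MDS of the subject-averaged matrix.

    Each subject's vector is normalised to unit root-mean-square first so
    arbitrary per-subject pixel scales contribute equally.
    """
    rms = np.sqrt(np.mean(delta**2, axis=1))
    rms = np.where(rms > 0, rms, 1.0)
    mean_sq = np.mean((delta / rms[:, None]) ** 2, axis=0)
    D2 = squareform(mean_sq)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    X = np.zeros((n, k))
    for a in range(k):
        if a < len(evals) and evals[a] > _EPS:
            X[:, a] = evecs[:, a] * np.sqrt(evals[a])
        else:
            X[:, a] = rng.normal(scale=1e-3, size=n)
    return X


def _normalise_solution(X: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-mean-square columns, scale absorbed into W, ordered by importance."""
    X = X - X.mean(axis=0)
    scale = np.sqrt(np.mean(X**2, axis=0))
    scale = np.where(scale > _EPS, scale, 1.0)
    X = X / scale
    W = W * scale[None, :] ** 2
    order = np.argsort(W.mean(axis=0))[::-1]
    return X[:, order], W[:, order]


def _subject_stress(
    delta: np.ndarray, b: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Per-subject Kruskal stress-1 with disparities b_s * delta_s."""
    resid = b[:, None] * delta - d
    den = np.maximum(np.sum(d**2, axis=1), _EPS)
    return np.sqrt(np.sum(resid**2, axis=1) / den)


def _fit_once(
    delta: np.ndarray,
    n: int,
    cfg: ScalingConfig,
    X0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, int, str, list[float]]:
    S, P = delta.shape
    k = cfg.dims
    iu, ju = np.triu_indices(n, k=1)
    X = X0.copy()
    W = np.ones((S, k))
    u = delta**2  # squared data, fixed

    # Ratio-level optimal scaling with the standard per-matrix
    # normalisation Sum dhat^2 = P.  For ratio data the normalisation
    # absorbs the free slope, so the disparities are fixed once:
    # dhat_s = b_s * delta_s with b_s = sqrt(P / Sum delta_s^2).  The
    # normalisation also pins the scale of the solution, preventing the
    # degenerate collapse (b, X, W) -> 0 that an unnormalised ratio
    # slope admits.
    ssum = np.sum(u, axis=1)
    b = np.sqrt(np.where(ssum > 0, P / ssum, 0.0))
    dhat = b[:, None] * delta
    dhat2 = dhat**2
    Dhat2 = np.zeros((S, n, n))
    Dhat2[:, iu, ju] = dhat2
    Dhat2[:, ju, iu] = dhat2

    best = None  # (stress1, X, W, per_subject)
    path: list[float] = []
    stop_reason = "max_iter"
    prev_ss = None
    n_iter = 0
    for it in range(1, cfg.max_iter + 1):
        n_iter = it

        # configuration update: one exact coordinate sweep
        X = _coordinate_sweep(X, W, Dhat2)

        # weight update: d^2 is linear in w, so per-subject NNLS is exact
        sq = (X[iu] - X[ju]) ** 2
        for s in range(S):
            w_s, _ = nnls(sq, dhat2[s])
            if w_s.sum() <= _EPS:
                w_s = np.full(k, _EPS)
            W[s] = w_s

        d2 = W @ sq.T
        d = np.sqrt(np.maximum(d2, 0.0))
        # reported stress-1 evaluates the ratio disparities at the
        # distance-domain least-squares slope (through the origin)
        b_rep = np.maximum(
            np.sum(delta * d, axis=1) / np.maximum(np.sum(u, axis=1), _EPS), 0.0
        )
        per_subject = _subject_stress(delta, b_rep, d)
        s1 = float(np.sqrt(np.mean(per_subject**2)))
        if best is None or s1 < best[0] - 1e-15:
            best = (s1, X.copy(), W.copy(), b_rep.copy(), per_subject.copy())
            path.append(s1)

        # termination criteria operate on the normalised squared-domain
        # stress that the updates actually minimise
        ss_num = np.sum((dhat2 - d2) ** 2, axis=1)
        ss_den = np.maximum(np.sum(dhat2**2, axis=1), _EPS)
        ss = float(np.sqrt(np.mean(ss_num / ss_den)))
        if ss < cfg.stress_floor:
            stop_reason = "floor"
            break
        if prev_ss is not None and prev_ss - ss <= cfg.stress_delta_tol:
            stop_reason = "delta"
            break
        prev_ss = ss
    s1, X, W, b_rep, per_subject = best
    return X, W, b_rep, s1, per_subject, n_iter, stop_reason, path


def fit(stack: ProximityStack, cfg: ScalingConfig) -> ScalingSolution:
    """Fit the weighted-Euclidean model to a stack at one dimensionality.

    Starts from a classical-MDS configuration of the subject-averaged
    matrix (plus ``n_restarts - 1`` seeded random starts) and keeps the
    solution with the lowest pooled stress-1.
    """
    n = stack.items.n_items
    if cfg.dims >= n:
        raise ValueError(f"dims={cfg.dims} must be below n_items={n}")
    delta = stack.condensed()
    if np.any(np.all(delta == 0, axis=1)):
        bad = [stack.subject_ids[s] for s in np.nonzero(np.all(delta == 0, axis=1))[0]]
        raise ValueError(f"all-zero dissimilarity matrix for subject(s) {bad}")

    rng = np.random.default_rng(cfg.seed)
    offdiag = delta[delta > 0]
    if offdiag.size and np.ptp(delta, axis=1).max() == 0:
        # every pair equally dissimilar: nothing to fit
        warnings.warn(
            "all dissimilarities are equal; returning a random configuration",
            stacklevel=2,
        )
        X = rng.normal(size=(n, cfg.dims))
        W = np.ones((stack.n_subjects, cfg.dims))
        X, W = _normalise_solution(X, W)
        d = _subject_distances(X, W)
        b = np.maximum(np.sum(delta * d, axis=1) / np.sum(delta**2, axis=1), 0.0)
        per = _subject_stress(delta, b, d)
        s1 = float(np.sqrt(np.mean(per**2)))
        return ScalingSolution(
            X, W, b, s1, _rsq_from_vectors(delta, d), per, 0, "degenerate"
        )

    best = None
    for r in range(cfg.n_restarts):
        if r == 0:
            X0 = _classical_init(delta, n, cfg.dims, rng)
        else:
            X0 = rng.normal(size=(n, cfg.dims))
        result = _fit_once(delta, n, cfg, X0)
        if best is None or result[3] < best[3]:
            best = result
    X, W, b, s1, per_subject, n_iter, stop_reason, path = best
    X, W = _normalise_solution(X, W)
    d = _subject_distances(X, W)
    sol = ScalingSolution(
        X=X,
        W=W,
        disparity_slope=b,
        stress1=s1,
        rsq=_rsq_from_vectors(delta, d),
        stress_per_subject=per_subject,
        n_iter=n_iter,
        stop_reason=stop_reason,
        stress_path=path,
    )
    return sol


def profile(
    stack: ProximityStack,
    dims: tuple[int, ...] = (1, 2, 3, 4, 5),
    cfg: ScalingConfig | None = None,
) -> ScalingProfile:
    """Fit the stack at each dimensionality and assemble scree data.

    Stress is expected to decrease with added dimensions; a violation is
    logged but not rejected, since alternating fits can land in local
    minima.
    """
    base = cfg or ScalingConfig()
    solutions: dict[int, ScalingSolution] = {}
    for k in dims:
        kcfg = ScalingConfig(
            dims=k,
            stress_delta_tol=base.stress_delta_tol,
            stress_floor=base.stress_floor,
            max_iter=base.max_iter,
            n_restarts=base.n_restarts,
            seed=base.seed,
        )
        solutions[k] = fit(stack, kcfg)
    ks = sorted(solutions)
    for lo, hi in zip(ks, ks[1:]):
        if solutions[hi].stress1 > solutions[lo].stress1 + 1e-9:
            logger.info(
                "stress increased from %.4f (k=%d) to %.4f (k=%d)",
                solutions[lo].stress1, lo, solutions[hi].stress1, hi,
            )
    return ScalingProfile(solutions)
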