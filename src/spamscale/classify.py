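"""Derived similarity products: pair continuum, prototypicality, agreement.

Inter-item distances in an MDS space carry no unit, so "very similar"
cannot be defined by a numeric cutoff.  Instead, pairs are rank-ordered
by distance in the group configuration and split into thirds
(close / mid / far); likewise each item's mean distance to all others
yields a prototypicality rank and an inner / mid / outer class.
Agreement curves quantify how consistent these products are across
solutions of different dimensionality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from spamscale.proximity import ItemSet
from spamscale.scaling import ScalingProfile, ScalingSolution

__all__ = [
    "pair_table",
    "centrality_table",
    "agreement_curves",
    "AgreementCurve",
    "ternary_split",
]

PAIR_CLASSES = ("close", "mid", "far")
CENTRALITY_CLASSES = ("inner", "mid", "outer")


def ternary_split(n: int, labels: tuple[str, str, str]) -> np.ndarray:
    """Class labels for ranks 1..n split into near-equal thirds.

    Base class size is floor(n/3); the 1-2 leftover slots go to the
    first class, then the second, so sizes differ by at most one
    (e.g. 136 -> 46/45/45, 17 -> 6/6/5).
    """
    base = n // 3
    rem = n % 3
    sizes = [base + (1 if c < rem else 0) for c in range(3)]
    return np.repeat(np.array(labels, dtype=object), sizes)


def _rank_ascending(values: np.ndarray) -> np.ndarray:
    """Ordinal ranks 1..n, ties broken by canonical item order (stable)."""
    order = np.lexsort((np.arange(len(values)), values))
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def pair_table(solution: ScalingSolution, items: ItemSet | None = None) -> pd.DataFrame:
    """Distance, rank, and close/mid/far class for every item pair.

    Distances are Euclidean in the k-dimensional group configuration
    (unit weights): the products describe the aggregate space, not any
    one subject's stretched version of it.  Rank 1 is the most similar
    pair.
    """
    dist = solution.group_distances()
    n = solution.n_items
    ids = list(items.item_ids) if items is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("item set does not match the solution's configuration")
    pairs = list(combinations(range(n), 2))
    ranks = _rank_ascending(dist)
    classes = ternary_split(len(pairs), PAIR_CLASSES)
    table = pd.DataFrame(
        {
            "item_a": [ids[i] for i, _ in pairs],
            "item_b": [ids[j] for _, j in pairs],
            "distance": dist,
            "rank": ranks,
        }
    )
    table["class"] = classes[ranks - 1]
    return table


def centrality_table(solution: ScalingSolution, items: ItemSet | None = None) -> pd.DataFrame:
    """Mean distance, rank, and inner/mid/outer class for every item.

    An item's prototypicality is indexed by its mean Euclidean distance
    to all other items in the group space; central (prototypical) items
    get small means and rank near 1.
    """
    D = squareform(solution.group_distances())
    n = solution.n_items
    ids = list(items.item_ids) if items is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("item set does not match the solution's configuration")
    mean_dist = D.sum(axis=1) / (n - 1)
    ranks = _rank_ascending(mean_dist)
    classes = ternary_split(n, CENTRALITY_CLASSES)
    table = pd.DataFrame({"item_id": ids, "mean_distance": mean_dist, "rank": ranks})
    table["class"] = classes[ranks - 1]
    return table


@dataclass
class AgreementCurve:
    """Mean cross-dimensionality Pearson correlation per dimensionality.

    ``values[k]`` is the average correlation of dimensionality ``k``'s
    vector (pair distances or item mean distances; raw or fractionally
    ranked) with the vectors of every other fitted dimensionality.
    """

    values: dict[int, float]
    mode: str
    basis: str

    @property
    def grand_mean(self) -> float:
        return float(np.mean(list(self.values.values())))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dimensionality": sorted(self.values),
                "mean_r": [self.values[k] for k in sorted(self.values)],
                "mode": self.mode,
                "basis": self.basis,
            }
        )


def agreement_curves(
    profile: ScalingProfile, mode: str = "raw", basis: str = "pairs"
) -> AgreementCurve:
    """Cross-dimensionality consistency of a scaling profile.

    ``basis='pairs'`` correlates the inter-item distance vectors of the
    solutions; ``basis='centrality'`` correlates the per-item mean
    distances.  ``mode='raw'`` uses the values themselves, ``'ordinal'``
    their fractional (average) ranks.  Zero-variance vectors produce an
    undefined correlation, which is excluded from the mean with a
    warning.
    """
    if mode not in ("raw", "ordinal"):
        raise ValueError(f"unknown mode {mode!r}")
    if basis not in ("pairs", "centrality"):
        raise ValueError(f"unknown basis {basis!r}")
    ks = profile.dims
    vectors: dict[int, np.ndarray] = {}
    for k in ks:
        sol = profile.solutions[k]
        if basis == "pairs":
            v = sol.group_distances()
        else:
            D = squareform(sol.group_distances())
            v = D.sum(axis=1) / (sol.n_items - 1)
        if mode == "ordinal":
            v = rankdata(v)
        vectors[k] = v
    values: dict[int, float] = {}
    for k in ks:
        rs = []
        for other in ks:
            if other == k:
                continue
            a, b = vectors[k], vectors[other]
            if np.std(a) <= 0 or np.std(b) <= 0:
                warnings.warn(
                    f"zero-variance vector at dimensionality {k} vs {other}; "
                    "correlation excluded",
                    stacklevel=2,
                )
                continue
            rs.append(np.corrcoef(a, b)[0, 1])
        values[k] = float(np.mean(rs)) if rs else np.nan
    return AgreementCurve(values=values, mode=mode, basis=basis)
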