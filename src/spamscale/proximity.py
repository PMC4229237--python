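"""Items, screen arrangements, and proximity matrices.

A spatial-arrangement (SpAM) trial ends with every item of a category
placed somewhere on the screen; the subject's dissimilarity matrix is the
table of pairwise Euclidean pixel distances between placements.  This
module holds the data model for that pipeline stage: item sets,
arrangements, single-subject proximity matrices, and aligned multi-subject
stacks, together with CSV/TSV readers and writers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ItemSet",
    "Arrangement",
    "ProximityMatrix",
    "ProximityStack",
    "distances_from_arrangement",
    "read_matrix",
    "write_matrix",
    "read_stack",
    "write_stack",
    "build_stack",
]

#: Relative tolerance for (a, b) vs (b, a) entries in long-format input.
#: Distances are deterministic, so asymmetry beyond rounding means the
#: file is corrupt.
SYMMETRY_RTOL = 1e-9


@dataclass(frozen=True)
class ItemSet:
    """An ordered set of unique item labels.

    The order is canonical: every matrix in a stack, every coordinate
    table and every classification output uses this order.
    """

    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.item_ids)
        object.__setattr__(self, "item_ids", ids)
        if len(ids) < 3:
            raise ValueError(f"need at least 3 items, got {len(ids)}")
        if any(not i for i in ids):
            raise ValueError("item ids must be non-empty strings")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids: {dupes}")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def n_pairs(self) -> int:
        n = self.n_items
        return n * (n - 1) // 2

    def index(self) -> dict[str, int]:
        return {item: k for k, item in enumerate(self.item_ids)}

    @classmethod
    def from_ids(cls, ids: Iterable[str], *, canonical: bool = True) -> "ItemSet":
        """Build an item set; ``canonical=True`` sorts ids lexicographically."""
        ids = list(ids)
        if canonical:
            ids = sorted(ids)
        return cls(tuple(ids))


@dataclass(frozen=True)
class Arrangement:
    """One subject's final SpAM placement of all items on the screen plane.

    Coordinates follow the screen convention (origin top-left, x rightward,
    y downward); only relative distances matter downstream.
    """

    subject_id: str
    items: ItemSet
    coords: Mapping[str, tuple[float, float]]
    plane_width: float = 1366.0
    plane_height: float = 768.0

    def __post_init__(self) -> None:
        missing = [i for i in self.items.item_ids if i not in self.coords]
        if missing:
            raise ValueError(
                f"arrangement for subject {self.subject_id!r} is missing "
                f"coordinates for items: {missing}"
            )
        for item in self.items.item_ids:
            x, y = self.coords[item]
            if not (0 <= x < self.plane_width and 0 <= y < self.plane_height):
                raise ValueError(
                    f"item {item!r} at ({x}, {y}) lies outside the "
                    f"{self.plane_width}x{self.plane_height} plane"
                )

    def coord_array(self) -> np.ndarray:
        """(n_items, 2) array of placements in canonical item order."""
        return np.array([self.coords[i] for i in self.items.item_ids], float)


@dataclass(frozen=True)
class ProximityMatrix:
    """One subject's square symmetric dissimilarity matrix.

    Values are non-negative dissimilarities — pixel distances for SpAM
    data, rating units for pairwise Likert data.  Zero diagonal.
    """

    subject_id: str
    items: ItemSet
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = self.items.n_items
        if vals.shape != (n, n):
            raise ValueError(
                f"matrix for subject {self.subject_id!r} has shape "
                f"{vals.shape}, expected ({n}, {n})"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in matrix {self.subject_id!r}")
        if not np.allclose(vals, vals.T, rtol=SYMMETRY_RTOL, atol=0.0):
            raise ValueError(f"matrix for subject {self.subject_id!r} is asymmetric")
        if not np.allclose(np.diag(vals), 0.0):
            raise ValueError(f"matrix for subject {self.subject_id!r} has nonzero diagonal")
        if np.any(vals < 0):
            raise ValueError(f"negative dissimilarities in matrix {self.subject_id!r}")

    def condensed(self) -> np.ndarray:
        """Upper-triangle pair vector in scipy's condensed order."""
        return squareform(self.values, checks=False)

    def reordered(self, items: ItemSet) -> "ProximityMatrix":
        """Return the same data with rows/columns in ``items`` order."""
        if set(items.item_ids) != set(self.items.item_ids):
            raise ValueError(
                f"item-set mismatch for subject {self.subject_id!r}: "
                f"{sorted(set(items.item_ids) ^ set(self.items.item_ids))}"
            )
        idx = [self.items.index()[i] for i in items.item_ids]
        return ProximityMatrix(self.subject_id, items, self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class ProximityStack:
    """Aligned proximity matrices from several subjects over one item set.

    This is the three-way input to the individual-differences scaling
    model: items x items x subjects.
    """

    items: ItemSet
    matrices: tuple[ProximityMatrix, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.matrices) < 1:
            raise ValueError("a stack needs at least one matrix")
        for m in self.matrices:
            if m.items.item_ids != self.items.item_ids:
                raise ValueError(
                    f"matrix for subject {m.subject_id!r} is not aligned to "
                    "the stack's item order"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(m.subject_id for m in self.matrices)

    def condensed(self) -> np.ndarray:
        """(n_subjects, n_pairs) array of condensed dissimilarity vectors."""
        return np.array([m.condensed() for m in self.matrices])


def distances_from_arrangement(arr: Arrangement) -> ProximityMatrix:
    """Convert a SpAM placement into a pixel-distance proximity matrix.

    Entry (i, j) is the 2-D Euclidean distance (in pixels) between the
    placements of items i and j, measured center to center.
    """
    coords = arr.coord_array()
    values = squareform(pdist(coords, metric="euclidean"))
    return ProximityMatrix(arr.subject_id, arr.items, values)


def build_stack(matrices: Sequence[ProximityMatrix], items: ItemSet | None = None) -> ProximityStack:
    """Align matrices on a shared canonical item order and stack them.

    Matrices may arrive with rows/columns permuted; they are reordered to
    the canonical order (lexicographic by id unless ``items`` is given).
    A matrix over a different item set is rejected, naming the subject.
    """
    if not matrices:
        raise ValueError("build_stack needs at least one matrix")
    if items is None:
        items = ItemSet.from_ids(matrices[0].items.item_ids, canonical=True)
    return ProximityStack(items, tuple(m.reordered(items) for m in matrices))


# ---------------------------------------------------------------------------
# File I/O
#
# Square dialect: CSV whose first row and first column are item ids.
# Long dialect:   TSV with columns subject_id, item_a, item_b, value; one
#                 stack per file, one row per (subject, unordered pair).
# ---------------------------------------------------------------------------


def write_matrix(m: ProximityMatrix, path: str | Path) -> None:
    """Write one matrix as a square CSV with item-id header row/column."""
    df = pd.DataFrame(m.values, index=m.items.item_ids, columns=m.items.item_ids)
    df.to_csv(path, index_label="item")


def read_matrix(
    path: str | Path,
    dialect: str = "square",
    subject_id: str | None = None,
) -> ProximityMatrix:
    """Read a single proximity matrix.

    ``dialect='square'`` reads an item-id-labelled CSV; ``dialect='long'``
    reads a long TSV and requires it to contain exactly one subject.
    """
    if dialect == "square":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column item ids disagree")
        items = ItemSet(tuple(df.index))
        sid = subject_id if subject_id is not None else Path(path).stem
        return ProximityMatrix(sid, items, df.to_numpy(dtype=float))
    if dialect == "long":
        stack = read_stack(path, dialect="long")
        if stack.n_subjects != 1:
            raise ValueError(
                f"{path}: expected one subject, found {stack.n_subjects}"
            )
        return stack.matrices[0]
    raise ValueError(f"unknown dialect {dialect!r}")


def write_stack(stack: ProximityStack, path: str | Path) -> None:
    """Write a stack as a long TSV (upper-triangle pairs only)."""
    rows = []
    ids = stack.items.item_ids
    for m in stack.matrices:
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                rows.append((m.subject_id, ids[a], ids[b], m.values[a, b]))
    df = pd.DataFrame(rows, columns=["subject_id", "item_a", "item_b", "value"])
    df.to_csv(path, sep="\t", index=False)


def read_stack(path: str | Path, dialect: str = "long") -> ProximityStack:
    """Read a multi-subject stack.

    Long TSVs may list each unordered pair once (either orientation) or
    twice; if both orientations are present their values must agree to
    within rounding, otherwise the file is rejected.  A pair listed twice
    in the same orientation is rejected as a duplicate.
    """
    if dialect != "long":
        raise ValueError(f"unknown stack dialect {dialect!r}")
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"subject_id": str, "item_a": str, "item_b": str},
        float_precision="round_trip",
    )
    required = {"subject_id", "item_a", "item_b", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: long TSV needs columns {sorted(required)}")
    if not np.all(np.isfinite(pd.to_numeric(df["value"], errors="coerce"))):
        raise ValueError(f"{path}: non-numeric value cell")
    items = ItemSet.from_ids(
        set(df["item_a"]) | set(df["item_b"]), canonical=True
    )
    index = items.index()
    n = items.n_items
    matrices = []
    for sid, grp in df.groupby("subject_id", sort=True):
        values = np.full((n, n), np.nan)
        np.fill_diagonal(values, 0.0)
        seen: set[tuple[int, int]] = set()
        for _, row in grp.iterrows():
            a, b = index[row["item_a"]], index[row["item_b"]]
            if a == b:
                if row["value"] != 0:
                    raise ValueError(f"{path}: nonzero self-distance for {row['item_a']!r}")
                continue
            v = float(row["value"])
            if (a, b) in seen:
                raise ValueError(
                    f"{path}: duplicated pair ({row['item_a']!r}, {row['item_b']!r}) "
                    f"for subject {sid!r}"
                )
            if (b, a) in seen and not math.isclose(
                values[a, b], v, rel_tol=SYMMETRY_RTOL, abs_tol=0.0
            ):
                raise ValueError(
                    f"{path}: asymmetric values for pair "
                    f"({row['item_a']!r}, {row['item_b']!r}) of subject {sid!r}: "
                    f"{values[a, b]} vs {v}"
                )
            seen.add((a, b))
            values[a, b] = v
            values[b, a] = v
        if np.isnan(values).any():
            missing = [
                (items.item_ids[a], items.item_ids[b])
                for a in range(n)
                for b in range(a + 1, n)
                if math.isnan(values[a, b])
            ]
            raise ValueError(
                f"{path}: subject {sid!r} is missing pairs: {missing[:5]}"
            )
        matrices.append(ProximityMatrix(str(sid), items, values))
    return ProximityStack(items, tuple(matrices))
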