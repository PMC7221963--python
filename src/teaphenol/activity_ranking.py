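"""Standard scores, RACI, and correlation-distance / average-linkage clustering.

The relative antioxidant capacity index (RACI) of a sample is the mean of its
standard scores (z-scores, sample SD) across assay metrics, after orienting
every metric so that "more antioxidant" is positive: lower-is-better metrics
(ID50 columns) have their z-scores negated, higher-is-better metrics (ORAC
Trolox equivalents) keep their sign. Because z-scoring absorbs location and
scale, RACI is invariant under affine rescaling of any metric column.

Clustering follows the common heatmap convention: Pearson correlation distance
D = 1 − r between profiles, agglomerated by unweighted average linkage (UPGMA)
with a deterministic smallest-index tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityMatrix",
    "RaciResult",
    "Dendrogram",
    "standard_scores",
    "raci",
    "correlation_distance",
    "average_linkage",
    "heatmap_matrix",
]

ORIENTATIONS = ("higher-better", "lower-better")


@dataclass
class ActivityMatrix:
    """Samples × metrics table with a declared orientation per metric."""

    values: pd.DataFrame  # rows = samples, columns = metrics
    orientation: Mapping[str, str]

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if self.values.isna().any().any():
            raise ValueError("activity matrix must have no missing cells")
        missing = [c for c in self.values.columns if c not in self.orientation]
        if missing:
            raise ValueError(f"no orientation declared for metrics: {missing}")
        bad = {m: o for m, o in self.orientation.items() if o not in ORIENTATIONS}
        if bad:
            raise ValueError(f"orientations must be one of {ORIENTATIONS}, got {bad}")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def metric_ids(self) -> list:
        return list(self.values.columns)


@dataclass(frozen=True)
class RaciResult:
    z: pd.DataFrame          # oriented standard scores, samples × metrics
    raci: pd.Series          # per-sample mean of oriented z

    def ranking(self) -> list:
        """Sample ids from most to least antioxidant."""
        return list(self.raci.sort_values(ascending=False).index)


def standard_scores(x: Sequence[float]) -> np.ndarray:
    """(x − mean) / SD with the sample SD (n−1 denominator).

    The result has mean 0 and sample SD 1. A constant vector has no scale and
    raises.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector has undefined standard scores")
    return (arr - arr.mean()) / sd


def raci(m: ActivityMatrix) -> RaciResult:
    """Per-sample mean of oriented standard scores across metrics."""
    z = pd.DataFrame(index=m.values.index, columns=m.values.columns, dtype=float)
    for metric in m.values.columns:
        col = standard_scores(m.values[metric].to_numpy())
        if m.orientation[metric] == "lower-better":
            col = -col
        z[metric] = col
    return RaciResult(z=z, raci=z.mean(axis=1))


def correlation_distance(matrix) -> np.ndarray:
    """Pairwise D(i,j) = 1 − Pearson r between rows; symmetric, zero diagonal."""
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.any(arr.std(axis=1) == 0):
        raise ValueError("constant row has undefined correlation")
    d = 1.0 - np.corrcoef(arr)
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge history.

    ``merges`` has one row per agglomeration: (node_a, node_b, height, size),
    with leaves numbered 0..n−1 and the k-th new cluster numbered n+k.
    """

    merges: tuple[tuple[int, int, float, int], ...]
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h, _ in self.merges])

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order of the tree drawing."""
        if not self.merges:
            return list(range(self.n_leaves))

        children = {self.n_leaves + k: (a, b) for k, (a, b, _, _) in enumerate(self.merges)}

        def leaves(node: int) -> list[int]:
            if node < self.n_leaves:
                return [node]
            a, b = children[node]
            return leaves(a) + leaves(b)

        return leaves(self.n_leaves + len(self.merges) - 1)

    def to_newick(self, labels: Sequence[str] | None = None) -> str:
        """Newick string with branch lengths = merge-height differences."""
        labels = list(labels) if labels is not None else [str(i) for i in range(self.n_leaves)]
        height = {i: 0.0 for i in range(self.n_leaves)}
        text = {i: labels[i] for i in range(self.n_leaves)}
        for k, (a, b, h, _) in enumerate(self.merges):
            node = self.n_leaves + k
            text[node] = (f"({text[a]}:{h - height[a]:.6g},"
                          f"{text[b]}:{h - height[b]:.6g})")
            height[node] = h
        return text[self.n_leaves + len(self.merges) - 1] + ";"


def average_linkage(D: np.ndarray) -> Dendrogram:
    """Agglomerative UPGMA clustering of a distance matrix.

    Inter-cluster distance is the unweighted mean of all cross-pair leaf
    distances, maintained by the Lance–Williams size-weighted update. Ties are
    broken by the smallest involved node index, so the result is deterministic.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two leaves")

    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n

    def get(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    for _ in range(n - 1):
        best = min(((get(a, b), a, b) for a in active for b in active if a < b),
                   key=lambda t: (t[0], t[1], t[2]))
        h, a, b = best
        new_size = size[a] + size[b]
        merges.append((a, b, h, new_size))
        for other in active - {a, b}:
            d_new = (size[a] * get(a, other) + size[b] * get(b, other)) / new_size
            dist[(other, next_id) if other < next_id else (next_id, other)] = d_new
        active -= {a, b}
        active.add(next_id)
        size[next_id] = new_size
        next_id += 1

    return Dendrogram(tuple(merges), n)


def heatmap_matrix(m: ActivityMatrix) -> tuple[pd.DataFrame, list, list]:
    """Row-scaled matrix with both axes ordered by their UPGMA dendrograms.

    Rows are centered and scaled to unit sample SD; rows and columns are then
    clustered on correlation distance and reordered by the dendrogram leaf
    order. Returns (scaled+reordered matrix, row order, column order).
    """
    values = m.values
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    scaled = values.apply(lambda row: standard_scores(row.to_numpy()),
                          axis=1, result_type="broadcast")
    row_tree = average_linkage(correlation_distance(scaled.to_numpy()))
    col_tree = average_linkage(correlation_distance(scaled.to_numpy().T))
    row_order = [values.index[i] for i in row_tree.leaf_order()]
    col_order = [values.columns[i] for i in col_tree.leaf_order()]
    return scaled.loc[row_order, col_order], row_order, col_order
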