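"""Spatial weight matrices: contiguity, inverse distance, k-nearest neighbors.

A SpatialWeights object wraps a dense nonnegative n x n matrix with zero
diagonal plus provenance (construction kind, row-standardization state) and
the ordered unit ids it refers to. Isolated units (no neighbors) are repaired
by linking them to their single nearest neighbor when centroids are
available, with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError

log = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    matrix: np.ndarray
    ids: list
    kind: str
    row_standardized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise GeometryError(
                f"weight matrix shape {self.matrix.shape} != ({n}, {n})")
        if (self.matrix < 0).any():
            raise GeometryError("weights must be nonnegative")
        if np.abs(np.diag(self.matrix)).max(initial=0.0) > 0:
            raise GeometryError("weight matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def s0(self) -> float:
        """Sum of all weights, the S0 normalizer of Moran's I."""
        return float(self.matrix.sum())

    def standardize(self) -> "SpatialWeights":
        """Row-standardized copy (connected rows sum to one)."""
        sums = self.matrix.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            isolated = [self.ids[i] for i in np.flatnonzero(sums.ravel() == 0)]
            raise GeometryError(f"cannot row-standardize isolated units: {isolated}")
        return SpatialWeights(self.matrix / sums, list(self.ids), self.kind,
                              row_standardized=True)

    def subset(self, keep) -> "SpatialWeights":
        """Restrict to a subset of units (re-standardizing if needed)."""
        keep = list(keep)
        idx = [self.ids.index(u) for u in keep]
        sub = self.matrix[np.ix_(idx, idx)]
        out = SpatialWeights(sub, keep, self.kind, row_standardized=False)
        return out.standardize() if self.row_standardized else out

    def permute(self, order) -> "SpatialWeights":
        idx = [self.ids.index(u) for u in order]
        return SpatialWeights(self.matrix[np.ix_(idx, idx)], list(order),
                              self.kind, self.row_standardized)


def _repair_islands(mat: np.ndarray, ids: list, centroids: pd.DataFrame | None):
    isolated = np.flatnonzero(mat.sum(axis=1) == 0)
    if isolated.size == 0:
        return mat
    if centroids is None:
        raise GeometryError(
            f"isolated units {[ids[i] for i in isolated]} and no centroids "
            "available for nearest-neighbor repair")
    xy = centroids.loc[ids, ["x", "y"]].to_numpy(dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    for i in isolated:
        j = int(np.argmin(d[i]))
        mat[i, j] = mat[j, i] = 1.0
        msg = f"isolated unit {ids[i]} linked to nearest neighbor {ids[j]}"
        log.warning(msg)
        warnings.warn(msg, stacklevel=3)
    return mat


def _check_ids(ids) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dup = set(), set()
        for u in ids:
            (dup if u in seen else seen).add(u)
        raise GeometryError(f"duplicate unit ids: {sorted(dup)}")
    return ids


def from_adjacency(
    pairs: pd.DataFrame,
    ids,
    row_standardize: bool = True,
    centroids: pd.DataFrame | None = None,
) -> SpatialWeights:
    """Binary symmetric contiguity weights from an adjacency list.

    ``pairs`` has columns (unit_a, unit_b); ``ids`` fixes the unit order.
    Unknown units in the adjacency list raise; islands are repaired via
    ``centroids`` (index unit, columns x, y) when provided.
    """
    ids = _check_ids(ids)
    pos = {u: i for i, u in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)))
    for a, b in pairs[["unit_a", "unit_b"]].itertuples(index=False):
        if a not in pos or b not in pos:
            raise GeometryError(f"adjacency pair ({a}, {b}) has unknown unit")
        if a == b:
            continue
        mat[pos[a], pos[b]] = mat[pos[b], pos[a]] = 1.0
    mat = _repair_islands(mat, ids, centroids)
    w = SpatialWeights(mat, ids, kind="contiguity")
    return w.standardize() if row_standardize else w


def from_centroids(
    centroids: pd.DataFrame,
    kind: str = "inverse_distance",
    k: int = 4,
    row_standardize: bool = True,
) -> SpatialWeights:
    """Distance-based weights from centroid coordinates.

    ``kind`` is "inverse_distance" (w_ij = 1/d_ij for all pairs) or "knn"
    (binary links to the k nearest neighbors, symmetrized by the union).
    ``centroids`` is indexed by unit with columns x, y.
    """
    ids = _check_ids(centroids.index)
    xy = centroids[["x", "y"]].to_numpy(dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    off = ~np.eye(len(ids), dtype=bool)
    if (d[off] == 0).any():
        i, j = np.argwhere((d == 0) & off)[0]
        raise GeometryError(
            f"zero distance between distinct units {ids[i]} and {ids[j]}")
    if kind == "inverse_distance":
        mat = np.zeros_like(d)
        mat[off] = 1.0 / d[off]
    elif kind == "knn":
        if not 1 <= k < len(ids):
            raise GeometryError(f"k must be in [1, n-1], got {k}")
        mat = np.zeros_like(d)
        dd = d.copy()
        np.fill_diagonal(dd, np.inf)
        nearest = np.argsort(dd, axis=1)[:, :k]
        rows = np.repeat(np.arange(len(ids)), k)
        mat[rows, nearest.ravel()] = 1.0
        mat = np.maximum(mat, mat.T)  # symmetrize: union of neighbor sets
    else:
        raise GeometryError(f"unknown weight kind {kind!r}")
    w = SpatialWeights(mat, ids, kind=kind)
    return w.standardize() if row_standardize else w


def build_weights(
    geometry,
    kind: str = "contiguity",
    row_standardize: bool = True,
    k: int = 4,
    ids=None,
    centroids: pd.DataFrame | None = None,
) -> SpatialWeights:
    """Dispatch: adjacency list -> contiguity, centroids -> distance weights."""
    if kind == "contiguity":
        if ids is None:
            ids = sorted(set(geometry["unit_a"]) | set(geometry["unit_b"]))
        return from_adjacency(geometry, ids, row_standardize, centroids)
    return from_centroids(geometry, kind=kind, k=k, row_standardize=row_standardize)
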