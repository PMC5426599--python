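"""Spatial weights: Queen contiguity with link augmentation, and kNN.

The two dependence schemes used throughout the analyses are (a) first-order
Queen contiguity optionally augmented with explicit ferry links and (b) a
k-nearest-neighbor adjacency on unit centroids. Both can be row-standardized.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import shapely
from shapely.strtree import STRtree

from ._errors import GeometryError, InvalidArgumentError
from .geo_core import SpatialUnitLayer

__all__ = [
    "SpatialWeights",
    "queen_contiguity",
    "augment_links",
    "knn_weights",
    "row_standardize",
    "write_weights",
    "read_weights",
]

logger = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    """Neighbor structure over an ordered list of units.

    ``neighbors[i]`` / ``weights[i]`` are parallel lists (indices into
    ``ids`` and weights w_ij). No self-neighbors are stored. Isolates (empty
    rows) are kept and reported in diagnostics; Moran computations exclude
    them.
    """

    ids: list[str]
    neighbors: list[list[int]]
    weights: list[list[float]]
    row_standardized: bool = False

    def __post_init__(self):
        n = len(self.ids)
        if not (len(self.neighbors) == len(self.weights) == n):
            raise InvalidArgumentError("neighbors/weights length mismatch")
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            if len(nb) != len(w):
                raise InvalidArgumentError(f"row {i}: neighbor/weight mismatch")
            if i in nb:
                raise InvalidArgumentError(f"row {i}: self-neighbor")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def s0(self) -> float:
        """Sum of all weights."""
        return float(sum(sum(w) for w in self.weights))

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=int)

    @property
    def isolates(self) -> list[str]:
        return [self.ids[i] for i in range(self.n) if not self.neighbors[i]]

    def degree(self, unit_id: str) -> int:
        return len(self.neighbors[self.ids.index(unit_id)])

    def to_sparse(self) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            rows.extend([i] * len(nb))
            cols.extend(nb)
            vals.extend(w)
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def n_components(self) -> int:
        """Number of weakly connected components of the neighbor graph."""
        adj = self.to_sparse()
        ncomp, _ = sp.csgraph.connected_components(adj, directed=True, connection="weak")
        return int(ncomp)

    def subset(self, keep: Sequence[int]) -> "SpatialWeights":
        """Restrict to the given unit indices (used to drop isolates)."""
        keep = list(keep)
        remap = {old: new for new, old in enumerate(keep)}
        nbs, wts = [], []
        for old in keep:
            nb, w = [], []
            for j, wij in zip(self.neighbors[old], self.weights[old]):
                if j in remap:
                    nb.append(remap[j])
                    w.append(wij)
            nbs.append(nb)
            wts.append(w)
        return SpatialWeights(
            [self.ids[i] for i in keep], nbs, wts, self.row_standardized
        )

    def copy(self) -> "SpatialWeights":
        return SpatialWeights(
            list(self.ids),
            [list(nb) for nb in self.neighbors],
            [list(w) for w in self.weights],
            self.row_standardized,
        )


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------


def queen_contiguity(layer: SpatialUnitLayer) -> SpatialWeights:
    """Binary Queen weights: neighbors share at least one boundary point."""
    for i, g in enumerate(layer.geometries):
        if g is None or g.is_empty or not g.is_valid:
            raise GeometryError(f"unit {layer.unit_ids[i]}: invalid geometry")
    tree = STRtree(layer.geometries)
    left, right = tree.query(layer.geometries, predicate="intersects")
    neighbors: list[list[int]] = [[] for _ in range(layer.n)]
    for i, j in zip(left.tolist(), right.tolist()):
        if i != j:
            neighbors[i].append(j)
    neighbors = [sorted(set(nb)) for nb in neighbors]
    weights = [[1.0] * len(nb) for nb in neighbors]
    w = SpatialWeights(list(layer.unit_ids), neighbors, weights)
    if w.isolates:
        logger.warning("queen contiguity produced isolates: %s", w.isolates)
    return w


def augment_links(
    w: SpatialWeights, edges: Iterable[tuple[str, str]]
) -> SpatialWeights:
    """Add symmetric unit-weight edges (ferry links); idempotent.

    Must be applied before row standardization.
    """
    if w.row_standardized:
        raise InvalidArgumentError("augment links before row standardization")
    out = w.copy()
    index = {uid: i for i, uid in enumerate(out.ids)}
    for a, b in edges:
        if a not in index or b not in index:
            raise InvalidArgumentError(f"unknown unit id in link ({a}, {b})")
        i, j = index[a], index[b]
        if i == j:
            raise InvalidArgumentError(f"self-link on {a}")
        for u, v in ((i, j), (j, i)):
            if v not in out.neighbors[u]:
                out.neighbors[u].append(v)
                out.weights[u].append(1.0)
    out.neighbors = [list(nb) for nb in out.neighbors]
    return out


def knn_weights(layer: SpatialUnitLayer, k: int) -> SpatialWeights:
    """Binary k-nearest-neighbor weights on unit centroids (directed).

    Distance ties are broken toward the smallest ``unit_id`` so the result is
    deterministic and independent of unit order.
    """
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if k >= layer.n:
        raise InvalidArgumentError(f"k={k} must be < number of units ({layer.n})")
    cents = layer.centroids()
    d = np.sqrt(((cents[:, None, :] - cents[None, :, :]) ** 2).sum(-1))
    id_rank = np.argsort(np.argsort(np.asarray(layer.unit_ids, dtype=object)))
    neighbors = []
    for i in range(layer.n):
        di = d[i].copy()
        di[i] = np.inf
        order = np.lexsort((id_rank, di))  # distance first, then unit_id
        neighbors.append(sorted(order[:k].tolist()))
    weights = [[1.0] * k for _ in range(layer.n)]
    return SpatialWeights(list(layer.unit_ids), neighbors, weights)


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Scale each non-isolate row to sum to one; idempotent.

    Isolate rows stay all-zero and are reported via ``isolates``.
    """
    out = w.copy()
    for i in range(out.n):
        s = sum(out.weights[i])
        if s > 0:
            out.weights[i] = [wij / s for wij in out.weights[i]]
    out.row_standardized = True
    if out.isolates:
        logger.warning("row standardization kept isolates: %s", out.isolates)
    return out


# ---------------------------------------------------------------------------
# serialization: sparse edge-list CSV + JSON header
# ---------------------------------------------------------------------------


def write_weights(w: SpatialWeights, csv_path, header_path=None) -> None:
    header_path = header_path or str(csv_path) + ".json"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["i", "j", "w"])
        for i in range(w.n):
            for j, wij in zip(w.neighbors[i], w.weights[i]):
                writer.writerow([w.ids[i], w.ids[j], repr(wij)])
    with open(header_path, "w") as fh:
        json.dump(
            {"ids": w.ids, "row_standardized": w.row_standardized}, fh, indent=1
        )
        fh.write("\n")


def read_weights(csv_path, header_path=None) -> SpatialWeights:
    header_path = header_path or str(csv_path) + ".json"
    with open(header_path) as fh:
        header = json.load(fh)
    ids = list(header["ids"])
    index = {uid: i for i, uid in enumerate(ids)}
    neighbors: list[list[int]] = [[] for _ in ids]
    weights: list[list[float]] = [[] for _ in ids]
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            i, j = index[row["i"]], index[row["j"]]
            neighbors[i].append(j)
            weights[i].append(float(row["w"]))
    return SpatialWeights(ids, neighbors, weights, bool(header["row_standardized"]))
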