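"""Core geographic data structures and plain-format I/O.

Holds the planar point pattern and polygon-layer containers used by every
analysis stage, GeoJSON/CSV readers and writers, point-in-polygon counting
and the centroid-based parent assignment used to copy values between
aggregation levels.

All coordinates are planar meters; no CRS handling is performed.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon, Point, box, mapping, shape
from shapely.strtree import STRtree

from ._errors import (
    FormatError,
    GeometryError,
    InvalidArgumentError,
    UnassignedChildError,
)

__all__ = [
    "StudyWindow",
    "PlanarPointPattern",
    "SpatialUnitLayer",
    "read_layer",
    "write_layer",
    "read_cases",
    "write_cases",
    "read_links",
    "write_links",
    "count_points_in_units",
    "assign_parent_by_centroid",
    "aggregate_children",
]

#: decimal places kept when writing geometry coordinates (1e-6 m precision)
COORD_PRECISION = 6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyWindow:
    """Planar observation window (simple polygon or multi-part polygon)."""

    polygon: Polygon | MultiPolygon

    def __post_init__(self):
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise GeometryError("study window must have positive area")
        if not self.polygon.is_valid:
            raise GeometryError("study window polygon is not simple/valid")

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds

    @property
    def diameter(self) -> float:
        """Diagonal of the bounding box — an upper bound used to cap r grids."""
        x0, y0, x1, y1 = self.polygon.bounds
        return math.hypot(x1 - x0, y1 - y0)

    def contains_xy(self, x, y) -> np.ndarray:
        """Vectorized covers test (boundary counts as inside)."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.covers(self.polygon, pts)

    @classmethod
    def square(cls, side: float, origin: tuple[float, float] = (0.0, 0.0)) -> "StudyWindow":
        x0, y0 = origin
        return cls(box(x0, y0, x0 + side, y0 + side))


@dataclass
class PlanarPointPattern:
    """Sex-marked case locations inside a study window.

    ``points`` is an (n, 2) float array of planar-meter coordinates;
    ``marks``, when present, is a length-n array of ``"M"``/``"F"`` labels.
    """

    points: np.ndarray
    window: StudyWindow
    marks: Optional[np.ndarray] = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.marks is not None:
            self.marks = np.asarray(self.marks, dtype=object)
            if len(self.marks) != len(self.points):
                raise InvalidArgumentError(
                    "marks must have the same length as points"
                )
        if len(self.points) and not bool(
            np.all(self.window.contains_xy(self.points[:, 0], self.points[:, 1]))
        ):
            raise InvalidArgumentError("all points must lie inside the window")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n(self) -> int:
        return len(self.points)

    def subset(self, mark: str) -> np.ndarray:
        """Coordinates of the points carrying ``mark``."""
        if self.marks is None:
            raise InvalidArgumentError("pattern has no marks")
        return self.points[self.marks == mark]

    def mark_counts(self) -> dict[str, int]:
        if self.marks is None:
            return {}
        vals, counts = np.unique(self.marks.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


class SpatialUnitLayer:
    """Polygon units at one aggregation level.

    Stores parallel arrays of ids, geometries, populations, case counts,
    period prevalence (NaN when unset) and optional parent ids. The layer is
    the common currency between the synthetic generator, the prevalence,
    weights, autocorrelation and zonation stages.
    """

    LEVELS = ("district", "zone", "random_zone")

    def __init__(
        self,
        unit_ids: Sequence[str],
        geometries: Sequence[Polygon | MultiPolygon],
        population: Optional[Sequence[int]] = None,
        cases: Optional[Sequence[int]] = None,
        pp: Optional[Sequence[float]] = None,
        parent_ids: Optional[Sequence[Optional[str]]] = None,
        level: str = "district",
    ):
        n = len(unit_ids)
        self.unit_ids = [str(u) for u in unit_ids]
        if len(set(self.unit_ids)) != n:
            raise FormatError("unit_ids must be unique")
        if len(geometries) != n:
            raise InvalidArgumentError("geometries length mismatch")
        self.geometries = list(geometries)
        self.population = np.zeros(n, dtype=np.int64) if population is None else np.asarray(population, dtype=np.int64)
        self.cases = np.zeros(n, dtype=np.int64) if cases is None else np.asarray(cases, dtype=np.int64)
        self.pp = np.full(n, np.nan) if pp is None else np.asarray(pp, dtype=float)
        self.parent_ids = [None] * n if parent_ids is None else list(parent_ids)
        if level not in self.LEVELS:
            raise InvalidArgumentError(f"unknown level {level!r}")
        self.level = level
        for arr, name in ((self.population, "population"), (self.cases, "cases")):
            if len(arr) != n:
                raise InvalidArgumentError(f"{name} length mismatch")
            if np.any(arr < 0):
                raise InvalidArgumentError(f"{name} must be non-negative")
        if len(self.pp) != n or len(self.parent_ids) != n:
            raise InvalidArgumentError("pp/parent_ids length mismatch")
        with np.errstate(invalid="ignore"):
            if np.any(self.pp[~np.isnan(self.pp)] < 0):
                raise InvalidArgumentError("pp must be non-negative when set")

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.unit_ids)

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    def index_of(self, unit_id: str) -> int:
        try:
            return self.unit_ids.index(unit_id)
        except ValueError:
            raise InvalidArgumentError(f"unknown unit_id {unit_id!r}") from None

    def copy(self) -> "SpatialUnitLayer":
        return SpatialUnitLayer(
            list(self.unit_ids),
            list(self.geometries),
            self.population.copy(),
            self.cases.copy(),
            self.pp.copy(),
            list(self.parent_ids),
            self.level,
        )

    # -- derived geometry --------------------------------------------------

    def centroids(self) -> np.ndarray:
        """(n, 2) array of polygon area centroids."""
        cents = shapely.centroid(np.asarray(self.geometries, dtype=object))
        return shapely.get_coordinates(cents)

    def areas(self) -> np.ndarray:
        return shapely.area(np.asarray(self.geometries, dtype=object))

    def union(self) -> Polygon | MultiPolygon:
        return shapely.unary_union(self.geometries)

    @property
    def total_population(self) -> int:
        return int(self.population.sum())

    @property
    def total_cases(self) -> int:
        return int(self.cases.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": self.unit_ids,
                "level": self.level,
                "parent_id": self.parent_ids,
                "population": self.population,
                "cases": self.cases,
                "pp": self.pp,
            }
        )


# ---------------------------------------------------------------------------
# GeoJSON / CSV I/O
# ---------------------------------------------------------------------------


def _round_coords(obj, ndigits: int = COORD_PRECISION):
    if isinstance(obj, (list, tuple)):
        return [_round_coords(o, ndigits) for o in obj]
    return round(float(obj), ndigits)


def write_layer(layer: SpatialUnitLayer, path) -> None:
    """Write a layer as a GeoJSON FeatureCollection.

    Coordinates are rounded to 1e-6 m so that write-read-write round trips
    are byte identical.
    """
    features = []
    for i in range(layer.n):
        geom = mapping(layer.geometries[i])
        geom = {"type": geom["type"], "coordinates": _round_coords(geom["coordinates"])}
        props = {
            "unit_id": layer.unit_ids[i],
            "parent_id": layer.parent_ids[i],
            "population": int(layer.population[i]),
            "cases": int(layer.cases[i]),
        }
        if not math.isnan(layer.pp[i]):
            props["pp"] = layer.pp[i]
        features.append({"type": "Feature", "geometry": geom, "properties": props})
    doc = {"type": "FeatureCollection", "level": layer.level, "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def read_layer(path, level: Optional[str] = None) -> SpatialUnitLayer:
    """Read a GeoJSON FeatureCollection written by :func:`write_layer`.

    Raises :class:`FormatError` naming the offending feature index when a
    required property (``unit_id``, ``population``) is missing, and on
    duplicate ids.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    ids, geoms, pops, cases, pps, parents = [], [], [], [], [], []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        if "unit_id" not in props or props["unit_id"] is None:
            raise FormatError(f"feature {i}: missing required property 'unit_id'")
        if "population" not in props or props["population"] is None:
            raise FormatError(f"feature {i}: missing required property 'population'")
        ids.append(str(props["unit_id"]))
        geoms.append(shape(feat["geometry"]))
        pops.append(int(props["population"]))
        cases.append(int(props.get("cases", 0) or 0))
        pp = props.get("pp")
        pps.append(float(pp) if pp is not None else np.nan)
        parents.append(props.get("parent_id"))
    if len(set(ids)) != len(ids):
        dupes = sorted({u for u in ids if ids.count(u) > 1})
        raise FormatError(f"duplicate unit_id values: {dupes}")
    lvl = level or doc.get("level") or "district"
    return SpatialUnitLayer(ids, geoms, pops, cases, pps, parents, level=lvl)


def write_cases(pattern: PlanarPointPattern, path) -> None:
    """Write a case point pattern as ``case_id,x,y,sex`` CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "x", "y", "sex"])
        for i, (x, y) in enumerate(pattern.points):
            sex = "" if pattern.marks is None else str(pattern.marks[i])
            w.writerow([f"C{i:05d}", round(float(x), COORD_PRECISION), round(float(y), COORD_PRECISION), sex])


def read_cases(path, window: Optional[StudyWindow] = None) -> PlanarPointPattern:
    """Read a ``case_id,x,y,sex`` CSV; window defaults to the bounding box."""
    df = pd.read_csv(path, dtype={"sex": str})
    for col in ("x", "y"):
        if col not in df.columns:
            raise FormatError(f"cases file missing column {col!r}")
    pts = df[["x", "y"]].to_numpy(dtype=float)
    marks = None
    if "sex" in df.columns and df["sex"].notna().any():
        marks = df["sex"].fillna("").to_numpy(dtype=object)
        bad = set(np.unique(marks.astype(str))) - {"M", "F", ""}
        if bad:
            raise FormatError(f"unknown sex labels: {sorted(bad)}")
    if window is None:
        x0, y0 = pts.min(axis=0) if len(pts) else (0.0, 0.0)
        x1, y1 = pts.max(axis=0) if len(pts) else (1.0, 1.0)
        pad = max(x1 - x0, y1 - y0, 1.0) * 0.01
        window = StudyWindow(box(x0 - pad, y0 - pad, x1 + pad, y1 + pad))
    return PlanarPointPattern(pts, window, marks)


def read_links(path) -> list[tuple[str, str]]:
    """Read a ferry edge list CSV (``unit_id_a,unit_id_b,kind``)."""
    edges = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            kind = (row.get("kind") or "ferry").strip()
            if kind != "ferry":
                raise FormatError(f"unknown link kind {kind!r}")
            edges.append((row["unit_id_a"].strip(), row["unit_id_b"].strip()))
    return edges


def write_links(edges: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["unit_id_a", "unit_id_b", "kind"])
        for a, b in edges:
            w.writerow([a, b, "ferry"])


# ---------------------------------------------------------------------------
# spatial joins
# ---------------------------------------------------------------------------


def count_points_in_units(
    pattern: PlanarPointPattern, layer: SpatialUnitLayer
) -> SpatialUnitLayer:
    """Count pattern points per unit (the spatial-join step).

    Each point is assigned to exactly one unit. A point lying exactly on a
    shared boundary is assigned to the unit with the lexicographically
    smallest ``unit_id`` — a deterministic, order-independent tie-break.
    """
    if layer.n == 0:
        raise InvalidArgumentError("layer has no units")
    out = layer.copy()
    out.cases = np.zeros(layer.n, dtype=np.int64)
    if pattern.n == 0:
        return out
    tree = STRtree(layer.geometries)
    pts = shapely.points(pattern.points[:, 0], pattern.points[:, 1])
    pt_idx, poly_idx = tree.query(pts, predicate="covered_by")
    # resolve multi-assignment (boundary points) toward the smallest unit_id
    order = np.lexsort((np.array([layer.unit_ids[j] for j in poly_idx]), pt_idx))
    seen: set[int] = set()
    for k in order:
        i = int(pt_idx[k])
        if i in seen:
            continue
        seen.add(i)
        out.cases[int(poly_idx[k])] += 1
    return out


def aggregate_children(
    child: SpatialUnitLayer, parent: SpatialUnitLayer
) -> SpatialUnitLayer:
    """Set parent population and case counts to the sums over member children.

    Children are matched by their ``parent_id``; a child with an unknown or
    missing parent raises :class:`InvalidArgumentError`.
    """
    out = parent.copy()
    out.population = np.zeros(parent.n, dtype=np.int64)
    out.cases = np.zeros(parent.n, dtype=np.int64)
    index = {uid: i for i, uid in enumerate(parent.unit_ids)}
    for i in range(child.n):
        pid = child.parent_ids[i]
        if pid is None or pid not in index:
            raise InvalidArgumentError(
                f"child {child.unit_ids[i]} has no valid parent_id ({pid!r})"
            )
        j = index[pid]
        out.population[j] += child.population[i]
        out.cases[j] += child.cases[i]
    return out


def assign_parent_by_centroid(
    child: SpatialUnitLayer,
    parent: SpatialUnitLayer,
    field: str = "pp",
    fallback_nearest: bool = False,
) -> SpatialUnitLayer:
    """Assign each child unit the parent containing its area centroid.

    Copies the parent's value of ``field`` (``pp``, ``population`` or
    ``cases``) onto the child and sets ``parent_id``. With
    ``fallback_nearest`` enabled, a child whose centroid falls outside every
    parent is attached to the parent with the nearest boundary; otherwise an
    :class:`UnassignedChildError` lists the orphaned ids.
    """
    if field not in ("pp", "population", "cases"):
        raise InvalidArgumentError(f"cannot propagate field {field!r}")
    out = child.copy()
    cents = child.centroids()
    cent_pts = shapely.points(cents[:, 0], cents[:, 1])
    tree = STRtree(parent.geometries)
    c_idx, p_idx = tree.query(cent_pts, predicate="covered_by")
    assigned = np.full(child.n, -1, dtype=int)
    # deterministic tie-break toward the smallest parent unit_id
    order = np.lexsort((np.array([parent.unit_ids[j] for j in p_idx]), c_idx))
    for k in order:
        i = int(c_idx[k])
        if assigned[i] < 0:
            assigned[i] = int(p_idx[k])
    missing = np.where(assigned < 0)[0]
    if len(missing):
        if not fallback_nearest:
            raise UnassignedChildError([child.unit_ids[i] for i in missing])
        for i in missing:
            d = shapely.distance(np.asarray(parent.geometries, dtype=object), cent_pts[i])
            assigned[i] = int(np.argmin(d))
    values = getattr(parent, field)
    target = getattr(out, field)
    for i in range(child.n):
        j = assigned[i]
        out.parent_ids[i] = parent.unit_ids[j]
        target[i] = values[j]
    return out
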