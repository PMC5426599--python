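"""Synthetic geographies, populations and sex-marked case patterns.

Emulates the statistical structure the downstream analyses assume — a few
hundred districts nested in ~10 contiguous zones, a multi-million total
population spread unevenly across districts, and a few hundred sex-marked
case locations — without any real boundary or patient data. Coordinates are
planar meters throughout.

Districts are a Voronoi tessellation of uniform random points in the study
window; zones group districts by k-means on centroids with a contiguity
repair pass; populations follow normalized log-normal weights rounded by
largest remainder so the total is exact; cases are drawn either
proportionally to district population or from a Thomas-style cluster
process. An optional island mode splits the window into two components
joined by explicit ferry links, to exercise the link-augmentation path of
the weights module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely
from shapely.geometry import MultiPoint, MultiPolygon, box
from sklearn.cluster import KMeans

from ._errors import InvalidArgumentError
from .geo_core import PlanarPointPattern, SpatialUnitLayer, StudyWindow

__all__ = [
    "SyntheticConfig",
    "generate_districts",
    "assign_zones",
    "allocate_population",
    "simulate_cases",
    "island_window",
    "ferry_links_for",
]

#: default study window: 200 km square, loosely the scale of a regional catchment
DEFAULT_SIDE = 200_000.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a full synthetic-region draw."""

    n_districts: int = 312
    n_zones: int = 10
    total_population: int = 3_163_546
    population_dispersion: float = 1.0
    n_cases: int = 511
    male_fraction: float = 0.467
    clustering: str = "proportional"  # or "clustered"
    parent_intensity: float = 10.0
    cluster_sd: float = 5_000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_districts < 1:
            raise InvalidArgumentError("n_districts must be >= 1")
        if not (1 <= self.n_zones <= self.n_districts):
            raise InvalidArgumentError("need 1 <= n_zones <= n_districts")
        if self.total_population < 0 or self.n_cases < 0:
            raise InvalidArgumentError("counts must be non-negative")
        if self.population_dispersion < 0:
            raise InvalidArgumentError("population_dispersion must be >= 0")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise InvalidArgumentError("male_fraction must be in [0, 1]")
        if self.clustering not in ("proportional", "clustered"):
            raise InvalidArgumentError(f"unknown clustering {self.clustering!r}")


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------


def _uniform_in_window(window: StudyWindow, n: int, rng: np.random.Generator) -> np.ndarray:
    x0, y0, x1, y1 = window.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = max(32, int(1.6 * (n - len(pts)) * (x1 - x0) * (y1 - y0) / window.area))
        cand = np.column_stack([rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)])
        pts = np.vstack([pts, cand[window.contains_xy(cand[:, 0], cand[:, 1])]])
    return pts[:n]


def generate_districts(
    window: StudyWindow, n_districts: int, seed: int
) -> SpatialUnitLayer:
    """Voronoi tessellation of uniform random generator points, clipped.

    The returned polygons partition the window exactly (their areas sum to
    the window area) and carry ids ``D000 ... D{n-1}``. A multi-part window
    (island mode) is tessellated one component at a time, with district
    counts proportional to component area, so no district straddles the sea
    strip and the contiguity graph stays disconnected until ferry links are
    added.
    """
    if n_districts < 1:
        raise InvalidArgumentError("n_districts must be >= 1")
    rng = np.random.default_rng([seed, 0x10])
    parts = (
        list(window.polygon.geoms)
        if isinstance(window.polygon, MultiPolygon)
        else [window.polygon]
    )
    if len(parts) > 1:
        shares = np.array([p.area for p in parts]) / window.area * n_districts
        counts = np.floor(shares).astype(int)
        rem = n_districts - counts.sum()
        order = np.argsort(-(shares - np.floor(shares)), kind="stable")
        counts[order[:rem]] += 1
    else:
        counts = np.array([n_districts])
    geoms: list = []
    for part, n_part in zip(parts, counts):
        if n_part == 0:
            continue
        geoms.extend(_tessellate(StudyWindow(part), int(n_part), rng))
    ids = [f"D{i:03d}" for i in range(n_districts)]
    return SpatialUnitLayer(ids, geoms, level="district")


def _tessellate(window: StudyWindow, n: int, rng: np.random.Generator) -> list:
    if n == 1:
        return [window.polygon]
    gens = _uniform_in_window(window, n, rng)
    cells = shapely.voronoi_polygons(
        MultiPoint(gens), extend_to=box(*window.bounds), ordered=True
    )
    return [cell.intersection(window.polygon) for cell in cells.geoms]


def assign_zones(
    districts: SpatialUnitLayer, n_zones: int, seed: int
) -> tuple[SpatialUnitLayer, SpatialUnitLayer]:
    """Group districts into contiguous zones; returns (districts, zones).

    Grouping is k-means on district centroids followed by a repair pass that
    reattaches any district stranded from its zone's main component to the
    adjacent zone with the nearest centroid. Zone polygons are dissolved
    member unions; zone population and case counts are member sums.
    """
    if not (1 <= n_zones <= districts.n):
        raise InvalidArgumentError("need 1 <= n_zones <= n_districts")
    cents = districts.centroids()
    if n_zones == districts.n:
        labels = np.arange(districts.n)
    else:
        km = KMeans(n_clusters=n_zones, n_init=4, random_state=seed & 0x7FFFFFFF)
        labels = km.fit_predict(cents)
    labels = _repair_contiguity(districts, cents, labels, n_zones)

    out = districts.copy()
    zone_ids = [f"Z{z:02d}" for z in range(n_zones)]
    for i in range(out.n):
        out.parent_ids[i] = zone_ids[int(labels[i])]

    z_geoms, z_pop, z_cases = [], [], []
    for z in range(n_zones):
        members = np.where(labels == z)[0]
        z_geoms.append(shapely.unary_union([districts.geometries[i] for i in members]))
        z_pop.append(int(districts.population[members].sum()))
        z_cases.append(int(districts.cases[members].sum()))
    zones = SpatialUnitLayer(zone_ids, z_geoms, z_pop, z_cases, level="zone")
    return out, zones


def _adjacency(districts: SpatialUnitLayer) -> list[set[int]]:
    tree = shapely.STRtree(districts.geometries)
    left, right = tree.query(districts.geometries, predicate="intersects")
    adj: list[set[int]] = [set() for _ in range(districts.n)]
    for i, j in zip(left.tolist(), right.tolist()):
        if i != j:
            adj[i].add(j)
    return adj


def _repair_contiguity(districts, cents, labels, n_zones, max_rounds=50):
    """Reassign districts stranded from their zone's largest component."""
    labels = np.asarray(labels).copy()
    adj = _adjacency(districts)
    for _ in range(max_rounds):
        stranded = []
        for z in range(n_zones):
            members = np.where(labels == z)[0]
            comps = _components(members, adj)
            if len(comps) <= 1:
                continue
            comps.sort(key=len, reverse=True)
            for comp in comps[1:]:
                stranded.extend(comp)
        if not stranded:
            break
        moved = False
        zone_cents = np.array(
            [
                cents[labels == z].mean(axis=0) if np.any(labels == z) else [np.inf, np.inf]
                for z in range(n_zones)
            ]
        )
        for i in stranded:
            neighbor_zones = {int(labels[j]) for j in adj[i]} - {int(labels[i])}
            if not neighbor_zones:
                continue
            # nearest adjacent zone by centroid, but never empty a zone
            if np.sum(labels == labels[i]) <= 1:
                continue
            d = {z: np.hypot(*(cents[i] - zone_cents[z])) for z in neighbor_zones}
            labels[i] = min(d, key=lambda z: (d[z], z))
            moved = True
        if not moved:
            break
    return labels


def _components(members: np.ndarray, adj: list[set[int]]) -> list[list[int]]:
    member_set = set(members.tolist())
    seen: set[int] = set()
    comps = []
    for start in members.tolist():
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v in member_set and v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# population and cases
# ---------------------------------------------------------------------------


def allocate_population(
    districts: SpatialUnitLayer,
    total_population: int,
    dispersion: float,
    seed: int,
) -> SpatialUnitLayer:
    """Allocate integer populations summing exactly to the total.

    Weights are log-normal with ``sigma = dispersion`` (equal weights when
    ``dispersion = 0``), normalized and rounded by largest remainder so the
    conservation invariant is exact.
    """
    if total_population < 0:
        raise InvalidArgumentError("total_population must be >= 0")
    if dispersion < 0:
        raise InvalidArgumentError("dispersion must be >= 0")
    rng = np.random.default_rng([seed, 0x20])
    n = districts.n
    weights = np.exp(rng.normal(0.0, dispersion, n)) if dispersion > 0 else np.ones(n)
    shares = weights / weights.sum() * total_population
    pops = np.floor(shares).astype(np.int64)
    remainder = int(total_population - pops.sum())
    if remainder > 0:
        order = np.argsort(-(shares - np.floor(shares)), kind="stable")
        pops[order[:remainder]] += 1
    out = districts.copy()
    out.population = pops
    return out


def simulate_cases(
    districts: SpatialUnitLayer, cfg: SyntheticConfig, window: Optional[StudyWindow] = None
) -> PlanarPointPattern:
    """Draw sex-marked case locations.

    ``proportional``: each case's district is multinomial with probabilities
    proportional to district population, and the location uniform within
    that district. ``clustered``: a Thomas-style parent-offspring process —
    Poisson(parent_intensity) uniform parents (at least one), offspring
    displaced by an isotropic Gaussian with ``sd = cluster_sd`` and accepted
    inside the window. Each point is labeled ``M`` with probability
    ``male_fraction``, else ``F``.
    """
    window = window or StudyWindow(districts.union())
    rng = np.random.default_rng([cfg.seed, 0x30])
    n = cfg.n_cases
    if n == 0:
        return PlanarPointPattern(np.empty((0, 2)), window, np.empty(0, dtype=object))

    if cfg.clustering == "proportional":
        total = districts.population.sum()
        if total <= 0:
            raise InvalidArgumentError(
                "cannot place cases proportionally: all populations are zero"
            )
        probs = districts.population / total
        counts = rng.multinomial(n, probs)
        pts_list = []
        for i in np.where(counts > 0)[0]:
            w = StudyWindow(districts.geometries[i])
            pts_list.append(_uniform_in_window(w, int(counts[i]), rng))
        pts = np.vstack(pts_list)
        pts = pts[rng.permutation(len(pts))]
    else:
        n_parents = max(1, int(rng.poisson(cfg.parent_intensity)))
        parents = _uniform_in_window(window, n_parents, rng)
        pts = np.empty((0, 2))
        while len(pts) < n:
            m = n - len(pts)
            pick = rng.integers(0, n_parents, m)
            cand = parents[pick] + rng.normal(0.0, cfg.cluster_sd, (m, 2))
            keep = window.contains_xy(cand[:, 0], cand[:, 1])
            pts = np.vstack([pts, cand[keep]])
        pts = pts[:n]

    marks = np.where(rng.random(n) < cfg.male_fraction, "M", "F").astype(object)
    return PlanarPointPattern(pts, window, marks)


# ---------------------------------------------------------------------------
# island emulation
# ---------------------------------------------------------------------------


def island_window(
    side: float = DEFAULT_SIDE,
    strip_fraction: float = 0.06,
    strip_position: float = 0.7,
) -> StudyWindow:
    """A window split into two components by a vertical sea strip.

    Emulates an island/mainland geography; districts generated inside it
    form (at least) two disconnected contiguity components that ferry links
    must re-join.
    """
    x_lo = side * (strip_position - strip_fraction / 2)
    x_hi = side * (strip_position + strip_fraction / 2)
    left = box(0, 0, x_lo, side)
    right = box(x_hi, 0, side, side)
    return StudyWindow(left.union(right))


def ferry_links_for(
    districts: SpatialUnitLayer, n_links: int = 2
) -> list[tuple[str, str]]:
    """Edges joining disconnected contiguity components by nearest centroids.

    Returns up to ``n_links`` (id_a, id_b) pairs per component pair, chosen
    as the closest centroid pairs across components.
    """
    adj = _adjacency(districts)
    labels = -np.ones(districts.n, dtype=int)
    comp = 0
    for start in range(districts.n):
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = comp
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if labels[v] < 0:
                    labels[v] = comp
                    stack.append(v)
        comp += 1
    if comp < 2:
        return []
    cents = districts.centroids()
    main = int(np.argmax(np.bincount(labels)))
    links = []
    for c in range(comp):
        if c == main:
            continue
        a_idx = np.where(labels == c)[0]
        b_idx = np.where(labels == main)[0]
        d = np.sqrt(
            ((cents[a_idx, None, :] - cents[None, b_idx, :]) ** 2).sum(-1)
        )
        flat = np.argsort(d, axis=None, kind="stable")[:n_links]
        for f in flat.tolist():
            ia, ib = np.unravel_index(f, d.shape)
            links.append((districts.unit_ids[a_idx[ia]], districts.unit_ids[b_idx[ib]]))
    return links
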