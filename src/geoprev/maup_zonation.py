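"""Random Voronoi re-zonation experiment (MAUP sensitivity).

Each replicate samples a handful of district centroids, builds their Voronoi
diagram over the layer's bounding window, assigns every district to the cell
containing its centroid, pools cases and population per random zone, and
runs the global Moran permutation test on the resulting prevalence values
under one or more spatial-dependence schemes. The summary records the
fraction of replicates significant per scheme and for the union over
schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, box

from ._errors import DegenerateInputError, InvalidArgumentError
from .autocorrelation import MoranResult, global_moran
from .geo_core import SpatialUnitLayer
from .prevalence import layer_prevalence
from .spatial_weights import (
    SpatialWeights,
    augment_links,
    knn_weights,
    queen_contiguity,
    row_standardize,
)

__all__ = ["ZonationReplicate", "MaupSummary", "random_zonation", "maup_experiment"]

logger = logging.getLogger(__name__)


@dataclass
class ZonationReplicate:
    """One random zonation: generators, assignment and pooled layer."""

    index: int
    generator_ids: list[str]
    assignment: dict[str, str]  # district id -> random zone id
    zones: SpatialUnitLayer
    moran: dict[str, MoranResult] = field(default_factory=dict)
    degenerate: bool = False


@dataclass
class MaupSummary:
    n_replicates: int
    alpha: float
    seed: int
    records: pd.DataFrame  # replicate, scheme, I, pseudo_p, significant, degenerate
    fraction_significant: dict[str, float]
    union_fraction_significant: float

    @property
    def pseudo_p_reference(self) -> dict[str, np.ndarray]:
        """Per-scheme reference distribution of pseudo-p over zonations."""
        out = {}
        for scheme, grp in self.records.groupby("scheme"):
            out[scheme] = grp["pseudo_p"].to_numpy()
        return out


# ---------------------------------------------------------------------------
# single replicate
# ---------------------------------------------------------------------------


def _nearest_generator(cents: np.ndarray, gen_xy: np.ndarray) -> np.ndarray:
    """Voronoi-cell membership: index of the nearest generator.

    A centroid equidistant from several generators (exactly on a Voronoi
    edge) goes to the smallest cell index, deterministically.
    """
    d = np.sqrt(((cents[:, None, :] - gen_xy[None, :, :]) ** 2).sum(-1))
    # argmin returns the first (= smallest index) among exact ties
    return np.argmin(d, axis=1)


def random_zonation(
    districts: SpatialUnitLayer,
    n_zones: int,
    seed: int,
    index: int = 0,
    dissolve: bool = True,
) -> ZonationReplicate:
    """One random Voronoi aggregation of the districts.

    Samples ``n_zones`` district centroids without replacement, assigns each
    district to the Voronoi cell containing its centroid (equivalently, to
    its nearest generator), pools population and cases per random zone and
    computes the pooled prevalence. Every generator district lands in its
    own cell, so all random zones are non-empty.

    ``dissolve=False`` skips building the dissolved zone polygons and places
    zone "centroids" at the area-weighted mean of member district centroids
    (identical to the dissolved-polygon centroid for non-overlapping
    members); the kNN scheme and pooled statistics are unaffected.
    """
    if n_zones > districts.n:
        raise InvalidArgumentError("n_zones must be <= number of districts")
    rng = np.random.default_rng([seed, 0x40, index])
    gen_idx = np.sort(rng.choice(districts.n, size=n_zones, replace=False))
    cents = districts.centroids()
    gen_xy = cents[gen_idx]
    labels = _nearest_generator(cents, gen_xy)

    zone_ids = [f"R{z:02d}" for z in range(n_zones)]
    assignment = {
        districts.unit_ids[i]: zone_ids[int(labels[i])] for i in range(districts.n)
    }
    areas = districts.areas()
    z_geoms, z_pop, z_cases = [], [], []
    for z in range(n_zones):
        members = np.where(labels == z)[0]
        z_pop.append(int(districts.population[members].sum()))
        z_cases.append(int(districts.cases[members].sum()))
        if dissolve:
            z_geoms.append(
                shapely.unary_union([districts.geometries[i] for i in members])
            )
        else:
            w = areas[members]
            cxy = (cents[members] * w[:, None]).sum(axis=0) / w.sum()
            z_geoms.append(shapely.Point(cxy).buffer(1.0))  # placeholder geometry
    zones = SpatialUnitLayer(
        zone_ids, z_geoms, z_pop, z_cases, level="random_zone"
    )
    zones = layer_prevalence(zones)
    return ZonationReplicate(
        index=index,
        generator_ids=[districts.unit_ids[i] for i in gen_idx],
        assignment=assignment,
        zones=zones,
    )


# ---------------------------------------------------------------------------
# experiment
# ---------------------------------------------------------------------------


def _contracted_queen(
    district_w: SpatialWeights, labels: np.ndarray, n_zones: int, zone_ids: list[str]
) -> SpatialWeights:
    """Queen weights on random zones by contracting the district graph.

    Two random zones are neighbors iff any of their member districts are
    neighbors (including ferry links), which for a tessellating district
    layer coincides with Queen contiguity on the dissolved zone polygons.
    """
    nb_sets: list[set[int]] = [set() for _ in range(n_zones)]
    for i in range(district_w.n):
        zi = int(labels[i])
        for j in district_w.neighbors[i]:
            zj = int(labels[j])
            if zi != zj:
                nb_sets[zi].add(zj)
    neighbors = [sorted(s) for s in nb_sets]
    weights = [[1.0] * len(nb) for nb in neighbors]
    return SpatialWeights(list(zone_ids), neighbors, weights)


def maup_experiment(
    districts: SpatialUnitLayer,
    n_zones: int = 10,
    n_replicates: int = 200,
    weights_schemes: Sequence[str] = ("queen", "knn4"),
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    ferry_links: Optional[Sequence[tuple[str, str]]] = None,
    keep_replicates: bool = False,
) -> MaupSummary | tuple[MaupSummary, list[ZonationReplicate]]:
    """Distribution of global Moran significance over random zonations.

    For each replicate the pooled prevalence values are tested with the
    one-sided global Moran permutation test under every requested scheme
    (``queen`` contiguity on the aggregated layer, ``knnK`` on zone
    centroids). Replicates with degenerate prevalence (zero variance) are
    retained, flagged, and counted as non-significant.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidArgumentError("alpha must be in (0, 1)")
    if n_replicates < 1:
        raise InvalidArgumentError("n_replicates must be >= 1")
    usable = []
    for scheme in weights_schemes:
        if scheme != "queen" and not scheme.startswith("knn"):
            raise InvalidArgumentError(f"unknown weights scheme {scheme!r}")
        if scheme.startswith("knn") and int(scheme[3:] or 4) >= n_zones:
            logger.warning("scheme %s skipped: k >= n_zones=%d", scheme, n_zones)
            continue
        usable.append(scheme)
    weights_schemes = usable
    if not weights_schemes:
        raise InvalidArgumentError("no usable weights scheme for this n_zones")

    district_w = queen_contiguity(districts)
    if ferry_links:
        district_w = augment_links(district_w, ferry_links)
    dist_index = {uid: i for i, uid in enumerate(districts.unit_ids)}

    rows = []
    replicates: list[ZonationReplicate] = []
    for rep in range(n_replicates):
        z = random_zonation(districts, n_zones, seed, index=rep, dissolve=False)
        labels = np.array(
            [int(z.assignment[uid][1:]) for uid in districts.unit_ids]
        )
        for scheme in weights_schemes:
            if scheme == "queen":
                w = _contracted_queen(district_w, labels, n_zones, z.zones.unit_ids)
            else:
                k = int(scheme[3:] or 4)
                w = knn_weights(z.zones, k)
            w = row_standardize(w)
            try:
                res = global_moran(
                    z.zones.pp, w, n_perm=n_perm, seed=seed * 100003 + rep,
                    alternative="greater",
                )
                z.moran[scheme] = res
                rows.append(
                    dict(
                        replicate=rep,
                        scheme=scheme,
                        I=res.I,
                        pseudo_p=res.pseudo_p,
                        significant=res.pseudo_p <= alpha,
                        degenerate=False,
                    )
                )
            except DegenerateInputError:
                z.degenerate = True
                logger.warning("replicate %d (%s): degenerate pp; non-significant", rep, scheme)
                rows.append(
                    dict(
                        replicate=rep,
                        scheme=scheme,
                        I=np.nan,
                        pseudo_p=np.nan,
                        significant=False,
                        degenerate=True,
                    )
                )
        if keep_replicates:
            replicates.append(z)

    records = pd.DataFrame(rows)
    frac = {
        scheme: float(grp["significant"].mean())
        for scheme, grp in records.groupby("scheme")
    }
    union = float(
        records.groupby("replicate")["significant"].any().mean()
    )
    summary = MaupSummary(
        n_replicates=n_replicates,
        alpha=alpha,
        seed=seed,
        records=records,
        fraction_significant=frac,
        union_fraction_significant=union,
    )
    return (summary, replicates) if keep_replicates else summary
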