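"""Global, local and bivariate Moran's I with permutation inference.

Global I uses full random permutations of the variable over units; the local
statistics use conditional permutation (the focal value held fixed, neighbor
values drawn without replacement from the remaining ``n - 1`` values, fresh
per unit and per replicate). Cluster centers are classified HH/LL/HL/LH from
the signs of the standardized value and its spatial lag; no multiple-testing
correction is applied — local results are exploratory by design.

Units with undefined values (NaN) and isolates are excluded with a warning
before any statistic is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import DegenerateInputError, InvalidArgumentError
from .spatial_weights import SpatialWeights

__all__ = [
    "MoranResult",
    "LocalMoranTable",
    "global_moran",
    "global_bivariate_moran",
    "local_moran",
    "bivariate_local_moran",
    "classify_clusters",
    "write_cluster_map",
]

logger = logging.getLogger(__name__)

QUADRANTS = ("HH", "LL", "HL", "LH")


@dataclass
class MoranResult:
    """Global Moran's I with its permutation reference distribution."""

    I: float
    n_perm: int
    permutation_Is: np.ndarray
    pseudo_p: float
    alternative: str
    seed: int
    n_used: int
    excluded_ids: list[str] = field(default_factory=list)


@dataclass
class LocalMoranTable:
    """Per-unit local Moran's I values, pseudo-p and quadrant classes."""

    table: pd.DataFrame  # unit_id, x, z, lag, I_i, pseudo_p, quadrant
    n_perm: int
    seed: int
    excluded_ids: list[str] = field(default_factory=list)
    alpha: Optional[float] = None

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# preparation
# ---------------------------------------------------------------------------


def _prepare(w: SpatialWeights, *xs: np.ndarray):
    """Drop NaN-valued units and isolates (iterating until stable)."""
    xs = [np.asarray(x, dtype=float) for x in xs]
    for x in xs:
        if len(x) != w.n:
            raise InvalidArgumentError("value vector length must match weights")
    keep = ~np.any(np.isnan(np.vstack(xs)), axis=0)
    dropped = set(np.where(~keep)[0].tolist())
    sub = w if not dropped else w.subset(np.where(keep)[0])
    # dropping units (or the input itself) may leave isolates; peel them off
    while True:
        iso = [i for i in range(sub.n) if not sub.neighbors[i]]
        if not iso:
            break
        dropped.update(w.ids.index(sub.ids[i]) for i in iso)
        sub = sub.subset([i for i in range(sub.n) if sub.neighbors[i]])
    keep_idx = [i for i in range(w.n) if i not in dropped]
    excluded = [w.ids[i] for i in sorted(dropped)]
    if excluded:
        logger.warning("excluded %d unit(s) from Moran analysis: %s", len(excluded), excluded)
    if len(keep_idx) < 3:
        raise InvalidArgumentError("need >= 3 usable (non-isolate) units")
    xs = [x[keep_idx] for x in xs]
    return sub, xs, excluded


def _perm_matrix(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    """(n_perm, n) independent uniform permutations of range(n)."""
    return np.argsort(rng.random((n_perm, n)), axis=1)


# ---------------------------------------------------------------------------
# global statistics
# ---------------------------------------------------------------------------


def _pseudo_p(stat_obs: float, stat_perm: np.ndarray, alternative: str) -> float:
    n_perm = len(stat_perm)
    p_greater = (1.0 + int(np.sum(stat_perm >= stat_obs))) / (1.0 + n_perm)
    p_less = (1.0 + int(np.sum(stat_perm <= stat_obs))) / (1.0 + n_perm)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    if alternative == "two_sided":
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise InvalidArgumentError(f"unknown alternative {alternative!r}")


def global_moran(
    x: Sequence[float],
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MoranResult:
    """Global Moran's I, ``I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i**2``.

    Significance comes from ``n_perm`` full random permutations of the
    values over the units; the default alternative is one-sided (greater),
    testing for positive spatial autocorrelation.
    """
    sub, (xv,), excluded = _prepare(w, np.asarray(x, dtype=float))
    n = sub.n
    z = xv - xv.mean()
    denom = float(z @ z)
    if denom <= 0:
        raise DegenerateInputError("variance of x is zero")
    wsp = sub.to_sparse()
    s0 = sub.s0
    i_obs = (n / s0) * float(z @ (wsp @ z)) / denom

    rng = np.random.default_rng([seed, 0x67])
    perms = _perm_matrix(rng, n_perm, n)
    zp = z[perms]  # (n_perm, n)
    lagp = zp @ wsp.T.toarray() if n <= 64 else np.asarray((wsp @ zp.T).T)
    i_perm = (n / s0) * np.sum(zp * lagp, axis=1) / denom

    return MoranResult(
        I=i_obs,
        n_perm=n_perm,
        permutation_Is=i_perm,
        pseudo_p=_pseudo_p(i_obs, i_perm, alternative),
        alternative=alternative,
        seed=seed,
        n_used=n,
        excluded_ids=excluded,
    )


def global_bivariate_moran(
    x: Sequence[float],
    y: Sequence[float],
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MoranResult:
    """Global bivariate Moran: ``(n/S0) * mean(z_x * lag(z_y))``.

    Both variables are standardized to mean 0 and unit (population) variance;
    the permutation null shuffles ``y`` over the units holding ``x`` fixed.
    """
    sub, (xv, yv), excluded = _prepare(
        w, np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    )
    n = sub.n
    zx = _standardize(xv)
    zy = _standardize(yv)
    wsp = sub.to_sparse()
    s0 = sub.s0
    i_obs = (n / s0) * float(zx @ (wsp @ zy)) / n

    rng = np.random.default_rng([seed, 0x68])
    perms = _perm_matrix(rng, n_perm, n)
    zyp = zy[perms]
    lagp = np.asarray((wsp @ zyp.T).T)
    i_perm = (n / s0) * np.sum(zx[None, :] * lagp, axis=1) / n

    return MoranResult(
        I=i_obs,
        n_perm=n_perm,
        permutation_Is=i_perm,
        pseudo_p=_pseudo_p(i_obs, i_perm, alternative),
        alternative=alternative,
        seed=seed,
        n_used=n,
        excluded_ids=excluded,
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()  # population standard deviation
    if sd <= 0:
        raise DegenerateInputError("variance is zero")
    return (v - v.mean()) / sd


# ---------------------------------------------------------------------------
# local statistics
# ---------------------------------------------------------------------------


def _quadrant(z_focal: np.ndarray, lag: np.ndarray) -> np.ndarray:
    hi_z = z_focal > 0
    hi_l = lag > 0
    out = np.where(
        hi_z & hi_l, "HH", np.where(~hi_z & ~hi_l, "LL", np.where(hi_z, "HL", "LH"))
    )
    return out.astype(object)


def _conditional_permutation(
    z_draw_pool: np.ndarray,
    sub: SpatialWeights,
    scale: np.ndarray,
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """Per-unit conditional-permutation local statistics.

    For unit i, ``n_perm`` replicates each draw ``k_i`` values without
    replacement from the pool with the focal value removed; the replicate
    statistic is ``scale_i * sum_j w_ij * draw_j``. The RNG stream is keyed
    by (seed, unit index) so results do not depend on evaluation order.
    Returns the (n, n_perm) matrix of permuted local statistics.
    """
    n = sub.n
    stats = np.empty((n, n_perm))
    for i in range(n):
        others = np.delete(z_draw_pool, i)
        k = len(sub.neighbors[i])
        w_row = np.asarray(sub.weights[i])
        rng = np.random.default_rng([seed, i])
        u = rng.random((n_perm, n - 1))
        picks = np.argpartition(u, k - 1, axis=1)[:, :k]
        drawn = others[picks]  # (n_perm, k)
        stats[i] = scale[i] * (drawn @ w_row)
    return stats


def local_moran(
    x: Sequence[float],
    w: SpatialWeights,
    n_perm: int = 9999,
    seed: int = 0,
) -> LocalMoranTable:
    """Univariate local Moran (LISA) with conditional-permutation pseudo-p.

    ``I_i = (z_i / m2) * sum_j w_ij z_j`` with ``m2 = sum_k z_k**2 / n``.
    The pseudo-p is two-sided on ``|I_i|`` so that both positive (HH/LL) and
    negative (HL/LH) cluster centers can be flagged. On a row-standardized
    matrix ``sum_i I_i = n * I_global``.
    """
    sub, (xv,), excluded = _prepare(w, np.asarray(x, dtype=float))
    n = sub.n
    z = xv - xv.mean()
    m2 = float(z @ z) / n
    if m2 <= 0:
        raise DegenerateInputError("variance of x is zero")
    wsp = sub.to_sparse()
    lag = np.asarray(wsp @ z)
    i_obs = z / m2 * lag

    perm_stats = _conditional_permutation(z, sub, z / m2, n_perm, seed)
    exceed = np.sum(np.abs(perm_stats) >= np.abs(i_obs)[:, None], axis=1)
    pseudo_p = (1.0 + exceed) / (1.0 + n_perm)

    table = pd.DataFrame(
        {
            "unit_id": sub.ids,
            "x": xv,
            "z": z,
            "lag": lag,
            "I_i": i_obs,
            "pseudo_p": pseudo_p,
            "quadrant": _quadrant(z, lag),
        }
    )
    return LocalMoranTable(table, n_perm, seed, excluded)


def bivariate_local_moran(
    x: Sequence[float],
    y: Sequence[float],
    w: SpatialWeights,
    n_perm: int = 9999,
    seed: int = 0,
) -> LocalMoranTable:
    """Bivariate local Moran: ``I_i = z_x_i * sum_j w_ij z_y_j``.

    ``x`` is the child-level variable, ``y`` the parent-level variable copied
    down onto the same units. Both are standardized to unit variance. The
    conditional permutation shuffles ``y`` over the other ``n - 1`` units
    while holding every ``x`` fixed.
    """
    sub, (xv, yv), excluded = _prepare(
        w, np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    )
    zx = _standardize(xv)
    zy = _standardize(yv)
    wsp = sub.to_sparse()
    lag = np.asarray(wsp @ zy)
    i_obs = zx * lag

    perm_stats = _conditional_permutation(zy, sub, zx, n_perm, seed)
    exceed = np.sum(np.abs(perm_stats) >= np.abs(i_obs)[:, None], axis=1)
    pseudo_p = (1.0 + exceed) / (1.0 + n_perm)

    table = pd.DataFrame(
        {
            "unit_id": sub.ids,
            "x": xv,
            "y": yv,
            "z": zx,
            "lag": lag,
            "I_i": i_obs,
            "pseudo_p": pseudo_p,
            "quadrant": _quadrant(zx, lag),
        }
    )
    return LocalMoranTable(table, n_perm, seed, excluded)


def classify_clusters(result: LocalMoranTable, alpha: float = 0.05) -> LocalMoranTable:
    """Label units significant at ``alpha`` by quadrant, the rest ``NS``.

    No multiple-testing correction is applied (deliberately): flagged units
    are unusual occurrences to explore, not confirmatory findings.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidArgumentError("alpha must be in (0, 1)")
    table = result.table.copy()
    table["significant"] = table["pseudo_p"] <= alpha
    table["cluster"] = np.where(table["significant"], table["quadrant"], "NS")
    return LocalMoranTable(table, result.n_perm, result.seed, list(result.excluded_ids), alpha)


def write_cluster_map(layer, result: LocalMoranTable, path) -> None:
    """Plain GeoJSON cluster map: unit polygons with their cluster label.

    Units excluded from the analysis (undefined value or isolate) carry the
    label ``excluded``. ``result`` must already be classified.
    """
    import json

    from shapely.geometry import mapping

    if "cluster" not in result.table.columns:
        raise InvalidArgumentError("classify_clusters must be applied first")
    labels = dict(zip(result.table["unit_id"], result.table["cluster"]))
    features = []
    for i, uid in enumerate(layer.unit_ids):
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(layer.geometries[i]),
                "properties": {"unit_id": uid, "cluster": labels.get(uid, "excluded")},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
        fh.write("\n")
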