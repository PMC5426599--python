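"""Ripley's-K family statistics for sex-interaction testing.

Implements the uncorrected K estimator, the cross-type K/L functions, the
Difference-K statistic, pointwise Monte-Carlo simulation envelopes under
random labeling or CSR, and the Diggle-Cressie-Loosmore-Ford (DCLF)
integrated-deviation test.

No edge correction is applied anywhere: the estimators are compared only
against simulations conditioned on the same window and point counts, so the
(positive) boundary bias relative to the theoretical ``pi * r**2`` cancels
between observed and simulated curves. Absolute comparisons against the CSR
theoretical curve are therefore only meaningful at small ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from ._errors import InvalidArgumentError
from .geo_core import PlanarPointPattern, StudyWindow

__all__ = [
    "RGrid",
    "SummaryFunctionResult",
    "khat",
    "cross_k",
    "cross_l",
    "difference_k",
    "envelope",
    "dclf_test",
]

DEFAULT_R_MAX = 80_000.0
DEFAULT_R_STEP = 160.0


@dataclass(frozen=True)
class RGrid:
    """Uniform evaluation grid ``0, step, 2*step, ..., r_max``."""

    r_max: float = DEFAULT_R_MAX
    step: float = DEFAULT_R_STEP

    def __post_init__(self):
        if self.r_max <= 0 or self.step <= 0:
            raise InvalidArgumentError("r_max and step must be positive")
        if self.r_max < self.step:
            raise InvalidArgumentError("r_max must be at least one step")

    @property
    def values(self) -> np.ndarray:
        n = int(round(self.r_max / self.step)) + 1
        return np.linspace(0.0, self.step * (n - 1), n)

    def __len__(self) -> int:
        return int(round(self.r_max / self.step)) + 1

    def validate_for_window(self, window: StudyWindow) -> None:
        if self.r_max > window.diameter:
            raise InvalidArgumentError(
                f"r_max {self.r_max} exceeds window diameter {window.diameter:.1f}"
            )


@dataclass
class SummaryFunctionResult:
    """Observed summary curve with its simulation ensemble and envelopes."""

    rgrid: RGrid
    observed: np.ndarray
    simulations: np.ndarray  # (n_sim, len(r))
    envelope_lo: np.ndarray
    envelope_hi: np.ndarray
    statistic: str
    null: str
    seed: int
    dclf_u: Optional[float] = None
    pseudo_p: Optional[float] = None
    alternative: Optional[str] = None

    @property
    def n_sim(self) -> int:
        return self.simulations.shape[0]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _counts_leq(distances: np.ndarray, r: np.ndarray) -> np.ndarray:
    """#{d <= r_k} for each grid value, counting ties on the boundary."""
    return np.searchsorted(np.sort(distances, kind="stable"), r, side="right")


def khat(pattern: PlanarPointPattern, rgrid: RGrid) -> np.ndarray:
    """Uncorrected Ripley K: ``A / (n (n-1)) * sum_{i != j} 1[d_ij <= r]``.

    Coincident pairs (``d_ij = 0``) are counted from ``r = 0`` upward.
    """
    pts = pattern.points
    if len(pts) < 2:
        raise InvalidArgumentError("khat requires at least 2 points")
    rgrid.validate_for_window(pattern.window)
    n = len(pts)
    d = pdist(pts)
    counts = 2.0 * _counts_leq(d, rgrid.values)  # unordered -> ordered pairs
    return pattern.window.area / (n * (n - 1)) * counts


def cross_k(
    pattern: PlanarPointPattern, mark_a: str, mark_b: str, rgrid: RGrid
) -> np.ndarray:
    """Cross-type K between the two mark classes (symmetric in a, b)."""
    a = pattern.subset(mark_a)
    b = pattern.subset(mark_b)
    if len(a) == 0 or len(b) == 0:
        raise InvalidArgumentError(
            f"both mark classes must be non-empty (|{mark_a}|={len(a)}, |{mark_b}|={len(b)})"
        )
    rgrid.validate_for_window(pattern.window)
    d = cdist(a, b).ravel()
    counts = _counts_leq(d, rgrid.values)
    return pattern.window.area / (len(a) * len(b)) * counts


def cross_l(
    pattern: PlanarPointPattern, mark_a: str, mark_b: str, rgrid: RGrid
) -> np.ndarray:
    """Elementwise L transform of the cross K: ``L = sqrt(K / pi)``."""
    return np.sqrt(cross_k(pattern, mark_a, mark_b, rgrid) / np.pi)


def difference_k(
    pattern: PlanarPointPattern,
    rgrid: RGrid,
    mark_a: str = "M",
    mark_b: str = "F",
) -> np.ndarray:
    """``K_a(r) - K_b(r)`` using the uncorrected estimator for each class."""
    a = pattern.subset(mark_a)
    b = pattern.subset(mark_b)
    if len(a) < 2 or len(b) < 2:
        raise InvalidArgumentError("both mark classes need >= 2 points")
    rgrid.validate_for_window(pattern.window)
    r = rgrid.values
    area = pattern.window.area
    ka = area / (len(a) * (len(a) - 1)) * 2.0 * _counts_leq(pdist(a), r)
    kb = area / (len(b) * (len(b) - 1)) * 2.0 * _counts_leq(pdist(b), r)
    return ka - kb


# ---------------------------------------------------------------------------
# fast label-permutation machinery
# ---------------------------------------------------------------------------


class _LabelStatEngine:
    """Computes label-dependent curves from a digitized distance matrix.

    Pairwise distances are computed once and digitized onto the r grid; each
    relabeling then only needs integer histogramming, which makes 199+
    random-labeling simulations cheap. Counting is exact (boundary ties
    included) because digitization uses the same ``<=`` convention as the
    direct estimators.
    """

    def __init__(self, pattern: PlanarPointPattern, rgrid: RGrid):
        self.r = rgrid.values
        self.area = pattern.window.area
        self.n = pattern.n
        d = squareform(pdist(pattern.points))
        # idx[i,j] = smallest k with r[k] >= d_ij ; len(r) if beyond the grid
        self.idx = np.searchsorted(self.r, d, side="left").astype(np.int32)
        self.nbins = len(self.r)

    def _cum(self, flat_idx: np.ndarray) -> np.ndarray:
        counts = np.bincount(flat_idx, minlength=self.nbins + 1)[: self.nbins]
        return np.cumsum(counts)

    def cross_k_curve(self, is_a: np.ndarray) -> np.ndarray:
        sub = self.idx[np.ix_(is_a, ~is_a)]
        na, nb = sub.shape
        return self.area / (na * nb) * self._cum(sub.ravel())

    def cross_l_curve(self, is_a: np.ndarray) -> np.ndarray:
        return np.sqrt(self.cross_k_curve(is_a) / np.pi)

    def k_curve(self, members: np.ndarray) -> np.ndarray:
        sub = self.idx[np.ix_(members, members)]
        m = sub.shape[0]
        counts = self._cum(sub.ravel()) - m  # drop the zero-distance diagonal
        return self.area / (m * (m - 1)) * counts

    def difference_k_curve(self, is_a: np.ndarray) -> np.ndarray:
        return self.k_curve(is_a) - self.k_curve(~is_a)


def _observed_and_engine(pattern, statistic, rgrid, mark_a, mark_b):
    marks = pattern.marks
    if marks is None:
        raise InvalidArgumentError("random labeling requires a marked pattern")
    is_a = np.asarray(marks, dtype=object) == mark_a
    if statistic in ("cross_k", "cross_l"):
        if is_a.sum() == 0 or (~is_a).sum() == 0:
            raise InvalidArgumentError("both mark classes must be non-empty")
    elif statistic == "difference_k":
        if is_a.sum() < 2 or (~is_a).sum() < 2:
            raise InvalidArgumentError("both mark classes need >= 2 points")
    engine = _LabelStatEngine(pattern, rgrid)
    fn = {
        "cross_k": engine.cross_k_curve,
        "cross_l": engine.cross_l_curve,
        "difference_k": engine.difference_k_curve,
        "k": engine.k_curve,
    }[statistic]
    return is_a, fn


def envelope(
    pattern: PlanarPointPattern,
    statistic: str = "cross_l",
    null: str = "random_labeling",
    n_sim: int = 199,
    seed: int = 0,
    rgrid: Optional[RGrid] = None,
    mark_a: str = "M",
    mark_b: str = "F",
) -> SummaryFunctionResult:
    """Pointwise rank-1 simulation envelopes for a summary statistic.

    ``random_labeling`` fixes locations and permutes the sex labels
    preserving class sizes; ``csr`` (for ``statistic="k"`` only) redraws the
    same number of points uniformly in the window. Envelopes are the
    pointwise min/max over the ``n_sim`` simulated curves, giving a per-tail
    pointwise exceedance probability of ``1 / (n_sim + 1)`` under the null.
    """
    if n_sim < 19:
        raise InvalidArgumentError("n_sim must be >= 19")
    if statistic not in ("cross_k", "cross_l", "difference_k", "k"):
        raise InvalidArgumentError(f"unknown statistic {statistic!r}")
    rgrid = rgrid or RGrid()
    rgrid.validate_for_window(pattern.window)
    rng = np.random.default_rng(seed)

    if null == "random_labeling":
        is_a, fn = _observed_and_engine(pattern, statistic, rgrid, mark_a, mark_b)
        observed = fn(is_a)
        sims = np.empty((n_sim, len(rgrid)))
        labels = is_a.copy()
        for s in range(n_sim):
            rng.shuffle(labels)  # in-place permutation preserves class sizes
            sims[s] = fn(labels)
    elif null == "csr":
        if statistic != "k":
            raise InvalidArgumentError("csr null is only defined for statistic='k'")
        observed = khat(pattern, rgrid)
        sims = np.empty((n_sim, len(rgrid)))
        for s in range(n_sim):
            sim_pat = _uniform_pattern(pattern.window, pattern.n, rng)
            sims[s] = khat(sim_pat, rgrid)
    else:
        raise InvalidArgumentError(f"unknown null {null!r}")

    return SummaryFunctionResult(
        rgrid=rgrid,
        observed=observed,
        simulations=sims,
        envelope_lo=sims.min(axis=0),
        envelope_hi=sims.max(axis=0),
        statistic=statistic,
        null=null,
        seed=seed,
    )


def _uniform_pattern(
    window: StudyWindow, n: int, rng: np.random.Generator
) -> PlanarPointPattern:
    """n uniform points in the window by bounding-box rejection sampling."""
    x0, y0, x1, y1 = window.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = max(64, int(1.5 * (n - len(pts)) * (x1 - x0) * (y1 - y0) / window.area))
        cand = np.column_stack(
            [rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)]
        )
        keep = window.contains_xy(cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[keep]])
    return PlanarPointPattern(pts[:n], window)


# ---------------------------------------------------------------------------
# DCLF test
# ---------------------------------------------------------------------------


def _deviation(obs: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """obs - ref with sub-precision noise snapped to zero.

    Curves that are equal up to float rounding (e.g. a degenerate
    random-labeling null where every permutation is the identity) must give
    u = 0 exactly, not an arbitrary ranking of accumulated rounding error.
    """
    dev = obs - ref
    tol = 1e-9 * (np.abs(obs) + np.abs(ref))
    dev[np.abs(dev) <= tol] = 0.0
    return dev


def _dclf_u(dev: np.ndarray, dr: float, alternative: str) -> float:
    if alternative == "greater":
        dev = np.maximum(dev, 0.0)
    elif alternative != "two_sided":
        raise InvalidArgumentError(f"unknown alternative {alternative!r}")
    return float(np.sum(dev * dev) * dr)


def dclf_test(
    result: SummaryFunctionResult,
    reference: str = "mean_of_simulations",
    alternative: str = "two_sided",
) -> tuple[float, float]:
    """Integrated-deviation Monte-Carlo test over the r grid.

    ``u = sum_k delta(r_k)**2 * dr`` with ``delta = obs - ref`` (two-sided)
    or ``delta = max(obs - ref, 0)`` (greater, testing attraction). The same
    functional is applied to every simulated curve; when the reference is the
    simulation mean, each simulation is compared against the mean of the
    *other* simulations (leave-one-out) so observed and simulated deviations
    are exchangeable under the null. Returns ``(u, pseudo_p)`` and stores
    both on ``result``.
    """
    sims = result.simulations
    if sims.size == 0:
        raise InvalidArgumentError("result holds no simulations")
    n_sim = sims.shape[0]
    dr = result.rgrid.step

    if reference == "mean_of_simulations":
        ref_obs = sims.mean(axis=0)
        total = sims.sum(axis=0)
        u_obs = _dclf_u(_deviation(result.observed, ref_obs), dr, alternative)
        u_sims = np.empty(n_sim)
        for s in range(n_sim):
            ref_s = (total - sims[s]) / (n_sim - 1)
            u_sims[s] = _dclf_u(_deviation(sims[s], ref_s), dr, alternative)
    elif reference == "theoretical":
        if result.statistic != "k" or result.null != "csr":
            raise InvalidArgumentError(
                "theoretical reference is only available for CSR K"
            )
        ref = np.pi * result.rgrid.values**2
        u_obs = _dclf_u(_deviation(result.observed, ref), dr, alternative)
        u_sims = np.array(
            [_dclf_u(_deviation(sims[s], ref), dr, alternative) for s in range(n_sim)]
        )
    else:
        raise InvalidArgumentError(f"unknown reference {reference!r}")

    pseudo_p = (1.0 + int(np.sum(u_sims >= u_obs))) / (1.0 + n_sim)
    result.dclf_u = u_obs
    result.pseudo_p = pseudo_p
    result.alternative = alternative
    return u_obs, pseudo_p
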