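"""Stratified spatial heterogeneity: the geographical-detector q-statistic.

``q = 1 - SSW/SST`` measures how much a stratification (e.g. zones) explains
the variance of a child-level variable (e.g. district prevalence); q = 0
when stratum means are all equal and q = 1 when every stratum is internally
constant. Significance is assessed by permuting the stratum labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._errors import DegenerateInputError, InvalidArgumentError

__all__ = ["QStatResult", "q_statistic", "q_significance"]


@dataclass
class QStatResult:
    q: float
    n: int
    n_strata: int
    stratum_sizes: dict[str, int]
    stratum_variances: dict[str, float]
    ssw: float
    sst: float
    pseudo_p: Optional[float] = None
    n_perm: Optional[int] = None
    seed: Optional[int] = None
    permutation_qs: Optional[np.ndarray] = None


def _validate(values: np.ndarray, strata: np.ndarray):
    if len(values) != len(strata):
        raise InvalidArgumentError("values and strata must have equal length")
    keep = ~np.isnan(values)
    values, strata = values[keep], strata[keep]
    labels, codes = np.unique(strata, return_inverse=True)
    if len(labels) < 2:
        raise InvalidArgumentError("need >= 2 strata")
    return values, codes, labels


def _ssw(values: np.ndarray, codes: np.ndarray, n_strata: int) -> float:
    # sum_h sum_{i in h} (y - ybar_h)^2  ==  sum y^2 - sum_h S_h^2 / N_h
    sums = np.bincount(codes, weights=values, minlength=n_strata)
    counts = np.bincount(codes, minlength=n_strata)
    return float(np.sum(values * values) - np.sum(sums * sums / counts))


def q_statistic(values: Sequence[float], strata: Sequence) -> QStatResult:
    """q = 1 - SSW/SST over the given stratification.

    Single-member strata contribute zero to SSW. Raises
    :class:`DegenerateInputError` when the total variance is zero.
    """
    values = np.asarray(values, dtype=float)
    strata = np.asarray(strata, dtype=object)
    values, codes, labels = _validate(values, strata)
    n = len(values)
    sst = float(np.sum((values - values.mean()) ** 2))
    if sst <= 0:
        raise DegenerateInputError("total variance is zero")
    ssw = _ssw(values, codes, len(labels))
    counts = np.bincount(codes, minlength=len(labels))
    variances = {}
    for h, lab in enumerate(labels):
        grp = values[codes == h]
        variances[str(lab)] = float(grp.var())  # population variance
    return QStatResult(
        q=1.0 - ssw / sst,
        n=n,
        n_strata=len(labels),
        stratum_sizes={str(lab): int(c) for lab, c in zip(labels, counts)},
        stratum_variances=variances,
        ssw=ssw,
        sst=sst,
    )


def q_significance(
    values: Sequence[float],
    strata: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> QStatResult:
    """Permutation test for q: stratum labels shuffled over units.

    One-sided pseudo-p, ``(1 + #{q_perm >= q_obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    result = q_statistic(values, strata)
    vals = np.asarray(values, dtype=float)
    strat = np.asarray(strata, dtype=object)
    vals, codes, labels = _validate(vals, strat)
    L = len(labels)
    rng = np.random.default_rng([seed, 0x71])
    q_perm = np.empty(n_perm)
    for p in range(n_perm):
        perm_codes = rng.permutation(codes)
        q_perm[p] = 1.0 - _ssw(vals, perm_codes, L) / result.sst
    result.pseudo_p = (1.0 + int(np.sum(q_perm >= result.q))) / (1.0 + n_perm)
    result.n_perm = n_perm
    result.seed = seed
    result.permutation_qs = q_perm
    return result
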