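"""Period prevalence per spatial unit.

Prevalence is cases accumulated over the study period divided by unit
population, scaled per 10,000 persons. Values are kept at full precision
internally; half-up rounding to two decimals is applied only when reporting.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from ._errors import InvalidArgumentError, UndefinedPrevalenceError
from .geo_core import SpatialUnitLayer

__all__ = ["PER", "period_prevalence", "round_half_up", "layer_prevalence", "prevalence_table"]

logger = logging.getLogger(__name__)

#: prevalence scale — cases per this many persons
PER = 10_000


def period_prevalence(cases: int, population: int) -> float:
    """Cases per 10,000 persons over the study period (full precision).

    Raises :class:`UndefinedPrevalenceError` when ``population <= 0``.
    """
    if population <= 0:
        raise UndefinedPrevalenceError(
            f"prevalence undefined for population {population}"
        )
    if cases < 0:
        raise InvalidArgumentError("cases must be non-negative")
    return PER * cases / population


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (reporting rule)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def layer_prevalence(layer: SpatialUnitLayer) -> SpatialUnitLayer:
    """Compute ``pp`` for every unit with positive population.

    Zero-population units keep ``pp = NaN`` and are logged; they are excluded
    from downstream autocorrelation analyses rather than treated as zero.
    """
    out = layer.copy()
    for i in range(out.n):
        if out.population[i] > 0:
            out.pp[i] = period_prevalence(int(out.cases[i]), int(out.population[i]))
        else:
            out.pp[i] = np.nan
            logger.warning(
                "unit %s has zero population; prevalence undefined, excluded",
                out.unit_ids[i],
            )
    return out


def prevalence_table(layer: SpatialUnitLayer, rounded: bool = True) -> pd.DataFrame:
    """Per-unit report table (``unit_id,level,cases,population,pp``)."""
    layer = layer_prevalence(layer)
    df = layer.to_dataframe()[["unit_id", "level", "cases", "population", "pp"]]
    if rounded:
        df["pp"] = [
            round_half_up(v) if np.isfinite(v) else np.nan for v in df["pp"]
        ]
    return df
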