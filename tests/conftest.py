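"""Shared fixtures: small synthetic geographies built programmatically."""

import numpy as np
import pytest
from shapely.geometry import box

from geoprev import (
    PlanarPointPattern,
    SpatialUnitLayer,
    StudyWindow,
    SyntheticConfig,
    allocate_population,
    generate_districts,
)


@pytest.fixture
def unit_window():
    return StudyWindow.square(1.0)


@pytest.fixture
def km100_window():
    return StudyWindow.square(100_000.0)


def make_grid_layer(nx: int, ny: int, cell: float = 1.0, level: str = "district") -> SpatialUnitLayer:
    """Regular nx x ny grid of square units, ids G00, G01, ... row-major."""
    ids, geoms = [], []
    k = 0
    for j in range(ny):
        for i in range(nx):
            ids.append(f"G{k:02d}")
            geoms.append(box(i * cell, j * cell, (i + 1) * cell, (j + 1) * cell))
            k += 1
    return SpatialUnitLayer(ids, geoms, level=level)


@pytest.fixture
def grid2x2():
    return make_grid_layer(2, 2)


@pytest.fixture
def grid5x5():
    return make_grid_layer(5, 5)


@pytest.fixture
def small_region(km100_window):
    """25 Voronoi districts with populations, deterministic."""
    d = generate_districts(km100_window, 25, seed=11)
    return allocate_population(d, 250_000, 1.0, seed=11)


def make_marked_pattern(n: int, window: StudyWindow, seed: int, male_frac: float = 0.5) -> PlanarPointPattern:
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = window.bounds
    pts = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
    marks = np.where(rng.random(n) < male_frac, "M", "F").astype(object)
    return PlanarPointPattern(pts, window, marks)
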