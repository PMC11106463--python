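"""Grid-to-region feature aggregation.

The order of operations is fixed and deliberate: temporal statistics are
computed per cell first (annual mean and standard deviation of each
pollutant), and only then spatially averaged within region boundaries.
Reversing the order would not commute for the standard deviation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .types import GridFieldSet

logger = logging.getLogger(__name__)


def temporal_stats(series: np.ndarray, sample_std: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell temporal mean and standard deviation.

    Parameters
    ----------
    series : (n_cells, n_timesteps) array
    sample_std : use ddof=1 instead of the population convention (ddof=0).
        Population std is the default so a single timestep yields 0.

    Returns
    -------
    (mean, std) arrays of shape (n_cells,)
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] < 1:
        raise InvalidInputError("series must be (n_cells, n_timesteps) with >= 1 timestep")
    bad = ~np.isfinite(series)
    if bad.any():
        cell, t = np.argwhere(bad)[0]
        raise InvalidInputError(f"non-finite value in series at cell {cell}, timestep {t}")
    ddof = 1 if sample_std else 0
    if ddof == 1 and series.shape[1] < 2:
        raise InvalidInputError("sample std needs >= 2 timesteps")
    return series.mean(axis=1), series.std(axis=1, ddof=ddof)


def zonal_mean(values: np.ndarray, membership: np.ndarray) -> pd.Series:
    """Unweighted arithmetic mean of member-cell values per region.

    Returns a Series indexed by region id, sorted by id. Regions are the
    distinct ids occurring in ``membership``; an explicit empty region can
    only arise through ``expected_regions``.
    """
    values = np.asarray(values, dtype=float)
    membership = np.asarray(membership)
    if values.shape != membership.shape:
        raise InvalidInputError("values and membership must align cell-wise")
    s = pd.Series(values).groupby(pd.Series(membership)).mean()
    s.index.name = "region_id"
    return s.sort_index()


def build_exposure_features(grid: GridFieldSet, sample_std: bool = False) -> pd.DataFrame:
    """FeatureMatrix of exposure features: "mean p" and "std p" per pollutant.

    Each is the zonal mean of the corresponding per-cell temporal statistic
    (temporal first, spatial second). Rows indexed by region_id.
    """
    grid.validate()
    cols: dict[str, pd.Series] = {}
    for name, series in grid.series.items():
        m, s = temporal_stats(series, sample_std=sample_std)
        cols[f"mean {name}"] = zonal_mean(m, grid.membership)
        cols[f"std {name}"] = zonal_mean(s, grid.membership)
    df = pd.DataFrame(cols)
    df.index.name = "region_id"
    return df


def assign_cells(cell_coords: np.ndarray, region_polygons: dict) -> np.ndarray:
    """Assign each cell to the region whose polygon contains its center.

    ``region_polygons`` maps region id -> shapely geometry. Cells outside
    every polygon get membership -1 and are counted in a log line; a region
    that captures no cell at all is a hard error (too small for the grid).
    """
    from shapely.geometry import Point

    cell_coords = np.asarray(cell_coords, dtype=float)
    membership = np.full(len(cell_coords), -1, dtype=int)
    ids = list(region_polygons)
    for i, (x, y) in enumerate(cell_coords):
        pt = Point(x, y)
        for rid in ids:
            if region_polygons[rid].covers(pt):  # interior or boundary
                membership[i] = rid
                break
    n_dropped = int((membership == -1).sum())
    if n_dropped:
        logger.info("assign_cells: %d cells outside all polygons, dropped", n_dropped)
    assigned = set(membership[membership != -1].tolist())
    missing = [rid for rid in ids if rid not in assigned]
    if missing:
        raise InvalidInputError(
            f"regions {missing} contain no cell centers (region smaller than grid resolution)"
        )
    return membership
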