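"""In-memory containers passed between pipeline stages.

All tabular data is keyed by ``region_id``; grids carry an explicit
cell -> region membership so zonal statistics never guess geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GridFieldSet:
    """Per-cell exposure time series on a regular grid.

    Attributes
    ----------
    cell_ids : (n_cells,) int array
    cell_coords : (n_cells, 2) array, cell-center x/y (or lon/lat)
    series : mapping pollutant name -> (n_cells, n_timesteps) array
    membership : (n_cells,) int array, region id per cell
    """

    cell_ids: np.ndarray
    cell_coords: np.ndarray
    series: dict[str, np.ndarray]
    membership: np.ndarray

    def validate(self) -> None:
        n = len(self.cell_ids)
        if self.cell_coords.shape != (n, 2):
            raise ValueError("cell_coords must be (n_cells, 2)")
        if self.membership.shape != (n,):
            raise ValueError("membership must cover every cell")
        n_t = {s.shape for s in self.series.values()}
        if len(n_t) > 1:
            raise ValueError("all pollutant series must share the (cell, time) shape")
        for name, s in self.series.items():
            if s.shape[0] != n:
                raise ValueError(f"series {name!r} has {s.shape[0]} cells, expected {n}")

    @property
    def n_timesteps(self) -> int:
        return next(iter(self.series.values())).shape[1]


@dataclass
class RegionTable:
    """Regions with centroids, age-stratified populations and observed deaths."""

    region_ids: np.ndarray           # (n_regions,)
    centroids: np.ndarray            # (n_regions, 2)
    population: np.ndarray           # (n_regions, n_age_classes), person counts
    age_classes: list[str]
    observed_deaths: np.ndarray      # (n_regions,) int
    cluster_labels: np.ndarray | None = None

    def validate(self) -> None:
        n = len(self.region_ids)
        if np.any(self.population < 0):
            raise ValueError("populations must be non-negative")
        if np.any(self.observed_deaths < 0):
            raise ValueError("observed deaths must be non-negative")
        if self.population.shape != (n, len(self.age_classes)):
            raise ValueError("population must be (n_regions, n_age_classes)")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "region_id": self.region_ids,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "observed_deaths": self.observed_deaths,
            }
        )
        if self.cluster_labels is not None:
            df["cluster"] = self.cluster_labels
        return df


@dataclass
class SMRTable:
    """Observed, expected, SMR and outlier flag per region."""

    frame: pd.DataFrame  # columns: region_id, observed, expected, smr, outlier

    def retained(self) -> pd.DataFrame:
        return self.frame[~self.frame["outlier"]]


@dataclass
class Semivariogram:
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    gamma: np.ndarray          # NaN in empty bins
    pair_counts: np.ndarray
    sill_estimate: float
    range_estimate: float | None = None
    converged: bool | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "gamma": self.gamma,
                "pair_count": self.pair_counts,
            }
        )


@dataclass
class BlockAssignment:
    region_ids: np.ndarray
    labels: np.ndarray          # contiguous 0..n_blocks-1
    cut_distance: float
    linkage_name: str
    n_blocks: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region_id": self.region_ids, "block": self.labels})


@dataclass
class CVResult:
    region_ids: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    fold_ids: np.ndarray
    r2_pooled: float
    mae_pooled: float
    r2_per_fold: np.ndarray     # NaN where undefined (constant truth in fold)
    mae_per_fold: np.ndarray
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "fold": self.fold_ids,
                "y_true": self.y_true,
                "y_pred": self.y_pred,
            }
        )


@dataclass
class ShapleyMatrix:
    region_ids: np.ndarray
    feature_names: list[str]
    phi: np.ndarray             # (n_regions, n_features), target units
    base_value: float
    method: str                 # "exact" | "tree"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.phi, columns=self.feature_names)
        df.insert(0, "region_id", self.region_ids)
        return df


@dataclass
class SyntheticWorld:
    """A complete simulated study: grid, regions, features and ground truth."""

    grid: GridFieldSet
    regions: RegionTable
    features: pd.DataFrame       # index region_id, one column per feature
    true_betas: np.ndarray       # full-length, zeros at inactive features
    true_range: float
    expected_deaths: np.ndarray = field(default=None)  # type: ignore[assignment]
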