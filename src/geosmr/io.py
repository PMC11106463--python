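"""Readers and writers for the pipeline's interchange formats.

All tabular interchange is CSV keyed by ``region_id``; grid series travel
as long CSV (cell_id, x, y, t, value per pollutant); geometries are
GeoJSON. Write-then-read round-trips preserve identifiers exactly and
values to float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .types import BlockAssignment, GridFieldSet, ShapleyMatrix, SMRTable


def write_feature_table(df: pd.DataFrame, path) -> None:
    out = df.reset_index() if df.index.name == "region_id" else df
    out.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "region_id" not in df.columns:
        raise InvalidInputError(f"{path}: missing region_id column")
    if df["region_id"].duplicated().any():
        dup = df["region_id"][df["region_id"].duplicated()].iloc[0]
        raise InvalidInputError(f"{path}: duplicated region_id {dup!r}")
    if df.columns.duplicated().any():
        raise InvalidInputError(f"{path}: duplicated feature names")
    return df.set_index("region_id")


def write_smr_table(table: SMRTable, path) -> None:
    table.frame.to_csv(path, index=False)


def read_smr_table(path) -> SMRTable:
    df = pd.read_csv(path)
    required = {"region_id", "observed", "expected", "smr", "outlier"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    if df["region_id"].duplicated().any():
        raise InvalidInputError(f"{path}: duplicated region_id")
    df["outlier"] = df["outlier"].astype(bool)
    return SMRTable(frame=df)


def write_blocks(assignment: BlockAssignment, path) -> None:
    assignment.to_frame().to_csv(path, index=False)


def read_blocks(path, cut_distance: float = float("nan"), linkage_name: str = "") -> BlockAssignment:
    df = pd.read_csv(path)
    labels = df["block"].to_numpy(dtype=int)
    return BlockAssignment(
        region_ids=df["region_id"].to_numpy(),
        labels=labels,
        cut_distance=cut_distance,
        linkage_name=linkage_name,
        n_blocks=int(labels.max()) + 1,
    )


def write_shapley(sm: ShapleyMatrix, path_csv, path_json=None) -> None:
    sm.to_frame().to_csv(path_csv, index=False)
    if path_json is not None:
        with open(path_json, "w") as fh:
            json.dump(
                {"base_value": sm.base_value, "method": sm.method},
                fh, indent=2, sort_keys=True,
            )


def read_shapley(path_csv, base_value: float = float("nan"), method: str = "") -> ShapleyMatrix:
    df = pd.read_csv(path_csv)
    feats = [c for c in df.columns if c != "region_id"]
    return ShapleyMatrix(
        region_ids=df["region_id"].to_numpy(),
        feature_names=feats,
        phi=df[feats].to_numpy(dtype=float),
        base_value=base_value,
        method=method,
    )


def write_grid_long(grid: GridFieldSet, path) -> None:
    """Grid series as long CSV: cell_id, x, y, region_id, pollutant, t, value."""
    frames = []
    n_t = grid.n_timesteps
    for name, series in grid.series.items():
        df = pd.DataFrame(
            {
                "cell_id": np.repeat(grid.cell_ids, n_t),
                "x": np.repeat(grid.cell_coords[:, 0], n_t),
                "y": np.repeat(grid.cell_coords[:, 1], n_t),
                "region_id": np.repeat(grid.membership, n_t),
                "pollutant": name,
                "t": np.tile(np.arange(n_t), len(grid.cell_ids)),
                "value": series.ravel(),
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_grid_long(path) -> GridFieldSet:
    df = pd.read_csv(path)
    cells = df[["cell_id", "x", "y", "region_id"]].drop_duplicates("cell_id").sort_values("cell_id")
    cell_ids = cells["cell_id"].to_numpy()
    order = {c: i for i, c in enumerate(cell_ids)}
    n_t = df["t"].nunique()
    series = {}
    for name, sub in df.groupby("pollutant"):
        arr = np.empty((len(cell_ids), n_t))
        sub = sub.sort_values(["cell_id", "t"])
        arr[[order[c] for c in sub["cell_id"].unique()]] = (
            sub["value"].to_numpy().reshape(-1, n_t)
        )
        series[name] = arr
    return GridFieldSet(
        cell_ids=cell_ids,
        cell_coords=cells[["x", "y"]].to_numpy(dtype=float),
        series=series,
        membership=cells["region_id"].to_numpy(dtype=int),
    )


def write_regions_geojson(membership: np.ndarray, cell_coords: np.ndarray, path) -> None:
    """Regions as GeoJSON polygons: union of unit cells per region."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    features = []
    for rid in np.unique(membership):
        cells = cell_coords[membership == rid]
        geom = unary_union([box(x - 0.5, y - 0.5, x + 0.5, y + 0.5) for x, y in cells])
        features.append(
            {
                "type": "Feature",
                "properties": {"region_id": int(rid)},
                "geometry": mapping(geom),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_regions_geojson(path) -> dict:
    """region_id -> shapely geometry; rejects features lacking geometry."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    polys = {}
    for feat in gj["features"]:
        rid = feat.get("properties", {}).get("region_id")
        if feat.get("geometry") is None:
            raise InvalidInputError(f"region {rid!r} has no geometry")
        polys[rid] = shape(feat["geometry"])
    return polys


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config_yaml(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
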