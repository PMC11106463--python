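"""Aggregate gridded exposures into region features and standardize mortality.

Reads the raw world files written by 01, computes per-cell temporal mean
and standard deviation of each pollutant, spatially averages them within
region boundaries, then derives expected deaths by indirect standardization
and the SMR per region, flagging Tukey-fence outliers. Writes features.csv
and smr.csv under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from geosmr import io as gio
from geosmr.standardize import build_smr_table
from geosmr.types import RegionTable
from geosmr.zonal import build_exposure_features

parser = argparse.ArgumentParser()
parser.add_argument("--world", type=Path, default=Path("results/world"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

grid = gio.read_grid_long(args.world / "grid.csv")
features = build_exposure_features(grid)
socio = gio.read_feature_table(args.world / "socio.csv")
features = features.join(socio)
gio.write_feature_table(features, args.out / "features.csv")

regions_df = pd.read_csv(args.world / "regions.csv")
pop = pd.read_csv(args.world / "population.csv").pivot(
    index="region_id", columns="age_class", values="population"
)
rates = pd.read_csv(args.world / "national_rates.csv").set_index("age_class")["rate"]
pop = pop[rates.index]  # align age axes
regions = RegionTable(
    region_ids=regions_df["region_id"].to_numpy(),
    centroids=regions_df[["x", "y"]].to_numpy(),
    population=pop.loc[regions_df["region_id"]].to_numpy(),
    age_classes=list(rates.index),
    observed_deaths=regions_df["observed_deaths"].to_numpy(),
)
table = build_smr_table(regions, rates.to_numpy())
gio.write_smr_table(table, args.out / "smr.csv")

f = table.frame
print(f"feature matrix: {features.shape[1]} columns "
      f"({features.shape[1] - socio.shape[1]} exposure + {socio.shape[1]} socio-economic) "
      f"x {features.shape[0]} regions")
print(f"SMR: mean={f['smr'].mean():.3f}, sd={f['smr'].std():.3f}, "
      f"range [{f['smr'].min():.3f}, {f['smr'].max():.3f}]")
print(f"outliers flagged (Tukey k=1.5): {int(f['outlier'].sum())} of {len(f)} regions")
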