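import numpy as np
import pytest

import geosmr
from geosmr.blocks import cluster_regions
from geosmr.geostat import pairwise_distances
from geosmr.standardize import build_smr_table
from geosmr.synth import SyntheticConfig


def modelling_frame(world, config):
    """Retained (non-outlier) regions: features x, SMR y, centroids, ids."""
    tab = build_smr_table(world.regions, np.asarray(config.national_rates)).retained()
    keep = tab["region_id"].to_numpy()
    mask = np.isin(world.regions.region_ids, keep)
    return world.features.loc[keep], tab["smr"].to_numpy(), world.regions.centroids[mask], keep


def leakage_cv_gap(seed, k_random=10):
    """Spatial-vs-random CV comparison on one leakage world, blocks cut at
    the generating decorrelation scale."""
    cfg = geosmr.leakage_config(seed)
    world = geosmr.build_world(cfg)
    x, y, centroids, keep = modelling_frame(world, cfg)
    distmat = pairwise_distances(centroids)
    assignment = cluster_regions(distmat, cfg.confounder_range, region_ids=keep)
    return geosmr.compare_cv_schemes(x, y, assignment, k_random=k_random, n_repeats=1, seed=seed)


@pytest.fixture(scope="session")
def small_world():
    """A compact world reused by read-only tests."""
    cfg = SyntheticConfig(
        grid_side=10, n_regions=12, n_timesteps=20, grf_range=4.0,
        n_pollutants=2, n_features=8, active_features=(0,), betas=(0.3,), seed=42,
    )
    return cfg, geosmr.build_world(cfg)
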