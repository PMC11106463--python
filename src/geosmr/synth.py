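"""Synthetic worlds with known spatial structure.

The generator produces everything the real pipeline consumes — spatially
autocorrelated exposure surfaces on a regular grid, contiguous regions
partitioning it, age-structured populations and Poisson death counts whose
log relative risk is linear in a known subset of standardized region-level
features — so every downstream stage can be tested against ground truth.

Exposure surfaces are Gaussian random fields with exponential covariance

    C(d) = sill * exp(-3 d / range),

i.e. ``range`` is the *effective* range at which correlation drops to 5%.
An optional hidden spatial confounder can drive mortality through a field
that is *not* exposed as a feature, which is the mechanism that creates
spatial leakage for cross-validation studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError, NumericalError
from .types import GridFieldSet, RegionTable, SyntheticWorld

_NEIGHBOURS = ((1, 0), (-1, 0), (0, 1), (0, -1))


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic world.

    Distances are in grid-cell units (cell centers sit at integer
    coordinates). ``national_rates`` are deaths per person-year per age
    class; populations are drawn so that expected deaths per region are in
    the low hundreds, comparable to province-level annual counts for a
    common cancer site.
    """

    grid_side: int = 20
    n_regions: int = 60
    n_timesteps: int = 60
    grf_range: float = 8.0
    grf_sill: float = 1.0
    grf_nugget: float = 0.05
    n_pollutants: int = 3
    n_features: int = 15
    active_features: tuple[int, ...] = ()
    betas: tuple[float, ...] = ()
    n_age_classes: int = 5
    national_rates: tuple[float, ...] = (0.0002, 0.0005, 0.002, 0.008, 0.03)
    mean_region_population: float = 60_000.0
    temporal_sd: float = 1.0
    heteroscedastic: bool = True
    # hidden spatial confounder driving mortality outside the feature set
    confounder_beta: float = 0.0
    confounder_range: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.grid_side < 1:
            raise InvalidConfigError("grid_side must be >= 1")
        if not (1 <= self.n_regions <= self.grid_side**2):
            raise InvalidConfigError(
                f"n_regions={self.n_regions} outside [1, {self.grid_side**2}]"
            )
        if self.grf_range <= 0 or self.grf_sill <= 0:
            raise InvalidConfigError("grf_range and grf_sill must be positive")
        if self.grf_nugget < 0:
            raise InvalidConfigError("grf_nugget must be non-negative")
        if self.n_features < 2 * self.n_pollutants:
            raise InvalidConfigError(
                "n_features must cover the 2 * n_pollutants exposure features"
            )
        if len(self.betas) != len(self.active_features):
            raise InvalidConfigError("betas must have one entry per active feature")
        if any(not (0 <= j < self.n_features) for j in self.active_features):
            raise InvalidConfigError("active_features must lie in [0, n_features)")
        if len(self.national_rates) != self.n_age_classes:
            raise InvalidConfigError("national_rates must have one entry per age class")
        if any(not (0.0 < r < 1.0) for r in self.national_rates):
            raise InvalidConfigError("national_rates must lie in (0, 1)")
        if self.n_timesteps < 1:
            raise InvalidConfigError("n_timesteps must be >= 1")


def grid_coords(grid_side: int) -> np.ndarray:
    """Cell-center coordinates of a grid_side x grid_side grid, row-major."""
    ii, jj = np.meshgrid(np.arange(grid_side), np.arange(grid_side), indexing="ij")
    return np.column_stack([jj.ravel().astype(float), ii.ravel().astype(float)])


def make_regions(grid_side: int, n_regions: int, seed: int | np.random.Generator) -> np.ndarray:
    """Partition the grid into contiguous regions by random seeded accretion.

    Seeds ``n_regions`` distinct cells, then repeatedly assigns a uniformly
    chosen unassigned cell that touches an assigned one (4-neighbour
    adjacency) to the region of a random assigned neighbour. Every region is
    connected by construction.

    Returns the (grid_side**2,) membership array, row-major cell order.
    """
    n_cells = grid_side * grid_side
    if not (1 <= n_regions <= n_cells):
        raise InvalidConfigError(f"n_regions={n_regions} outside [1, {n_cells}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    membership = np.full((grid_side, grid_side), -1, dtype=int)
    seeds = rng.choice(n_cells, size=n_regions, replace=False)
    for rid, c in enumerate(seeds):
        membership[c // grid_side, c % grid_side] = rid

    n_assigned = n_regions
    while n_assigned < n_cells:
        # all (unassigned cell, assigned neighbour region) candidate accretions
        frontier: list[tuple[int, int, int]] = []
        for i in range(grid_side):
            for j in range(grid_side):
                if membership[i, j] != -1:
                    continue
                for di, dj in _NEIGHBOURS:
                    ni, nj = i + di, j + dj
                    if 0 <= ni < grid_side and 0 <= nj < grid_side and membership[ni, nj] != -1:
                        frontier.append((i, j, membership[ni, nj]))
        i, j, rid = frontier[rng.integers(len(frontier))]
        membership[i, j] = rid
        n_assigned += 1
    return membership.ravel()


def simulate_grf(
    cell_coords: np.ndarray,
    range_: float,
    sill: float,
    nugget: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One draw of a zero-mean GRF with exponential covariance plus nugget.

    Covariance C(d) = sill * exp(-3 d / range_); the factor 3 makes
    ``range_`` the effective range (5% residual correlation). Dense Cholesky
    factorization — intended for desk-scale grids (<= a few thousand cells).
    """
    if range_ <= 0 or sill <= 0:
        raise InvalidConfigError("range and sill must be positive")
    if nugget < 0:
        raise InvalidConfigError("nugget must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    from scipy.spatial.distance import squareform, pdist

    n = len(cell_coords)
    d = squareform(pdist(cell_coords))
    cov = sill * np.exp(-3.0 * d / range_)
    jitter = 1e-10 * sill
    for _ in range(4):
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter *= 100
    else:
        raise NumericalError(
            f"covariance not positive definite after jitter up to {jitter:g} "
            f"(n={n}, range={range_}, sill={sill})"
        )
    z = chol @ rng.standard_normal(n)
    if nugget > 0:
        z = z + np.sqrt(nugget) * rng.standard_normal(n)
    return z


def simulate_exposure_series(
    base_field: np.ndarray,
    n_timesteps: int,
    temporal_sd: float | np.ndarray,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Daily series per cell: base field plus iid temporal noise.

    ``temporal_sd`` may be a scalar or a per-cell array (heteroscedastic
    noise), so the per-cell temporal s.d. can itself carry spatial signal.
    """
    if n_timesteps < 1:
        raise InvalidConfigError("n_timesteps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = np.asarray(base_field, dtype=float)
    sd = np.broadcast_to(np.asarray(temporal_sd, dtype=float), base.shape)
    noise = rng.standard_normal((base.shape[0], n_timesteps)) * sd[:, None]
    return base[:, None] + noise


def simulate_mortality(
    expected: np.ndarray,
    features_std: np.ndarray,
    betas: np.ndarray,
    active: np.ndarray,
    seed: int | np.random.Generator,
    extra_log_rr: np.ndarray | None = None,
) -> np.ndarray:
    """Poisson deaths per region with log-linear relative risk.

    deaths_i ~ Poisson(E_i * exp(sum_{j in active} beta_j x_ij [+ extra_i]))
    where x are *standardized* feature columns. ``extra_log_rr`` plants an
    additional log relative-risk term (e.g. a hidden spatial confounder).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise InvalidInputError("expected deaths must be non-negative")
    eta = np.zeros(len(expected))
    if len(active):
        eta += features_std[:, np.asarray(active, dtype=int)] @ np.asarray(betas, dtype=float)
    if extra_log_rr is not None:
        eta += extra_log_rr
    rr = np.exp(eta)
    if np.any((expected == 0) & (rr > 0)):
        warnings.warn("region with zero expected deaths: simulated deaths will be 0")
    return rng.poisson(expected * rr).astype(int)


def _region_populations(
    n_regions: int, n_age: int, mean_pop: float, rng: np.random.Generator
) -> np.ndarray:
    """Age-structured populations: lognormal totals, Dirichlet age shares."""
    totals = mean_pop * rng.lognormal(mean=0.0, sigma=0.35, size=n_regions)
    base_shares = np.linspace(2.0, 1.0, n_age)  # mildly younger-heavy pyramid
    shares = rng.dirichlet(base_shares * 20, size=n_regions)
    return totals[:, None] * shares


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def build_world(config: SyntheticConfig) -> SyntheticWorld:
    """Compose the full synthetic study; deterministic given ``config.seed``."""
    from .standardize import expected_deaths
    from .zonal import build_exposure_features, zonal_mean

    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_regions, rng_fields, rng_noise, rng_pop, rng_deaths, rng_conf = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    coords = grid_coords(config.grid_side)
    membership = make_regions(config.grid_side, config.n_regions, rng_regions)

    series: dict[str, np.ndarray] = {}
    for p in range(config.n_pollutants):
        base = simulate_grf(
            coords, config.grf_range, config.grf_sill, config.grf_nugget, rng_fields
        )
        if config.heteroscedastic:
            log_sd_field = simulate_grf(coords, config.grf_range, 1.0, 0.0, rng_fields)
            sd = config.temporal_sd * np.exp(0.5 * log_sd_field)
        else:
            sd = config.temporal_sd
        series[f"pol{p + 1}"] = simulate_exposure_series(
            base, config.n_timesteps, sd, rng_fields
        )

    grid = GridFieldSet(
        cell_ids=np.arange(config.grid_side**2),
        cell_coords=coords,
        series=series,
        membership=membership,
    )
    grid.validate()

    exposure = build_exposure_features(grid)  # index region_id
    region_ids = exposure.index.to_numpy()
    n_noise = config.n_features - exposure.shape[1]
    noise_cols = {
        f"socio{k + 1}": rng_noise.standard_normal(config.n_regions) for k in range(n_noise)
    }
    features = pd.concat([exposure, pd.DataFrame(noise_cols, index=exposure.index)], axis=1)

    centroids = np.column_stack(
        [
            zonal_mean(coords[:, 0], membership).to_numpy(),
            zonal_mean(coords[:, 1], membership).to_numpy(),
        ]
    )

    population = _region_populations(
        config.n_regions, config.n_age_classes, config.mean_region_population, rng_pop
    )
    rates = np.asarray(config.national_rates)
    expected = expected_deaths(population, rates)

    extra = None
    if config.confounder_beta != 0.0:
        conf_field = simulate_grf(coords, config.confounder_range, 1.0, 0.0, rng_conf)
        conf_region = zonal_mean(conf_field, membership).to_numpy()
        conf_region = (conf_region - conf_region.mean()) / conf_region.std(ddof=0)
        extra = config.confounder_beta * conf_region

    x_std = _standardize(features.to_numpy())
    deaths = simulate_mortality(
        expected,
        x_std,
        np.asarray(config.betas, dtype=float),
        np.asarray(config.active_features, dtype=int),
        rng_deaths,
        extra_log_rr=extra,
    )

    true_betas = np.zeros(config.n_features)
    for j, b in zip(config.active_features, config.betas):
        true_betas[j] = b

    regions = RegionTable(
        region_ids=region_ids,
        centroids=centroids,
        population=population,
        age_classes=[f"age{a}" for a in range(config.n_age_classes)],
        observed_deaths=deaths,
    )
    regions.validate()

    return SyntheticWorld(
        grid=grid,
        regions=regions,
        features=features,
        true_betas=true_betas,
        true_range=config.grf_range,
        expected_deaths=expected,
    )


def leakage_config(seed: int) -> SyntheticConfig:
    """Study conditions for the spatial-leakage demonstration.

    The target is driven only by a hidden smooth spatial field; the observed
    features are spatially autocorrelated but causally unrelated to it, so
    any skill under random CV is leakage through spatial proximity.
    """
    return SyntheticConfig(
        grid_side=20,
        n_regions=60,
        grf_range=10.0,
        confounder_beta=0.5,
        confounder_range=10.0,
        seed=seed,
    )


def recovery_config(seed: int, beta: float = 0.3) -> SyntheticConfig:
    """Study conditions for planted-feature recovery: 2 active of 15."""
    return SyntheticConfig(
        grid_side=20,
        n_regions=60,
        active_features=(0, 2),
        betas=(beta, -beta),
        seed=seed,
    )
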