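"""End-to-end driver: simulate/load -> aggregate -> standardize -> variogram
-> blocks -> blocked CV -> CV-scheme comparison -> attribution -> report.

Every stage writes its artifact into the run directory and the manifest
records a checksum per artifact plus the master seed, so a rerun with the
same configuration is bit-identical and auditable. One master seed fans
out to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as gio
from .blocks import block_summary, cluster_regions
from .errors import GeoSMRError, PipelineStageError
from .explain import global_rank, shapley_all_regions
from .geostat import default_bin_edges, empirical_semivariogram, estimate_range, pairwise_distances
from .regression import (
    compare_cv_schemes,
    fit_full,
    fit_predict_cv,
    locv_folds,
    permutation_importance_table,
)
from .standardize import build_smr_table
from .synth import SyntheticConfig, build_world
from .types import BlockAssignment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to YAML."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    outlier_k: float = 1.5
    metric: str = "euclidean"
    n_bins: int = 15
    sill_threshold: float = 0.95
    smooth_window: int = 3
    range_override: float | None = None
    linkage: str = "complete"
    model_config: dict = field(default_factory=dict)
    importance_repeats: int = 10
    k_random: int = 10
    cv_repeats: int = 1
    explain_method: str = "tree"
    background_cap: int = 100
    seed: int = 0
    write_grid: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small fully synthetic run exercising every stage in seconds."""
    synth = SyntheticConfig(
        grid_side=12,
        n_regions=30,
        n_timesteps=30,
        grf_range=5.0,
        n_pollutants=2,
        n_features=8,
        active_features=(0, 2),
        betas=(0.3, -0.3),
        confounder_beta=0.3,
        confounder_range=5.0,
        seed=seed,
    )
    return PipelineConfig(synthetic=synth, seed=seed, model_config={"n_estimators": 100})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage, returning the manifest dictionary.

    A stage failure aborts with the stage name; artifacts written so far
    are retained for inspection.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "setup"

    def _write(name, writer, *args):
        path = out / name
        writer(*args, path)
        artifacts.append(path)
        logger.info("[%s] wrote %s", stage, path.name)
        return path

    try:
        stage = "simulate"
        world = build_world(config.synthetic)
        if config.write_grid:
            _write("grid.csv", lambda g, p: gio.write_grid_long(g, p), world.grid)
        _write(
            "regions.geojson",
            lambda m, c, p: gio.write_regions_geojson(m, c, p),
            world.grid.membership,
            world.grid.cell_coords,
        )

        stage = "aggregate"
        features = world.features
        _write("features.csv", lambda f, p: gio.write_feature_table(f, p), features)

        stage = "standardize"
        smr_table = build_smr_table(
            world.regions, np.asarray(config.synthetic.national_rates), config.outlier_k
        )
        _write("smr.csv", lambda t, p: gio.write_smr_table(t, p), smr_table)
        retained = smr_table.retained()
        keep = retained["region_id"].to_numpy()
        mask = np.isin(world.regions.region_ids, keep)
        y = retained["smr"].to_numpy()
        x = features.loc[keep]
        centroids = world.regions.centroids[mask]

        stage = "variogram"
        distmat = pairwise_distances(centroids, metric=config.metric)
        sv = empirical_semivariogram(y, distmat, default_bin_edges(distmat, config.n_bins))
        sv = estimate_range(sv, config.sill_threshold, config.smooth_window)
        cut = config.range_override if config.range_override is not None else sv.range_estimate
        sv.to_frame().to_csv(out / "variogram.csv", index=False)
        artifacts.append(out / "variogram.csv")
        gio.write_json(
            {
                "sill": sv.sill_estimate,
                "range": sv.range_estimate,
                "converged": sv.converged,
                "cut_distance": cut,
            },
            out / "variogram.json",
        )
        artifacts.append(out / "variogram.json")

        stage = "blocks"
        assignment = cluster_regions(distmat, cut, config.linkage, region_ids=keep)
        _write("blocks.csv", lambda a, p: gio.write_blocks(a, p), assignment)
        block_summary(assignment, distmat).to_csv(out / "block_summary.csv", index=False)
        artifacts.append(out / "block_summary.csv")

        stage = "fit"
        cv = fit_predict_cv(x, y, locv_folds(assignment), config.model_config, config.seed)
        cv.to_frame().to_csv(out / "cv_predictions.csv", index=False)
        artifacts.append(out / "cv_predictions.csv")
        gio.write_json(
            {
                "r2_pooled": cv.r2_pooled,
                "mae_pooled": cv.mae_pooled,
                "r2_per_fold_mean": float(np.nanmean(cv.r2_per_fold)),
                "mae_per_fold_mean": float(np.mean(cv.mae_per_fold)),
                "n_blocks": assignment.n_blocks,
                "seed": config.seed,
            },
            out / "metrics.json",
        )
        artifacts.append(out / "metrics.json")

        stage = "importance"
        model = fit_full(x, y, config.model_config, config.seed)
        imp = permutation_importance_table(
            model, x, y, n_repeats=config.importance_repeats, seed=config.seed
        )
        imp.to_csv(out / "importance.csv", index=False)
        artifacts.append(out / "importance.csv")

        stage = "compare_cv"
        cmp = compare_cv_schemes(
            x, y, assignment,
            k_random=min(config.k_random, len(y)),
            n_repeats=config.cv_repeats,
            seed=config.seed,
            model_config=config.model_config,
        )
        gio.write_json(
            {
                "r2_spatial": cmp.r2_spatial,
                "r2_random": cmp.r2_random,
                "gap": cmp.gap,
                "mae_spatial": cmp.mae_spatial,
                "mae_random": cmp.mae_random,
            },
            out / "cv_comparison.json",
        )
        artifacts.append(out / "cv_comparison.json")

        stage = "explain"
        sm = shapley_all_regions(
            model, x,
            method=config.explain_method,
            background_cap=config.background_cap,
            seed=config.seed,
        )
        gio.write_shapley(sm, out / "shapley.csv", out / "shapley.json")
        artifacts.extend([out / "shapley.csv", out / "shapley.json"])
        global_rank(sm).to_csv(out / "shapley_ranking.csv", index=False)
        artifacts.append(out / "shapley_ranking.csv")

        stage = "report"
        manifest = {
            "seed": config.seed,
            "config": config.to_dict(),
            "artifacts": {p.name: _sha256(p) for p in artifacts},
        }
        gio.write_json(manifest, out / "manifest.json")
        return manifest
    except GeoSMRError as exc:
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, str(exc)) from exc
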