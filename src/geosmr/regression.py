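"""Random-forest regression of SMR under leave-one-block-out CV.

The learner is an ensemble of decision trees with library defaults (the
point of the analysis is the validation scheme, not the model). Headline
metrics are pooled over the concatenated out-of-fold predictions; per-fold
metrics are also kept, since per-fold r-squared on small folds is unstable.

``compare_cv_schemes`` quantifies spatial leakage: the same data scored
under spatially blocked CV and under randomly shuffled k-fold CV, whose
difference in r-squared is the optimism induced by splitting spatial
neighbours across train and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .errors import InvalidInputError
from .types import BlockAssignment, CVResult


def r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot; may be negative."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) < 2:
        raise InvalidInputError("r2 needs n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise InvalidInputError("r2 undefined for constant y")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def mae(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute error (1/n) sum |y_i - y_hat_i|."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) < 1:
        raise InvalidInputError("mae needs n >= 1")
    return float(np.mean(np.abs(y - y_hat)))


def locv_folds(assignment: BlockAssignment) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-block-out folds: (train indices, validation indices) per block."""
    if assignment.n_blocks < 2:
        raise InvalidInputError("need >= 2 blocks for cross-validation")
    folds = []
    idx = np.arange(len(assignment.labels))
    for b in range(assignment.n_blocks):
        val = idx[assignment.labels == b]
        train = idx[assignment.labels != b]
        folds.append((train, val))
    return folds


def _fold_seed(master_seed: int, fold: int) -> int:
    # fixed counter scheme so folds are independently reproducible
    return (master_seed * 100_003 + 7919 * fold + 1) % (2**31)


def make_model(model_config: dict | None, seed: int) -> RandomForestRegressor:
    cfg = dict(model_config or {})
    return RandomForestRegressor(random_state=seed, **cfg)


def fit_predict_cv(
    features: pd.DataFrame,
    target: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    model_config: dict | None = None,
    seed: int = 0,
) -> CVResult:
    """One regressor per fold, trained on the training regions only.

    ``features`` is indexed by region_id; ``target`` aligns with its rows.
    Every region is predicted exactly once, out of fold.
    """
    y = np.asarray(target, dtype=float)
    if len(y) != len(features):
        raise InvalidInputError("feature and target region counts differ")
    x = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("missing or non-finite feature values")

    n = len(y)
    y_pred = np.full(n, np.nan)
    fold_ids = np.full(n, -1, dtype=int)
    covered = np.zeros(n, dtype=bool)
    r2_f, mae_f = [], []
    for k, (train, val) in enumerate(folds):
        if covered[val].any():
            raise InvalidInputError("folds overlap: a region appears in two validation sets")
        model = make_model(model_config, _fold_seed(seed, k))
        model.fit(x[train], y[train])
        y_pred[val] = model.predict(x[val])
        fold_ids[val] = k
        covered[val] = True
        mae_f.append(mae(y[val], y_pred[val]))
        if len(val) >= 2 and np.ptp(y[val]) > 0:
            r2_f.append(r2(y[val], y_pred[val]))
        else:
            r2_f.append(np.nan)
    if not covered.all():
        raise InvalidInputError("folds do not cover every region")

    # pooled r2 is undefined for a constant target (SS_tot = 0): report NaN
    r2_pooled = r2(y, y_pred) if np.ptp(y) > 0 else float("nan")
    return CVResult(
        region_ids=features.index.to_numpy(),
        y_true=y,
        y_pred=y_pred,
        fold_ids=fold_ids,
        r2_pooled=r2_pooled,
        mae_pooled=mae(y, y_pred),
        r2_per_fold=np.asarray(r2_f),
        mae_per_fold=np.asarray(mae_f),
        seed=seed,
    )


def fit_full(
    features: pd.DataFrame, target: np.ndarray, model_config: dict | None = None, seed: int = 0
) -> RandomForestRegressor:
    """Full-data refit (used for attribution after CV assessment)."""
    model = make_model(model_config, _fold_seed(seed, 9999))
    model.fit(features.to_numpy(dtype=float), np.asarray(target, dtype=float))
    return model


def permutation_importance_table(
    model,
    features: pd.DataFrame,
    target: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature importance: mean r-squared degradation per feature.

    Thin wrapper over scikit-learn's permutation importance, reported as a
    ranked table. A feature the model never uses degrades nothing and gets
    importance exactly 0.
    """
    from sklearn.inspection import permutation_importance

    res = permutation_importance(
        model,
        features.to_numpy(dtype=float),
        np.asarray(target, dtype=float),
        scoring="r2",
        n_repeats=n_repeats,
        random_state=seed % (2**31),
    )
    df = pd.DataFrame(
        {
            "feature": features.columns,
            "importance_mean": res.importances_mean,
            "importance_std": res.importances_std,
        }
    )
    df["rank"] = (
        df["importance_mean"].rank(ascending=False, method="first").astype(int)
    )
    return df.sort_values("rank").reset_index(drop=True)


@dataclass
class CVComparison:
    r2_spatial: float
    r2_random: float            # mean over shuffle repeats
    gap: float                  # r2_random - r2_spatial
    r2_random_repeats: list[float] = field(default_factory=list)
    mae_spatial: float = float("nan")
    mae_random: float = float("nan")


def compare_cv_schemes(
    features: pd.DataFrame,
    target: np.ndarray,
    assignment: BlockAssignment,
    k_random: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
    model_config: dict | None = None,
) -> CVComparison:
    """Spatially blocked vs randomly shuffled k-fold CV on identical data.

    The spatial scheme is leave-one-block-out; the random scheme shuffles
    regions into ``k_random`` folds, repeated ``n_repeats`` times with
    different shuffles. Reports pooled r-squared of each and their gap.
    """
    spatial = fit_predict_cv(features, target, locv_folds(assignment), model_config, seed)
    y = np.asarray(target, dtype=float)
    r2_rand, mae_rand = [], []
    for rep in range(n_repeats):
        kf = KFold(n_splits=k_random, shuffle=True, random_state=_fold_seed(seed, 500 + rep))
        folds = [(tr, va) for tr, va in kf.split(features)]
        res = fit_predict_cv(features, target, folds, model_config, seed + 1 + rep)
        r2_rand.append(res.r2_pooled)
        mae_rand.append(res.mae_pooled)
    r2_random = float(np.mean(r2_rand))
    return CVComparison(
        r2_spatial=spatial.r2_pooled,
        r2_random=r2_random,
        gap=r2_random - spatial.r2_pooled,
        r2_random_repeats=[float(v) for v in r2_rand],
        mae_spatial=spatial.mae_pooled,
        mae_random=float(np.mean(mae_rand)),
    )
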