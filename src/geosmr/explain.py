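"""Shapley feature attributions for tree-ensemble predictions.

The attribution of feature j for an instance x is the game-theoretic value

    Phi_j(x) = sum_{F subseteq S\\{j}} |F|! (|S|-|F|-1)! / |S|!
               * [ f_x(F u {j}) - f_x(F) ]

with the interventional value function: f_x(F) is the model prediction
averaged over a background sample, with the instance's values imposed on
the coalition F and background values elsewhere. Two independent
implementations are provided:

* :func:`exact_shapley` — literal enumeration of all 2^p coalitions,
  feasible for p <= 12 and usable as an oracle for any black-box model;
* :func:`tree_shapley` — an exact polynomial-time algorithm specific to
  tree ensembles. For a single tree, background row b and instance x, the
  value function restricted to one leaf is a (weighted) unanimity game:
  the composite row reaches the leaf iff the features that must take the
  instance's value are all in the coalition (set A) and the features that
  must keep the background value are all out (set B). The Shapley value of
  such a game is closed-form — (|A|-1)!|B|!/(|A|+|B|)! per member of A and
  the negative mirror for B — and attributions sum over leaves, background
  rows and trees by linearity.

Both satisfy efficiency (base value plus attributions equals the
prediction) and the dummy axiom exactly, and agree to float precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import InvalidInputError
from .types import ShapleyMatrix

MAX_EXACT_FEATURES = 12


def _subset_weights(p: int) -> np.ndarray:
    """w[s] = s! (p-s-1)! / p! for coalition size s."""
    s = np.arange(p)
    return np.exp(gammaln(s + 1) + gammaln(p - s) - gammaln(p + 1))


def exact_shapley(
    predict_fn, instance: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float]:
    """Shapley attributions by full coalition enumeration.

    Returns (phi, base_value) with base_value = f_x(empty set), the mean
    prediction over the background. Refuses more than 12 features (2^p
    model evaluations per background row).
    """
    x = np.asarray(instance, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    p = len(x)
    if p > MAX_EXACT_FEATURES:
        raise InvalidInputError(
            f"exact enumeration capped at {MAX_EXACT_FEATURES} features "
            f"(got {p}); use the tree method"
        )
    if bg.shape[1] != p:
        raise InvalidInputError("background and instance feature counts differ")
    nb = bg.shape[0]

    n_sub = 1 << p
    composites = np.tile(bg, (n_sub, 1))
    for mask in range(n_sub):
        block = composites[mask * nb: (mask + 1) * nb]
        for j in range(p):
            if mask >> j & 1:
                block[:, j] = x[j]
    preds = np.asarray(predict_fn(composites), dtype=float)
    f = preds.reshape(n_sub, nb).mean(axis=1)  # f[mask] = value of coalition

    w = _subset_weights(p)
    popcount = np.array([bin(m).count("1") for m in range(n_sub)])
    phi = np.zeros(p)
    for mask in range(n_sub - 1):  # full coalition has no j to add
        wm = w[popcount[mask]]
        for j in range(p):
            if not (mask >> j & 1):
                phi[j] += wm * (f[mask | (1 << j)] - f[mask])
    return phi, float(f[0])


# ---------------------------------------------------------------------------
# tree-specific exact interventional algorithm


def _leaf_paths(tree_):
    """Root-to-leaf paths of an sklearn tree: (value, feats, thresholds, went_left)."""
    paths = []
    stack: list[tuple[int, list, list, list]] = [(0, [], [], [])]
    left, right = tree_.children_left, tree_.children_right
    while stack:
        node, feats, thrs, lefts = stack.pop()
        if left[node] == -1:
            paths.append(
                (
                    float(tree_.value[node].ravel()[0]),
                    np.asarray(feats, dtype=int),
                    np.asarray(thrs, dtype=float),
                    np.asarray(lefts, dtype=bool),
                )
            )
        else:
            f, t = int(tree_.feature[node]), float(tree_.threshold[node])
            stack.append((left[node], feats + [f], thrs + [t], lefts + [True]))
            stack.append((right[node], feats + [f], thrs + [t], lefts + [False]))
    return paths


def _unanimity_weight_tables(max_n: int) -> tuple[np.ndarray, np.ndarray]:
    """wA[a,b] = (a-1)! b! / (a+b)!  (0 when a=0); wB is the mirror for B."""
    a = np.arange(max_n + 1)[:, None]
    b = np.arange(max_n + 1)[None, :]
    with np.errstate(divide="ignore"):
        wa = np.exp(gammaln(a) + gammaln(b + 1) - gammaln(a + b + 1))
        wb = np.exp(gammaln(a + 1) + gammaln(b) - gammaln(a + b + 1))
    wa[0, :] = 0.0
    wb[:, 0] = 0.0
    return wa, wb


def tree_shapley(model, X: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley attributions for a tree ensemble.

    Works for sklearn RandomForestRegressor / DecisionTreeRegressor. The
    ensemble prediction is the mean over trees, so per-leaf unanimity-game
    attributions are averaged over trees and background rows.

    Returns (phi matrix of shape (n_instances, p), base_value).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    if X.shape[1] != bg.shape[1]:
        raise InvalidInputError("background and instance feature counts differ")
    estimators = getattr(model, "estimators_", [model])
    n_inst, p = X.shape
    nb = bg.shape[0]
    phi = np.zeros((n_inst, p))
    wa_tab, wb_tab = _unanimity_weight_tables(64)

    for est in estimators:
        tree_ = est.tree_
        for value, feats, thrs, lefts in _leaf_paths(tree_):
            if len(feats) == 0:  # stump leaf: constant, no attribution
                continue
            u_feats, inv = np.unique(feats, return_inverse=True)
            u = len(u_feats)
            # node-level satisfaction, then AND within each unique feature
            sat_x = (X[:, feats] <= thrs) == lefts          # (n_inst, L)
            sat_b = (bg[:, feats] <= thrs) == lefts         # (nb, L)
            x_ok = np.ones((n_inst, u), dtype=bool)
            b_ok = np.ones((nb, u), dtype=bool)
            np.logical_and.at(x_ok, (slice(None), inv), sat_x)
            np.logical_and.at(b_ok, (slice(None), inv), sat_b)

            in_a = x_ok[:, None, :] & ~b_ok[None, :, :]     # (n_inst, nb, u)
            in_b = ~x_ok[:, None, :] & b_ok[None, :, :]
            dead = (~x_ok[:, None, :] & ~b_ok[None, :, :]).any(axis=2)
            a_cnt = in_a.sum(axis=2)
            b_cnt = in_b.sum(axis=2)
            alive = ~dead
            wa = wa_tab[a_cnt, b_cnt] * alive
            wb = wb_tab[a_cnt, b_cnt] * alive
            contrib = (wa[:, :, None] * in_a - wb[:, :, None] * in_b).sum(axis=1)
            phi[:, u_feats] += value * contrib / nb

    phi /= len(estimators)
    base = float(np.mean(model.predict(bg)))
    return phi, base


# ---------------------------------------------------------------------------


def shapley_all_regions(
    model,
    features: pd.DataFrame,
    background: pd.DataFrame | np.ndarray | None = None,
    method: str = "tree",
    background_cap: int = 100,
    seed: int = 0,
) -> ShapleyMatrix:
    """One attribution row per region.

    ``background`` defaults to the training feature matrix itself; for the
    tree method a seeded subsample of at most ``background_cap`` rows is
    used when the set is larger.
    """
    x = features.to_numpy(dtype=float)
    bg = x if background is None else np.atleast_2d(
        background.to_numpy(dtype=float) if isinstance(background, pd.DataFrame) else np.asarray(background, dtype=float)
    )
    if method == "tree":
        if len(bg) > background_cap:
            rng = np.random.default_rng(seed)
            bg = bg[rng.choice(len(bg), size=background_cap, replace=False)]
        phi, base = tree_shapley(model, x, bg)
    elif method == "exact":
        rows = [exact_shapley(model.predict, xi, bg) for xi in x]
        phi = np.vstack([r[0] for r in rows])
        base = rows[0][1]
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    return ShapleyMatrix(
        region_ids=features.index.to_numpy(),
        feature_names=list(features.columns),
        phi=phi,
        base_value=base,
        method=method,
    )


def check_efficiency(sm: ShapleyMatrix, predictions: np.ndarray, rtol: float = 1e-6) -> float:
    """Max relative efficiency violation |base + sum phi - pred| / scale."""
    total = sm.base_value + sm.phi.sum(axis=1)
    scale = np.maximum(np.abs(predictions), 1.0)
    return float(np.max(np.abs(total - predictions) / scale))


def global_rank(sm: ShapleyMatrix) -> pd.DataFrame:
    """Features ranked by mean absolute attribution, ties lexicographic."""
    if sm.phi.size == 0:
        raise InvalidInputError("empty attribution matrix")
    df = pd.DataFrame(
        {
            "feature": sm.feature_names,
            "mean_abs_phi": np.abs(sm.phi).mean(axis=0),
        }
    )
    df = df.sort_values(
        ["mean_abs_phi", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
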