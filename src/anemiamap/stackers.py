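"""Child learners of the stacked ensemble and the sum-to-one combination.

Three learners — a penalized additive spline model (the smooth-additive
stand-in for a GAM), gradient-boosted regression trees, and an L1-penalized
linear model — are fit to the empirical logit of each continuation-ratio
stage response with effective-sample-size weights.  Per-observation
predictions are strictly out-of-sample (cluster-stratified K-fold); grid
predictions come from a final all-data refit.  Their predictions enter the
geostatistical model as logit-scale covariates whose coefficients are
constrained to sum to one.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import Lasso, Ridge
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "LEARNERS",
    "StackerPredictions",
    "stage_response",
    "fit_stackers",
    "constrain_weights",
    "fit_constrained_combination",
]

LEARNERS = ("gam", "brt", "lasso")


@dataclasses.dataclass
class StackerPredictions:
    """Logit-scale learner predictions at observations and on the grid.

    obs: (n_obs, 3) out-of-sample predictions, learner order ``LEARNERS``.
    grid: (3, n_years, n_rows, n_cols) predictions from the all-data refit.
    """

    obs: np.ndarray
    grid: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.obs)) and np.all(np.isfinite(self.grid))):
            raise ValueError("stacker predictions must be finite")


def stage_response(obs: pd.DataFrame, stage: int) -> tuple[np.ndarray, np.ndarray]:
    """(successes, trials) for continuation-ratio stage 1, 2 or 3."""
    if stage == 1:
        return obs["anemic"].to_numpy(float), obs["N"].to_numpy(float)
    if stage == 2:
        return obs["mild"].to_numpy(float), obs["anemic"].to_numpy(float)
    if stage == 3:
        return (
            obs["severe"].to_numpy(float),
            (obs["moderate"] + obs["severe"]).to_numpy(float),
        )
    raise ValueError("stage must be 1, 2 or 3")


def _empirical_logit(y: np.ndarray, n: np.ndarray) -> np.ndarray:
    return np.log(y + 0.5) - np.log(n - y + 0.5)


def _make_learner(name: str, seed: int, config: dict):
    if name == "gam":
        return make_pipeline(
            StandardScaler(),
            SplineTransformer(
                n_knots=config.get("gam_knots", 5), degree=3, extrapolation="constant"
            ),
            Ridge(alpha=config.get("gam_alpha", 1.0)),
        )
    if name == "brt":
        return GradientBoostingRegressor(
            n_estimators=config.get("brt_trees", 150),
            max_depth=config.get("brt_depth", 2),
            learning_rate=config.get("brt_learning_rate", 0.1),
            subsample=config.get("brt_subsample", 0.9),
            random_state=seed,
        )
    if name == "lasso":
        return make_pipeline(
            StandardScaler(),
            Lasso(alpha=config.get("lasso_alpha", 1e-3), max_iter=50000),
        )
    raise KeyError(name)


def fit_stackers(
    observations: pd.DataFrame,
    obs_covariates: np.ndarray,
    grid_covariates: np.ndarray,
    stage: int,
    cv_folds: int = 5,
    seed: int = 0,
    config: dict | None = None,
) -> StackerPredictions:
    """Fit the three child learners for one continuation-ratio stage.

    Parameters
    ----------
    observations:
        Cluster observations with count columns; stage defines the response.
    obs_covariates:
        (n_obs, p) covariate values at the observations.
    grid_covariates:
        (n_years, n_rows, n_cols, p) covariate rasters.
    """
    config = config or {}
    y, n = stage_response(observations, stage)
    keep = n > 0
    X = np.asarray(obs_covariates, dtype=float)
    w = (observations["weight"].to_numpy(float) * n)[keep]
    Xk, yk, nk = X[keep], y[keep], n[keep]
    target = _empirical_logit(yk, nk)

    n_years, n_rows, n_cols, p = grid_covariates.shape
    Xgrid = grid_covariates.reshape(-1, p)

    obs_pred = np.zeros((len(observations), len(LEARNERS)))
    grid_pred = np.zeros((len(LEARNERS), n_years * n_rows * n_cols))

    if np.all(yk == 0) or np.all(yk == nk):
        logger.warning(
            "degenerate stage-%d response; stackers return the empirical logit", stage
        )
        const = _empirical_logit(yk.sum(), nk.sum())
        obs_pred[:] = const
        grid_pred[:] = const
        return StackerPredictions(
            obs=obs_pred, grid=grid_pred.reshape(-1, n_years, n_rows, n_cols)
        )

    # out-of-sample predictions via cluster-stratified folds
    clusters = observations.loc[keep, "cluster_id"].to_numpy()
    unique = np.unique(clusters)
    n_folds = min(cv_folds, len(unique))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of_cluster = np.empty(len(unique), dtype=int)
    for f, (_, test) in enumerate(kf.split(unique)):
        fold_of_cluster[test] = f
    fold = fold_of_cluster[np.searchsorted(unique, clusters)]

    oos = np.zeros((keep.sum(), len(LEARNERS)))
    for f in range(n_folds):
        train, test = fold != f, fold == f
        for j, name in enumerate(LEARNERS):
            model = _make_learner(name, seed + 100 * f + j, config)
            _weighted_fit(model, Xk[train], target[train], w[train])
            oos[test, j] = model.predict(Xk[test])

    for j, name in enumerate(LEARNERS):
        model = _make_learner(name, seed + j, config)
        _weighted_fit(model, Xk, target, w)
        grid_pred[j] = model.predict(Xgrid)
        # rows with empty denominators get the all-data prediction
        obs_pred[:, j] = model.predict(X)
    obs_pred[keep] = oos

    return StackerPredictions(
        obs=obs_pred, grid=grid_pred.reshape(-1, n_years, n_rows, n_cols)
    )


def _weighted_fit(model, X, y, w):
    """Pass sample weights to the final estimator of a pipeline."""
    if hasattr(model, "steps"):
        name = model.steps[-1][0]
        model.fit(X, y, **{f"{name}__sample_weight": w})
    else:
        model.fit(X, y, sample_weight=w)


def constrain_weights(beta: np.ndarray) -> np.ndarray:
    """Minimal-norm projection of learner coefficients onto Σβ_h = 1."""
    beta = np.asarray(beta, dtype=float)
    return beta + (1.0 - beta.sum()) / beta.size


def fit_constrained_combination(
    logit_preds: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    weights: np.ndarray | None = None,
    constrained: bool = True,
) -> tuple[float, np.ndarray]:
    """Binomial logit fit of the learner combination (intercept + Σβ = 1).

    Maximizes the weighted binomial log-likelihood over (β0, β) with the
    coefficients of the three logit-scale predictions constrained to sum to
    one (via the reparameterization β3 = 1 − β1 − β2), so the combination is
    an affine combination of logits.  With ``constrained=False`` all three
    coefficients are free (used to verify the constraint is active).
    """
    P = np.asarray(logit_preds, dtype=float)
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    def nll(theta):
        if constrained:
            b0, b1, b2 = theta
            beta = np.array([b1, b2, 1.0 - b1 - b2])
        else:
            b0 = theta[0]
            beta = theta[1:]
        eta = b0 + P @ beta
        return -np.sum(w * (y * eta - n * np.logaddexp(0.0, eta)))

    x0 = np.array([0.0, 1 / 3, 1 / 3]) if constrained else np.array([0.0, 1 / 3, 1 / 3, 1 / 3])
    res = minimize(nll, x0, method="BFGS")
    if constrained:
        b0, b1, b2 = res.x
        beta = np.array([b1, b2, 1.0 - b1 - b2])
    else:
        b0, beta = res.x[0], res.x[1:]
    return float(b0), beta


def ensemble_deviance(
    logit_preds: np.ndarray, beta0: float, beta: np.ndarray, y, n
) -> float:
    """Binomial deviance of a fitted combination (lower is better)."""
    eta = beta0 + np.asarray(logit_preds) @ np.asarray(beta)
    mu = expit(eta)
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_sat = np.where(y > 0, y * np.log(y / n), 0.0) + np.where(
            n - y > 0, (n - y) * np.log(1 - y / n), 0.0
        )
    ll = y * np.log(mu) + (n - y) * np.log1p(-mu)
    return float(2 * np.sum(ll_sat - ll))
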