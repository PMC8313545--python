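"""Random-forest variable importance and follow-up regressions on site features.

``fit_forest`` wraps a scikit-learn random-forest regression (bootstrap
trees, ``mtry`` candidate variables per split) and reports the percent of
response variance explained out-of-bag. ``permutation_importance`` computes
%IncMSE (mean decrease accuracy) by explicit column permutation: for each
variable, the column is shuffled ``n_perm`` times, the out-of-bag MSE is
recomputed, and the importance is the mean percent increase over the
baseline MSE. ``fit_scatter_models`` fits the linear and quadratic
least-squares follow-ups, flagging relationships with adjusted R^2 > 0.24
for reporting.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import cross_val_predict

from .errors import ConfigError, DegenerateModelError, ValidationError
from .survey import SurveyBundle

logger = logging.getLogger("fieldmargins")


@dataclasses.dataclass
class ForestFit:
    """A fitted forest plus the data and settings needed downstream."""

    model: RandomForestRegressor
    response: str
    variables: list[str]
    X: pd.DataFrame
    y: np.ndarray
    mtry: int
    n_trees: int
    oob_mse: float
    pct_var_explained: float


def fit_forest(features: pd.DataFrame, response: str,
               variables: Sequence[str] | None = None,
               mtry: int | None = None, n_trees: int = 500,
               seed: int | None = None,
               min_complete: int = 8) -> ForestFit:
    """Random-forest regression of ``response`` on ``variables``.

    Rows with missing values in the response or any predictor are dropped
    (listwise, logged). ``mtry`` defaults to round(p / 3) as is conventional
    for regression forests. Percent variance explained is
    100 * (1 - MSE_oob / var(y)); when out-of-bag predictions are not
    available for every row, 5-fold cross-validation is used instead.
    """
    if variables is None:
        variables = [c for c in features.columns
                     if c != response
                     and pd.api.types.is_numeric_dtype(features[c])]
    variables = list(variables)
    missing = [v for v in variables if v not in features.columns]
    if missing:
        raise ValidationError(f"fit_forest: unknown variable(s) {missing}")
    p = len(variables)
    if mtry is None:
        mtry = max(1, round(p / 3))
    if mtry > p:
        raise ConfigError(f"mtry={mtry} exceeds number of variables ({p})")

    sub = features[[response, *variables]].dropna()
    dropped = len(features) - len(sub)
    if dropped:
        logger.warning("fit_forest(%s): %d row(s) dropped for missing values",
                       response, dropped)
    if len(sub) < min_complete:
        raise ValidationError(
            f"fit_forest: only {len(sub)} complete cases (need >= "
            f"{min_complete})")
    y = sub[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateModelError(f"response {response!r} is constant")
    X = sub[variables]

    model = RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry, bootstrap=True,
        oob_score=True, random_state=seed, n_jobs=1)
    model.fit(X.to_numpy(), y)
    oob_pred = model.oob_prediction_
    if not np.all(np.isfinite(oob_pred)):
        logger.warning("fit_forest(%s): incomplete out-of-bag coverage; "
                       "using 5-fold CV for %% variance explained", response)
        oob_pred = cross_val_predict(model, X.to_numpy(), y, cv=5)
    oob_mse = float(np.mean((y - oob_pred) ** 2))
    pct = 100.0 * (1.0 - oob_mse / np.var(y, ddof=1))
    return ForestFit(model=model, response=response, variables=variables,
                     X=X, y=y, mtry=mtry, n_trees=n_trees, oob_mse=oob_mse,
                     pct_var_explained=pct)


def _oob_mask(model: RandomForestRegressor, n: int) -> np.ndarray | None:
    """Boolean (n_trees, n) matrix, True where a sample is out-of-bag."""
    try:
        samples = model.estimators_samples_
    except AttributeError:
        return None
    mask = np.ones((len(samples), n), dtype=bool)
    for i, idx in enumerate(samples):
        mask[i, idx] = False
    if not mask.any(axis=0).all():    # a row in-bag for every tree
        return None
    return mask


def _tree_predictions(model: RandomForestRegressor,
                      X: np.ndarray) -> np.ndarray:
    return np.stack([t.predict(X) for t in model.estimators_])


def _masked_mean(P: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return (P * mask).sum(axis=0) / mask.sum(axis=0)


def permutation_importance(fit: ForestFit, n_perm: int = 10,
                           seed: int | None = None,
                           use_oob: bool = True) -> pd.DataFrame:
    """%IncMSE per variable by explicit column permutation.

    importance = 100 * mean(MSE_perm - MSE_base) / MSE_base over ``n_perm``
    independent shuffles of the variable's column, evaluated on out-of-bag
    predictions (each row predicted only by trees that did not see it);
    falls back to whole-sample predictions when the fitted engine does not
    expose per-tree bootstrap indices. Also reports the Monte-Carlo standard
    error over permutations. Invariant to the order of feature columns.
    """
    if n_perm < 2:
        raise ConfigError("permutation_importance: n_perm must be >= 2")
    rng = np.random.default_rng(seed)
    X = fit.X.to_numpy(dtype=float)
    y = fit.y
    n = len(y)
    mask = _oob_mask(fit.model, n) if use_oob else None

    def _mse(Xe: np.ndarray) -> float:
        if mask is not None:
            pred = _masked_mean(_tree_predictions(fit.model, Xe), mask)
        else:
            pred = fit.model.predict(Xe)
        return float(np.mean((y - pred) ** 2))

    mse_base = _mse(X)
    rows = []
    for j, var in enumerate(fit.variables):
        mses = np.empty(n_perm)
        for r in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            mses[r] = _mse(Xp)
        inc = 100.0 * (mses - mse_base) / mse_base
        rows.append((var, float(inc.mean()),
                     float(inc.std(ddof=1) / np.sqrt(n_perm))))
    out = pd.DataFrame(rows, columns=["variable", "pct_inc_mse", "se"])
    return out.sort_values("pct_inc_mse", ascending=False,
                           ignore_index=True)


def fit_scatter_models(features: pd.DataFrame, response: str,
                       predictor: str) -> pd.DataFrame:
    """Linear and quadratic OLS fits of ``response`` on ``predictor``.

    Returns one row per form with coefficients (intercept, slope, quad),
    R^2, adjusted R^2 and a ``reported`` flag (adjusted R^2 > 0.24, the
    display threshold used for the follow-up regressions).
    """
    sub = features[[response, predictor]].dropna()
    if len(sub) < 4:
        raise ValidationError(
            f"fit_scatter_models: only {len(sub)} complete pairs (need >= 4)")
    x = sub[predictor].to_numpy(dtype=float)
    y = sub[response].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateModelError(f"predictor {predictor!r} has zero variance")

    rows = []
    for form, cols in (("linear", [x]), ("quadratic", [x, x ** 2])):
        X = sm.add_constant(np.column_stack(cols))
        res = sm.OLS(y, X).fit()
        coefs = list(res.params) + [np.nan] * (3 - len(res.params))
        adj = float(res.rsquared_adj)
        rows.append((response, predictor, form, *coefs[:3],
                     float(res.rsquared), adj, bool(adj > 0.24)))
    return pd.DataFrame(rows, columns=["response", "predictor", "form",
                                       "intercept", "slope", "quad",
                                       "r2", "adj_r2", "reported"])


def site_insect_responses(bundle: SurveyBundle) -> pd.DataFrame:
    """Per-site insect response variables for the predictor models.

    Columns: ``visits_all`` (all flower visits), ``visits_carpenter``
    (carpenter-bee visits to the bean crop), ``ne_abundance`` (summed trap
    counts of natural-enemy guilds), ``ne_richness`` (mean natural-enemy
    guilds per trap sample, an effort-adjusted functional-group richness)
    and ``dolichopodidae`` (long-legged fly trap counts). Guild roles come
    from the bundle's vocabulary.
    """
    roles = bundle.guild_roles
    if roles is None:
        from .survey import default_guild_roles
        roles = default_guild_roles()
    ne_guilds = set(roles.loc[roles["role"].isin(["natural_enemy", "both"]),
                              "guild"])
    sites = sorted(set(bundle.quadrats["site_id"]))
    out = pd.DataFrame({"site_id": sites}).set_index("site_id")

    v = bundle.visits
    out["visits_all"] = v.groupby("site_id")["visits"].sum()
    carp = v[(v["visitor_guild"] == "carpenter_bee")
             & (v["plant_species"] == "phaseolus_vulgaris")]
    out["visits_carpenter"] = carp.groupby("site_id")["visits"].sum()

    t = bundle.traps
    ne = t[t["guild"].isin(ne_guilds)]
    out["ne_abundance"] = ne.groupby("site_id")["count"].sum()
    per_event = ne.groupby(["site_id", "transect", "point_index", "stage"])[
        "guild"].nunique()
    out["ne_richness"] = per_event.groupby("site_id").mean()
    doli = t[t["guild"] == "dolichopodidae"]
    out["dolichopodidae"] = doli.groupby("site_id")["count"].sum()
    return out.fillna(0).reset_index()
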