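"""Feasible generalized least squares for unbalanced heteroskedastic panels.

Repeated observations (days, or urge reports) are nested within
participants, and residual spread differs between participants. The
two-step FGLS estimator used here assumes the error variance is constant
*within* a participant but free to vary *between* participants
(panel-level heteroskedasticity):

1. pooled OLS of the response on the predictors;
2. per-participant residual variance estimated from the stage-1 residuals
   (participants with fewer than ``min_group_obs`` observations fall back
   to the pooled residual variance, so no group gets a degenerate weight);
3. weighted least squares with weights 1 / sigma_i^2, standard errors from
   the weighted information matrix.

No autocorrelation structure is modelled: with unbalanced, unequally
spaced panels there is no common lag grid to estimate one on. Inference
uses the normal reference (z), and 95% intervals are beta +/- 1.96 SE.

When every participant truly has the same variance the estimated weights
are near-equal and FGLS collapses to pooled OLS; under real variance
heterogeneity the reweighting is more efficient (both properties are
exercised in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


class FGLSRegressor(RegressorMixin, BaseEstimator):
    """Two-step feasible GLS linear regression with group-wise variances.

    Scikit-learn-compatible estimator: ``fit(X, y, groups=...)`` where
    ``groups`` labels the panel unit (participant) of each row. Without
    ``groups`` the estimator degenerates to pooled OLS (a single variance
    group).

    Parameters
    ----------
    min_group_obs : int, default 3
        Minimum observations a group needs for its own variance estimate;
        smaller groups use the pooled residual variance.
    fit_intercept : bool, default True

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Slope estimates from the weighted stage.
    intercept_ : float
    bse_ : ndarray of shape (n_features,)
        Standard errors of ``coef_`` from the weighted information matrix.
    intercept_se_ : float
    group_variances_ : dict
        Stage-2 residual variance per group label.
    n_groups_ : int
    """

    def __init__(self, min_group_obs: int = 3, fit_intercept: bool = True):
        self.min_group_obs = min_group_obs
        self.fit_intercept = fit_intercept

    def _design(self, X: np.ndarray) -> np.ndarray:
        return sm.add_constant(X, has_constant="add") if self.fit_intercept else X

    def fit(self, X, y, groups=None):
        X, y = check_X_y(X, y, y_numeric=True)
        if groups is None:
            groups = np.zeros(len(y), dtype=int)
        groups = np.asarray(groups)
        if groups.shape[0] != len(y):
            raise ValueError("groups must align with X rows")

        design = self._design(X)
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError("collinear design matrix (including intercept)")

        ols = sm.OLS(y, design).fit()
        resid = ols.resid
        pooled_var = float(np.mean(resid**2))
        if pooled_var == 0.0:
            pooled_var = np.finfo(float).tiny

        codes, uniques = pd.factorize(groups)
        counts = np.bincount(codes)
        sums = np.bincount(codes, weights=resid**2)
        group_var = sums / counts
        small = counts < self.min_group_obs
        group_var[small | (group_var == 0.0)] = pooled_var

        weights = 1.0 / group_var[codes]
        wls = sm.WLS(y, design, weights=weights).fit()

        params, bse = np.asarray(wls.params), np.asarray(wls.bse)
        if self.fit_intercept:
            self.intercept_, self.coef_ = float(params[0]), params[1:]
            self.intercept_se_, self.bse_ = float(bse[0]), bse[1:]
        else:
            self.intercept_, self.coef_ = 0.0, params
            self.intercept_se_, self.bse_ = 0.0, bse
        self.group_variances_ = dict(zip(uniques.tolist(), group_var.tolist()))
        self.n_groups_ = len(uniques)
        self.n_features_in_ = X.shape[1]
        self._wls_result = wls
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self.intercept_ + X @ self.coef_

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Normal-reference confidence intervals for ``coef_``, shape (p, 2)."""
        check_is_fitted(self, "coef_")
        z = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.coef_ - z * self.bse_, self.coef_ + z * self.bse_])

    def z_pvalues(self) -> np.ndarray:
        check_is_fitted(self, "coef_")
        z = self.coef_ / self.bse_
        return 2 * stats.norm.sf(np.abs(z))


@dataclass
class PanelFit:
    """One fitted steps-urge association.

    ``beta`` (with ``se`` and the 95% CI) is the urge change per ``scale``
    steps; ``p_value`` is two-sided from the normal reference.
    """

    beta: float
    scale: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_obs: int
    n_participants: int
    covariates: list = field(default_factory=list)
    model: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "beta": self.beta,
            "scale": self.scale,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "covariates": list(self.covariates),
        }


def fit_fgls(
    panel: pd.DataFrame,
    response: str,
    predictor: str,
    covariates: list[str] | None = None,
    cluster: str = "participant",
    scale: float = 1.0,
    min_group_obs: int = 3,
    model_name: str = "",
) -> PanelFit:
    """Panel FGLS of ``response`` on ``predictor`` (+ covariates), variance
    groups given by ``cluster``.

    ``scale`` re-expresses the slope per ``scale`` predictor units (e.g.
    1000 steps). Requires a nonempty panel with >= 2 participants and a
    predictor with nonzero variance.
    """
    covariates = list(covariates or [])
    if panel.empty:
        raise ValueError("empty panel")
    if panel[cluster].nunique() < 2:
        raise ValueError("need at least 2 participants")
    cols = [predictor] + covariates
    data = panel[[response, cluster] + cols].dropna()
    x = data[cols].to_numpy(dtype=float)
    if np.var(x[:, 0]) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    x = x.copy()
    x[:, 0] = x[:, 0] / scale  # slope reported per `scale` predictor units
    y = data[response].to_numpy(dtype=float)
    try:
        est = FGLSRegressor(min_group_obs=min_group_obs).fit(x, y, groups=data[cluster].to_numpy())
    except ValueError as err:
        if "collinear" in str(err):
            raise ValueError(f"collinear columns among {cols!r}") from err
        raise
    beta, se = float(est.coef_[0]), float(est.bse_[0])
    p = float(est.z_pvalues()[0])
    return PanelFit(
        beta=beta,
        scale=scale,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        p_value=p,
        n_obs=len(y),
        n_participants=int(data[cluster].nunique()),
        covariates=covariates,
        model=model_name,
    )


DAY_MODEL_COVARIATES = ["age", "sex_male", "race_nonwhite", "cigs_per_day", "ipaq_high"]


def fit_day_model(
    day_panel: pd.DataFrame,
    adjusted: bool = False,
    covariate_table: pd.DataFrame | None = None,
) -> PanelFit:
    """Day-level association: mean daily urge on daily steps, per 1000 steps.

    The adjusted variant controls for age, sex, race, baseline smoking
    level and baseline activity category (coding: age and cigarettes/day
    continuous; sex, race and IPAQ-high binary).
    """
    panel = day_panel
    covs: list[str] = []
    if adjusted:
        if covariate_table is None:
            raise ValueError("adjusted fit requires a covariate table")
        covs = DAY_MODEL_COVARIATES
        panel = day_panel.merge(covariate_table[["participant"] + covs], on="participant", how="left")
        missing = panel[covs].isna().any(axis=1)
        if missing.any():
            who = sorted(panel.loc[missing, "participant"].unique())
            raise ValueError(f"missing covariates for participants: {who}")
    return fit_fgls(
        panel,
        response="mean_urge",
        predictor="daily_steps",
        covariates=covs,
        scale=1000,
        model_name="day_adjusted" if adjusted else "day",
    )


def fit_window_model(
    window_panel: pd.DataFrame,
    window: int = 30,
    coverage_threshold: float = 0.8,
) -> PanelFit:
    """Acute model: urge on steps in the ``window``-minute lookback, per 100 steps.

    Rows whose lookback HR coverage falls below ``coverage_threshold`` are
    dropped for this window only.
    """
    col, cov = f"steps_{window}", f"coverage_{window}"
    if col not in window_panel.columns:
        raise ValueError(f"window panel lacks {col}; available windows differ")
    retained = window_panel.loc[window_panel[cov] >= coverage_threshold]
    return fit_fgls(
        retained,
        response="urge",
        predictor=col,
        scale=100,
        model_name=f"window_{window}",
    )


def rescale_beta(fit: PanelFit, new_scale: float) -> PanelFit:
    """Re-express a fit per ``new_scale`` predictor units (p unchanged)."""
    if new_scale <= 0 or fit.scale <= 0:
        raise ValueError("scales must be positive")
    f = new_scale / fit.scale
    return replace(
        fit,
        beta=fit.beta * f,
        se=fit.se * f,
        ci_low=fit.ci_low * f,
        ci_high=fit.ci_high * f,
        scale=new_scale,
    )


@dataclass
class InteractionResult:
    moderator: str
    fit_low: PanelFit  # moderator == 0 subgroup
    fit_high: PanelFit  # moderator == 1 subgroup
    interaction_p: float


def interaction_analysis(
    panel: pd.DataFrame,
    moderator: str,
    response: str = "mean_urge",
    predictor: str = "daily_steps",
    scale: float = 1000,
) -> InteractionResult:
    """Moderation of the steps-urge slope by a binary participant covariate.

    Subgroup slopes come from separate FGLS fits; the interaction p-value
    comes from the moderator x steps term of a pooled FGLS model. A p-value
    of .10 or less is conventionally read as evidence of interaction for
    these exploratory contrasts.
    """
    vals = panel[moderator].dropna().unique()
    if not set(np.asarray(vals).astype(float)) <= {0.0, 1.0}:
        raise ValueError(f"moderator {moderator!r} must be binary 0/1")
    for v in (0, 1):
        sub = panel[panel[moderator] == v]
        if sub["participant"].nunique() < 2:
            raise ValueError(f"subgroup {moderator}={v} has fewer than 2 participants")

    data = panel.dropna(subset=[response, predictor, moderator]).copy()
    data["_x"] = data[predictor] / scale
    data["_xm"] = data["_x"] * data[moderator]
    x = data[["_x", moderator, "_xm"]].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    est = FGLSRegressor().fit(x, y, groups=data["participant"].to_numpy())
    p_int = float(est.z_pvalues()[2])

    fit_low = fit_fgls(
        panel[panel[moderator] == 0], response, predictor, scale=scale,
        model_name=f"{moderator}=0",
    )
    fit_high = fit_fgls(
        panel[panel[moderator] == 1], response, predictor, scale=scale,
        model_name=f"{moderator}=1",
    )
    return InteractionResult(moderator, fit_low, fit_high, p_int)
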