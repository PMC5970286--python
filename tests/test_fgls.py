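"""Two-step panel FGLS: reductions, oracles, invariances, interactions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from oracles import wls_slope_oracle
from stepurge import (
    FGLSRegressor,
    PanelFit,
    fit_day_model,
    fit_fgls,
    fit_window_model,
    interaction_analysis,
    rescale_beta,
)


def _panel(groups, x, y, **extra):
    return pd.DataFrame({"participant": groups, "daily_steps": x, "mean_urge": y, **extra})


def test_fgls_equals_ols_when_group_variances_are_identical():
    # identical per-group data -> stage-2 variances exactly equal -> OLS weights
    rng = np.random.default_rng(0)
    x1 = rng.normal(0, 1, 8)
    y1 = 2.0 + 0.5 * x1 + rng.normal(0, 1, 8)
    x = np.tile(x1, 4)
    y = np.tile(y1, 4)
    groups = np.repeat(list("ABCD"), 8)
    est = FGLSRegressor().fit(x[:, None], y, groups=groups)
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    assert est.coef_[0] == pytest.approx(ols.params[1], abs=1e-10)
    assert len(set(np.round(list(est.group_variances_.values()), 12))) == 1


def test_small_groups_fall_back_to_pooled_variance_giving_ols():
    # every group below min_group_obs -> uniform pooled weights -> exact OLS
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 20)
    y = 1.0 - 0.3 * x + rng.normal(0, 1, 20)
    groups = np.repeat(np.arange(10), 2)
    est = FGLSRegressor(min_group_obs=3).fit(x[:, None], y, groups=groups)
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    assert est.coef_[0] == pytest.approx(ols.params[1], abs=1e-12)


def test_two_participant_toy_panel_matches_hand_weighted_regression():
    # 6 printed rows; the expected slope comes from the closed-form WLS oracle
    x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    y = np.array([1.1, 1.9, 3.2, 2.0, 0.5, 4.5])
    groups = np.array(["A", "A", "A", "B", "B", "B"])
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    resid = y - ols.predict(sm.add_constant(x))
    w = np.empty(6)
    for g in ("A", "B"):
        w[groups == g] = 1.0 / np.mean(resid[groups == g] ** 2)
    expected = wls_slope_oracle(x, y, w)
    fit = fit_fgls(_panel(groups, x, y), "mean_urge", "daily_steps")
    assert fit.beta == pytest.approx(expected, rel=1e-10)
    assert fit.n_obs == 6 and fit.n_participants == 2


def test_fgls_is_more_efficient_than_ols_under_heteroskedasticity():
    # strong between-participant variance differences: FGLS SEs smaller on average
    rng = np.random.default_rng(3)
    wins = 0
    for _ in range(20):
        groups = np.repeat(np.arange(8), 25)
        sigma = np.repeat(rng.uniform(0.3, 3.0, 8), 25)
        x = rng.normal(0, 1, 200)
        y = 0.2 * x + rng.normal(0, sigma)
        fit = fit_fgls(_panel(groups, x, y), "mean_urge", "daily_steps")
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        wins += fit.se <= ols.bse[1]
    assert wins >= 17


def test_estimates_invariant_to_row_order_and_relabeling():
    rng = np.random.default_rng(4)
    groups = np.repeat(list("ABCD"), 15)
    x = rng.normal(0, 1, 60)
    y = 0.4 * x + rng.normal(0, np.repeat([0.5, 1, 2, 3], 15))
    panel = _panel(groups, x, y)
    fit = fit_fgls(panel, "mean_urge", "daily_steps")
    shuffled = panel.sample(frac=1, random_state=9)
    fit_shuf = fit_fgls(shuffled, "mean_urge", "daily_steps")
    relabeled = panel.assign(participant=panel["participant"].map({"A": "Z9", "B": "Y8", "C": "X7", "D": "W6"}))
    fit_rel = fit_fgls(relabeled, "mean_urge", "daily_steps")
    assert fit.beta == pytest.approx(fit_shuf.beta, abs=1e-12)
    assert fit.se == pytest.approx(fit_rel.se, abs=1e-12)


def test_input_validation_errors():
    panel = _panel(["A"] * 5, [1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    with pytest.raises(ValueError, match="2 participants"):
        fit_fgls(panel, "mean_urge", "daily_steps")
    panel2 = _panel(list("AABB"), [1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
    with pytest.raises(ValueError, match="zero variance"):
        fit_fgls(panel2, "mean_urge", "daily_steps")
    with pytest.raises(ValueError, match="empty"):
        fit_fgls(panel.iloc[:0], "mean_urge", "daily_steps")
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    panel3 = _panel(np.repeat(list("AB"), 10), x, rng.normal(size=20), dup=2 * x)
    with pytest.raises(ValueError, match="collinear"):
        fit_fgls(panel3, "mean_urge", "daily_steps", covariates=["dup"])


def test_pvalues_use_normal_reference():
    rng = np.random.default_rng(6)
    panel = _panel(np.repeat(list("ABC"), 20), rng.normal(size=60), rng.normal(size=60))
    fit = fit_fgls(panel, "mean_urge", "daily_steps")
    from scipy import stats

    assert fit.p_value == pytest.approx(2 * stats.norm.sf(abs(fit.beta / fit.se)), rel=1e-12)
    assert fit.ci_low <= fit.beta <= fit.ci_high


def test_rescaling_printed_acute_coefficient_to_per_1000():
    fit = PanelFit(beta=-0.0191, scale=100, se=0.00474, ci_low=-0.0284,
                   ci_high=-0.0098, p_value=1e-4, n_obs=100, n_participants=10)
    per1000 = rescale_beta(fit, 1000)
    assert per1000.beta == pytest.approx(-0.191)
    assert per1000.ci_low == pytest.approx(-0.284)
    assert per1000.p_value == fit.p_value
    # identity and round trip
    assert rescale_beta(fit, 100).beta == fit.beta
    back = rescale_beta(rescale_beta(fit, 1000), 100)
    assert back.beta == pytest.approx(fit.beta, abs=1e-12)
    with pytest.raises(ValueError):
        rescale_beta(fit, 0)


def test_day_and_window_models_report_on_their_scales():
    rng = np.random.default_rng(8)
    groups = np.repeat([f"P{i}" for i in range(6)], 20)
    steps = rng.normal(6000, 2000, 120)
    urge = 5 - 0.0002 * steps + rng.normal(0, 1, 120)
    day_panel = _panel(groups, steps, urge)
    fit = fit_day_model(day_panel)
    assert fit.scale == 1000
    # per-1000 slope should sit near -0.2
    assert fit.beta == pytest.approx(-0.2, abs=0.15)

    wp = pd.DataFrame(
        {"participant": groups, "urge": urge, "steps_30": steps / 10,
         "coverage_30": 1.0}
    )
    wfit = fit_window_model(wp, 30)
    assert wfit.scale == 100
    assert rescale_beta(wfit, 1000).beta == pytest.approx(10 * wfit.beta)


def test_window_model_drops_low_coverage_rows():
    rng = np.random.default_rng(10)
    n = 80
    wp = pd.DataFrame(
        {"participant": np.repeat(list("AB"), n // 2),
         "urge": rng.integers(1, 10, n).astype(float),
         "steps_30": rng.normal(200, 100, n),
         "coverage_30": np.where(np.arange(n) % 4 == 0, 0.2, 1.0)}
    )
    fit = fit_window_model(wp, 30)
    assert fit.n_obs == (wp["coverage_30"] >= 0.8).sum()


def test_adjusted_day_model_requires_and_uses_covariates():
    rng = np.random.default_rng(12)
    groups = np.repeat([f"P{i}" for i in range(8)], 15)
    steps = rng.normal(6000, 2000, 120)
    urge = 5 - 0.0001 * steps + rng.normal(0, 1, 120)
    day_panel = _panel(groups, steps, urge)
    cov = pd.DataFrame(
        {"participant": [f"P{i}" for i in range(8)],
         "age": rng.integers(20, 70, 8), "sex_male": rng.integers(0, 2, 8),
         "race_nonwhite": rng.integers(0, 2, 8), "cigs_per_day": rng.integers(3, 30, 8),
         "ipaq_high": rng.integers(0, 2, 8)}
    )
    with pytest.raises(ValueError):
        fit_day_model(day_panel, adjusted=True)
    adj = fit_day_model(day_panel, adjusted=True, covariate_table=cov)
    unadj = fit_day_model(day_panel)
    assert set(adj.covariates) == {"age", "sex_male", "race_nonwhite", "cigs_per_day", "ipaq_high"}
    # irrelevant covariates leave the slope within one SE
    assert abs(adj.beta - unadj.beta) < unadj.se
    with pytest.raises(ValueError, match="P0"):
        fit_day_model(day_panel, adjusted=True, covariate_table=cov.iloc[1:])


def _interaction_panel(effect_high=0.0, seed=0, n_per=30):
    rng = np.random.default_rng(seed)
    pids = [f"P{i}" for i in range(10)]
    mod = dict(zip(pids, [0] * 5 + [1] * 5))
    rows = []
    for pid in pids:
        steps = rng.normal(6000, 2000, n_per)
        slope = effect_high if mod[pid] else 0.0
        urge = 5 + slope * (steps - 6000) / 1000 + rng.normal(0, 1, n_per)
        rows.append(pd.DataFrame(
            {"participant": pid, "daily_steps": steps, "mean_urge": urge, "moderator": mod[pid]}
        ))
    return pd.concat(rows, ignore_index=True)


def test_interaction_subgroups_reproduce_subset_fits_exactly():
    panel = _interaction_panel(effect_high=-0.3, seed=5)
    res = interaction_analysis(panel, "moderator")
    sub0 = fit_fgls(panel[panel.moderator == 0], "mean_urge", "daily_steps", scale=1000)
    sub1 = fit_fgls(panel[panel.moderator == 1], "mean_urge", "daily_steps", scale=1000)
    assert res.fit_low.beta == pytest.approx(sub0.beta, abs=1e-12)
    assert res.fit_high.beta == pytest.approx(sub1.beta, abs=1e-12)
    assert 0 <= res.interaction_p <= 1


def test_interaction_power_rises_with_effect_size():
    detect = {0.0: 0, -0.4: 0}
    for effect in detect:
        for seed in range(8):
            res = interaction_analysis(_interaction_panel(effect, seed + 1), "moderator")
            detect[effect] += res.interaction_p <= 0.10
    assert detect[-0.4] > detect[0.0]
    assert detect[-0.4] >= 6  # a strong subgroup effect is almost always flagged


def test_interaction_rejects_bad_moderators():
    panel = _interaction_panel()
    with pytest.raises(ValueError, match="binary"):
        interaction_analysis(panel.assign(moderator=panel.daily_steps), "moderator")
    with pytest.raises(ValueError, match="fewer than 2"):
        interaction_analysis(panel.assign(moderator=0), "moderator")


def test_sklearn_estimator_contract():
    from sklearn.utils.validation import check_is_fitted
    from sklearn.exceptions import NotFittedError

    est = FGLSRegressor(min_group_obs=5)
    assert est.get_params()["min_group_obs"] == 5
    est.set_params(min_group_obs=3)
    with pytest.raises(NotFittedError):
        check_is_fitted(est, "coef_")
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 2))
    y = X @ [1.0, -2.0] + rng.normal(0, 0.1, 40)
    est.fit(X, y, groups=np.repeat([0, 1], 20))
    assert est.coef_ == pytest.approx([1.0, -2.0], abs=0.1)
    assert est.predict(X).shape == (40,)
    assert est.score(X, y) > 0.95
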