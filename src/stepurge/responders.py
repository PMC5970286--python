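"""Individualized (n-of-1) slopes and extreme-responder classification.

Population-averaged panel estimates can mask strong individual
heterogeneity: a small subgroup may drive a pooled acute effect. Each
participant therefore gets their own ordinary least squares fit at two
levels — mean daily urge on daily steps, and per-report urge on steps in
the 30-minute lookback — both expressed per 1000 steps. A participant is
an *extreme responder* when the 95% CI excludes zero with the same sign at
BOTH levels (inverse responders: both negative; positive responders: both
positive); everyone else is classified null.

Per-person fits use plain OLS (a single participant is a single variance
group, so FGLS has nothing to reweight) with t-reference intervals, which
is the standard small-sample treatment. No multiplicity correction is
applied across participants; with ~50 simultaneous per-person tests the
classification is exploratory by nature (see docs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .fgls import Z95, PanelFit, fit_window_model

logger = logging.getLogger(__name__)

MIN_OBS_PER_LEVEL = 10
STEP_CUTOFF = 500


@dataclass
class IndividualFit:
    participant: str
    level: str  # "day" or "window30"
    beta: float  # per 1000 steps
    se: float
    ci_low: float
    ci_high: float
    n_obs: int


def _ols_per_1000(
    pid: str, level: str, x_steps: np.ndarray, y: np.ndarray
) -> IndividualFit | None:
    if len(y) < MIN_OBS_PER_LEVEL:
        logger.info("participant %s: %d %s rows < %d; skipped", pid, len(y), level, MIN_OBS_PER_LEVEL)
        return None
    x = x_steps / 1000.0
    if np.var(x) == 0:
        logger.info("participant %s: zero step variance at %s level; skipped", pid, level)
        return None
    res = sm.OLS(y, sm.add_constant(x)).fit()
    beta, se = float(res.params[1]), float(res.bse[1])
    tcrit = stats.t.ppf(0.975, res.df_resid)
    return IndividualFit(pid, level, beta, se, beta - tcrit * se, beta + tcrit * se, len(y))


def fit_individual(
    day_panel: pd.DataFrame,
    window_panel: pd.DataFrame,
    coverage_threshold: float = 0.8,
) -> tuple[IndividualFit | None, IndividualFit | None]:
    """Per-participant OLS at the day and 30-minute-window levels.

    Both inputs must already be restricted to one participant. Either fit
    is None when that level has fewer than 10 usable rows or no step
    variance (such participants classify as null).
    """
    pid = str(
        day_panel["participant"].iloc[0]
        if len(day_panel)
        else window_panel["participant"].iloc[0]
    )
    day_fit = _ols_per_1000(
        pid, "day", day_panel["daily_steps"].to_numpy(dtype=float),
        day_panel["mean_urge"].to_numpy(dtype=float),
    ) if len(day_panel) else None
    wp = window_panel.loc[window_panel["coverage_30"] >= coverage_threshold]
    win_fit = _ols_per_1000(
        pid, "window30", wp["steps_30"].to_numpy(dtype=float),
        wp["urge"].to_numpy(dtype=float),
    ) if len(wp) else None
    return day_fit, win_fit


@dataclass
class ResponderResult:
    participant: str
    classification: str  # inverse_responder | positive_responder | null
    day_fit: IndividualFit | None
    window_fit: IndividualFit | None


def classify_responders(
    fits: dict[str, tuple[IndividualFit | None, IndividualFit | None]]
) -> list[ResponderResult]:
    """Classify every participant from their two individual fits.

    Consistency at both levels is required; a missing fit at either level
    forces the null classification. Output order follows sorted
    participant ids, so classification is invariant to input ordering.
    """
    out = []
    for pid in sorted(fits):
        day_fit, win_fit = fits[pid]
        label = "null"
        if day_fit is not None and win_fit is not None:
            if day_fit.ci_high < 0 and win_fit.ci_high < 0:
                label = "inverse_responder"
            elif day_fit.ci_low > 0 and win_fit.ci_low > 0:
                label = "positive_responder"
        out.append(ResponderResult(pid, label, day_fit, win_fit))
    return out


def summarize_responders(
    results: list[ResponderResult],
    classification: str = "inverse_responder",
) -> dict[str, dict] | None:
    """Pooled mean individualized slope (per 1000 steps) among responders.

    Unweighted mean of the responder betas at each level; the 95% CI uses
    the standard error of that mean. A single responder's summary reuses
    its own fit SE. Returns None when no participant has the requested
    classification.
    """
    chosen = [r for r in results if r.classification == classification]
    if not chosen:
        logger.info("no participants classified %s", classification)
        return None
    summary = {}
    for level, getter in (("day", lambda r: r.day_fit), ("window30", lambda r: r.window_fit)):
        betas = np.array([getter(r).beta for r in chosen], dtype=float)
        if len(betas) == 1:
            se = getter(chosen[0]).se
        else:
            se = float(betas.std(ddof=1) / np.sqrt(len(betas)))
        mean = float(betas.mean())
        summary[level] = {
            "mean_beta": mean,
            "se": se,
            "ci_low": mean - Z95 * se,
            "ci_high": mean + Z95 * se,
            "n_responders": int(len(betas)),
        }
    return summary


def stratify_by_step_cutoff(
    window_panel: pd.DataFrame,
    cutoff: int = STEP_CUTOFF,
    window: int = 30,
) -> pd.DataFrame:
    """Mean urge (95% CI) for episodes at or below vs above a step cutoff.

    Intended for the responder subset of the 30-minute panel. CIs are
    mean +/- 1.96 x SE over episodes, ignoring within-person clustering (a
    deliberately simple presentation; see docs). An empty stratum is
    reported with NaN mean and a zero count.
    """
    if window_panel.empty:
        raise ValueError("empty window panel")
    col = f"steps_{window}"
    rows = []
    for label, mask in (
        (f"<= {cutoff}", window_panel[col] <= cutoff),
        (f"> {cutoff}", window_panel[col] > cutoff),
    ):
        vals = window_panel.loc[mask, "urge"].to_numpy(dtype=float)
        if vals.size == 0:
            logger.warning("stratum %s steps is empty", label)
            rows.append({"stratum": label, "n": 0, "mean_urge": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
        rows.append({
            "stratum": label, "n": int(vals.size), "mean_urge": mean,
            "ci_low": mean - Z95 * se, "ci_high": mean + Z95 * se,
        })
    return pd.DataFrame(rows)


def leave_out_sensitivity(
    window_panel: pd.DataFrame,
    excluded: set[str],
    window: int = 30,
    coverage_threshold: float = 0.8,
) -> PanelFit:
    """Refit the pooled acute model with some participants excluded.

    Used to check whether a pooled acute association survives removal of
    the extreme responders (an effect carried by a small subgroup should
    attenuate toward zero).
    """
    remaining = window_panel.loc[~window_panel["participant"].isin(excluded)]
    if remaining.empty:
        raise ValueError("exclusion removed every observation")
    return fit_window_model(remaining, window=window, coverage_threshold=coverage_threshold)
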