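"""Synthetic EMA cohort generator with known ground truth.

No participant data were released by the study this pipeline emulates, so
every downstream stage is exercised on simulated cohorts whose generating
parameters are known exactly. The generator emulates the study's data
structure: ~53 participants wearing a wrist device for ~84 days, minute
step counts with a diurnal profile and discrete walking bouts, heart-rate
presence with injected nonwear gaps, and 3-6 urge reports per day on the
1-9 Likert scale (mostly prompted at preferred clock times, a few
spontaneous).

The latent-urge mechanism is additive and linear, matching the fitted
models: for participant i on day d reporting at time t,

    u = base + b0_i + beta_day_i * (daily_steps_d - S_day) / 1000
             + beta_win_i * (steps_30(t) - S_30) / 1000 + eps,

with eps ~ N(0, sigma_i), then rounded to the nearest integer and clamped
to [1, 9]. S_day and S_30 are fixed population centering constants (the
configured mean daily steps and its 30-minute waking-rate equivalent), so
they shift intercepts only, never slopes. A configured minority of
"extreme responders" receives stronger inverse slopes; everyone else gets
the population slopes. Walking bouts (not just smooth Poisson noise) are
essential: they give the 30-minute step sums the hundreds-of-steps spread
that makes an acute effect identifiable at all.

Ground truth (per-participant slopes, responder flags, injected nonwear
intervals) is returned alongside the data and serializable as JSON, so
recovery tests can compare estimates against the generating values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .streams import MINUTES_PER_DAY, ParticipantStream

# hours 0-23; zero overnight, commute/evening peaks
DEFAULT_DIURNAL_PROFILE = (
    0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
    0.5, 0.8, 1.0, 1.0, 1.0, 0.9, 0.9, 1.0,
    1.0, 1.2, 1.2, 1.0, 0.7, 0.5, 0.3, 0.0,
)


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic cohort.

    Slope units mirror how the corresponding models report them:
    ``day_beta`` and ``responder_day_beta`` are urge change per 1000 daily
    steps; ``window_beta_30`` is per 100 steps in the trailing 30-minute
    window (population) while ``responder_window_beta_30`` is per 1000
    (the scale on which individualized slopes are reported).
    """

    n_participants: int = 53
    study_days: int = 84
    prompts_per_day: float = 3.4
    spontaneous_rate: float = 0.05
    base_urge_mean: float = 5.0
    urge_noise_sd: float = 1.2
    day_beta: float = 0.0
    window_beta_30: float = 0.0
    responder_fraction: float = 6 / 53
    responder_day_beta: float = -0.15
    responder_window_beta_30: float = -1.66
    nonwear_gap_rate: float = 1.5
    nonwear_gap_minutes: tuple[int, int] = (30, 200)
    mean_daily_steps: float = 6000.0
    step_diurnal_profile: tuple[float, ...] = DEFAULT_DIURNAL_PROFILE
    seed: int = 0
    # secondary realism knobs
    intercept_sd: float = 0.0
    noise_sd_spread: float = 0.3
    activity_spread: float = 0.3
    day_sigma: float = 0.25
    ambient_fraction: float = 0.3
    bout_minutes: tuple[int, int] = (8, 25)
    bout_cadence: tuple[float, float] = (95.0, 12.0)
    wear_span: tuple[int, int] = (8 * 60, 23 * 60)
    prompt_times: tuple[float, ...] = (630.0, 810.0, 990.0, 1170.0)
    prompt_jitter: float = 20.0
    start_date: date = date(2017, 1, 2)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be a positive count")
        if self.study_days < 1:
            raise ConfigError("study_days must be a positive count")
        if not 0 <= self.prompts_per_day <= len(self.prompt_times):
            raise ConfigError("prompts_per_day exceeds the configured prompt_times")
        if self.spontaneous_rate < 0:
            raise ConfigError("spontaneous_rate must be nonnegative")
        if not 1 <= self.base_urge_mean <= 9:
            raise ConfigError("base_urge_mean must lie on the 1-9 scale")
        if self.urge_noise_sd < 0:
            raise ConfigError("urge_noise_sd must be nonnegative")
        if not 0 <= self.responder_fraction <= 1:
            raise ConfigError("responder_fraction must be in [0, 1]")
        if self.nonwear_gap_rate < 0:
            raise ConfigError("nonwear_gap_rate must be nonnegative")
        lo, hi = self.nonwear_gap_minutes
        if not 0 < lo <= hi:
            raise ConfigError("nonwear_gap_minutes bounds must satisfy 0 < lo <= hi")
        if self.mean_daily_steps <= 0:
            raise ConfigError("mean_daily_steps must be positive")
        if len(self.step_diurnal_profile) != 24 or min(self.step_diurnal_profile) < 0:
            raise ConfigError("step_diurnal_profile needs 24 nonnegative hourly weights")
        if sum(self.step_diurnal_profile) == 0:
            raise ConfigError("step_diurnal_profile must have positive total weight")


@dataclass
class GroundTruth:
    """Generating values per participant plus injected nonwear intervals.

    Slopes are stored per 1000 steps at both levels so recovery tests
    compare on one scale.
    """

    table: pd.DataFrame
    nonwear_intervals: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "participants": self.table.to_dict(orient="records"),
            "nonwear_intervals": self.nonwear_intervals,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(pd.DataFrame(payload["participants"]),
                   {k: [tuple(iv) for iv in v] for k, v in payload["nonwear_intervals"].items()})


@dataclass
class Cohort:
    streams: dict[str, ParticipantStream]
    urges: pd.DataFrame
    covariates: pd.DataFrame
    followup: pd.DataFrame
    truth: GroundTruth


def participant_id(index: int) -> str:
    return f"P{index:03d}"


def responder_flags(config: CohortConfig) -> np.ndarray:
    """Deterministic responder assignment: exactly round(f*n) flags set."""
    k = int(round(config.responder_fraction * config.n_participants))
    rng = np.random.default_rng([config.seed, 1 << 20])
    flags = np.zeros(config.n_participants, dtype=bool)
    flags[rng.permutation(config.n_participants)[:k]] = True
    return flags


def _participant_rng(config: CohortConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1 + index])


def generate_participant(
    config: CohortConfig, participant_index: int, responder: bool | None = None
) -> tuple[ParticipantStream, pd.DataFrame, dict, list[tuple[str, str]]]:
    """One participant's stream, urge events, truth record and gap list.

    Deterministic given (config.seed, participant_index). ``responder``
    defaults to this index's flag under the cohort-level assignment.
    """
    config.validate()
    if not 0 <= participant_index < config.n_participants:
        raise ConfigError("participant_index out of range for n_participants")
    if responder is None:
        responder = bool(responder_flags(config)[participant_index])
    pid = participant_id(participant_index)
    rng = _participant_rng(config, participant_index)
    days = config.study_days
    n_min = days * MINUTES_PER_DAY

    # --- participant traits ------------------------------------------------
    def _lognorm(sigma: float) -> float:
        return float(rng.lognormal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0

    activity = _lognorm(config.activity_spread)
    noise_sd = config.urge_noise_sd * _lognorm(config.noise_sd_spread)
    intercept = float(rng.normal(0.0, config.intercept_sd)) if config.intercept_sd > 0 else 0.0
    if responder:
        beta_day = config.responder_day_beta
        beta_win_1000 = config.responder_window_beta_30
    else:
        beta_day = config.day_beta
        beta_win_1000 = config.window_beta_30 * 10.0  # per 100 -> per 1000

    # --- step process: ambient ambling + walking bouts ---------------------
    day_mult = (
        rng.lognormal(-0.5 * config.day_sigma**2, config.day_sigma, days)
        if config.day_sigma > 0 else np.ones(days)
    )
    target_day = config.mean_daily_steps * activity * day_mult  # expected steps/day
    profile_min = np.repeat(np.asarray(config.step_diurnal_profile, dtype=float), 60)
    pm = profile_min / profile_min.sum()
    ambient_rate = np.outer(target_day * config.ambient_fraction, pm).ravel()
    steps = rng.poisson(ambient_rate).astype(np.int64)

    blo, bhi = config.bout_minutes
    cad_mean, cad_sd = config.bout_cadence
    mean_bout_steps = 0.5 * (blo + bhi) * cad_mean
    lam_bouts = target_day * (1.0 - config.ambient_fraction) / mean_bout_steps
    n_bouts = rng.poisson(lam_bouts)
    total_bouts = int(n_bouts.sum())
    if total_bouts:
        bout_day = np.repeat(np.arange(days), n_bouts)
        start_mod = rng.choice(MINUTES_PER_DAY, size=total_bouts, p=pm)
        durations = rng.integers(blo, bhi + 1, total_bouts)
        cadence = np.clip(rng.normal(cad_mean, cad_sd, total_bouts), 30.0, None)
        reps = durations
        idx = np.repeat(bout_day * MINUTES_PER_DAY + start_mod, reps)
        ramp = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
        idx = idx + ramp
        vals = np.repeat(np.rint(cadence).astype(np.int64), reps)
        ok = idx < n_min
        np.add.at(steps, idx[ok], vals[ok])

    # --- heart-rate presence with injected nonwear gaps --------------------
    hr = np.zeros(n_min, dtype=bool)
    minute_of_day = np.arange(n_min) % MINUTES_PER_DAY
    wlo, whi = config.wear_span
    hr[(minute_of_day >= wlo) & (minute_of_day < whi)] = True
    gaps: list[tuple[str, str]] = []
    origin = datetime.combine(config.start_date, datetime.min.time())
    n_gaps = rng.poisson(config.nonwear_gap_rate, days)
    glo, ghi = config.nonwear_gap_minutes
    for d in range(days):
        for _ in range(int(n_gaps[d])):
            start_mod = int(rng.integers(9 * 60, 21 * 60))
            length = int(rng.integers(glo, ghi + 1))
            a = d * MINUTES_PER_DAY + start_mod
            b = min(a + length, (d + 1) * MINUTES_PER_DAY)
            hr[a:b] = False
            gaps.append(
                ((origin + timedelta(minutes=a)).isoformat(sep=" "),
                 (origin + timedelta(minutes=b)).isoformat(sep=" "))
            )

    stream = ParticipantStream(pid, config.start_date, steps, hr)

    # --- urge events --------------------------------------------------------
    n_base = int(np.floor(config.prompts_per_day))
    frac = config.prompts_per_day - n_base
    n_prompts = n_base + (rng.random(days) < frac).astype(int)
    p_times = np.asarray(config.prompt_times, dtype=float)
    n_slots = len(p_times)
    ranks = rng.random((days, n_slots)).argsort(axis=1).argsort(axis=1)
    keep = ranks < np.minimum(n_prompts, n_slots)[:, None]
    jitter = rng.uniform(-config.prompt_jitter, config.prompt_jitter, (days, n_slots))
    slot_minutes = (np.arange(days)[:, None] * MINUTES_PER_DAY + p_times[None, :] + jitter)
    prompt_abs = slot_minutes[keep].astype(np.int64)

    n_spont = rng.poisson(config.spontaneous_rate, days)
    spont_day = np.repeat(np.arange(days), n_spont)
    spont_abs = spont_day * MINUTES_PER_DAY + rng.integers(10 * 60, 22 * 60, int(n_spont.sum()))

    t_abs = np.concatenate([prompt_abs, spont_abs])
    prompted = np.concatenate(
        [np.ones(prompt_abs.size, dtype=bool), np.zeros(spont_abs.size, dtype=bool)]
    )
    order = np.argsort(t_abs, kind="stable")
    t_abs, prompted = t_abs[order], prompted[order]

    cs = np.concatenate(([0], np.cumsum(steps)))
    s30 = cs[t_abs] - cs[np.maximum(t_abs - 30, 0)]
    daily_steps = steps.reshape(days, MINUTES_PER_DAY).sum(axis=1)
    d_of = t_abs // MINUTES_PER_DAY
    s30_ref = config.mean_daily_steps * 30.0 / 900.0
    latent = (
        config.base_urge_mean
        + intercept
        + beta_day * (daily_steps[d_of] - config.mean_daily_steps) / 1000.0
        + beta_win_1000 * (s30 - s30_ref) / 1000.0
        + rng.normal(0.0, noise_sd, t_abs.size)
    )
    urge = np.clip(np.rint(latent), 1, 9).astype(int)
    timestamps = pd.Timestamp(origin) + pd.to_timedelta(t_abs, unit="m")
    urges = pd.DataFrame(
        {"participant": pid, "timestamp": timestamps, "urge": urge, "prompted": prompted}
    )

    truth_row = {
        "participant": pid,
        "responder": bool(responder),
        "day_beta_per_1000": float(beta_day),
        "window_beta_per_1000": float(beta_win_1000),
        "intercept": intercept,
        "noise_sd": float(noise_sd),
        "activity_level": activity,
    }
    return stream, urges, truth_row, gaps


def _covariates(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline and follow-up covariate tables (cohort-level RNG stream)."""
    rng = np.random.default_rng([config.seed, (1 << 20) + 1])
    n = config.n_participants
    ids = [participant_id(i) for i in range(n)]
    cigs = np.clip(np.rint(rng.normal(12, 8, n)), 3, 40)
    baseline = pd.DataFrame(
        {
            "participant": ids,
            "age": np.clip(np.rint(rng.normal(40, 12, n)), 18, 75).astype(int),
            "sex_male": (rng.random(n) < 0.43).astype(int),
            "race_nonwhite": (rng.random(n) < 0.49).astype(int),
            "cigs_per_day": cigs.astype(int),
            "ipaq_high": (rng.random(n) < 0.53).astype(int),
            "quit_intent_yes": (rng.random(n) < 0.5).astype(int),
        }
    )
    # follow-up consumption drops by ~3 cigarettes/day on average; ~10% attrition
    fup_cigs = np.clip(np.rint(cigs - 3 + rng.normal(0, 3, n)), 0, None).astype(int)
    responded = rng.random(n) < 0.9
    followup = pd.DataFrame(
        {"participant": np.asarray(ids)[responded], "cigs_per_day": fup_cigs[responded]}
    )
    return baseline, followup.reset_index(drop=True)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Full cohort: streams, urges, covariates and ground truth.

    Deterministic given the seed; participants use independent RNG
    substreams so any single participant regenerates identically on its
    own.
    """
    config.validate()
    flags = responder_flags(config)
    streams: dict[str, ParticipantStream] = {}
    all_urges, truth_rows = [], []
    intervals: dict[str, list[tuple[str, str]]] = {}
    for i in range(config.n_participants):
        stream, urges, row, gaps = generate_participant(config, i, responder=bool(flags[i]))
        streams[stream.participant_id] = stream
        all_urges.append(urges)
        truth_rows.append(row)
        intervals[stream.participant_id] = gaps
    urges = pd.concat(all_urges, ignore_index=True)
    baseline, followup = _covariates(config)
    truth = GroundTruth(pd.DataFrame(truth_rows), intervals)
    return Cohort(streams, urges, baseline, followup, truth)


@dataclass
class PowerResult:
    power: float
    mc_se: float
    n_reps: int
    n_total: int


def power_simulation(
    n_participants: int,
    days_each: int,
    true_corr: float,
    icc: float,
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo power of the day-level association test.

    Each replicate draws ``n_participants x days_each`` bivariate
    (steps, urge) day pairs with observation-level correlation
    ``true_corr``; a fraction ``icc`` of each variable's variance sits at
    the participant level (random intercepts sharing the same
    cross-correlation), inducing within-person correlation of the repeated
    days. The test is the Fisher-z correlation test at ``alpha``
    (two-sided) on the pooled correlation, accounting for the design's
    intraindividual correlation through the design effect of a clustered
    correlate pair, DE = 1 + (m - 1) * icc^2 for m days per participant:
    the z statistic uses n_eff = N / DE pairs. At icc=0 this is the plain
    pooled test and matches the closed-form Fisher-z power; with icc > 0
    the unadjusted pooled test would be oversized. Power is the rejection
    proportion with its binomial MC standard error.
    """
    if n_participants < 2 or days_each < 2:
        raise ValueError("need n_participants >= 2 and days_each >= 2")
    if not 0 <= true_corr < 1:
        raise ValueError("true_corr must be in [0, 1)")
    if not 0 <= icc < 1:
        raise ValueError("icc must be in [0, 1)")
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")

    rng = np.random.default_rng(seed)
    n_total = n_participants * days_each
    design_effect = 1.0 + (days_each - 1) * icc**2
    n_eff = max(n_total / design_effect, 4.0)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    r = true_corr
    rejections = 0
    chunk = max(1, min(n_reps, int(2e7 // max(n_total, 1)) or 1))
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)

        def _pairs(size):
            z1 = rng.standard_normal(size)
            z2 = rng.standard_normal(size)
            return z1, r * z1 + np.sqrt(1 - r**2) * z2

        a, b = _pairs((m, n_participants))  # participant-level components
        e, f = _pairs((m, n_participants, days_each))  # day-level components
        x = np.sqrt(icc) * a[:, :, None] + np.sqrt(1 - icc) * e
        y = np.sqrt(icc) * b[:, :, None] + np.sqrt(1 - icc) * f
        x = x.reshape(m, n_total)
        y = y.reshape(m, n_total)
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        rhat = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        z = np.arctanh(np.clip(rhat, -0.999999, 0.999999)) * np.sqrt(n_eff - 3)
        rejections += int((np.abs(z) > zcrit).sum())
        done += m

    power = rejections / n_reps
    mc_se = float(np.sqrt(power * (1 - power) / n_reps))
    return PowerResult(power=float(power), mc_se=mc_se, n_reps=n_reps, n_total=n_total)


def fisher_z_power(true_corr: float, n_total: int, alpha: float = 0.05) -> float:
    """Closed-form power of the two-sided Fisher-z correlation test for
    ``n_total`` independent pairs (used as the simulation's oracle)."""
    zcrit = stats.norm.ppf(1 - alpha / 2)
    mu = np.arctanh(true_corr) * np.sqrt(n_total - 3)
    return float(stats.norm.sf(zcrit - mu) + stats.norm.cdf(-zcrit - mu))
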