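# stepurge

**stepurge** is a Python package for analyzing the within-person relationship
between objectively measured physical activity and momentary smoking urges in
intensive-longitudinal (EMA) wearable studies. It is aimed at behavioral and
cardiovascular epidemiologists working with consumer-wearable exports
(minute-level step counts, continuous heart-rate streams) combined with
timestamped ecological momentary assessments — here, instantaneous smoking
urge on a 1–9 Likert scale.

The package covers the full analysis chain:

1. **Wear-time filtering** — heart-rate presence is the wear signal; nonwear
   is a maximal run of ≥ 90 consecutive missing-HR minutes inside the
   10:00–22:00 target window. A day is valid with fewer than two nonwear
   windows and ≥ 6 h of wear; participants need ≥ 42 valid days.
2. **Panel alignment** — a day-level panel (mean daily urge vs. daily steps)
   and an acute panel pairing each urge report with the steps accumulated in
   the 5/30/60/120-minute lookbacks `[t−w, t)` before the report, with
   HR-coverage–based retention (≥ 80% of the lookback worn).
3. **Pooled association models** — two-step feasible generalized least
   squares (FGLS) for the unbalanced, participant-heteroskedastic panel:
   pooled OLS, per-participant residual variances σ̂ᵢ², then WLS with weights
   1/σ̂ᵢ². Day-level slopes are reported per 1000 steps, acute slopes per
   100 steps; binary-moderator interaction models use a steps × moderator
   term (p ≤ .10 read as evidence of interaction).
4. **Individualized responder analysis** — per-participant OLS slopes at both
   the day and 30-minute level; an *extreme responder* has 95% CIs excluding
   zero with the same sign at both levels. Responder-level summaries include
   the pooled mean individualized slope, a 500-step stratified urge
   comparison, and leave-responders-out sensitivity refits.
5. **Synthetic cohort generator** — because no participant-level data were
   released for this design, a simulator with known ground truth (diurnal
   bursty step process, injected nonwear gaps, prompted + spontaneous urge
   reports, a configurable extreme-responder subpopulation) exercises every
   stage, plus a Monte-Carlo power tool for the day-level correlation design.

The core model: for observation *j* of participant *i*,

```
urge_ij = α + β · steps_ij / scale + γ'z_i + ε_ij ,   Var(ε_ij) = σ_i²
```

estimated by two-step FGLS (no autocorrelation structure — the panels are
unbalanced and unequally spaced), with 95% CIs β ± 1.96·SE and normal-reference
p-values.

## Worked example

```python
from stepurge import CohortConfig, StudyConfig, analyze_cohort, generate_cohort

cohort = generate_cohort(CohortConfig(n_participants=20, study_days=30, seed=3))
res = analyze_cohort(cohort.streams, cohort.urges, cohort.covariates,
                     StudyConfig(min_valid_days=15))
```

With the default generating conditions (null population effects, ~11% planted
inverse responders at −0.15 urge/1000 daily steps and −1.66 urge/1000
30-minute steps) this prints:

```
502 of 600 days valid; 20 of 20 participants eligible
day-level slope: -0.0008 urge per 1000 steps (p = 0.93)
30-min acute slope: -0.0196 urge per 100 steps (95% CI -0.0319 to -0.0072, p = 0.00189)
inverse responders detected: ['P001', 'P009']
planted responders:          ['P001', 'P009']
mean individualized 30-min slope among responders: -1.84 per 1000 steps
```

Read: the day-level association is null, the pooled acute (30-minute) effect
is a small significant inverse slope — about 0.2 urge points per 1000 steps
accumulated in the half hour before a report — and both planted extreme
responders are recovered by the two-level CI classification.

The same stages are scriptable from a shell:

```sh
stepurge simulate --seed 3 --out cohort/ --n-participants 20 --study-days 30
stepurge run --seed 3 --out results/        # full pipeline + manifest
stepurge power --true-corr 0.12 --icc 0.0   # design power simulation
```

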