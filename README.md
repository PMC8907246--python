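# herdspace

Analysis pipeline for a year-long, two-arm randomised controlled trial of
indoor **living space** in dairy cows: a high-space group (6.5 m² living
space per cow) against a control group (3 m²), with matched cow pairs and
all other husbandry identical. The package implements the trial's full
statistical chain — milk production, reproduction and behaviour — together
with a seeded synthetic-herd generator so that every estimator can be
validated by parameter recovery against known ground truth.

It is written for quantitative epidemiologists and animal scientists who
want to reproduce, stress-test or extend this style of housing-trial
analysis without access to the raw herd data.

## What it computes

**Milk production (two-step model).** Daily volumes are first summarised by
a four-parameter non-linear lactation curve (the MilkBot form)

```
V(t) = a · (1 − e^{(c − t)/b} / 2) · e^{−d·t}
```

with scale *a*, ramp *b*, offset *c* and decay *d*, fitted to the pooled
7-day rolling volumes by Levenberg–Marquardt least squares. Per-cow-day
residuals from the curve are then modelled with a linear mixed model

```
O_ij = α + β·DIM_ij + Σ_g (γ_g + δ_g·DIM_ij) · 1[group_j = g] + u_j + e_ij,
u_j ~ N(0, σ²_v)
```

with a random intercept per cow-lactation and parity-by-treatment groups
(reference: primiparous control). 305-day yields are the sum over DIM
1–305 of curve plus fixed effects. The same machinery drives the daily
rumination model; monthly milk solids (kg = (fat% + protein%)/100 × 1.03 ×
volume) use a quartic-in-DIM mixed model with group interactions.

**Reproduction.** Time from calving to conception for pairs open at trial
entry, right-censored at trial exit: Kaplan–Meier curves, medians and risk
tables plus a Cox proportional-hazards model `h(t) = h₀(t)·exp(βx)` with
Schoenfeld-residual diagnostics. Supporting analyses: inter-service
interval blocks (18–26 d = normal oestrous cycle), rule-based milk
progesterone profile classification (Normal / delayed ovulation /
Abnormal: cessation, prolonged luteal, short luteal), commencement of
luteal activity (first two consecutive samples > 5 ng/ml), chi-squared
contingency comparisons, BHB/NEFA energy-balance flags, days-pregnant
adjusted milk models and a mixed-effects logistic model for conception at
service.

**Behaviour.** ~0.11 Hz position fixes are averaged to one coordinate per
cow-minute, allocated to named pen zones (half-open rectangles), summed to
per-cow-day zone hours and summarised per group with 500-rep percentile
bootstrap confidence intervals (within-cow or all-rows resampling).

## Worked example

Run the numbered drivers in order (they share `results/study/`):

```
python analysis/01_simulate_herd.py
python analysis/02_fit_lactation.py
python analysis/03_reproduction_survival.py
python analysis/04_behaviour_budgets.py
python analysis/05_summary_report.py
```

The final driver printed, for the default seeded herd of 35 pairs:

```
305-day yield difference, primiparous high - control: 551 L
305-day yield difference, multiparous high - control: 731 L
median days to conception: {'control': 111.0, 'high': 130.0}
lying-zone hours: high 12.34 vs control 11.23 (diff 66 min/day)
```

i.e. the simulated high-space herd produces more milk per 305-day
lactation, takes ~19 days longer (median) to conceive, and spends about an
hour a day longer in the lying areas — the generator's built-in effect
structure, recovered end-to-end through the fitting pipeline. Equivalent
subcommands exist on the CLI: `herdspace simulate|lactation|reproduction|
behaviour|all --seed <int> --out <dir>`.

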