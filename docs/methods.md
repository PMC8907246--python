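# Methods

This note documents the models, the synthetic-herd generator, the numerical
choices and the known limitations of the `herdspace` pipeline.

## The trial being modelled

A 364-day, two-arm randomised controlled trial in housed Holstein dairy
cows: matched pairs (equal parity; entry days-in-milk within ±3 d for
parity ≤ 2, ±5 d for parity ≥ 3), one member per pair allocated by fair
coin to a high-living-space pen (6.5 m²/cow) and one to a control pen
(3 m²/cow), 35 pairs present at all times, exits at dry-off replaced by
fresh pairs. Outcomes: 305-day milk yield, time from calving to
conception, and daily location time budgets, with supporting physiology
(milk solids, rumination, milk progesterone, BHB/NEFA).

## Milk production: the two-step model

A single mixed model of raw daily volumes fits this kind of data poorly
(the lactation curve is strongly non-linear in DIM), so the pipeline uses
two steps.

**Step one** fits the four-parameter MilkBot-form curve
`V(t) = a(1 − e^{(c−t)/b}/2)e^{−dt}` to the herd's pooled series by
Levenberg–Marquardt least squares, starting from the conventional values
(a, b, c, d) = (49, 27, 4, 0.00206). By default the fitted series is the
trailing 7-day rolling mean (window 7, ≥ 4 observed days); raw daily
volumes are available behind a flag, and the parameter-recovery studies use
them because rolling means are autocorrelated and would invalidate the
least-squares standard errors. Convergence: relative tolerance 1e-8 on the
objective and parameters, iteration cap 1000. Standard errors come from
the Gauss–Newton covariance `σ²(JᵀJ)⁻¹`; t-values are estimate/SE. The
sign convention of `(c − t)/b` is taken literally, which is why a fitted
offset can be negative while the starting value is positive.

**Step two** models daily residuals (observed minus curve, always on the
raw volume scale) with intercept, DIM slope, offsets and DIM-interactions
for the three non-reference parity-by-treatment groups, and a random
intercept per **cow-lactation** — a cow contributing two lactations
contributes two grouping units. Fits use REML (variance components are the
quantity of interest); maximum likelihood is available for likelihood
comparisons. The intraclass correlation is σ²_cow/(σ²_cow + σ²_resid).
305-day yields sum curve + fixed effects over integer DIM 1–305 with
random effects at zero; "first 100 days" means DIM 1–100 inclusive.

Recomputing published 305-day totals from *printed* (rounded) coefficients
carries substantial propagated rounding error — a DIM slope printed to two
decimals moves the total by up to ~230 L, and the quartic solids terms are
worse — so the worked-example tests assert tolerance bands (2% for milk,
5% for solids) rather than printed-precision equality. One printed
interaction ("0.00") has unrecoverable magnitude; the generator uses
−0.005, the midpoint of its printed interval.

**Milk solids** convert monthly constituent percentages to mass via
(fat% + protein%)/100 × 1.03 kg/L × volume; records with both percentages
zero are failed assays and are excluded (counted and logged). The solids
model is quartic in DIM with group interactions; DIM is internally scaled
by 100 before raising to powers (condition number) and coefficients are
back-transformed. The published model structures are fitted directly; the
forward-stepwise covariate selection used to arrive at them is out of the
default path.

**Rumination** reuses the group-by-DIM mixed model with minutes/day as the
outcome.

## Reproduction

**Time to conception.** Only pairs with *both* members non-pregnant at
entry are eligible; a pregnant member excludes the whole pair. Event time
is conception DIM; cows still open contribute censored time to trial exit
or trial end. Kaplan–Meier medians are the first time survival drops to
≤ 0.5 (infinity when not reached); the Cox model uses dummy-coded
parity-treatment groups (reference: primiparous control), Efron tie
handling, and attaches a Schoenfeld-residual proportional-hazards test.
Confounder variants (progesterone profile covariate, metabolite-pair
exclusion) are options of the same fit, not separate code paths.

**Inter-service intervals** are blocked 1–17 / 18–26 / 27–35 / 36–52 /
52+; the printed 36–52 and 52+ blocks overlap at 52, resolved here as 52
belonging to 36–52 with 52+ starting at 53.

**Progesterone profiles.** Thrice-weekly milk samples between 14–84 DIM
(Monday day, Wednesday day, Thursday evening). Two thresholds: first
*rise* > 3 ng/ml, *luteal* membership > 5 ng/ml. Rules, in order: first
rise after 45 DIM (or never) → delayed ovulation (DOV); a sub-5 run longer
than 12 days after the first luteal episode → Abnormal/cessation (trailing
runs count — cessation typically *is* a trailing low); a luteal run longer
than 21 days with no insemination inside it → Abnormal/prolonged; a
non-first luteal run shorter than 10 days → Abnormal/short, with the first
cycle exempt (a short first luteal phase is physiologically typical) and a
final run truncated by the end of sampling exempt (censoring, not a short
phase); otherwise Normal. Because sampling is thrice weekly, run lengths
are measured in calendar days between the first and last sample of the
run, not in sample counts — the key interpretive choice in this module. A
luteal run interrupted by a single sub-threshold sample is *not* bridged;
bridging is left to sensitivity analyses.

**Commencement of luteal activity** is the day of the first sample of the
earliest pair of consecutive samples both > 5 ng/ml, censored at 84 DIM.

**Contingency comparisons** use Pearson chi-squared; the Yates continuity
correction is applied exactly for 2×2 tables by default (matching the
published service-outcome comparison, which an uncorrected test does not
reproduce) and is a flag.

**Energy balance.** BHB ≥ 1.2 mmol/l and NEFA ≥ 0.8 mmol/l are "high"
(inclusive); the sensitivity rerun of the survival model drops every pair
with at least one high result in either member.

**Service-outcome model.** Conception at service on prior 7-day rolling
volume, ln(DIM) and trial group with a cow random intercept. No installed
frequentist GLMM exists in this stack, so the fit is a Bayesian logistic
GLMM by Laplace/MAP approximation (variational fallback), with posterior
means/SDs reported as estimates/SEs; continuous covariates are
standardised internally for the solver and back-transformed. The MAP
posterior SDs track frequentist SEs closely in the recovery studies,
whereas the variational ones were visibly too small — the reason MAP is
the default.

**Days-pregnant decomposition.** Days pregnant is recoded into ordinal
categories 0 (open), 1–50, 51–100, …, 250+; the milk model gains six
category effects (code 0 reference). The part of a 305-day group yield
difference attributable to reproduction is a difference-of-differences:
total difference minus the difference recomputed with both groups at a
common conception date.

## Behaviour

Fixes (~0.11 Hz, ±50 cm at 95% confidence) are floored to the cow-minute
and averaged; minutes without a fix are missing, with no interpolation.
Zones are axis-aligned rectangles per pen (half-open: minimum edge
inclusive), anything unmatched inside the pen is "other"
(passageways/movement area), outside the pen is flagged. Daily budgets are
assigned minutes / 60 with a coverage fraction; cow-days under 80%
coverage are dropped by default (the threshold is a flag — published
results were robust across data-quality criteria without stating one).
Raw hours plus coverage are reported; normalising to 24 h is a flag, off
by default. Outputs are labelled **zone** time, never behaviour time: a
minute in the cubicle zone is lying-area occupancy, not verified lying.
Bootstrap CIs are percentile intervals of the group mean over 500
resamples, either within each cow's rows (cows stay represented at their
own weight) or from all rows. With exactly one row per cow the within-cow
scheme is degenerate (each resample reproduces the data); the pipeline
warns rather than silently switching schemes.

The pen geometry shipped in `default_zonemap()` is synthetic but
schema-complete: 33 × 15 m mirror pens, a 32.4 m feed face, cubicle block,
robot, two water troughs, brush, and a loafing area only in the high-space
pen. Only partial real dimensions are public, so absolute zone areas are
illustrative; the budget arithmetic is geometry-agnostic.

## The synthetic herd generator

One `SeedSequence` per run spawns an independent child stream per
generator, so adding or rerunning one generator never perturbs another's
draws; identical config + seed gives byte-identical CSVs.

Defaults are the study conditions wherever the trial states them: 35
pairs; parity mix 20/9/4/0/2 over parities 1/2/3/4/5; curve parameters
(60.19, 30.2, −4.33, 0.001782); milk fixed effects and variance components
(cow 64.23, residual 16.37) from the published residual-model table;
rumination fixed effects from the published table; assay CV 13.2% with
truncation at 20 ng/ml; lying schedules 12.43 h (high) vs 11.42 h
(control); BHB/NEFA thresholds as above. Where the trial is silent the
defaults are single documented choices: voluntary waiting period 42 d and
oestrus-detection sensitivity 0.9 (both exposed as config, no fidelity
claim); rumination variance components (not printed) as cow SD 30 and
residual SD 55 min/day; zero-constituent assay failure rate 40/828;
metabolite levels lognormal with ~8% high prevalence per analyte.

Conception is simulated as per-service Bernoulli on the oestrous-cycle
grid (cycle ~ N(21, 2²) clipped to 18–26 d) — discrete-time proportional
hazards: the group probability is `1 − (1 − p₀)^s` with baseline p₀ =
37/99 (the control group's observed conceptions per service) and hazard
scale s = 0.58 for the high group, the published hazard ratio. A
continuous-time exponential two-arm simulator backs the Cox recovery
studies.

Progesterone trajectories are piecewise baseline/plateau templates drawn
per assigned class, with template durations chosen so the class remains
identifiable from thrice-weekly samples: a sampled run can appear up to ~8
days shorter than the true phase (two 4-day weekend gaps), so normal
luteal phases are 18.5–20.5 d (sampled span always > 10 but < 21),
prolonged phases > 31 d (span always > 21), cessation lows 22–26 d (span
always > 12), short phases 5–8 d, and inter-luteal lows 4.6–6.0 d so every
low window contains at least one sample and adjacent cycles can never
merge into an apparent prolonged phase. Noise is multiplicative lognormal
calibrated to the assay CV (mean-unbiased). Under these conditions the
classifier agrees with the generating labels exactly, with noise and
without — the identifiability margins, not classifier tuning, carry that
result.

Location fixes: per cow-day the lying total is drawn around the group
schedule (SD 1.5 h), remaining hours rescaled across the other zones,
minutes laid out as shuffled ~40-minute bouts, Poisson fix counts per
minute at the 9-s mean interval, positions uniform inside the scheduled
zone's rectangle (0.6 m inset) plus N(0, 0.255 m) jitter.

### What the generator does not emulate

Cross-over pen swaps and their excluded days (the exclusion filter exists
and is tested, but the generator does not schedule swaps), robot-milking
queueing, feed intake, seasonal trends, heteroscedastic early-lactation
noise, missing-sensor dropout patterns beyond a uniform rate, and any
correlation between a cow's milk, fertility and behaviour beyond what the
shared roster induces. Passing recovery tests therefore demonstrates
estimator correctness under the stated generating assumptions, not
robustness to every failure mode of real herd data.

## Problem sizes in the validation studies

Chosen once as a balance of statistical resolution against a fast,
deterministic suite: curve-fit recovery at 150 cows × 305 d over 50 seeded
fits; mixed-model recovery at 150 cow-lactations × 171 d over 50 fits
(~25,600 rows each, the published model's order of magnitude); Cox
recovery at 500/arm over 100 fits; classifier exactness on 500 noisy
series plus 1,000 random series against a brute-force scan; behaviour
recovery from ~1.2 M fixes (16 pairs × 4 days) and bootstrap calibration
over 200 repetitions of 480 cow-day budgets. Coverage assertions use the
binomial tolerance appropriate to the repetition count (e.g. ≥ 89% for a
nominal 95% over 100 runs).

## Known limitations

* The headline group contrasts of the real trial depend on the
  unavailable herd data; here they exist only as generator ground truth,
  and the pipeline demonstrates *recovery*, not re-estimation from real
  records.
* The service-outcome model reports approximate Bayesian posterior
  summaries, not REML/ML frequentist estimates; severe random-effect
  variance or quasi-separation will degrade the approximation (complete
  separation raises an explicit error).
* The progesterone classifier is deliberately rule-based and unsmoothed;
  real profiles with assay artefacts near thresholds will be more
  ambiguous than the templates.
* Bootstrap CIs are percentile intervals; no BCa correction is applied,
  matching the published procedure rather than improving on it.
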