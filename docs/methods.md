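# Methods

This note documents the model implemented by `strainsim`, the defaults it
ships with, the reasoning behind the genuinely open design choices, and
what the packaged synthetic conditions do and do not show about real
workers.

## Model overview and assumptions

The simulator advances a single worker through one shift in discrete steps
of `dt` seconds (default 1 s; a 480-minute shift is 28,800 steps).  Within
a step the update order is fixed as events → perception → stress →
capacity → performance, matching the causal chain of the underlying
demand–control view of job strain.  The main simplifications:

* All static effects (personal profile, workstation stressors) are linear
  and additive on capacities and benchmarks, and multiplicative on
  degradation rates; capacities are clamped to [0, 1] after application.
* Each task-load component affects only its matching workload component;
  cross-component effects are available only through explicit, configurable
  interaction rules (none by default).
* Stress stocks are abstract units without physical calibration; what the
  model predicts is *behaviour* (accumulation, transformation, relaxation),
  not physiological stress levels.
* Chronic stress does not relax within a shift, and its long-term carry-over
  into the next day's profile is out of scope.
* Capacities never recover during the shift; breaks freeze them (recovery
  is assigned to between-shift processes).  Stress stocks do relax during
  breaks.

## Perception

Per-component workload is the relative excess of the load over the basic
benchmark, moderated by `K_c(0)/K_c(t)` (capped at 10 when a capacity is
depleted, to avoid division by zero).  The moderation form is a declared
choice: perception must rise as capacity falls, but no functional form is
prescribed by the underlying theory; the initial/current ratio is the
simplest form that is exactly 1 for a fresh worker.

The demand score averages only the *challenging* (positive) components.
Averaging over all seven would dilute a single strongly-exceeding component
below any reasonable threshold, making the zero-challenge and
one-big-challenge cases nearly indistinguishable.  One caveat follows from
this choice: the score is monotone in each load component only while the
challenging set is unchanged — a component crossing its benchmark enters
the mean with a small value and can lower the average.  Per-component
workloads are strictly monotone regardless.

The capability score compares the current capacity outflow against the
worker's *innate* natural rate (before workstation multipliers).  Two
consequences are intended: a worker in a poor workstation correctly
perceives the faster-than-natural drain from day one, and the
demand–control cascade does not deadlock (if the comparison baseline
already included every static multiplier, no degradation excess could exist
until stress did, and no stress could exist until a degradation excess
did).  The sustained-attention *enhancement* multiplier is deliberately
excluded from the perceived rates: it models an arousal state, not a
perceived competence gain, and letting it enter the comparison makes
vigilance suppress the very demand that sustains it.

Time pressure uses the worker's no-pressure band `B_time · (1 ± tolerance)`
(tolerance default 0.10).  The task's required time is inflated by the
worker's time variation (proficiency spread, default 0.05), so less
proficient workers cross the band earlier.  Completing below the band
yields zero pressure and boosts the relaxation rates by a factor of 1.5
for the task's duration.

Age enters perception as a multiplicative gain `1/effect(age)` from a
piecewise-linear lookup: effect 1.05 at 18, 1.0 across 30–45, declining to
0.70 at 70.  Within the 20–40 band this yields only mild variation; the
lookup is configuration, not a validated curve.

## Stress dynamics

Rates default to the unit-accumulation reading: sustained attention gains
1 unit per demanding on-task step.  Relaxation is slower than accumulation
(defaults: SA 0.1/step, AC 0.05/step; both enforced strictly smaller than
their accumulation rates).  Stage `n+1` accumulates while stage `n` is
still accumulating *and* stage `n` has exceeded its endurance — a value
threshold or a continuous-duration threshold, either sufficing.  Duration
thresholds default to 15/30/60 minutes for the three stages.  Within one
step the stages update in cascade order: acute sees the freshly updated
sustained-attention stock but the previous step's duration counters;
statuses and counters update last.  This makes the worked small-case exact:
with a threshold of 10, acute accumulation begins on the step in which
sustained attention first exceeds 10.

Value thresholds (SA 300, AC 1500 stress units) and the demand/capability
thresholds (0.08 / 0.10) are calibration constants, not measured values —
no quantitative scale exists for them.  They were fixed once so that the
four packaged scenarios separate qualitatively: the normal schedule keeps
sustained attention near its endurance with no activated acute stress; the
overload schedule drives several hours of active acute stress and builds
chronic stress; both interventions end the day with zero chronic stress.
These constants are part of the packaged study conditions, and every
threshold is per-worker configuration.

Stress degradation is additive and proportional to the active stock
(coefficients 2·10⁻⁹ per acute unit per step and 1·10⁻⁹ per chronic unit
per step, against a natural outflow of ≈5.4·10⁻⁶/step).  The acute
coefficient is sized so that at the activation threshold the stress outflow
is below the natural outflow — a worker whose acute stress has only just
activated degrades noticeably but does not fall off a cliff; deep overload
(stocks several times the threshold) still saturates the performance
clamps.  Sustained
attention alone multiplies the natural outflow by the enhancement
multiplier (default 0.5); acute activation cancels the enhancement.
Acute relaxation requires only that acute accumulation has stopped, not
that sustained attention has returned to baseline (the simpler reading,
consistent with stock-flow semantics).

## Scheduling and synthetic conditions

The generator's defaults *are* the packaged use case: an 8-hour shift with
a 15-minute lunch at minute 240; tasks drawn serially with truncated-normal
inter-arrivals around a 3-minute basic pace (sd 10%, buffer effect +10%)
and truncated-normal load components around the scenario benchmarks
(cv 10%); and a Poisson failure process (mean inter-arrival 40 minutes,
handling time 205 s) that adds visual/cognitive/psychomotor load to
concurrent tasks and an extra cognitive outflow of 2·10⁻⁶/step while being
handled.  The 205-second figure is read as the failure *handling duration*
and the 40-minute figure as the *inter-arrival mean*; both are ordinary
configuration fields, since the source material admits either reading.
Arrivals falling inside a break are dropped (no incoming task during
breaks); a task that cannot finish before a break is deferred past it.
Hourly breaks (10 min) are placed at the end of each full worked hour,
skipping the lunch hour.  Three RNG substreams (arrivals, loads, failures)
derive from the master seed, so paired scenario comparisons share their
failure histories.

The worker profile mirrors a middle-aged, experienced operator: no
impairments, neutral factors, basic load slightly above the designed task
load (e.g. 25 N basic force against a 10 N task).  The workstation preset
applies: unergonomic design (posture −10%, force −15%, psychomotor −5%
initial capacity; posture degradation ×1.15), slightly sub-standard
lighting (visual −15%; visual degradation ×1.10; basic task time −10%),
and low-quality input material (visual/cognitive benchmarks tightened by
≈10%).  Static benchmark additions land on the basic-load side with a sign
convention: negative additions tighten the benchmark, which is how "the
worker feels extra checking load" is expressed in a relative-excess model.

What this synthetic shift does **not** emulate: real task autocorrelation
and learning within a shift, multi-day carry-over, team effects,
physiological noise, and any calibrated mapping from stress units to
measurable biomarkers.  Passing tests therefore demonstrate internal
consistency and the expected qualitative contrasts, not predictive
validity on real workers.

## Capacities and natural degradation

Natural rates are derived from the assumption that stress-free work leaves
85% of each initial capacity at the end of the reference on-time (shift
minus lunch, 465 min), scaled by the chronic-history factor.  The reference
on-time deliberately ignores intervention breaks: the natural rate is a
personal trait, not a schedule property.  Capacities floor at exactly 0; the
state classifier treats ≤ 0.01 as depleted, since exact zero is rarely hit
with floating-point rates.

## Performance

The three OLE components are clamped additive forms over capacity ratios
normalised by their shift-start values, so a fresh worker scores exactly
100% on all three even in a degraded workstation.  "Excess degradation" is
measured against the applied (post-static-multiplier) natural outflow —
at shift start it is zero by construction.  The availability distractor
term uses an *indicator* of an active failure window (weight 0.5), read as
the worker being partly unavailable for production while handling a
breakdown, plus a configurable pace-increment term (0 by default).  The
time-proficiency support of availability is constant within a shift
(time variation does not evolve intra-shift), so availability is carried
by the psychomotor ratio.  Weights default to (1, 0.5, 1, 1, 0.05) for
availability, distraction, productivity, quality and the attention bonus.
Because the forms are linear with hard clamps, heavily stressed components
saturate at 0 — the overload scenario's end-of-shift OLE is exactly zero
rather than asymptotically small.

State labels are evaluated per step over a trailing 60-minute window
(partial windows early in the shift) with precedence burnout > fatigue >
overload > under-load > optimal > nominal; the under-load rule (demanding
fraction < 0.05 and sustained attention below threshold throughout the
window) is a reading of an internally tension-laden description, not a
given formula.  The demanding flag is evaluated once at task onset and
held for the task's duration.

## Sensitivity analysis

Plain Monte Carlo (no Latin hypercube by default): one draw per parameter
per repetition from a seeded substream, a derived per-repetition simulation
seed, and pointwise median / central-90% envelopes over the collected
series.  Normal draws for the failure inter-arrival are truncated at a
60-second floor.  Rank correlations use Spearman's rho; a zero-variance
parameter is reported as NaN.  200 repetitions of the full-resolution
normal scenario run in a few minutes on one core.

## Numerical choices and degenerate inputs

* `dt` must divide the shift evenly; breaks are aligned to steps.
* A zero-length shift yields an empty schedule, no events and an empty run.
* Truncated-normal draws are implemented by redraw (100 attempts, then the
  benchmark), which preserves the mean far from the bounds; with cv = 0 the
  draw degenerates to the benchmark exactly.
* A failure process with `mean_interarrival: null` is disabled.
* Stocks floor at 0 on relaxation; capacities floor at 0 on outflow.
* Determinism: all randomness flows from `numpy.random.default_rng`
  seeded with `[master_seed, substream_id]`; identical configuration and
  seed give bit-identical records across processes.

## Known limitations

The thresholds and rates are calibration constants (see above), the OLE
weights are not fitted to any measured effectiveness data, and the linear
clamped performance forms saturate under heavy stress.  The model is a
tool for comparing work-content designs under explicit assumptions, not a
validated predictor of individual stress or output.
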