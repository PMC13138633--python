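# Configuration schema

`strainsim` reads nested YAML documents; every field has a default drawn
from the packaged assembly-line use case, so a minimal document such as
`seed: 7` is a complete configuration.  Units: minutes for shift-level
times, seconds for task-level times, Newtons for force, unitless fractions
elsewhere.

```yaml
seed: 7                 # master seed; all RNG substreams derive from it
dt: 1.0                 # step size (s); must divide the shift evenly

profile:                # the worker
  age: 40.0
  experience_factor: 1.0        # neutral = 1
  impairment: {posture: 0.10, force: 0.20}   # per-capacity fractions
  chronic_history_factor: 1.0   # scales natural degradation
  training_factor: 1.0
  skill_decay_factor: 1.0
  problem_solving_factor: 1.0
  demand_threshold: 0.08        # demand score gate
  capability_threshold: 0.10    # capability score gate
  sa_accum_rate: 1.0            # stress units per step (SA/AC/CH)
  sa_relax_rate: 0.10           # must be < the accumulation rate
  ac_accum_rate: 1.0
  ac_relax_rate: 0.05
  ch_accum_rate: 1.0
  sa_value_threshold: 300.0     # stress units
  ac_value_threshold: 1500.0
  sa_duration_threshold: 15.0   # minutes
  ac_duration_threshold: 30.0
  ch_duration_threshold: 60.0
  enhancement_multiplier: 0.5   # vigilance slows degradation
  stress_degradation_coeff_acute: 2.0e-9    # capacity/step per stress unit
  stress_degradation_coeff_chronic: 1.0e-9
  relaxation_boost: 1.5         # easy-task relaxation multiplier
  moderation_cap: 10.0          # cap on initial/current capacity ratio

basic:                  # the worker's benchmark (basic task load)
  posture: 6.0          # REEDCO-style score
  force: 25.0           # N
  task_time: 35.0       # s (the basic task time)
  visual: 3.5           # VACP 0-7
  auditory: 3.5
  cognitive: 3.0
  psychomotor: 2.5
  basic_pace_time: 180.0        # s between adjacent tasks
  task_time_tolerance: 0.10     # no-pressure band around the basic time

circumstantial:
  buffer_effect: 0.10   # fraction added to the pace allowance
  static:               # named stressors; targets unique within each
    - name: poor_lighting
      records:
        - {target: visual, initial_capacity_delta: -0.15,
           degradation_multiplier: 1.10}
        - {target: task_time, load_addition: -3.5}  # negative tightens
  failure:
    mean_interarrival: 2400.0   # s; null disables the process
    handling_duration: 205.0    # s
    extra_load: {cognitive: 1.5, visual: 0.5, psychomotor: 0.5}
    extra_degradation: {cognitive: 2.0e-6}   # per step while handling

shift:
  duration: 480.0               # minutes
  lunch_break: {start: 240.0, length: 15.0}   # null for none
  hourly_breaks: {length: 10.0}               # optional intervention
  reduced_pace: {after: 255.0, pace_factor: 2.0}   # optional intervention

task_generation:
  benchmark:            # expected task load (seven components, as `basic`)
    posture: 5.7
    force: 23.75
    task_time: 33.25
    visual: 3.325
    auditory: 3.325
    cognitive: 2.85
    psychomotor: 2.375
  component_cv: 0.10    # truncated-normal cv per component
  pace_sd: 0.10         # fraction of the (current) pace

interactions: []        # optional interacted-load rules:
# - {triggers: {posture: 0.3, time: 0.3}, target: force, magnitude: 0.25}

performance:            # OLE weights
  w_availability: 1.0
  w_distraction: 0.5
  w_productivity: 1.0
  w_quality: 1.0
  w_attention: 0.05
  pace_increment: 0.0

state_rules:
  window: 60.0          # minutes; trailing classification window
  overload_fraction: 0.8
  under_fraction: 0.05
  optimal_fraction: 0.3
  optimal_acute_cap: 0.2
  depletion_eps: 0.01

capacity:
  stress_free_remainder: 0.85   # fraction left after a stress-free shift
  base_time_variation: 0.05

posture_scale: [0.0, 10.0]
```

Validation is strict: a `dt` that does not divide the shift, a negative
benchmark, a relaxation rate at or above its accumulation rate, or a static
record targeting an unknown component all raise `ConfigError` naming the
offending field.
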