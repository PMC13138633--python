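"""Domain types, configuration loading and static (pre-shift) effects.

The simulator describes one industrial worker over one shift.  A *task load*
is the designed, objective requirement of a task: three physical components
(posture on a REEDCO-style score sheet, force in Newtons, task time in
seconds) and four mental components on the VACP scale (visual, auditory,
cognitive, psychomotor, each 0-7).  The worker owns a *basic task load* --
the per-component benchmark sustainable over a whole shift without fatigue --
and six depletable *work capacities* (one per load component except time,
which is represented by a proficiency spread called *time variation*).

Before the shift starts, two groups of static effects shape the initial
state:

* the *personal profile* (age, impairments, experience and stress-related
  parameters) linearly reduces the initial capacities and sets the natural
  degradation rates, and
* the *circumstantial stressors* of the assigned workstation (ergonomics,
  lighting, buffer level, ...) additively shift capacities and benchmarks
  and multiply per-component degradation rates.

Both applications are linear and additive across stressor records, so they
commute; capacities are clamped to [0, 1] after every application.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

#: the six depletable capacities (everything except time)
CAPACITY_COMPONENTS = (
    "posture",
    "force",
    "visual",
    "auditory",
    "cognitive",
    "psychomotor",
)

#: the seven designed task-load components
LOAD_COMPONENTS = (
    "posture",
    "force",
    "task_time",
    "visual",
    "auditory",
    "cognitive",
    "psychomotor",
)

VACP_COMPONENTS = ("visual", "auditory", "cognitive", "psychomotor")

#: valid targets of a static circumstantial record
STATIC_TARGETS = CAPACITY_COMPONENTS + ("task_time", "pace_time")


class ConfigError(ValueError):
    """Raised when a configuration document violates a model invariant."""


class TaskLoad(BaseModel):
    """The seven designed requirement components of one task."""

    posture: float = Field(ge=0.0)
    force: float = Field(ge=0.0)
    task_time: float = Field(gt=0.0)
    visual: float = Field(ge=0.0, le=7.0)
    auditory: float = Field(ge=0.0, le=7.0)
    cognitive: float = Field(ge=0.0, le=7.0)
    psychomotor: float = Field(ge=0.0, le=7.0)

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in LOAD_COMPONENTS}


class LoadDelta(BaseModel):
    """A partial task load added by a dynamic stressor (all default 0)."""

    posture: float = 0.0
    force: float = 0.0
    task_time: float = 0.0
    visual: float = 0.0
    auditory: float = 0.0
    cognitive: float = 0.0
    psychomotor: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in LOAD_COMPONENTS}


class BasicTaskLoad(BaseModel):
    """Per-component benchmarks plus pace preferences.

    ``task_time`` is the basic task time (preferred duration of one task);
    ``basic_pace_time`` is the preferred interval between adjacent tasks.
    ``task_time_tolerance`` defines the relative no-pressure band around the
    basic task time.
    """

    posture: float = Field(default=6.0, gt=0.0)
    force: float = Field(default=25.0, gt=0.0)
    task_time: float = Field(default=35.0, gt=0.0)
    visual: float = Field(default=3.5, gt=0.0)
    auditory: float = Field(default=3.5, gt=0.0)
    cognitive: float = Field(default=3.0, gt=0.0)
    psychomotor: float = Field(default=2.5, gt=0.0)
    basic_pace_time: float = Field(default=180.0, gt=0.0)
    task_time_tolerance: float = Field(default=0.10, ge=0.0, lt=1.0)

    @property
    def basic_task_time(self) -> float:
        return self.task_time

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in LOAD_COMPONENTS}


class AgeLookupPoint(BaseModel):
    age: float
    effect: float = Field(gt=0.0)


#: default piecewise-linear age-effect curve: mild decline through early
#: adulthood, flat through middle age, declining after 45.
DEFAULT_AGE_LOOKUP = (
    AgeLookupPoint(age=18.0, effect=1.05),
    AgeLookupPoint(age=30.0, effect=1.00),
    AgeLookupPoint(age=45.0, effect=1.00),
    AgeLookupPoint(age=70.0, effect=0.70),
)


def age_effect(age: float, lookup: tuple[AgeLookupPoint, ...] = DEFAULT_AGE_LOOKUP) -> float:
    """Piecewise-linear age-effect factor (1 = neutral, < 1 = reduced).

    Values outside the table are clamped to the end points.
    """
    pts = sorted(lookup, key=lambda p: p.age)
    if age <= pts[0].age:
        return pts[0].effect
    for lo, hi in zip(pts, pts[1:]):
        if age <= hi.age:
            w = (age - lo.age) / (hi.age - lo.age)
            return lo.effect + w * (hi.effect - lo.effect)
    return pts[-1].effect


class PersonalProfile(BaseModel):
    """Static, dynamic and stress-related parameters of one worker.

    Stress rates are in abstract stress units per simulation step; the
    duration thresholds are in minutes.  Relaxation is slower than
    accumulation for the sustained-attention and acute stocks.
    """

    # static factors
    age: float = Field(default=40.0, ge=16.0, le=100.0)
    experience_factor: float = Field(default=1.0, gt=0.0)
    impairment: dict[str, float] = Field(default_factory=dict)
    chronic_history_factor: float = Field(default=1.0, gt=0.0)
    # dynamic factors
    training_factor: float = Field(default=1.0, gt=0.0)
    skill_decay_factor: float = Field(default=1.0, gt=0.0)
    problem_solving_factor: float = Field(default=1.0, gt=0.0)
    # stress-related parameters
    demand_threshold: float = Field(default=0.08, ge=0.0)
    capability_threshold: float = Field(default=0.10, ge=0.0)
    sa_accum_rate: float = Field(default=1.0, ge=0.0)
    sa_relax_rate: float = Field(default=0.10, ge=0.0)
    ac_accum_rate: float = Field(default=1.0, ge=0.0)
    ac_relax_rate: float = Field(default=0.05, ge=0.0)
    ch_accum_rate: float = Field(default=1.0, ge=0.0)
    sa_value_threshold: float = Field(default=300.0, ge=0.0)
    ac_value_threshold: float = Field(default=1500.0, ge=0.0)
    sa_duration_threshold: float = Field(default=15.0, ge=0.0)  # minutes
    ac_duration_threshold: float = Field(default=30.0, ge=0.0)  # minutes
    ch_duration_threshold: float = Field(default=60.0, ge=0.0)  # minutes
    enhancement_multiplier: float = Field(default=0.5, gt=0.0, le=1.0)
    stress_degradation_coeff_acute: float = Field(default=2.0e-9, ge=0.0)
    stress_degradation_coeff_chronic: float = Field(default=1.0e-9, ge=0.0)
    relaxation_boost: float = Field(default=1.5, ge=1.0)
    moderation_cap: float = Field(default=10.0, ge=1.0)

    @field_validator("impairment")
    @classmethod
    def _check_impairment(cls, v: dict[str, float]) -> dict[str, float]:
        for comp, frac in v.items():
            if comp not in CAPACITY_COMPONENTS:
                raise ValueError(f"impairment targets unknown capacity {comp!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"impairment[{comp!r}] = {frac} outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_relaxation_slower(self) -> "PersonalProfile":
        if self.sa_accum_rate > 0 and self.sa_relax_rate >= self.sa_accum_rate:
            raise ValueError(
                f"sa_relax_rate {self.sa_relax_rate} must be slower than "
                f"sa_accum_rate {self.sa_accum_rate}"
            )
        if self.ac_accum_rate > 0 and self.ac_relax_rate >= self.ac_accum_rate:
            raise ValueError(
                f"ac_relax_rate {self.ac_relax_rate} must be slower than "
                f"ac_accum_rate {self.ac_accum_rate}"
            )
        return self


class CapacityState(BaseModel):
    """Six capacity stocks (fractions of the normative maximum) plus rates.

    ``capacities`` hold the current level, ``initial`` the post-static level
    at shift start (used for the perception moderation factor and for
    normalising the performance components), ``natural_rates`` the innate
    per-step natural degradation of each component, and ``time_variation``
    the proficiency spread around the basic task time.
    """

    capacities: dict[str, float]
    initial: dict[str, float]
    natural_rates: dict[str, float]
    time_variation: float = Field(default=0.05, ge=0.0)

    @model_validator(mode="after")
    def _check_components(self) -> "CapacityState":
        for d, name in (
            (self.capacities, "capacities"),
            (self.initial, "initial"),
            (self.natural_rates, "natural_rates"),
        ):
            if set(d) != set(CAPACITY_COMPONENTS):
                raise ValueError(f"{name} must have exactly the six capacity components")
        for c, v in self.capacities.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"capacity {c!r} = {v} outside [0, 1]")
        for c, v in self.natural_rates.items():
            if v < 0:
                raise ValueError(f"natural rate {c!r} = {v} negative")
        return self


class StaticRecord(BaseModel):
    """One static circumstantial effect on a capacity or benchmark.

    ``initial_capacity_delta`` shifts the initial capacity additively (signed
    fraction, clamped afterwards); ``degradation_multiplier`` multiplies the
    component's natural degradation rate; ``load_addition`` shifts the
    corresponding basic-load benchmark (component units; negative tightens
    the benchmark, i.e. the worker effectively feels an additional load).
    """

    target: str
    initial_capacity_delta: float = 0.0
    degradation_multiplier: float = Field(default=1.0, ge=0.0)
    load_addition: float = 0.0

    @model_validator(mode="after")
    def _check_target(self) -> "StaticRecord":
        if self.target not in STATIC_TARGETS:
            raise ValueError(f"static record targets unknown component {self.target!r}")
        if self.target not in CAPACITY_COMPONENTS and (
            self.initial_capacity_delta != 0.0 or self.degradation_multiplier != 1.0
        ):
            raise ValueError(
                f"capacity delta/multiplier set on non-capacity target {self.target!r}"
            )
        return self


class Stressor(BaseModel):
    """A named static circumstantial stressor; targets unique within it."""

    name: str
    records: list[StaticRecord] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_unique_targets(self) -> "Stressor":
        targets = [r.target for r in self.records]
        if len(targets) != len(set(targets)):
            raise ValueError(f"stressor {self.name!r} lists a target more than once")
        return self


class FailureProcess(BaseModel):
    """Random machine-failure/problem process (a dynamic stressor).

    Failure starts follow exponential inter-arrivals with the given mean;
    each failure lasts ``handling_duration`` seconds, adds ``extra_load`` to
    the concurrent task load and ``extra_degradation`` (per-step rates) to
    the capacity outflows while being handled.  ``mean_interarrival = None``
    disables the process.
    """

    mean_interarrival: Optional[float] = Field(default=2400.0, gt=0.0)
    handling_duration: float = Field(default=205.0, gt=0.0)
    extra_load: LoadDelta = Field(
        default_factory=lambda: LoadDelta(cognitive=1.5, visual=0.5, psychomotor=0.5)
    )
    extra_degradation: dict[str, float] = Field(
        default_factory=lambda: {"cognitive": 2.0e-6}
    )

    @field_validator("extra_degradation")
    @classmethod
    def _check_extras(cls, v: dict[str, float]) -> dict[str, float]:
        for comp, rate in v.items():
            if comp not in CAPACITY_COMPONENTS:
                raise ValueError(f"extra degradation targets unknown capacity {comp!r}")
            if rate < 0:
                raise ValueError(f"extra degradation rate for {comp!r} negative")
        return v


def default_workstation() -> list[Stressor]:
    """Static stressors of the packaged assembly-workstation preset.

    Unergonomic cell design reduces posture/force/psychomotor capacities by
    10/15/5% and makes posture degrade 15% faster; slightly sub-standard
    lighting costs 15% of visual capacity, makes it degrade at 110% of the
    natural rate and removes 10% of the basic task time; low-quality input
    material tightens the visual and cognitive benchmarks (felt as extra
    checking load).
    """
    return [
        Stressor(
            name="unergonomic_design",
            records=[
                StaticRecord(target="posture", initial_capacity_delta=-0.10,
                             degradation_multiplier=1.15),
                StaticRecord(target="force", initial_capacity_delta=-0.15),
                StaticRecord(target="psychomotor", initial_capacity_delta=-0.05),
            ],
        ),
        Stressor(
            name="poor_lighting",
            records=[
                StaticRecord(target="visual", initial_capacity_delta=-0.15,
                             degradation_multiplier=1.10),
                StaticRecord(target="task_time", load_addition=-3.5),
            ],
        ),
        Stressor(
            name="material_quality",
            records=[
                StaticRecord(target="visual", load_addition=-0.35),
                StaticRecord(target="cognitive", load_addition=-0.30),
            ],
        ),
    ]


class CircumstantialConfig(BaseModel):
    """Static and dynamic work-environment stressors plus buffer effect."""

    static: list[Stressor] = Field(default_factory=default_workstation)
    failure: FailureProcess = Field(default_factory=FailureProcess)
    buffer_effect: float = Field(default=0.10, ge=0.0)


class LunchBreak(BaseModel):
    start: float = Field(default=240.0, ge=0.0)  # minutes from shift start
    length: float = Field(default=15.0, gt=0.0)  # minutes


class HourlyBreaks(BaseModel):
    length: float = Field(default=10.0, gt=0.0)  # minutes


class ReducedPace(BaseModel):
    after: float = Field(default=240.0, ge=0.0)  # minutes from shift start
    pace_factor: float = Field(default=2.0, ge=1.0)


class ShiftConfig(BaseModel):
    duration: float = Field(default=480.0, ge=0.0)  # minutes
    lunch_break: Optional[LunchBreak] = Field(default_factory=LunchBreak)
    hourly_breaks: Optional[HourlyBreaks] = None
    reduced_pace: Optional[ReducedPace] = None

    @model_validator(mode="after")
    def _check_breaks(self) -> "ShiftConfig":
        if self.lunch_break is not None and self.duration > 0:
            end = self.lunch_break.start + self.lunch_break.length
            if end > self.duration:
                raise ValueError(
                    f"lunch break [{self.lunch_break.start}, {end}) min overlaps "
                    f"the shift end at {self.duration} min"
                )
        return self


def default_task_benchmark() -> TaskLoad:
    """Normal-schedule benchmark: task loads close to (95% of) the basic load."""
    b = BasicTaskLoad()
    return TaskLoad(**{c: 0.95 * v for c, v in b.as_dict().items()})


class TaskGeneration(BaseModel):
    benchmark: TaskLoad = Field(default_factory=default_task_benchmark)
    component_cv: float = Field(default=0.10, ge=0.0)
    pace_sd: float = Field(default=0.10, ge=0.0)  # fraction of the pace


class InteractionRule(BaseModel):
    """Extra workload on a prominent component when triggers jointly exceed."""

    triggers: dict[str, float]
    target: str
    magnitude: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _check_components(self) -> "InteractionRule":
        comps = LOAD_COMPONENTS + ("time",)
        for c in self.triggers:
            if c not in comps:
                raise ValueError(f"interaction rule triggers unknown component {c!r}")
        if self.target not in comps:
            raise ValueError(f"interaction rule targets unknown component {self.target!r}")
        return self


class PerformanceWeights(BaseModel):
    """Weights of the clamped-additive OLE component forms."""

    w_availability: float = Field(default=1.0, ge=0.0)
    w_distraction: float = Field(default=0.5, ge=0.0)
    w_productivity: float = Field(default=1.0, ge=0.0)
    w_quality: float = Field(default=1.0, ge=0.0)
    w_attention: float = Field(default=0.05, ge=0.0)
    pace_increment: float = Field(default=0.0, ge=0.0)


class StateRules(BaseModel):
    """Sliding-window rules for the stress-induced state labels."""

    window: float = Field(default=60.0, gt=0.0)  # minutes
    overload_fraction: float = Field(default=0.8, ge=0.0, le=1.0)
    under_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    optimal_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    optimal_acute_cap: float = Field(default=0.2, ge=0.0, le=1.0)
    depletion_eps: float = Field(default=0.01, ge=0.0)


class CapacityConfig(BaseModel):
    """Derivation of the natural degradation rates.

    Rates are set so that stress-free work over the reference on-time (shift
    minus lunch) leaves ``stress_free_remainder`` of the initial capacity.
    """

    stress_free_remainder: float = Field(default=0.85, gt=0.0, le=1.0)
    base_time_variation: float = Field(default=0.05, ge=0.0)


class ScenarioConfig(BaseModel):
    """Complete, validated configuration of one simulated shift."""

    profile: PersonalProfile = Field(default_factory=PersonalProfile)
    basic: BasicTaskLoad = Field(default_factory=BasicTaskLoad)
    circumstantial: CircumstantialConfig = Field(default_factory=CircumstantialConfig)
    shift: ShiftConfig = Field(default_factory=ShiftConfig)
    task_generation: TaskGeneration = Field(default_factory=TaskGeneration)
    interactions: list[InteractionRule] = Field(default_factory=list)
    performance: PerformanceWeights = Field(default_factory=PerformanceWeights)
    state_rules: StateRules = Field(default_factory=StateRules)
    capacity: CapacityConfig = Field(default_factory=CapacityConfig)
    posture_scale: tuple[float, float] = (0.0, 10.0)
    dt: float = Field(default=1.0, gt=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_consistency(self) -> "ScenarioConfig":
        shift_s = self.shift.duration * 60.0
        n = shift_s / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"dt = {self.dt} s does not divide the shift length of {shift_s} s evenly"
            )
        lo, hi = self.posture_scale
        if not lo <= self.task_generation.benchmark.posture <= hi:
            raise ValueError(
                f"posture benchmark {self.task_generation.benchmark.posture} outside "
                f"the configured scale [{lo}, {hi}]"
            )
        if not lo <= self.basic.posture <= hi:
            raise ValueError(
                f"basic posture {self.basic.posture} outside the scale [{lo}, {hi}]"
            )
        return self

    @property
    def n_steps(self) -> int:
        return int(round(self.shift.duration * 60.0 / self.dt))

    def steps_per_minute(self) -> float:
        return 60.0 / self.dt


def load_config(text: str) -> ScenarioConfig:
    """Parse a YAML configuration document into a validated ScenarioConfig.

    A minimal document (e.g. ``seed: 1``) is filled with the packaged
    use-case defaults: a 480-minute shift with a 15-minute lunch break, a
    3-minute basic pace and the assembly-workstation stressors.
    """
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - message path
        raise ConfigError(f"configuration does not parse: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration document must be a mapping")
    try:
        return ScenarioConfig.model_validate(data)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config_file(path) -> ScenarioConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return load_config(fh.read())


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def apply_personal_static_effects(
    profile: PersonalProfile,
    capacity_cfg: CapacityConfig | None = None,
    reference_on_steps: int = 27_900,
) -> CapacityState:
    """Initial conditions implied by the personal profile.

    Initial capacities are one minus the additive linear reductions
    (impairment fractions), clamped to [0, 1].  Natural degradation rates
    deplete ``1 - stress_free_remainder`` of each initial capacity over the
    reference on-time, scaled by the chronic-history factor.  Time variation
    scales with skill decay and inversely with experience and training.
    """
    cc = capacity_cfg or CapacityConfig()
    caps: dict[str, float] = {}
    rates: dict[str, float] = {}
    for c in CAPACITY_COMPONENTS:
        cap = _clamp01(1.0 - profile.impairment.get(c, 0.0))
        caps[c] = cap
        rates[c] = (
            cap * (1.0 - cc.stress_free_remainder) / max(reference_on_steps, 1)
        ) * profile.chronic_history_factor
    tv = cc.base_time_variation * profile.skill_decay_factor / (
        profile.experience_factor * profile.training_factor
    )
    return CapacityState(
        capacities=dict(caps), initial=dict(caps), natural_rates=rates,
        time_variation=max(tv, 0.0),
    )


def apply_circumstantial_static(
    capacity: CapacityState,
    basic: BasicTaskLoad,
    circ: CircumstantialConfig,
) -> tuple[CapacityState, BasicTaskLoad, dict[str, float]]:
    """Fold the static circumstantial effects into the initial state.

    Each record additively shifts the target's initial capacity (clamped),
    multiplies its degradation rate, and additively shifts the matching
    benchmark.  Effects combine additively across stressors, so application
    order does not matter.  Returns the adjusted capacity state, the
    adjusted basic load and the per-component degradation multipliers
    (multipliers are reported; innate natural rates stay untouched so the
    perception module can compare against them).
    """
    caps = dict(capacity.capacities)
    deltas = {c: 0.0 for c in CAPACITY_COMPONENTS}
    mults = {c: 1.0 for c in CAPACITY_COMPONENTS}
    basics = basic.as_dict()
    for stressor in circ.static:
        for rec in stressor.records:
            if rec.target in CAPACITY_COMPONENTS:
                deltas[rec.target] += rec.initial_capacity_delta
                mults[rec.target] *= rec.degradation_multiplier
            if rec.target in LOAD_COMPONENTS:
                basics[rec.target] += rec.load_addition
    for c in CAPACITY_COMPONENTS:
        caps[c] = _clamp01(caps[c] + deltas[c])
    for c, v in basics.items():
        if v <= 0:
            raise ConfigError(
                f"static load additions drive basic {c!r} to {v} (must stay positive)"
            )
    pace = basic.basic_pace_time * (1.0 + circ.buffer_effect)
    new_basic = BasicTaskLoad(
        **basics, basic_pace_time=pace, task_time_tolerance=basic.task_time_tolerance
    )
    new_cap = CapacityState(
        capacities=caps,
        initial=dict(caps),
        natural_rates=dict(capacity.natural_rates),
        time_variation=capacity.time_variation,
    )
    return new_cap, new_basic, mults


def perception_gain(profile: PersonalProfile) -> float:
    """Age-dependent gain on perceived workload (reduced attentional
    capacity past the age lookup makes the same load feel larger)."""
    return 1.0 / age_effect(profile.age)
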