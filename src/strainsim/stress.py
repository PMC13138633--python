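"""Per-step dynamics of the three stress stocks.

Sustained attention (SA) accumulates one unit-rate per step while a
demanding task is being worked on and relaxes (more slowly) otherwise.
Acute stress (AC) accumulates while SA is still accumulating *and* SA has
exceeded its personal endurance (value threshold, or continuous time over
the threshold); it relaxes, more slowly still, when not accumulating.
Chronic stress (CH) follows the same cascade above AC but never relaxes
within the shift.  Stocks are abstract stress units, not physical values.

Within a step, the stocks update in cascade order (SA, then AC seeing the
freshly updated SA, then CH seeing the freshly updated AC) while the
duration counters seen by the triggers are those of the previous step;
activation statuses and counters are updated last.  Activation status is
1 iff the stock strictly exceeds its value threshold.

While SA is active without AC, capacity degradation is *reduced*
(vigilance-driven enhancement); once AC activates, the enhancement fades
and an additive stress degradation proportional to the acute (and, if
active, chronic) stock applies.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PersonalProfile


@dataclass
class StressState:
    """Three stress stocks, activation statuses and exposure counters."""

    sa: float = 0.0
    ac: float = 0.0
    ch: float = 0.0
    sa_status: int = 0
    ac_status: int = 0
    ch_status: int = 0
    sa_over_duration: int = 0  # steps SA has continuously exceeded its threshold
    ac_over_duration: int = 0

    def copy(self) -> "StressState":
        return StressState(self.sa, self.ac, self.ch, self.sa_status,
                           self.ac_status, self.ch_status,
                           self.sa_over_duration, self.ac_over_duration)


@dataclass(frozen=True)
class StressParams:
    """Profile stress parameters with durations converted to steps."""

    sa_accum: float
    sa_relax: float
    ac_accum: float
    ac_relax: float
    ch_accum: float
    sa_value: float
    ac_value: float
    sa_duration_steps: int
    ac_duration_steps: int
    relaxation_boost: float

    @classmethod
    def from_profile(cls, profile: PersonalProfile, dt: float) -> "StressParams":
        spm = 60.0 / dt
        return cls(
            sa_accum=profile.sa_accum_rate,
            sa_relax=profile.sa_relax_rate,
            ac_accum=profile.ac_accum_rate,
            ac_relax=profile.ac_relax_rate,
            ch_accum=profile.ch_accum_rate,
            sa_value=profile.sa_value_threshold,
            ac_value=profile.ac_value_threshold,
            sa_duration_steps=int(round(profile.sa_duration_threshold * spm)),
            ac_duration_steps=int(round(profile.ac_duration_threshold * spm)),
            relaxation_boost=profile.relaxation_boost,
        )


def step_stress(
    state: StressState,
    demanding: int,
    on_task: int,
    params: StressParams,
    extra_relaxation: bool = False,
) -> StressState:
    """Advance the stress stocks by one step (mutates and returns state).

    ``demanding`` is the flag of the currently active task (0 when idle);
    ``on_task`` the schedule bit; ``extra_relaxation`` boosts the relaxation
    rates for this step (set while completing a faster-than-basic task).
    """
    boost = params.relaxation_boost if extra_relaxation else 1.0
    sa_accumulating = bool(on_task) and bool(demanding)
    if sa_accumulating:
        state.sa += params.sa_accum
    else:
        state.sa -= params.sa_relax * boost
        if state.sa < 0.0:
            state.sa = 0.0
    ac_accumulating = sa_accumulating and (
        state.sa > params.sa_value
        or state.sa_over_duration >= params.sa_duration_steps
    )
    if ac_accumulating:
        state.ac += params.ac_accum
    else:
        state.ac -= params.ac_relax * boost
        if state.ac < 0.0:
            state.ac = 0.0
    ch_accumulating = ac_accumulating and (
        state.ac > params.ac_value
        or state.ac_over_duration >= params.ac_duration_steps
    )
    if ch_accumulating:
        state.ch += params.ch_accum
    # statuses and counters last
    if state.sa > params.sa_value:
        state.sa_status = 1
        state.sa_over_duration += 1
    else:
        state.sa_status = 0
        state.sa_over_duration = 0
    if state.ac > params.ac_value:
        state.ac_status = 1
        state.ac_over_duration += 1
    else:
        state.ac_status = 0
        state.ac_over_duration = 0
    state.ch_status = 1 if state.ch > 0.0 else 0
    return state


def stress_capacity_modifier(
    state: StressState, profile: PersonalProfile
) -> tuple[float, float]:
    """(multiplier, additive-rate) applied to the capacity outflows.

    Acute activation cancels the sustained-attention enhancement; the
    additive term is proportional to the acute (and chronic, if present)
    stocks.
    """
    if state.ac_status:
        additive = profile.stress_degradation_coeff_acute * state.ac
        if state.ch_status:
            additive += profile.stress_degradation_coeff_chronic * state.ch
        return 1.0, additive
    if state.sa_status:
        return profile.enhancement_multiplier, 0.0
    return 1.0, 0.0
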