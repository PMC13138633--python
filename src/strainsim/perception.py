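"""Workload perception and the demand-control assessment of one task.

Following the demand-control view of job strain, an incoming task is
compared against the worker's basic task load.  Only *challenging*
components (those exceeding the benchmark) contribute: the per-component
workload is the relative excess over the benchmark, moderated by the ratio
of initial to current capacity, so a tired worker feels the same load as
more demanding.  Time enters through a separate time-pressure term (short
inter-arrival gaps or task times above the no-pressure band).

Two aggregate scores decide whether a task is *demanding*:

* the demand score -- the mean workload over challenging components, and
* the capability score -- the mean relative excess of the current capacity
  degradation over the innate natural degradation (the worker noticing the
  capacities draining faster than normal).

A task is demanding (1) only if both scores exceed their personal
thresholds; demanding tasks feed the stress stocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import (
    CAPACITY_COMPONENTS,
    LOAD_COMPONENTS,
    BasicTaskLoad,
    CapacityState,
    InteractionRule,
)

#: workload component names: the six capacity-matched components plus time
WORKLOAD_COMPONENTS = (
    "posture", "force", "visual", "auditory", "cognitive", "psychomotor", "time",
)


@dataclass
class DemandAssessment:
    """Perceived workload and demand/capability verdict for one task."""

    workload: dict[str, float]
    time_pressure: float
    interacted_extra: dict[str, float]
    demand_score: float
    capability_score: float
    demand_exceeds: bool
    capability_exceeds: bool
    demanding: int
    extra_relaxation: bool = False

    def total_workload(self) -> dict[str, float]:
        out = dict(self.workload)
        for c, v in self.interacted_extra.items():
            out[c] = out.get(c, 0.0) + v
        return out


def _moderation(initial: float, current: float, cap: float) -> float:
    """Capacity moderation factor initial/current, capped for depleted
    capacities instead of dividing by zero."""
    if current <= initial / cap:
        return cap
    return initial / current


def compute_workload(
    load,
    basic: BasicTaskLoad,
    capacity: CapacityState,
    gain: float = 1.0,
    moderation_cap: float = 10.0,
) -> dict[str, float]:
    """Per-component perceived workload (time excluded; see time_pressure).

    ``workload_c = max(0, (load_c - basic_c) / basic_c) * initial_c/current_c``
    for each non-time component; components at or below the benchmark yield
    zero.  ``gain`` scales the perception (age wiring); a depleted capacity
    maps the moderation factor to ``moderation_cap`` instead of dividing by
    zero.
    """
    loads = load.as_dict() if hasattr(load, "as_dict") else dict(load)
    cap = capacity.capacities
    init = capacity.initial
    mcap = moderation_cap
    out: dict[str, float] = {}
    for c in CAPACITY_COMPONENTS:
        excess = (loads[c] - getattr(basic, c)) / getattr(basic, c)
        if excess <= 0.0:
            out[c] = 0.0
        else:
            out[c] = excess * _moderation(init[c], cap[c], mcap) * gain
    return out


def time_pressure(
    inter_arrival: float,
    required_time: float,
    basic: BasicTaskLoad,
    time_variation: float,
) -> tuple[float, bool]:
    """Unitless time workload plus the extra-relaxation flag.

    The effective required time is the task's time demand inflated by the
    worker's proficiency spread.  Pressure is zero inside the no-pressure
    band around the basic task time with a normal pace; otherwise it is the
    larger relative deficit of the two time benchmarks.  Finishing faster
    than the basic time yields zero pressure and flags extra relaxation.
    """
    if inter_arrival < 0:
        raise ValueError(f"negative inter-arrival {inter_arrival} (event ordering broken)")
    eff = required_time * (1.0 + time_variation)
    btt = basic.basic_task_time
    band_hi = btt * (1.0 + basic.task_time_tolerance)
    band_lo = btt * (1.0 - basic.task_time_tolerance)
    task_deficit = max(0.0, (eff - band_hi) / btt)
    pace_deficit = 0.0
    if math.isfinite(inter_arrival) and inter_arrival < basic.basic_pace_time:
        pace_deficit = (basic.basic_pace_time - inter_arrival) / basic.basic_pace_time
    relax = eff < band_lo and pace_deficit == 0.0
    if relax:
        return 0.0, True
    return max(task_deficit, pace_deficit), False


def compute_interacted_load(
    workload: dict[str, float], rules: list[InteractionRule]
) -> dict[str, float]:
    """Additional workload on prominent components from firing rules.

    A rule fires when every trigger component strictly exceeds its
    threshold; magnitudes add across rules targeting the same component.
    The default rule set is empty (no interacted load).
    """
    out: dict[str, float] = {}
    for rule in rules:
        tgt = "time" if rule.target == "task_time" else rule.target
        if all(
            workload.get("time" if c == "task_time" else c, 0.0) > thr
            for c, thr in rule.triggers.items()
        ):
            out[tgt] = out.get(tgt, 0.0) + rule.magnitude
    return out


def demand_score(workload: dict[str, float], threshold: float) -> tuple[float, bool]:
    """Mean workload over challenging (positive) components; 0 if none."""
    positive = [v for v in workload.values() if v > 0.0]
    score = sum(positive) / len(positive) if positive else 0.0
    return score, score > threshold


def capability_score(
    current_rates: dict[str, float],
    natural_rates: dict[str, float],
    capacity: CapacityState,
    threshold: float,
    moderation_cap: float = 10.0,
) -> tuple[float, bool]:
    """Mean relative excess of current over natural degradation.

    Only components degrading faster than their innate natural rate enter
    the mean; each excess is moderated by initial/current capacity as for
    the workload.  Exceeding the threshold means the worker perceives the
    capability as insufficient for the incoming load.
    """
    cap = capacity.capacities
    init = capacity.initial
    mcap = moderation_cap
    excesses = []
    for c, cur in current_rates.items():
        nat = natural_rates[c]
        if cur > nat:
            if nat <= 0:
                raise ValueError(f"natural rate for {c!r} must be positive to compare")
            excesses.append((cur - nat) / nat * _moderation(init[c], cap[c], mcap))
    score = sum(excesses) / len(excesses) if excesses else 0.0
    return score, score > threshold


def classify_demanding(demand_exceeds: bool, capability_exceeds: bool) -> int:
    """1 iff both the demand and capability thresholds are exceeded."""
    return 1 if (demand_exceeds and capability_exceeds) else 0


def assess_task(
    load,
    inter_arrival: float,
    basic: BasicTaskLoad,
    capacity: CapacityState,
    current_rates: dict[str, float],
    demand_threshold: float,
    capability_threshold: float,
    rules: list[InteractionRule] | None = None,
    gain: float = 1.0,
    moderation_cap: float = 10.0,
) -> DemandAssessment:
    """Full demand-control assessment at task onset."""
    loads = load.as_dict() if hasattr(load, "as_dict") else dict(load)
    wl = compute_workload(loads, basic, capacity, gain=gain,
                          moderation_cap=moderation_cap)
    tp, relax = time_pressure(
        inter_arrival, loads["task_time"], basic, capacity.time_variation
    )
    wl["time"] = tp * gain
    extra = compute_interacted_load(wl, rules or [])
    total = dict(wl)
    for c, v in extra.items():
        total[c] = total.get(c, 0.0) + v
    d_score, d_flag = demand_score(total, demand_threshold)
    c_score, c_flag = capability_score(
        current_rates, capacity.natural_rates, capacity, capability_threshold,
        moderation_cap=moderation_cap,
    )
    return DemandAssessment(
        workload=wl,
        time_pressure=tp,
        interacted_extra=extra,
        demand_score=d_score,
        capability_score=c_score,
        demand_exceeds=d_flag,
        capability_exceeds=c_flag,
        demanding=classify_demanding(d_flag, c_flag),
        extra_relaxation=relax,
    )
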