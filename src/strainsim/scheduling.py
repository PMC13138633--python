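"""Work schedules and stochastic task / failure event streams.

The shift is discretised into steps of ``dt`` seconds.  The schedule is a
binary sequence (1 = work scheduled, 0 = break) with per-step labels.  Task
arrivals are drawn around the basic pace (truncated normal, strictly
positive); each event's seven load components are drawn around the scenario
benchmarks (truncated normal, respecting the component bounds).  Failures
arrive as a Poisson process (exponential inter-arrivals) and only occur
while work is scheduled.

Three independent RNG substreams (arrivals, loads, failures) are derived
from the master seed, so toggling one process leaves the others unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import (
    LOAD_COMPONENTS,
    VACP_COMPONENTS,
    BasicTaskLoad,
    CircumstantialConfig,
    ShiftConfig,
    TaskGeneration,
)

LABEL_WORK = "work"
LABEL_LUNCH = "lunch"
LABEL_HOURLY = "hourly_break"

# RNG substream identifiers
_STREAM_ARRIVALS = 1
_STREAM_LOADS = 2
_STREAM_FAILURES = 3


@dataclass
class Schedule:
    """Binary work schedule over the shift steps."""

    dt: float
    on_task: np.ndarray  # int8, 1 = work scheduled
    labels: list[str] = field(repr=False, default_factory=list)

    def __len__(self) -> int:
        return len(self.on_task)

    @property
    def n_on_steps(self) -> int:
        return int(self.on_task.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"step": np.arange(len(self.on_task)), "on_task": self.on_task,
             "label": self.labels}
        )


@dataclass
class TaskEvent:
    """One task (or failure window) on the schedule."""

    start: int            # step index
    duration: int         # steps, >= 1
    load: dict[str, float]
    is_failure: bool = False
    inter_arrival: float = math.inf  # seconds since the previous task started

    @property
    def end(self) -> int:
        return self.start + self.duration


def build_work_schedule(shift: ShiftConfig, dt: float) -> Schedule:
    """Mark lunch and (optionally) hourly breaks as 0, everything else 1.

    Hourly breaks are placed at the end of each full worked hour; a break
    that would overlap the lunch window or the shift end is skipped.
    """
    n = int(round(shift.duration * 60.0 / dt))
    on = np.ones(n, dtype=np.int8)
    labels = [LABEL_WORK] * n
    spm = 60.0 / dt  # steps per minute

    def _mark(start_min: float, length_min: float, label: str) -> None:
        a = int(round(start_min * spm))
        b = int(round((start_min + length_min) * spm))
        if b > n:
            raise ValueError(
                f"break window [{start_min}, {start_min + length_min}) min "
                f"overlaps the shift end"
            )
        on[a:b] = 0
        for i in range(a, b):
            labels[i] = label

    lunch = shift.lunch_break
    if lunch is not None and n > 0:
        _mark(lunch.start, lunch.length, LABEL_LUNCH)
    if shift.hourly_breaks is not None and n > 0:
        blen = shift.hourly_breaks.length
        hour = 60.0
        k = 1
        while k * hour + blen <= shift.duration:
            start = k * hour
            overlaps_lunch = lunch is not None and (
                start < lunch.start + lunch.length and lunch.start < start + blen
            )
            if not overlaps_lunch:
                _mark(start, blen, LABEL_HOURLY)
            k += 1
    return Schedule(dt=dt, on_task=on, labels=labels)


def _off_regions(schedule: Schedule) -> list[tuple[int, int]]:
    """Half-open [start, end) step ranges where work is not scheduled."""
    off = np.flatnonzero(schedule.on_task == 0)
    regions: list[tuple[int, int]] = []
    if off.size == 0:
        return regions
    start = prev = int(off[0])
    for i in off[1:]:
        i = int(i)
        if i != prev + 1:
            regions.append((start, prev + 1))
            start = i
        prev = i
    regions.append((start, prev + 1))
    return regions


def _draw_positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated to > 0 by redraw (sd = 0 returns the mean)."""
    if sd == 0.0:
        return mean
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > 0.0:
            return x
    return mean  # pathological sd; fall back to the benchmark


def _draw_component(
    rng: np.random.Generator, comp: str, mean: float, cv: float,
    posture_scale: tuple[float, float],
) -> float:
    """Component draw truncated to the component's scale bounds."""
    lo, hi = 0.0, math.inf
    if comp in VACP_COMPONENTS:
        hi = 7.0
    elif comp == "posture":
        lo, hi = posture_scale
    elif comp == "task_time":
        lo = 1e-9  # task time must stay strictly positive
    if cv == 0.0:
        return min(max(mean, lo), hi)
    sd = cv * mean
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi and (comp != "task_time" or x > 0.0):
            return x
    return min(max(mean, lo), hi)


def generate_task_events(
    schedule: Schedule,
    basic: BasicTaskLoad,
    gen: TaskGeneration,
    seed: int,
    reduced_pace=None,
    posture_scale: tuple[float, float] = (0.0, 10.0),
) -> list[TaskEvent]:
    """Ordered task events for one shift.

    Inter-arrival gaps are drawn around the basic pace time (multiplied by
    the pace factor once the reduced-pace intervention is active).  Arrivals
    that fall inside a break are dropped (no incoming task during breaks);
    tasks execute serially, and a task that would overlap a break is
    deferred to the break's end.  ``inter_arrival`` records the realised
    start-to-start gap in seconds (infinite for the first task).
    """
    n = len(schedule)
    if n == 0:
        return []
    dt = schedule.dt
    rng_arr = np.random.default_rng([seed, _STREAM_ARRIVALS])
    rng_load = np.random.default_rng([seed, _STREAM_LOADS])
    off_regions = _off_regions(schedule)
    on = schedule.on_task
    pace_after = math.inf
    pace_factor = 1.0
    if reduced_pace is not None:
        pace_after = reduced_pace.after * 60.0  # seconds
        pace_factor = reduced_pace.pace_factor

    events: list[TaskEvent] = []
    t = 0.0  # arrival clock, seconds
    prev_end = 0  # step after which the worker is free
    prev_start_s = None
    shift_s = n * dt
    while True:
        pace = basic.basic_pace_time * (pace_factor if t >= pace_after else 1.0)
        t += _draw_positive_normal(rng_arr, pace, gen.pace_sd * pace)
        if t >= shift_s:
            break
        load = {
            c: _draw_component(rng_load, c, getattr(gen.benchmark, c),
                               gen.component_cv, posture_scale)
            for c in LOAD_COMPONENTS
        }
        arrival_step = int(t / dt)
        if on[arrival_step] == 0:
            continue  # no incoming task during a break
        duration = max(1, int(round(load["task_time"] / dt)))
        start = max(arrival_step, prev_end)
        # defer past any break the task window would touch
        placed = False
        while not placed:
            placed = True
            if start + duration > n:
                break
            for a, b in off_regions:
                if start < b and a < start + duration:
                    start = b
                    placed = False
                    break
        if start + duration > n:
            continue  # does not fit before the shift end
        start_s = start * dt
        gap = math.inf if prev_start_s is None else start_s - prev_start_s
        events.append(
            TaskEvent(start=start, duration=duration, load=load,
                      inter_arrival=gap)
        )
        prev_end = start + duration
        prev_start_s = start_s
    return events


def generate_failure_events(
    schedule: Schedule, circ: CircumstantialConfig, seed: int
) -> list[TaskEvent]:
    """Failure windows with exponential inter-arrivals, on-task only.

    Each failure lasts ``handling_duration`` seconds (truncated at the shift
    end) and carries the configured extra load; a failure arriving during a
    break is skipped (machines are idle).
    """
    n = len(schedule)
    fail = circ.failure
    if n == 0 or fail.mean_interarrival is None or not math.isfinite(
        fail.mean_interarrival
    ):
        return []
    dt = schedule.dt
    rng = np.random.default_rng([seed, _STREAM_FAILURES])
    on = schedule.on_task
    events: list[TaskEvent] = []
    off_regions = _off_regions(schedule)
    t = 0.0
    shift_s = n * dt
    dur_steps = max(1, int(round(fail.handling_duration / dt)))
    while True:
        t += rng.exponential(fail.mean_interarrival)
        if t >= shift_s:
            break
        start = int(t / dt)
        if on[start] == 0:
            continue
        limit = n
        for a, _b in off_regions:
            if a > start:
                limit = min(limit, a)
                break
        duration = min(dur_steps, limit - start)
        events.append(
            TaskEvent(start=start, duration=duration,
                      load=fail.extra_load.as_dict(), is_failure=True)
        )
    return events


def events_to_frame(events: list[TaskEvent]):
    """Tidy export of an event list."""
    import pandas as pd

    rows = []
    for e in events:
        row = {"start": e.start, "duration": e.duration,
               "is_failure": e.is_failure, "inter_arrival": e.inter_arrival}
        row.update({f"load_{c}": e.load.get(c, 0.0) for c in LOAD_COMPONENTS})
        rows.append(row)
    return pd.DataFrame(rows)
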