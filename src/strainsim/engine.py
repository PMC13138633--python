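"""Simulation loop, packaged scenarios and output writing.

One step of the loop follows the causal chain task -> workload -> stress ->
degradation -> performance: resolve the active task and failure window,
assess the task at its onset (the demanding flag is evaluated once when the
task is received and held for its duration), advance the stress stocks,
advance the capacities, then evaluate the OLE components.  Identical
configurations and seeds give bit-identical records.

The four packaged scenarios mirror a repetitive assembly-line use case:

* ``normal`` -- task loads drawn close to (95% of) the basic task load;
* ``overload`` -- task loads drawn 25% above the basic task load;
* ``hourly_breaks`` -- normal loads plus a 10-minute break after every
  worked hour (skipping the lunch hour);
* ``reduced_pace`` -- normal loads with the work pace doubled (half the
  arrival rate) after the lunch break.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .capacity import applied_base_rates, dynamic_circumstantial_rates
from .config import (
    CAPACITY_COMPONENTS,
    BasicTaskLoad,
    CapacityState,
    HourlyBreaks,
    ReducedPace,
    ScenarioConfig,
    TaskLoad,
    apply_circumstantial_static,
    apply_personal_static_effects,
    perception_gain,
)
from .performance import classify_series, compute_ole_series
from .perception import WORKLOAD_COMPONENTS, assess_task
from .scheduling import (
    build_work_schedule,
    generate_failure_events,
    generate_task_events,
)
from .stress import StressParams, StressState, step_stress

SCENARIO_NAMES = ("normal", "overload", "hourly_breaks", "reduced_pace")


@dataclass
class SimulationResult:
    """Per-step records, shift summary and provenance of one run."""

    records: pd.DataFrame
    summary: dict
    provenance: dict
    assessments: list = field(default_factory=list, repr=False)

    def recompute_summary(self) -> dict:
        """Re-derive the summary from the records (consistency check)."""
        r = self.records
        on = r["on_task"].to_numpy(dtype=bool)
        out = {
            "end_capacities": {
                c: float(r[f"cap_{c}"].iloc[-1]) for c in CAPACITY_COMPONENTS
            } if len(r) else {},
            "total_demanding_tasks": (
                sum(1 for a in self.assessments if a.demanding)
                if self.assessments else self.summary["total_demanding_tasks"]
            ),
            "steps_sa_active": int(r["sa_status"].sum()),
            "steps_ac_active": int(r["ac_status"].sum()),
            "steps_ch_active": int(r["ch_status"].sum()),
            "end_stocks": {
                "sa": float(r["sa"].iloc[-1]) if len(r) else 0.0,
                "ac": float(r["ac"].iloc[-1]) if len(r) else 0.0,
                "ch": float(r["ch"].iloc[-1]) if len(r) else 0.0,
            },
            "mean_ole": float(r["ole"].mean()) if len(r) else 1.0,
            "end_ole": float(r["ole"].iloc[-1]) if len(r) else 1.0,
        }
        if on.any():
            lab = r.loc[on, "state"]
            out["dominant_state"] = lab.mode().iloc[0]
        else:
            out["dominant_state"] = "nominal"
        return out


def _config_hash(config: ScenarioConfig) -> str:
    payload = config.model_dump_json().encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_simulation(config: ScenarioConfig) -> SimulationResult:
    """Simulate one shift under the given configuration."""
    t0 = _time.perf_counter()
    dt = config.dt
    n = config.n_steps
    spm = 60.0 / dt

    # --- static initialisation ------------------------------------------
    lunch_min = config.shift.lunch_break.length if config.shift.lunch_break else 0.0
    ref_on_steps = max(1, int(round((config.shift.duration - lunch_min) * spm)))
    cap0 = apply_personal_static_effects(config.profile, config.capacity, ref_on_steps)
    cap_state, basic, mults = apply_circumstantial_static(
        cap0, config.basic, config.circumstantial
    )
    base_rates = applied_base_rates(cap_state, mults)  # innate x static multiplier
    innate = cap_state.natural_rates
    gain = perception_gain(config.profile)

    schedule = build_work_schedule(config.shift, dt)
    events = generate_task_events(
        schedule, basic, config.task_generation, config.seed,
        reduced_pace=config.shift.reduced_pace, posture_scale=config.posture_scale,
    )
    failures = generate_failure_events(schedule, config.circumstantial, config.seed)

    # --- per-step lookups ------------------------------------------------
    task_idx = np.full(n, -1, dtype=np.int32)
    for i, ev in enumerate(events):
        task_idx[ev.start:ev.end] = i
    fail_active = np.zeros(n, dtype=np.int8)
    for ev in failures:
        fail_active[ev.start:ev.end] += 1
    extra_load = config.circumstantial.failure.extra_load.as_dict()
    # tasks overlapping a failure window carry the extra load
    overlapped = np.zeros(len(events), dtype=bool)
    for i, ev in enumerate(events):
        if fail_active[ev.start:ev.end].any():
            overlapped[i] = True

    sparams = StressParams.from_profile(config.profile, dt)
    profile = config.profile
    comps = CAPACITY_COMPONENTS
    caps = [cap_state.capacities[c] for c in comps]
    init = [cap_state.initial[c] for c in comps]
    base = [base_rates[c] for c in comps]
    extra_deg = [config.circumstantial.failure.extra_degradation.get(c, 0.0)
                 for c in comps]
    enh = profile.enhancement_multiplier
    coeff_ac = profile.stress_degradation_coeff_acute
    coeff_ch = profile.stress_degradation_coeff_chronic

    on_list = schedule.on_task.tolist()
    tidx_list = task_idx.tolist()
    fail_list = fail_active.tolist()

    # --- record arrays ---------------------------------------------------
    rec_sa = np.empty(n); rec_ac = np.empty(n); rec_ch = np.empty(n)
    rec_sa_st = np.empty(n, dtype=np.int8)
    rec_ac_st = np.empty(n, dtype=np.int8)
    rec_ch_st = np.empty(n, dtype=np.int8)
    rec_caps = np.empty((n, 6))
    rec_mult = np.empty(n)
    rec_add = np.empty(n)
    rec_dem = np.zeros(n, dtype=np.int8)
    workload_rows = np.zeros((len(events), len(WORKLOAD_COMPONENTS)))

    state = StressState()
    assessments: list = []
    demanding_of = [0] * len(events)
    relax_of = [False] * len(events)
    current_task = -1

    for t in range(n):
        on = on_list[t]
        ti = tidx_list[t]
        nf = fail_list[t]
        if ti != current_task:
            current_task = ti
            if ti >= 0:
                ev = events[ti]
                load = dict(ev.load)
                if overlapped[ti]:
                    for c, v in extra_load.items():
                        load[c] = load.get(c, 0.0) + v
                    load["visual"] = min(load["visual"], 7.0)
                    load["auditory"] = min(load["auditory"], 7.0)
                    load["cognitive"] = min(load["cognitive"], 7.0)
                    load["psychomotor"] = min(load["psychomotor"], 7.0)
                # perceived outflow rates at onset (pre-update statuses);
                # the vigilance enhancement is an arousal state, not a
                # perceived competence gain, so it does not enter the
                # capability comparison
                if state.ac_status:
                    a = coeff_ac * state.ac + (
                        coeff_ch * state.ch if state.ch_status else 0.0
                    )
                else:
                    a = 0.0
                snapshot = CapacityState(
                    capacities={c: caps[j] for j, c in enumerate(comps)},
                    initial={c: init[j] for j, c in enumerate(comps)},
                    natural_rates=dict(innate),
                    time_variation=cap_state.time_variation,
                )
                dyn = dynamic_circumstantial_rates(config.circumstantial, nf)
                cur_rates = {
                    c: base[j] + a + dyn.get(c, 0.0)
                    for j, c in enumerate(comps)
                }
                assessment = assess_task(
                    load, ev.inter_arrival, basic, snapshot, cur_rates,
                    profile.demand_threshold, profile.capability_threshold,
                    config.interactions, gain=gain,
                    moderation_cap=profile.moderation_cap,
                )
                assessments.append(assessment)
                demanding_of[ti] = assessment.demanding
                relax_of[ti] = assessment.extra_relaxation
                tot = assessment.total_workload()
                workload_rows[ti] = [tot.get(c, 0.0) for c in WORKLOAD_COMPONENTS]
        demanding = demanding_of[ti] if ti >= 0 else 0
        relaxing = relax_of[ti] if ti >= 0 else False
        step_stress(state, demanding, on, sparams, extra_relaxation=relaxing)
        # capacity outflow using the just-updated statuses
        if state.ac_status:
            mult = 1.0
            additive = coeff_ac * state.ac + (
                coeff_ch * state.ch if state.ch_status else 0.0
            )
        elif state.sa_status:
            mult = enh
            additive = 0.0
        else:
            mult = 1.0
            additive = 0.0
        if on:
            for j in range(6):
                v = caps[j] - (base[j] * mult + additive + extra_deg[j] * nf)
                caps[j] = v if v > 0.0 else 0.0
        rec_sa[t] = state.sa; rec_ac[t] = state.ac; rec_ch[t] = state.ch
        rec_sa_st[t] = state.sa_status
        rec_ac_st[t] = state.ac_status
        rec_ch_st[t] = state.ch_status
        rec_caps[t] = caps
        rec_mult[t] = mult
        rec_add[t] = additive
        rec_dem[t] = demanding

    # --- vectorised post-processing --------------------------------------
    on_arr = schedule.on_task.astype(float)
    base_arr = np.array(base)
    extra_arr = np.array(extra_deg)
    fail_arr = fail_active.astype(float)
    cap_ratio = {}
    excess = {}
    for j, c in enumerate(comps):
        cap_ratio[c] = rec_caps[:, j] / init[j] if init[j] > 0 else np.zeros(n)
        current = base_arr[j] * rec_mult + rec_add + extra_arr[j] * fail_arr
        excess[c] = np.maximum(0.0, (current - base_arr[j]) / base_arr[j]) \
            if base_arr[j] > 0 else np.zeros(n)
    avail, prod, qual, ole = compute_ole_series(
        cap_ratio, excess, rec_sa_st.astype(float),
        (fail_active > 0).astype(float),  # distractor is an indicator
        config.performance,
    )
    labels = classify_series(
        rec_caps, rec_sa, rec_sa_st.astype(float), rec_ac_st.astype(float),
        rec_dem.astype(float), profile.sa_value_threshold, config.state_rules,
        spm,
    )

    records = pd.DataFrame({
        "time_min": np.arange(n) * dt / 60.0,
        "on_task": schedule.on_task,
        "task_active": (task_idx >= 0).astype(np.int8),
        "failure_active": fail_active,
        "demanding": rec_dem,
        "sa": rec_sa, "ac": rec_ac, "ch": rec_ch,
        "sa_status": rec_sa_st, "ac_status": rec_ac_st, "ch_status": rec_ch_st,
        **{f"cap_{c}": rec_caps[:, j] for j, c in enumerate(comps)},
        **{
            f"workload_{c}": np.where(
                task_idx >= 0, workload_rows[np.maximum(task_idx, 0), k], 0.0
            )
            for k, c in enumerate(WORKLOAD_COMPONENTS)
        },
        "availability": avail, "productivity": prod, "quality": qual, "ole": ole,
        "state": labels,
    })

    n_demanding = int(sum(demanding_of))
    on_mask = schedule.on_task.astype(bool)
    if n and on_mask.any():
        lab_series = pd.Series(labels[on_mask])
        dominant = lab_series.mode().iloc[0]
    else:
        dominant = "nominal"
    summary = {
        "total_tasks": len(events),
        "total_failures": len(failures),
        "total_demanding_tasks": n_demanding,
        "steps_sa_active": int(rec_sa_st.sum()),
        "steps_ac_active": int(rec_ac_st.sum()),
        "steps_ch_active": int(rec_ch_st.sum()),
        "end_capacities": {c: float(rec_caps[-1, j]) for j, c in enumerate(comps)}
        if n else {c: cap_state.capacities[c] for c in comps},
        "end_stocks": {
            "sa": float(rec_sa[-1]) if n else 0.0,
            "ac": float(rec_ac[-1]) if n else 0.0,
            "ch": float(rec_ch[-1]) if n else 0.0,
        },
        "mean_ole": float(ole.mean()) if n else 1.0,
        "end_ole": float(ole[-1]) if n else 1.0,
        "dominant_state": dominant,
    }
    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "n_steps": n,
        "dt": dt,
        "runtime_s": round(_time.perf_counter() - t0, 3),
    }
    return SimulationResult(records=records, summary=summary,
                            provenance=provenance, assessments=assessments)


def scenario_config(name: str, seed: int = 0) -> ScenarioConfig:
    """Packaged configuration preset for one of the four scenarios."""
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; choose one of {', '.join(SCENARIO_NAMES)}"
        )
    cfg = ScenarioConfig(seed=seed)
    if name == "overload":
        b = BasicTaskLoad()
        bench = {c: min(1.25 * v, 7.0) if c in
                 ("visual", "auditory", "cognitive", "psychomotor") else 1.25 * v
                 for c, v in b.as_dict().items()}
        cfg = cfg.model_copy(update={
            "task_generation": cfg.task_generation.model_copy(
                update={"benchmark": TaskLoad(**bench)}
            )
        })
    elif name == "hourly_breaks":
        cfg = cfg.model_copy(update={
            "shift": cfg.shift.model_copy(update={
                "hourly_breaks": HourlyBreaks(length=10.0)
            })
        })
    elif name == "reduced_pace":
        cfg = cfg.model_copy(update={
            "shift": cfg.shift.model_copy(update={
                "reduced_pace": ReducedPace(after=255.0, pace_factor=2.0)
            })
        })
    return ScenarioConfig.model_validate(cfg.model_dump())


def run_scenario(name: str, seed: int = 0) -> SimulationResult:
    """Run one of the packaged scenarios."""
    return run_simulation(scenario_config(name, seed))


def write_outputs(result: SimulationResult, out_path, plots: bool = False) -> list[Path]:
    """Write the tidy per-step CSV, the JSON summary and optional plots."""
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    csv_path = out / "timeseries.csv"
    try:
        result.records.to_csv(csv_path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write time series to {csv_path}: {exc}") from exc
    written.append(csv_path)
    json_path = out / "summary.json"
    payload = {"summary": result.summary, "provenance": result.provenance}
    try:
        json_path.write_text(json.dumps(payload, indent=2))
    except OSError as exc:
        raise OSError(f"cannot write summary to {json_path}: {exc}") from exc
    written.append(json_path)
    if plots:
        written.extend(_write_plots(result, out))
    return written


def _write_plots(result: SimulationResult, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = result.records
    t = r["time_min"]
    fig, axes = plt.subplots(3, 1, figsize=(9, 9), sharex=True)
    axes[0].plot(t, r["sa"], label="sustained attention")
    axes[0].plot(t, r["ac"], label="acute stress")
    axes[0].plot(t, r["ch"], label="chronic stress")
    axes[0].set_ylabel("stress units")
    axes[0].legend(loc="upper left", fontsize=8)
    for c in CAPACITY_COMPONENTS:
        axes[1].plot(t, r[f"cap_{c}"], label=c)
    axes[1].set_ylabel("capacity")
    axes[1].legend(loc="lower left", fontsize=8, ncol=3)
    axes[2].plot(t, r["ole"], label="OLE", color="k")
    axes[2].plot(t, r["availability"], alpha=0.6, label="availability")
    axes[2].plot(t, r["productivity"], alpha=0.6, label="productivity")
    axes[2].plot(t, r["quality"], alpha=0.6, label="quality")
    axes[2].set_ylabel("probability")
    axes[2].set_xlabel("time (min)")
    axes[2].legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    path = out / "trajectories.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return [path]


def compare_scenarios(names: list[str], seeds: list[int]) -> pd.DataFrame:
    """Paired-seed comparison table of scenario summaries."""
    rows = []
    for seed in seeds:
        for name in names:
            res = run_scenario(name, seed)
            row = {"scenario": name, "seed": seed}
            row.update({
                k: v for k, v in res.summary.items()
                if not isinstance(v, dict)
            })
            row["end_ch"] = res.summary["end_stocks"]["ch"]
            row["end_sa"] = res.summary["end_stocks"]["sa"]
            rows.append(row)
    return pd.DataFrame(rows)
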