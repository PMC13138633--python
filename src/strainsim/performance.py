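"""Overall Labour Effectiveness (OLE) and stress-induced state labels.

Performance is predicted as three probabilities -- availability (keeping
the predefined pace; supported by the time proficiency and the psychomotor
capacity, hindered by distractors such as an active failure), productivity
(force and posture capacities) and quality (cognitive and visual
capacities, compensated by active sustained attention) -- whose product is
the OLE.  Each component is a clamped additive form: the mean of its
supporting capacity ratios minus a weighted excess-degradation term, where
the capacity ratios are normalised by the shift-start values so that a
fresh worker starts at exactly 100% on all three, and *excess degradation*
is the relative excess of the current over the applied natural outflow
(mirroring the capability score).

The worker's state label follows a precedence rule over a sliding window:
burnout (all capacities depleted) > fatigue (any depleted) > overload
(acute stress active most of the window) > under-load (almost no demanding
tasks and sustained attention below threshold throughout) > optimal
(regular sustained-attention activity with little acute stress) > nominal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PerformanceWeights, StateRules

STATE_LABELS = ("nominal", "optimal", "under_load", "overload", "fatigue", "burnout")

#: capacity groups supporting each OLE component
AVAILABILITY_COMPONENTS = ("psychomotor",)
PRODUCTIVITY_COMPONENTS = ("force", "posture")
QUALITY_COMPONENTS = ("cognitive", "visual")


def _clamp01(x):
    return np.clip(x, 0.0, 1.0)


@dataclass
class PerformanceState:
    """Availability, productivity, quality probabilities and their product."""

    availability: float
    productivity: float
    quality: float

    @property
    def ole(self) -> float:
        return self.availability * self.productivity * self.quality


def _excess(current: float, natural: float) -> float:
    if natural <= 0.0:
        return 0.0
    return max(0.0, (current - natural) / natural)


def compute_ole(
    capacity_ratios: dict[str, float],
    natural_rates: dict[str, float],
    current_rates: dict[str, float],
    sa_status: int,
    distractors: tuple[float, float] = (0.0, 0.0),
    weights: PerformanceWeights | None = None,
) -> PerformanceState:
    """OLE components for one step.

    ``capacity_ratios`` are current/initial capacities; ``natural_rates``
    the applied (post-static) natural outflows and ``current_rates`` the
    actually applied outflows; ``distractors`` is the (pace_increment,
    problem_rate) pair.
    """
    w = weights or PerformanceWeights()
    pace_inc, problem_rate = distractors

    def group_excess(comps) -> float:
        vals = [_excess(current_rates[c], natural_rates[c]) for c in comps]
        return sum(vals) / len(vals) if vals else 0.0

    avail = float(_clamp01(
        (1.0 + capacity_ratios["psychomotor"]) / 2.0
        - w.w_availability * group_excess(AVAILABILITY_COMPONENTS)
        - w.w_distraction * (pace_inc + problem_rate)
    ))
    prod = float(_clamp01(
        (capacity_ratios["force"] + capacity_ratios["posture"]) / 2.0
        - w.w_productivity * group_excess(PRODUCTIVITY_COMPONENTS)
    ))
    qual = float(_clamp01(
        (capacity_ratios["cognitive"] + capacity_ratios["visual"]) / 2.0
        - w.w_quality * group_excess(QUALITY_COMPONENTS)
        + w.w_attention * sa_status
    ))
    return PerformanceState(availability=avail, productivity=prod, quality=qual)


def compute_ole_series(
    cap_ratio: dict[str, np.ndarray],
    excess: dict[str, np.ndarray],
    sa_status: np.ndarray,
    problem_rate: np.ndarray,
    weights: PerformanceWeights,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLE over a whole run (same formulas as compute_ole)."""
    w = weights
    avail = _clamp01(
        (1.0 + cap_ratio["psychomotor"]) / 2.0
        - w.w_availability * excess["psychomotor"]
        - w.w_distraction * (w.pace_increment + problem_rate)
    )
    prod = _clamp01(
        (cap_ratio["force"] + cap_ratio["posture"]) / 2.0
        - w.w_productivity * (excess["force"] + excess["posture"]) / 2.0
    )
    qual = _clamp01(
        (cap_ratio["cognitive"] + cap_ratio["visual"]) / 2.0
        - w.w_quality * (excess["cognitive"] + excess["visual"]) / 2.0
        + w.w_attention * sa_status
    )
    return avail, prod, qual, avail * prod * qual


def classify_state(
    capacities: dict[str, float],
    sa_status_window: np.ndarray,
    ac_status_window: np.ndarray,
    demanding_window: np.ndarray,
    sa_below_threshold_all: bool,
    rules: StateRules,
) -> str:
    """Label the worker's state from the current capacities and a trailing
    window of statuses and demanding flags.

    Precedence: burnout > fatigue > overload > under_load > optimal >
    nominal.
    """
    n = len(ac_status_window)
    if n == 0:
        raise ValueError("classification window is empty")
    eps = rules.depletion_eps
    vals = list(capacities.values())
    if all(v <= eps for v in vals):
        return "burnout"
    if any(v <= eps for v in vals):
        return "fatigue"
    ac_frac = float(np.mean(ac_status_window))
    if ac_frac >= rules.overload_fraction:
        return "overload"
    dem_frac = float(np.mean(demanding_window))
    if dem_frac < rules.under_fraction and sa_below_threshold_all:
        return "under_load"
    sa_frac = float(np.mean(sa_status_window))
    if sa_frac >= rules.optimal_fraction and ac_frac < rules.optimal_acute_cap:
        return "optimal"
    return "nominal"


def _trailing_fraction(x: np.ndarray, window: int) -> np.ndarray:
    """Mean of x over the trailing window ending at each step (partial
    windows at the start use the available history)."""
    cs = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - window + 1, 0)
    return (cs[idx + 1] - cs[lo]) / (idx - lo + 1)


def classify_series(
    capacities: np.ndarray,  # (n, 6)
    sa: np.ndarray,
    sa_status: np.ndarray,
    ac_status: np.ndarray,
    demanding: np.ndarray,
    sa_value_threshold: float,
    rules: StateRules,
    steps_per_minute: float,
) -> np.ndarray:
    """Per-step state labels for a whole run (vectorised classify_state)."""
    n = len(sa)
    window = max(1, int(round(rules.window * steps_per_minute)))
    eps = rules.depletion_eps
    cap_min = capacities.min(axis=1)
    cap_max = capacities.max(axis=1)
    ac_frac = _trailing_fraction(ac_status, window)
    sa_frac = _trailing_fraction(sa_status, window)
    dem_frac = _trailing_fraction(demanding, window)
    sa_over = _trailing_fraction((sa > sa_value_threshold).astype(float), window)

    labels = np.full(n, "nominal", dtype=object)
    optimal = (sa_frac >= rules.optimal_fraction) & (ac_frac < rules.optimal_acute_cap)
    labels[optimal] = "optimal"
    under = (dem_frac < rules.under_fraction) & (sa_over == 0.0)
    labels[under] = "under_load"
    labels[ac_frac >= rules.overload_fraction] = "overload"
    labels[cap_min <= eps] = "fatigue"
    labels[cap_max <= eps] = "burnout"
    return labels
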