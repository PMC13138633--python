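"""Per-step advancement of the six capacity stocks.

Each on-task step the capacities drain by a constant outflow: the applied
natural degradation (innate rate times the static circumstantial
multiplier, reduced by the enhancement multiplier while sustained attention
is beneficially active), plus the additive stress degradation, plus any
dynamic circumstantial extras (e.g. while a machine failure is being
handled).  Capacities floor at zero and hold constant during breaks --
in-shift recovery is not modelled (regeneration belongs to between-shift
processes).
"""

from __future__ import annotations

from .config import CAPACITY_COMPONENTS, CapacityState, CircumstantialConfig


def applied_base_rates(
    capacity: CapacityState, multipliers: dict[str, float]
) -> dict[str, float]:
    """Fold the static degradation multipliers into the natural rates."""
    return {
        c: capacity.natural_rates[c] * multipliers.get(c, 1.0)
        for c in CAPACITY_COMPONENTS
    }


def step_capacity(
    capacity: CapacityState,
    modifier: tuple[float, float],
    dynamic_extra: dict[str, float] | None,
    on_task: int,
    base_rates: dict[str, float] | None = None,
) -> CapacityState:
    """Advance the capacities one step (mutates and returns the state).

    ``modifier`` is the (multiplier, additive-rate) pair from the stress
    state; ``base_rates`` default to the innate natural rates (pass the
    statically multiplied rates when circumstantial multipliers apply).
    """
    if not on_task:
        return capacity
    mult, additive = modifier
    rates = base_rates or capacity.natural_rates
    caps = capacity.capacities
    for c in CAPACITY_COMPONENTS:
        extra = dynamic_extra.get(c, 0.0) if dynamic_extra else 0.0
        v = caps[c] - (rates[c] * mult + additive + extra)
        caps[c] = v if v > 0.0 else 0.0
    return capacity


def dynamic_circumstantial_rates(
    circ: CircumstantialConfig, active_failures: int
) -> dict[str, float]:
    """Extra per-component degradation from currently active failures.

    ``active_failures`` counts overlapping failure-handling windows;
    simultaneous windows add.  Static multipliers are not included here --
    they are folded into the base rates at initialisation.
    """
    if active_failures <= 0:
        return {}
    return {
        c: rate * active_failures
        for c, rate in circ.failure.extra_degradation.items()
    }
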