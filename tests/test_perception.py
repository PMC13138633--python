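"""Workload perception and the demand-control assessment."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainsim.config import (
    CAPACITY_COMPONENTS,
    BasicTaskLoad,
    CapacityState,
    InteractionRule,
    PersonalProfile,
    apply_personal_static_effects,
)
from strainsim.perception import (
    capability_score,
    classify_demanding,
    compute_interacted_load,
    compute_workload,
    demand_score,
    time_pressure,
)


def fresh_capacity(**levels) -> CapacityState:
    cap = apply_personal_static_effects(PersonalProfile())
    if levels:
        caps = dict(cap.capacities)
        caps.update(levels)
        cap = CapacityState(capacities=caps, initial=cap.initial,
                            natural_rates=cap.natural_rates,
                            time_variation=cap.time_variation)
    return cap


BASIC = BasicTaskLoad(posture=5.0, force=50.0, task_time=30.0, visual=3.0,
                      auditory=3.0, cognitive=2.5, psychomotor=2.0)


def load_at(**over):
    base = {c: getattr(BASIC, c) for c in
            ("posture", "force", "task_time", "visual", "auditory",
             "cognitive", "psychomotor")}
    base.update(over)
    return base


class TestComputeWorkload:
    def test_load_below_benchmark_yields_zero(self):
        wl = compute_workload(load_at(force=20.0), BASIC, fresh_capacity())
        assert wl["force"] == 0.0

    def test_posture_excess_at_full_capacity(self):
        wl = compute_workload(load_at(posture=7.0), BASIC, fresh_capacity())
        assert wl["posture"] == pytest.approx(0.4)  # (7 - 5) / 5

    def test_load_identical_to_basic_is_all_zero(self):
        wl = compute_workload(load_at(), BASIC, fresh_capacity())
        assert all(v == 0.0 for v in wl.values())

    def test_lower_capacity_raises_perception(self):
        full = compute_workload(load_at(posture=7.0), BASIC, fresh_capacity())
        tired = compute_workload(load_at(posture=7.0), BASIC,
                                 fresh_capacity(posture=0.5))
        assert tired["posture"] == pytest.approx(2 * full["posture"])

    def test_depleted_capacity_uses_the_moderation_cap(self):
        wl = compute_workload(load_at(posture=7.0), BASIC,
                              fresh_capacity(posture=0.0), moderation_cap=10.0)
        assert wl["posture"] == pytest.approx(0.4 * 10.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        comp=st.sampled_from(("posture", "force", "visual", "cognitive")),
        bump=st.floats(min_value=0.0, max_value=2.0),
    )
    def test_raising_one_component_never_lowers_workload(self, comp, bump):
        lo = compute_workload(load_at(), BASIC, fresh_capacity())
        scale = getattr(BASIC, comp)
        hi_load = load_at(**{comp: min(getattr(BASIC, comp) + bump, 7.0)
                             if comp in ("visual", "cognitive")
                             else getattr(BASIC, comp) + bump * scale})
        hi = compute_workload(hi_load, BASIC, fresh_capacity())
        assert all(hi[c] >= lo[c] for c in hi)
        assert demand_score(hi, 0.0)[0] >= demand_score(lo, 0.0)[0]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.dictionaries(
        st.sampled_from(CAPACITY_COMPONENTS),
        st.floats(min_value=0.05, max_value=1.0), min_size=6, max_size=6))
    def test_matches_per_component_oracle(self, caps):
        load = load_at(posture=6.5, force=70.0, visual=4.0, cognitive=1.0)
        cap = fresh_capacity(**caps)
        wl = compute_workload(load, BASIC, cap)
        for c in CAPACITY_COMPONENTS:
            excess = max(0.0, (load[c] - getattr(BASIC, c)) / getattr(BASIC, c))
            moderation = min(cap.initial[c] / caps[c], 10.0)
            assert wl[c] == pytest.approx(excess * moderation)


class TestTimePressure:
    def test_no_pressure_within_tolerance_band_at_normal_pace(self):
        value, relax = time_pressure(200.0, 31.0, BASIC, time_variation=0.0)
        assert value == 0.0 and not relax

    def test_short_interarrival_gives_the_deficit_ratio(self):
        basic = BasicTaskLoad(basic_pace_time=90.0)
        value, _ = time_pressure(45.0, basic.task_time, basic, time_variation=0.0)
        assert value == pytest.approx(0.5)  # (90 - 45) / 90

    def test_faster_than_basic_completion_flags_extra_relaxation(self):
        value, relax = time_pressure(200.0, 15.0, BASIC, time_variation=0.0)
        assert value == 0.0 and relax

    def test_slow_task_gives_relative_shortfall(self):
        # eff 40 s vs band top 33 s -> (40 - 33) / 30
        value, _ = time_pressure(200.0, 40.0, BASIC, time_variation=0.0)
        assert value == pytest.approx((40.0 - 33.0) / 30.0)

    def test_proficiency_spread_inflates_the_required_time(self):
        tight, _ = time_pressure(200.0, 32.0, BASIC, time_variation=0.0)
        loose, _ = time_pressure(200.0, 32.0, BASIC, time_variation=0.2)
        assert tight == 0.0 and loose > 0.0

    def test_negative_interarrival_is_an_error(self):
        with pytest.raises(ValueError, match="inter-arrival"):
            time_pressure(-1.0, 30.0, BASIC, 0.0)

    def test_first_task_infinite_gap_has_no_pace_pressure(self):
        value, _ = time_pressure(math.inf, 31.0, BASIC, 0.0)
        assert value == 0.0


class TestInteractedLoad:
    RULE = InteractionRule(triggers={"posture": 0.3, "task_time": 0.3},
                           target="force", magnitude=0.25)

    def test_all_components_below_thresholds_add_nothing(self):
        assert compute_interacted_load({"posture": 0.1, "time": 0.1}, [self.RULE]) == {}

    def test_joint_exceedance_adds_to_the_target(self):
        wl = {"posture": 0.5, "time": 0.4, "force": 0.0}
        assert compute_interacted_load(wl, [self.RULE]) == {"force": 0.25}

    def test_two_rules_firing_on_same_target_add_up(self):
        rules = [self.RULE,
                 InteractionRule(triggers={"posture": 0.2}, target="force",
                                 magnitude=0.1)]
        wl = {"posture": 0.5, "time": 0.4}
        assert compute_interacted_load(wl, rules) == {"force": pytest.approx(0.35)}

    def test_default_rule_set_is_empty(self):
        assert compute_interacted_load({"posture": 9.9}, []) == {}


class TestScores:
    def test_all_zero_workload_scores_zero(self):
        score, exceeds = demand_score({c: 0.0 for c in CAPACITY_COMPONENTS}, 0.05)
        assert score == 0.0 and not exceeds

    def test_mean_over_challenging_components_only(self):
        wl = {"posture": 0.4, "visual": 0.23, "force": 0.0, "time": 0.0}
        score, exceeds = demand_score(wl, 0.3)
        assert score == pytest.approx(0.315)
        assert exceeds

    def test_capability_baseline_is_zero(self):
        cap = fresh_capacity()
        score, exceeds = capability_score(
            dict(cap.natural_rates), dict(cap.natural_rates), cap, 0.0)
        assert score == 0.0 and not exceeds

    def test_capability_from_single_fast_component(self):
        cap = fresh_capacity()
        current = dict(cap.natural_rates)
        current["posture"] = 1.5 * current["posture"]
        score, _ = capability_score(current, cap.natural_rates, cap, 0.1)
        assert score == pytest.approx(0.5)

    def test_only_fast_components_enter_the_mean(self):
        cap = fresh_capacity()
        current = dict(cap.natural_rates)
        for c in ("posture", "visual", "psychomotor"):
            current[c] = 2.0 * current[c]
        current["force"] = 0.5 * current["force"]  # slower than natural: excluded
        score, _ = capability_score(current, cap.natural_rates, cap, 0.1)
        assert score == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "d, c, expected", [(True, True, 1), (True, False, 0),
                           (False, True, 0), (False, False, 0)])
    def test_demanding_requires_both_exceedances(self, d, c, expected):
        assert classify_demanding(d, c) == expected

    def test_load_below_basic_cannot_be_demanding(self):
        wl = compute_workload(load_at(force=20.0, posture=4.0), BASIC,
                              fresh_capacity())
        score, exceeds = demand_score(wl, 0.0)
        assert score == 0.0
        assert classify_demanding(exceeds, True) == 0
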