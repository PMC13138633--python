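"""Stress stock dynamics against a straight-line oracle re-implementation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainsim.config import PersonalProfile
from strainsim.stress import (
    StressParams,
    StressState,
    step_stress,
    stress_capacity_modifier,
)


def params(**over) -> StressParams:
    defaults = dict(sa_accum=1.0, sa_relax=0.5, ac_accum=1.0, ac_relax=0.25,
                    ch_accum=1.0, sa_value=1e9, ac_value=1e9,
                    sa_duration_steps=10**9, ac_duration_steps=10**9,
                    relaxation_boost=1.5)
    defaults.update(over)
    return StressParams(**defaults)


def oracle_trajectory(demand, on, p: StressParams, relax_flags=None):
    """Independent, literal re-implementation of the update rules.

    Kept deliberately plain (scalar step-through with explicit branches) and
    separate from the package's implementation.
    """
    sa = ac = ch = 0.0
    sa_over = ac_over = 0
    out = []
    for i in range(len(demand)):
        boost = p.relaxation_boost if (relax_flags is not None and relax_flags[i]) else 1.0
        working = (on[i] == 1) and (demand[i] == 1)
        if working:
            sa = sa + p.sa_accum
        else:
            sa = sa - p.sa_relax * boost
            if sa < 0:
                sa = 0.0
        ac_acc = working and (sa > p.sa_value or sa_over >= p.sa_duration_steps)
        if ac_acc:
            ac = ac + p.ac_accum
        else:
            ac = ac - p.ac_relax * boost
            if ac < 0:
                ac = 0.0
        ch_acc = ac_acc and (ac > p.ac_value or ac_over >= p.ac_duration_steps)
        if ch_acc:
            ch = ch + p.ch_accum
        sa_over = sa_over + 1 if sa > p.sa_value else 0
        ac_over = ac_over + 1 if ac > p.ac_value else 0
        out.append((sa, ac, ch))
    return out


class TestStepStress:
    def test_unit_accumulation_under_demanding_work(self):
        state = StressState()
        p = params(sa_accum=1.0)
        for _ in range(10):
            step_stress(state, 1, 1, p)
        assert state.sa == 10.0 and state.ac == 0.0 and state.ch == 0.0

    def test_zero_stocks_absorb_without_demand(self):
        state = StressState()
        p = params()
        for _ in range(500):
            step_stress(state, 0, 1, p)
        assert state.sa == 0.0 and state.ac == 0.0 and state.ch == 0.0

    def test_accumulate_then_relax_pattern(self):
        # 5 demanding steps at rate 1 then 4 idle at 0.5 -> 5 - 2 = 3
        state = StressState()
        p = params(sa_accum=1.0, sa_relax=0.5)
        for _ in range(5):
            step_stress(state, 1, 1, p)
        for _ in range(4):
            step_stress(state, 0, 1, p)
        assert state.sa == pytest.approx(3.0)

    def test_acute_starts_when_sustained_attention_crosses_threshold(self):
        # threshold 10: acute starts at step 11, reaching 5 after step 15
        state = StressState()
        p = params(sa_value=10.0)
        for _ in range(15):
            step_stress(state, 1, 1, p)
        assert state.sa == 15.0
        assert state.ac == pytest.approx(5.0)
        assert state.ch == 0.0

    def test_extra_relaxation_boost_speeds_recovery(self):
        p = params(sa_relax=0.5, relaxation_boost=1.5)
        plain, boosted = StressState(sa=10.0), StressState(sa=10.0)
        step_stress(plain, 0, 1, p)
        step_stress(boosted, 0, 1, p, extra_relaxation=True)
        assert plain.sa == pytest.approx(9.5)
        assert boosted.sa == pytest.approx(9.25)

    def test_stocks_non_increasing_during_breaks(self):
        state = StressState(sa=50.0, ac=30.0, ch=5.0, sa_status=1, ac_status=1,
                            ch_status=1)
        p = params(sa_value=20.0, ac_value=20.0)
        prev = (state.sa, state.ac, state.ch)
        for _ in range(100):
            step_stress(state, 1, 0, p)  # demanding task queued, but on break
            cur = (state.sa, state.ac, state.ch)
            assert all(c <= p_ for c, p_ in zip(cur, prev))
            prev = cur

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(1, 400),
        sa_value=st.floats(1.0, 30.0),
        ac_value=st.floats(1.0, 30.0),
    )
    def test_matches_straight_line_oracle_exactly(self, seed, n, sa_value, ac_value):
        rng = np.random.default_rng(seed)
        demand = rng.integers(0, 2, n)
        on = rng.integers(0, 2, n)
        relax = rng.integers(0, 2, n).astype(bool)
        p = params(sa_value=sa_value, ac_value=ac_value,
                   sa_duration_steps=20, ac_duration_steps=20)
        state = StressState()
        got = []
        for i in range(n):
            step_stress(state, int(demand[i]), int(on[i]), p,
                        extra_relaxation=bool(relax[i]))
            got.append((state.sa, state.ac, state.ch))
        assert got == oracle_trajectory(demand, on, p, relax)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(10, 300))
    def test_cascade_ordering_holds_on_random_sequences(self, seed, n):
        rng = np.random.default_rng(seed)
        demand = rng.integers(0, 2, n)
        p = params(sa_value=5.0, ac_value=5.0)
        state = StressState()
        sa_crossed = ac_crossed = False
        prev_ch = 0.0
        for i in range(n):
            step_stress(state, int(demand[i]), 1, p)
            if state.ac > 0:
                assert sa_crossed or state.sa > p.sa_value
            if state.ch > prev_ch:
                assert ac_crossed or state.ac > p.ac_value
            assert state.ch >= prev_ch  # chronic never relaxes
            sa_crossed = sa_crossed or state.sa > p.sa_value
            ac_crossed = ac_crossed or state.ac > p.ac_value
            prev_ch = state.ch

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_extra_demand_never_lowers_total_stress(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        demand = rng.integers(0, 2, n)
        more = demand.copy()
        idle = np.flatnonzero(more == 0)
        if idle.size:
            more[rng.choice(idle, size=max(1, idle.size // 3), replace=False)] = 1
        p = params(sa_value=10.0, ac_value=10.0)

        def total(seq):
            s = StressState()
            for d in seq:
                step_stress(s, int(d), 1, p)
            return s.sa + s.ac + s.ch

        assert total(more) >= total(demand)


class TestCapacityModifier:
    PROFILE = PersonalProfile(enhancement_multiplier=0.5,
                              stress_degradation_coeff_acute=0.001,
                              stress_degradation_coeff_chronic=0.0005)

    def test_no_active_stress_is_identity(self):
        assert stress_capacity_modifier(StressState(), self.PROFILE) == (1.0, 0.0)

    def test_sustained_attention_alone_enhances(self):
        state = StressState(sa=50.0, sa_status=1)
        assert stress_capacity_modifier(state, self.PROFILE) == (0.5, 0.0)

    def test_acute_cancels_enhancement_and_adds_proportionally(self):
        state = StressState(sa=50.0, ac=20.0, sa_status=1, ac_status=1)
        mult, additive = stress_capacity_modifier(state, self.PROFILE)
        assert mult == 1.0
        assert additive == pytest.approx(0.02)

    def test_chronic_adds_on_top_of_acute(self):
        state = StressState(ac=20.0, ch=10.0, ac_status=1, ch_status=1)
        _, additive = stress_capacity_modifier(state, self.PROFILE)
        assert additive == pytest.approx(0.02 + 0.005)
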