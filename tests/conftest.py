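"""Shared fixtures: configurations used across the suite.

Everything is generated programmatically; there are no data files.
"""

from __future__ import annotations

import pytest

import strainsim as ss
from strainsim.config import BasicTaskLoad, ScenarioConfig


def stress_free_config(seed: int = 3, duration_min: float = 480.0) -> ScenarioConfig:
    """A shift that can never produce a demanding task: benchmarks strictly
    below the basic load, no draw noise, no failures, neutral workstation."""
    d = ScenarioConfig(seed=seed).model_dump()
    d["task_generation"]["benchmark"] = {
        c: 0.5 * v for c, v in BasicTaskLoad().as_dict().items()
    }
    d["task_generation"]["component_cv"] = 0.0
    d["task_generation"]["pace_sd"] = 0.0
    d["circumstantial"] = {
        "static": [],
        "failure": {"mean_interarrival": None},
        "buffer_effect": 0.0,
    }
    d["shift"]["duration"] = duration_min
    if duration_min < 480.0:
        d["shift"]["lunch_break"] = None
    return ScenarioConfig.model_validate(d)


def short_config(seed: int = 0, duration_min: float = 120.0, **profile_overrides):
    """Default use-case dynamics on a shorter shift (fast unit runs)."""
    d = ss.scenario_config("normal", seed).model_dump()
    d["shift"]["duration"] = duration_min
    d["shift"]["lunch_break"] = None
    d["profile"].update(profile_overrides)
    return ScenarioConfig.model_validate(d)


@pytest.fixture
def neutral_config() -> ScenarioConfig:
    return stress_free_config()


@pytest.fixture
def normal_config() -> ScenarioConfig:
    return ss.scenario_config("normal", seed=1)
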