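"""Monte-Carlo sensitivity analysis over configuration parameters.

Each repetition draws one value per parameter specification (uniform,
normal or fixed), overrides the dotted path in a copy of the base
configuration, runs the simulation with a derived seed and collects the
shift summary plus selected per-step series (sustained attention by
default).  Pointwise envelopes (median and central 90% band) are computed
across repetitions.  The whole procedure is reproducible from the master
seed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator
from scipy import stats

from .config import ScenarioConfig
from .engine import run_simulation

_STREAM_DRAWS = 9
_SEED_MOD = 2**31 - 1

SERIES_COLUMNS = {"sa": "sa", "ac": "ac", "ch": "ch", "ole": "ole"}


class ParamSpec(BaseModel):
    """One varied parameter: dotted config path plus a distribution."""

    path: str
    distribution: str  # uniform | normal | fixed
    lo: float | None = None
    hi: float | None = None
    mean: float | None = None
    sd: float | None = None
    value: float | None = None
    floor: float | None = None  # truncation floor for normal draws

    @model_validator(mode="after")
    def _check(self) -> "ParamSpec":
        if self.distribution == "uniform":
            if self.lo is None or self.hi is None or not self.lo < self.hi:
                raise ValueError(f"uniform spec for {self.path!r} needs lo < hi")
        elif self.distribution == "normal":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError(f"normal spec for {self.path!r} needs mean and sd > 0")
        elif self.distribution == "fixed":
            if self.value is None:
                raise ValueError(f"fixed spec for {self.path!r} needs a value")
        else:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        return self

    @classmethod
    def parse(cls, text: str) -> "ParamSpec":
        """Parse ``"profile.age=uniform:20:40"`` style spec strings."""
        m = re.fullmatch(r"([\w.]+)=(\w+):?([-\d.:e+]*)", text.strip())
        if not m:
            raise ValueError(f"cannot parse parameter spec {text!r}")
        path, dist, rest = m.groups()
        args = [float(x) for x in rest.split(":") if x] if rest else []
        if dist == "uniform":
            return cls(path=path, distribution="uniform", lo=args[0], hi=args[1])
        if dist == "normal":
            sd = args[1] if len(args) > 1 else 0.25 * args[0]
            return cls(path=path, distribution="normal", mean=args[0], sd=sd)
        if dist == "fixed":
            return cls(path=path, distribution="fixed", value=args[0])
        raise ValueError(f"unknown distribution {dist!r} in {text!r}")

    def draw(self, rng: np.random.Generator) -> float:
        if self.distribution == "uniform":
            return float(rng.uniform(self.lo, self.hi))
        if self.distribution == "fixed":
            return float(self.value)
        floor = self.floor if self.floor is not None else 60.0
        for _ in range(100):
            x = float(rng.normal(self.mean, self.sd))
            if x >= floor:
                return x
        raise ValueError(
            f"cannot draw a value >= {floor} from normal({self.mean}, {self.sd}) "
            f"for {self.path!r}"
        )


def _set_path(data: dict, path: str, value: float) -> None:
    keys = path.split(".")
    node = data
    for k in keys[:-1]:
        if not isinstance(node, dict) or k not in node:
            raise KeyError(f"parameter path {path!r} does not resolve")
        node = node[k]
    if not isinstance(node, dict) or keys[-1] not in node:
        raise KeyError(f"parameter path {path!r} does not resolve")
    if isinstance(node[keys[-1]], (dict, list)):
        raise KeyError(f"parameter path {path!r} does not point at a scalar")
    node[keys[-1]] = value


@dataclass
class SensitivityResult:
    """Per-rep draws and summaries plus pointwise series envelopes."""

    draws: pd.DataFrame           # one row per rep: parameter values
    summaries: pd.DataFrame       # one row per rep: summary scalars
    envelopes: dict[str, pd.DataFrame] = field(default_factory=dict)
    series: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def run_sensitivity(
    base: ScenarioConfig,
    specs: list[ParamSpec],
    n_reps: int,
    seed: int,
    series: tuple[str, ...] = ("sa",),
    keep_series: bool = False,
) -> SensitivityResult:
    """Monte-Carlo parameter sweep around a base configuration."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng([seed, _STREAM_DRAWS])
    draw_rows = []
    summary_rows = []
    collected: dict[str, list[np.ndarray]] = {s: [] for s in series}
    for rep in range(n_reps):
        draws = {spec.path: spec.draw(rng) for spec in specs}
        data = base.model_dump()
        for path, value in draws.items():
            _set_path(data, path, value)
        data["seed"] = int((seed * 1_000 + rep) % _SEED_MOD)
        cfg = ScenarioConfig.model_validate(data)
        res = run_simulation(cfg)
        draw_rows.append({"rep": rep, **draws})
        summary_rows.append({
            "rep": rep,
            **draws,
            "end_sa": res.summary["end_stocks"]["sa"],
            "end_ac": res.summary["end_stocks"]["ac"],
            "end_ch": res.summary["end_stocks"]["ch"],
            "mean_ole": res.summary["mean_ole"],
            "end_ole": res.summary["end_ole"],
            "total_demanding_tasks": res.summary["total_demanding_tasks"],
            "dominant_state": res.summary["dominant_state"],
        })
        for s in series:
            collected[s].append(res.records[SERIES_COLUMNS[s]].to_numpy())
    envelopes = {}
    series_arrays = {}
    for s in series:
        arr = np.vstack(collected[s])
        lo, med, hi = np.percentile(arr, [5.0, 50.0, 95.0], axis=0)
        envelopes[s] = pd.DataFrame(
            {"step": np.arange(arr.shape[1]), "p05": lo, "median": med, "p95": hi}
        )
        if keep_series:
            series_arrays[s] = arr
    return SensitivityResult(
        draws=pd.DataFrame(draw_rows),
        summaries=pd.DataFrame(summary_rows),
        envelopes=envelopes,
        series=series_arrays,
    )


def summarize_sensitivity(
    result: SensitivityResult, target: str = "end_sa"
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Tidy per-rep table plus Spearman rank correlation per parameter.

    A parameter drawn with zero variance is reported as NaN (correlation
    undefined).
    """
    table = result.summaries.copy()
    params = [c for c in result.draws.columns if c != "rep"]
    correlations: dict[str, float] = {}
    if len(table) < 2:
        return table, {p: math.nan for p in params}
    for p in params:
        x = table[p].to_numpy()
        if np.ptp(x) == 0.0:
            correlations[p] = math.nan
            continue
        rho = stats.spearmanr(x, table[target].to_numpy()).statistic
        correlations[p] = float(rho)
    return table, correlations
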