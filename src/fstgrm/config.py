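"""YAML configuration for the simulator and the scenario study.

A config file maps 1:1 onto :class:`fstgrm.sim.SimConfig` under the ``sim``
key; plan-level keys (replicates, sampling sizes, quantiles, top-k, blend)
sit at the top level.  Scenario entries are strings: ``"100:0"``-style budget
shares, ``"ps"``, ``"equal"``, ``"top-equal"`` or ``"top-fst"``.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .pipeline import ExperimentPlan
from .sim import SimConfig
from .weights import WeightingScenario

__all__ = ["load_sim_config", "load_plan", "parse_scenario"]


def _sim_from_dict(data: dict) -> SimConfig:
    known = {f.name for f in fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
    if "hist_pop_size_schedule" in data:
        data = dict(data, hist_pop_size_schedule=tuple(data["hist_pop_size_schedule"]))
    return SimConfig(**data)


def load_sim_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "sim" in data:
        data = data["sim"]
    return _sim_from_dict(data)


def parse_scenario(spec: str) -> WeightingScenario:
    """Parse a scenario label: 'x:y' budget shares, 'ps', 'equal', 'top-equal', 'top-fst'."""
    s = spec.strip().lower()
    if s == "ps":
        return WeightingScenario("PS", None, None, within="fst")
    if s == "equal":
        return WeightingScenario("equal", None, None, within="equal")
    if s == "top-equal":
        return WeightingScenario("top-equal", panel="top", within="equal")
    if s in ("top-fst", "top-ps"):
        return WeightingScenario("top-fst", panel="top", within="fst")
    if ":" in s:
        x, y = s.split(":", 1)
        return WeightingScenario(f"{int(x)}:{int(y)}", float(x), float(y))
    raise ValueError(f"unrecognized scenario {spec!r}")


def load_plan(path: str | Path) -> ExperimentPlan:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sim = _sim_from_dict(data.pop("sim", {}))
    scenarios = data.pop("scenarios", None)
    kwargs: dict = {"sim": sim}
    if scenarios is not None:
        kwargs["scenarios"] = tuple(parse_scenario(s) for s in scenarios)
    known = {f.name for f in fields(ExperimentPlan)} - {"sim", "scenarios"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown plan keys: {sorted(unknown)}")
    if "thresholds" in data:
        data["thresholds"] = tuple(data["thresholds"])
    kwargs.update(data)
    return ExperimentPlan(**kwargs)
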