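"""Named parameter scenarios and flat key-value configuration files.

Three presets ship with the package, spanning the model's qualitative
regimes:

* ``case1`` — R0 < 1 with b > 0: only the disease-free equilibrium, which
  attracts everything (strong treatment supply, r = 2.5).
* ``case2`` — R0 > 1 with k < k1 and d > r: a unique endemic equilibrium,
  globally stable by the geometric criterion.
* ``case3`` — R0c < R0 < 1 with b < 0 (k > k0): backward bifurcation, two
  endemic points coexisting with the stable disease-free point (bistability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import yaml

from .model import Parameters

__all__ = ["Scenario", "PRESETS", "get_preset", "load_config", "save_config"]

_PARAM_KEYS = ("A", "beta", "alpha", "d", "epsilon", "mu", "upsilon", "r", "k")


@dataclass
class Scenario:
    """A named parameter set with optional simulation defaults."""

    name: str
    parameters: Parameters
    x0: Optional[tuple] = None
    t_end: float = 2000.0
    solver: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"name": self.name}
        d.update(self.parameters.to_dict())
        if self.x0 is not None:
            d["x0"] = list(self.x0)
        d["t_end"] = self.t_end
        d.update(self.solver)
        return d


PRESETS: Dict[str, Scenario] = {
    "case1": Scenario(
        name="case1",
        parameters=Parameters(
            A=10, beta=0.05, alpha=1.25, d=0.2, epsilon=1.2, mu=0.2, upsilon=0.4, r=2.5, k=1.25
        ),
        x0=(40.0, 5.0, 5.0, 0.0),
    ),
    "case2": Scenario(
        name="case2",
        parameters=Parameters(
            A=10, beta=0.3, alpha=0.8, d=0.5, epsilon=1.2, mu=0.2, upsilon=0.4, r=0.1, k=2.0
        ),
        x0=(10.0, 1.0, 1.0),
    ),
    "case3": Scenario(
        name="case3",
        parameters=Parameters(
            A=10, beta=0.05, alpha=0.1, d=0.2, epsilon=1.2, mu=0.2, upsilon=0.4, r=1.5, k=2.0
        ),
        x0=(30.0, 3.0, 3.0),
    ),
}


def get_preset(name: str) -> Scenario:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def load_config(path) -> Scenario:
    """Read a scenario from a flat key-value (YAML) config file.

    Required keys: the nine parameters A, beta, alpha, d, epsilon, mu,
    upsilon, r, k. Optional: name, x0 (list), t_end, and any solver options.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    missing = [kk for kk in _PARAM_KEYS if kk not in raw]
    if missing:
        raise ValueError(f"config {path} missing parameter keys: {missing}")
    params = Parameters(**{kk: float(raw[kk]) for kk in _PARAM_KEYS})
    x0 = tuple(float(v) for v in raw["x0"]) if "x0" in raw and raw["x0"] is not None else None
    solver = {
        kk: v
        for kk, v in raw.items()
        if kk not in _PARAM_KEYS + ("name", "x0", "t_end")
    }
    return Scenario(
        name=str(raw.get("name", "custom")),
        parameters=params,
        x0=x0,
        t_end=float(raw.get("t_end", 2000.0)),
        solver=solver,
    )


def save_config(scenario: Scenario, path) -> None:
    """Write a scenario as a flat key-value YAML file (round-trips)."""
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)
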