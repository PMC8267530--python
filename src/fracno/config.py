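"""Run configuration, figure-scenario presets, and structured outputs.

A run is described by a flat key-value file (YAML, of which JSON is a
subset).  Absent keys fall back to the canonical parameter table of the
model: a 25 um arteriole lumen, a 0.5 um endothelium, normal-condition
wall mechanics (E = 6e3 N/m, gamma = 0.75) and normal extracellular
superoxide.  The baseline anomalous-diffusion setting is epsilon = 0.85
with a dominant forward direction p = 0.75.  Unknown keys are rejected
by name so typos cannot silently revert a parameter to its default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .fractional import AnomalousDiffusionParams
from .geometry import Geometry
from .kinetics import InactivationParams, SynthesisParams, superoxide_decay_rate
from .simulator import (
    ModelSpec,
    SimulationResult,
    endothelium_profile,
    peak_metrics,
    simulate,
)
from .wall import WallParams

__all__ = [
    "RunConfig",
    "load_config",
    "run_scenario",
    "scenario_names",
    "scenario_overrides",
    "write_result",
]

log = logging.getLogger("fracno")

# superoxide concentrations (M): normal vs ischemic extracellular levels
C_SUPEROXIDE_NORMAL = 1.95e-6
C_SUPEROXIDE_ELEVATED = 3.9e-6


@dataclass(frozen=True)
class RunConfig:
    """Flat record of every model, grid and solver setting for one run."""

    # geometry (m)
    a: float = 25e-6
    h: float = 0.5e-6
    d: float = 4e-6
    g: float = 5e-6
    # grid
    n_intervals: int = 300
    # anomalous diffusion
    D: float = 3.3e-9
    epsilon: float = 0.85
    p: float = 0.75
    q: float = 0.25
    # neuronal synthesis
    v1: float = 1.6e-3
    k1: float = 2.0
    k2: float = 1.5
    k2_sign_positive: bool = False
    # inactivation
    vmax: float = 2e-3
    Kmax: float = 1e-5
    lam: float = 2.3e2
    k_superoxide: float = 6.7e9
    c_superoxide: float = C_SUPEROXIDE_NORMAL
    sod_fraction: float = 0.5
    lambda_tilde: float | None = None
    # Maxwell wall
    rho: float = 1.0
    E: float = 6e3
    gamma: float = 0.75
    omega: float = 1.0
    frequency_is_hz: bool = False
    xi0: float = 1e-3
    wall_formula: str = "derived"
    # integration
    t_final: float = 10.04
    n_outputs: int = 401
    rtol: float = 1e-6
    atol: float = 1e-12

    def to_model(self) -> ModelSpec:
        """Materialize the validated parameter objects."""
        omega = self.omega * (2.0 * 3.141592653589793 if self.frequency_is_hz else 1.0)
        return ModelSpec(
            geometry=Geometry(a=self.a, h=self.h, d=self.d, g=self.g),
            n_intervals=self.n_intervals,
            diffusion=AnomalousDiffusionParams(D=self.D, epsilon=self.epsilon, p=self.p, q=self.q),
            synthesis=SynthesisParams(
                v1=self.v1, k1=self.k1, k2=self.k2, k2_sign_positive=self.k2_sign_positive
            ),
            inactivation=InactivationParams(
                vmax=self.vmax,
                Kmax=self.Kmax,
                lam=self.lam,
                k_superoxide=self.k_superoxide,
                c_superoxide=self.c_superoxide,
                sod_fraction=self.sod_fraction,
                lambda_tilde_override=self.lambda_tilde,
            ),
            wall=WallParams(rho=self.rho, E=self.E, gamma=self.gamma, omega=omega, xi0=self.xi0),
            wall_formula=self.wall_formula,
        )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    """Build a RunConfig from a flat mapping, rejecting unknown keys.

    ``p`` and ``q`` may be given singly (the other follows from
    p + q = 1); giving both with p + q != 1 is an error.
    """
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    data = dict(data)
    # YAML 1.1 reads exponent forms like 6.0e4 (no sign) as strings; coerce
    # every value to its declared field type so both spellings work
    types = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    for key, value in data.items():
        if value is None:
            continue
        ftype = types[key]
        try:
            if ftype == "int":
                data[key] = int(value)
            elif ftype == "bool":
                data[key] = bool(value)
            elif ftype.startswith("float"):
                data[key] = float(value)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"configuration key {key!r} has invalid value {value!r}") from exc
    if "p" in data and "q" not in data:
        data["q"] = 1.0 - float(data["p"])
    elif "q" in data and "p" not in data:
        data["p"] = 1.0 - float(data["q"])
    elif "p" in data and "q" in data:
        if abs(float(data["p"]) + float(data["q"]) - 1.0) > 1e-12:
            raise ValueError(
                f"p + q must equal 1, got p={data['p']}, q={data['q']}"
            )
    cfg = RunConfig(**data)
    cfg.to_model()  # validate eagerly so errors name the offending value
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load a flat YAML/JSON configuration file; absent keys take defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must hold a flat mapping")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# figure-scenario presets
# ---------------------------------------------------------------------------

_NORMAL_WALL = {"E": 6e3, "gamma": 0.75}
_STIFF_WALL = {"E": 6e4, "gamma": 1.25}
_NORMAL_SO = {"c_superoxide": C_SUPEROXIDE_NORMAL}
_ELEVATED_SO = {"c_superoxide": C_SUPEROXIDE_ELEVATED}

# condition order used across the figure panels:
# normal wall / stiff wall / elevated superoxide / stiff wall + elevated superoxide
_CONDITIONS = [
    {**_NORMAL_WALL, **_NORMAL_SO},
    {**_STIFF_WALL, **_NORMAL_SO},
    {**_NORMAL_WALL, **_ELEVATED_SO},
    {**_STIFF_WALL, **_ELEVATED_SO},
]


def _build_scenarios() -> dict[str, dict[str, Any]]:
    scenarios: dict[str, dict[str, Any]] = {}
    # classical diffusion, unskewed: four wall/superoxide conditions
    for name, cond in zip(("fig3a", "fig3c", "fig3e", "fig3g"), _CONDITIONS):
        scenarios[name] = {"epsilon": 1.0, "p": 0.5, "q": 0.5, **cond}
    # anomalous diffusion panels: (figure, epsilon, p)
    panels = [
        ("fig7", 0.85, 0.75),
        ("fig8", 0.85, 0.25),
        ("fig9", 0.95, 0.75),
        ("fig9r", 0.95, 0.25),
        ("fig10", 0.75, 0.75),
        ("fig10r", 0.75, 0.25),
    ]
    for figname, eps, p in panels:
        for suffix, cond in zip("abcd", _CONDITIONS):
            scenarios[f"{figname}{suffix}"] = {"epsilon": eps, "p": p, "q": 1.0 - p, **cond}
    # aliases: temporal-profile figures share the parameter sets above
    scenarios["fig6a"] = dict(scenarios["fig7a"])
    scenarios["fig6b"] = dict(scenarios["fig8a"])
    return scenarios


_SCENARIOS = _build_scenarios()


def scenario_names() -> list[str]:
    return sorted(_SCENARIOS)


def scenario_overrides(name: str) -> dict[str, Any]:
    """Parameter overrides for a named figure scenario."""
    try:
        return dict(_SCENARIOS[name])
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        ) from None


def run_scenario(
    name: str,
    out_dir: str | Path | None = None,
    overrides: dict[str, Any] | None = None,
) -> SimulationResult:
    """Run a figure preset, optionally writing outputs, and log peak metrics."""
    data = scenario_overrides(name)
    if overrides:
        data.update(overrides)
    cfg = config_from_dict(data)
    model = cfg.to_model()
    log.info("scenario %s: %s", name, cfg.to_dict())
    result = simulate(
        model, t_final=cfg.t_final, n_outputs=cfg.n_outputs, rtol=cfg.rtol, atol=cfg.atol
    )
    result.metadata["scenario"] = name
    result.metadata["config"] = cfg.to_dict()
    prof = endothelium_profile(result, model.geometry)
    result.metadata["endothelium_node_index"] = prof.node_index
    result.metadata["endothelium_node_position_m"] = prof.node_position
    metrics = peak_metrics(prof)
    log.info("scenario %s peak metrics: %s", name, metrics)
    if out_dir is not None:
        write_result(result, out_dir, profile=prof)
    return result


# ---------------------------------------------------------------------------
# structured outputs
# ---------------------------------------------------------------------------

def write_result(
    result: SimulationResult,
    out_dir: str | Path,
    profile: Any | None = None,
) -> dict[str, Path]:
    """Write the field CSV, a JSON metadata sidecar, and an optional profile CSV.

    The long-format field CSV has header ``r_m,t_s,c_no_mol_per_m3`` and
    one row per (node, time), node-major.  Units are spelled out in the
    headers to keep nM/pM bookkeeping explicit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    n_nodes, n_times = result.concentration.shape
    field_path = out / "concentration.csv"
    df = pd.DataFrame(
        {
            "r_m": np.repeat(result.nodes, n_times),
            "t_s": np.tile(result.times, n_nodes),
            "c_no_mol_per_m3": result.concentration.ravel(),
        }
    )
    df.to_csv(field_path, index=False)
    paths["field"] = field_path

    meta_path = out / "metadata.json"
    meta_path.write_text(json.dumps(result.metadata, indent=2, default=float))
    paths["metadata"] = meta_path

    if profile is not None:
        prof_path = out / "endothelium_profile.csv"
        pd.DataFrame({"t_s": profile.times, "c_no_mol_per_m3": profile.values}).to_csv(
            prof_path, index=False
        )
        paths["profile"] = prof_path
    return paths
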