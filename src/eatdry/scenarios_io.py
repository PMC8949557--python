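"""Configuration, scenario presets, and run-log I/O.

One YAML file describes a complete run: dryer geometry, kinetics anchors,
equilibrium constants, controller settings and the scenario (disturbance
schedule).  Validation is strict - unknown keys are rejected with the
offending key named - and an empty file yields the full defaults, which
reproduce the continuous-operation test: hot air 110/100/110 degC, target
moisture 14.5 % w.b., initial window 12,000 degC.min, 36 h.

Four presets ship with the package:

========== ==================================================================
continuous 110/100/110 degC, 36 h, no disturbances
step       90 degC everywhere, stepped to 80 degC at 10 h and back at 20 h
pulse      90 degC everywhere; upper section pulsed to 60 degC for 10 min at
           16 h, lower section to 50 degC for 10 min at 20 h
sinusoid   continuous conditions plus a +-2 degC ambient sinusoid (4 h period)
========== ==================================================================
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .controller import ControlGains, ControllerConfig, GAConfig, WindowConfig
from .eat import DryerGeometry
from .equilibrium import CAEConstants, available_forms
from .errors import ConfigError
from .dryer_sim import LOG_COLUMNS, Disturbance, ScenarioSpec
from .kinetics import ParamMapConfig

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "preset_scenario",
    "PRESET_NAMES",
    "write_run_log",
    "read_run_log",
    "write_summary",
]

PRESET_NAMES = ("continuous", "step", "pulse", "sinusoid")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Strict):
    Vg1: float = 92.382
    Vg2h1: float = 107.971
    Vg3h2: float = 107.971
    Vl: float = 92.382
    Vpp: float = 69.027
    Vp: float = 8.0


class KineticsSection(_Strict):
    """Controller-side Weibull anchor map plus the simulator mismatch."""

    a_ref: float = 0.0
    b_ref: float = 1.0
    k_ref: float = 0.5248852
    N_ref: float = 1.1
    T_ref: float = 105.0
    RH_ref: float = 0.10
    V_ref: float = 0.6
    W0_ref: float = 25.5
    cT: float = 0.012
    cRH: float = 0.8
    cV: float = 0.05
    cW: float = 0.0
    cN: float = 0.0
    Me_db: float = 5.0
    truth_k_scale: float = 0.87
    tau_g_min: float = 15.0


class EquilibriumSection(_Strict):
    A: float = 4.218
    B: float = -32.013
    C: float = -0.0274
    form: str = "default"


class GASection(_Strict):
    w1: float = 1.0
    w2: float = 0.01
    w3: float = 0.1
    bounds_lo: tuple[float, float, float, float] = (-0.02, -0.08, -0.3, -0.05)
    bounds_hi: tuple[float, float, float, float] = (0.02, 0.08, 0.3, 0.05)
    population: int = 40
    generations: int = 50
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    seed: int = 0


class ControllerSection(_Strict):
    target_wb: float = 14.5
    AT_set_init: float = 0.0   # 0 -> window selection computes it
    delta1: float = 0.5
    delta2: float = 1.0
    epsilon: float = 0.05
    prediction_window: int = 30
    prediction_horizon: int = 0   # 0 -> one bed turnover
    kH: float = 0.01
    kS: float = 0.0
    kI: float = 0.02
    coefficients: Literal["printed", "geometry", "printed-literal"] = "printed"
    tx_min: float = 1.0
    tx_max: float = 30.0
    tx_rate_limit: float = 0.2
    trim_limit_min: float = 0.3
    adjust_cooldown_events: int = 20
    warmup_turnovers: float = 0.85
    fit_tail: int = 40
    area_gain: float = 0.9
    area_gain_trim: float = 0.7
    area_cap_first: float = 0.30
    area_cap_trim: float = 0.05
    ga: GASection = Field(default_factory=GASection)
    enabled: bool = True


class DisturbanceSection(_Strict):
    kind: Literal["step", "pulse", "sinusoid"]
    target: Literal["section1", "section2", "section3", "ambient"]
    magnitude: float
    start_min: float = 0.0
    duration_min: float | None = None
    period_min: float | None = None


class ScenarioSection(_Strict):
    duration_h: float = 36.0
    dt_min: float = 0.1
    hot_air_C: tuple[float, float, float] = (110.0, 100.0, 110.0)
    inlet_wb_mean: float = 25.5
    inlet_wb_sd: float = 0.15
    inlet_ar1_rho: float = 0.95
    inlet_lot_range: tuple[float, float] | None = (24.7, 26.3)
    ambient_temp_C: float = 22.0
    ambient_rh: float = 0.35
    exhaust_rh_pickup: float = 0.15
    hot_air_rh: float = 0.10
    air_velocity_ms: float = 0.6
    disturbances: tuple[DisturbanceSection, ...] = ()


class RunConfig(_Strict):
    """Validated top-level run description (defaults = continuous preset)."""

    geometry: GeometrySection = Field(default_factory=GeometrySection)
    kinetics: KineticsSection = Field(default_factory=KineticsSection)
    equilibrium: EquilibriumSection = Field(default_factory=EquilibriumSection)
    controller: ControllerSection = Field(default_factory=ControllerSection)
    scenario: ScenarioSection = Field(default_factory=ScenarioSection)
    seed: int = 0
    outdir: str = "runs"

    # -- converters to the domain objects --------------------------------

    def dryer_geometry(self) -> DryerGeometry:
        g = self.geometry
        return DryerGeometry(Vg1=g.Vg1, Vg2h1=g.Vg2h1, Vg3h2=g.Vg3h2,
                             Vl=g.Vl, Vpp=g.Vpp, Vp=g.Vp)

    def ctrl_map(self) -> ParamMapConfig:
        k = self.kinetics
        return ParamMapConfig(a_ref=k.a_ref, b_ref=k.b_ref, k_ref=k.k_ref,
                              N_ref=k.N_ref, T_ref=k.T_ref, RH_ref=k.RH_ref,
                              V_ref=k.V_ref, W0_ref=k.W0_ref, cT=k.cT,
                              cRH=k.cRH, cV=k.cV, cW=k.cW, cN=k.cN)

    def truth_map(self) -> ParamMapConfig:
        return self.ctrl_map().scaled(self.kinetics.truth_k_scale)

    def cae_constants(self) -> CAEConstants:
        e = self.equilibrium
        if e.form not in available_forms():
            raise ConfigError(f"unknown equilibrium form {e.form!r}; have {available_forms()}")
        return CAEConstants(A=e.A, B=e.B, C=e.C)

    def scenario_spec(self) -> ScenarioSpec:
        s = self.scenario
        disturbances = tuple(
            Disturbance(kind=d.kind, target=d.target, magnitude=d.magnitude,
                        start_min=d.start_min, duration_min=d.duration_min,
                        period_min=d.period_min)
            for d in s.disturbances)
        return ScenarioSpec(
            duration_h=s.duration_h, dt_min=s.dt_min, hot_air_C=s.hot_air_C,
            inlet_wb_mean=s.inlet_wb_mean, inlet_wb_sd=s.inlet_wb_sd,
            inlet_ar1_rho=s.inlet_ar1_rho, inlet_lot_range=s.inlet_lot_range,
            ambient_temp_C=s.ambient_temp_C, ambient_rh=s.ambient_rh,
            exhaust_rh_pickup=s.exhaust_rh_pickup, hot_air_rh=s.hot_air_rh,
            air_velocity_ms=s.air_velocity_ms, disturbances=disturbances,
            seed=self.seed)

    def controller_config(self) -> ControllerConfig:
        c = self.controller
        window = WindowConfig(
            AT_set=c.AT_set_init if c.AT_set_init > 0 else 12000.0,
            target_wb=c.target_wb, delta1=c.delta1, delta2=c.delta2,
            epsilon=c.epsilon, prediction_window=c.prediction_window,
            prediction_horizon=c.prediction_horizon or None)
        ga = GAConfig(weights=(c.ga.w1, c.ga.w2, c.ga.w3),
                      bounds_lo=c.ga.bounds_lo, bounds_hi=c.ga.bounds_hi,
                      population=c.ga.population, generations=c.ga.generations,
                      crossover_rate=c.ga.crossover_rate,
                      mutation_rate=c.ga.mutation_rate, seed=c.ga.seed)
        gamma = (self.geometry.Vg2h1 / 2.0 + self.geometry.Vg3h2 / 2.0) / (
            self.geometry.Vg1 + self.geometry.Vg2h1 / 2.0 + self.geometry.Vg3h2 / 2.0)
        return ControllerConfig(
            window=window, gains=ControlGains(kH=c.kH, kS=c.kS, kI=c.kI),
            ga=ga, ctrl_map=self.ctrl_map(), Me_db=self.kinetics.Me_db,
            gamma=gamma, coefficients=c.coefficients, tx_min=c.tx_min,
            tx_max=c.tx_max, tx_rate_limit=c.tx_rate_limit,
            trim_limit_min=c.trim_limit_min,
            adjust_cooldown_events=c.adjust_cooldown_events,
            warmup_turnovers=c.warmup_turnovers, fit_tail=c.fit_tail,
            tau_g_est=self.kinetics.tau_g_min,
            area_gain=c.area_gain, area_gain_trim=c.area_gain_trim,
            area_cap_first=c.area_cap_first, area_cap_trim=c.area_cap_trim,
            enabled=c.enabled)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``None`` or an empty file yields the full defaults.  Schema violations
    raise :class:`ConfigError` naming the offending key.
    """
    data = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        text = p.read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(x) for x in first["loc"]) or "<root>"
        raise ConfigError(f"invalid config at {loc!r}: {first['msg']}") from exc


def dump_config(cfg: RunConfig, path: str | Path | None = None) -> str:
    """Serialize a config back to YAML (roundtrips through load_config)."""
    text = yaml.safe_dump(json.loads(cfg.model_dump_json()), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset_scenario(name: str, seed: int = 0) -> RunConfig:
    """One of the shipped scenario presets as a full RunConfig."""
    cfg = RunConfig(seed=seed)
    if name == "continuous":
        return cfg
    if name == "step":
        sc = cfg.scenario.model_copy(update=dict(
            duration_h=33.5, hot_air_C=(90.0, 90.0, 90.0),
            disturbances=tuple(
                DisturbanceSection(kind="step", target=t, magnitude=m, start_min=s)
                for s, m in ((600.0, -10.0), (1200.0, 10.0))
                for t in ("section1", "section2", "section3"))))
        return cfg.model_copy(update=dict(scenario=sc))
    if name == "pulse":
        sc = cfg.scenario.model_copy(update=dict(
            duration_h=26.0, hot_air_C=(90.0, 90.0, 90.0),
            disturbances=(
                DisturbanceSection(kind="pulse", target="section1", magnitude=-30.0,
                                   start_min=960.0, duration_min=10.0),
                DisturbanceSection(kind="pulse", target="section3", magnitude=-40.0,
                                   start_min=1200.0, duration_min=10.0))))
        return cfg.model_copy(update=dict(scenario=sc))
    if name == "sinusoid":
        sc = cfg.scenario.model_copy(update=dict(
            disturbances=(
                DisturbanceSection(kind="sinusoid", target="ambient", magnitude=2.0,
                                   start_min=0.0, period_min=240.0),)))
        return cfg.model_copy(update=dict(scenario=sc))
    raise ConfigError(f"unknown preset {name!r}; available: {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# Run logs and summaries
# ---------------------------------------------------------------------------

def write_run_log(log: pd.DataFrame, path: str | Path, append: bool = False) -> Path:
    """Write a per-discharge run log as CSV with the stable column order."""
    missing = [c for c in LOG_COLUMNS if c not in log.columns]
    if missing:
        raise ConfigError(f"run log missing columns: {missing}")
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    mode = "a" if append and p.exists() else "w"
    log[list(LOG_COLUMNS)].to_csv(p, index=False, mode=mode, header=(mode == "w"))
    return p


def read_run_log(path: str | Path) -> pd.DataFrame:
    """Read a run log written by :func:`write_run_log`."""
    df = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"not a run log (missing columns {missing}): {path}")
    return df


def write_summary(summary: dict, path: str | Path) -> Path:
    """Write a run summary as a small JSON text file."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return p
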