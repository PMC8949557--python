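"""Discrete-event simulator of a six-section continuous mixed-flow dryer.

The bed is an ordered queue of fixed-volume grain slabs (one slab = one
discharge quantum of the discharge wheel).  Top-down the sections are:
upper drying, middle drying, middle tempering, lower drying, lower
tempering, cooling, discharge.  Every ``tx + 0.5`` minutes the wheel turns,
the bottom slab leaves and a fresh slab enters at the top, so slab count and
bed volume are conserved.

Physics per time step (``dt`` <= 1 min):

* drying sections - moisture advances along the local thin-layer Weibull
  curve by the *equivalent-time* method: invert the curve at the slab's
  current moisture ratio, add dt, re-evaluate.  This reproduces the analytic
  curve exactly under constant conditions and handles condition changes
  (disturbances) consistently.
* tempering sections - moisture and grain temperature hold (zero-airflow
  rest; internal kernel redistribution is out of scope).
* cooling/discharge sections - moisture holds, grain temperature relaxes to
  ambient.
* grain temperature in drying sections follows a first-order lag toward the
  local air temperature with time constant ``tau_g`` (synthetic ground
  truth; the reference rig publishes no heat-transfer model).
* every slab accumulates effective accumulated temperature
  ``max(T_grain - Te, 0) * dt``.

Inlet moisture follows a seeded AR(1) process on wet basis, emulating the
slow lot-to-lot drift of wet corn deliveries rather than white noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .equilibrium import CAEConstants, EquilibriumQuery, equilibrium_temperature
from .errors import ConfigError, DomainError
from .eat import DISCHARGE_DURATION_MIN, DryerGeometry
from .kinetics import (
    DryingConditions,
    ParamMapConfig,
    db_to_wb,
    params_for_conditions,
    wb_to_db,
)

__all__ = [
    "GrainSlab",
    "Disturbance",
    "ScenarioSpec",
    "AirState",
    "DryerState",
    "init_bed",
    "step_sim",
    "discharge_event",
    "apply_disturbance",
    "effective_air",
    "run_open_loop",
]

_SECTION_DRY = 0
_SECTION_TEMPER = 1
_SECTION_COOL = 2

#: (kind, drying-section index or -1) top-down; tempering sits below its
#: drying section, cooling and discharge close the column.
_SECTION_KINDS = (
    (_SECTION_DRY, 0),
    (_SECTION_DRY, 1),
    (_SECTION_TEMPER, -1),
    (_SECTION_DRY, 2),
    (_SECTION_TEMPER, -1),
    (_SECTION_COOL, -1),
    (_SECTION_COOL, -1),
)


@dataclass(frozen=True)
class GrainSlab:
    """One discharge quantum of grain as reported at the outlet."""

    moisture_db: float
    moisture_wb: float
    temp: float
    residence_min: float
    eat: float
    effective_drying_time_h: float
    volume_l: float


@dataclass(frozen=True)
class Disturbance:
    """One scheduled disturbance on a hot-air section or the ambient air.

    kind: ``step`` (additive from ``start_min`` on), ``pulse`` (additive
    during [start, start+duration)), or ``sinusoid`` (additive
    magnitude*sin(2*pi*(t-start)/period) from ``start_min`` on).
    target: ``section1`` | ``section2`` | ``section3`` | ``ambient``.
    magnitude: deg C.
    """

    kind: Literal["step", "pulse", "sinusoid"]
    target: Literal["section1", "section2", "section3", "ambient"]
    magnitude: float
    start_min: float = 0.0
    duration_min: float | None = None
    period_min: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("step", "pulse", "sinusoid"):
            raise ConfigError(f"unknown disturbance kind {self.kind!r}")
        if self.target not in ("section1", "section2", "section3", "ambient"):
            raise ConfigError(f"unknown disturbance target {self.target!r}")
        if self.kind == "pulse" and (self.duration_min is None or self.duration_min <= 0):
            raise ConfigError("pulse disturbance needs a positive duration_min")
        if self.kind == "sinusoid" and (self.period_min is None or self.period_min <= 0):
            raise ConfigError("sinusoid disturbance needs a positive period_min")

    def offset(self, clock_min: float) -> float:
        """Additive temperature offset contributed at ``clock_min``."""
        if clock_min < self.start_min:
            return 0.0
        if self.kind == "step":
            return self.magnitude
        if self.kind == "pulse":
            return self.magnitude if clock_min < self.start_min + self.duration_min else 0.0
        return self.magnitude * math.sin(2.0 * math.pi * (clock_min - self.start_min) / self.period_min)


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete run description: conditions, disturbances, length, seed."""

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
    disturbances: tuple[Disturbance, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_h < 0:
            raise ConfigError(f"duration_h must be >= 0, got {self.duration_h}")
        if not (0 < self.dt_min <= 1.0):
            raise ConfigError(f"dt_min must be in (0, 1] min, got {self.dt_min}")
        if self.inlet_wb_sd < 0:
            raise ConfigError("inlet_wb_sd must be >= 0")
        if not (0 <= self.inlet_ar1_rho < 1):
            raise ConfigError("inlet_ar1_rho must be in [0, 1)")


@dataclass(frozen=True)
class AirState:
    """Effective air temperatures after disturbances, at one instant."""

    hot_air_C: tuple[float, float, float]
    ambient_temp_C: float
    ambient_rh: float


def apply_disturbance(base: AirState, item: Disturbance, clock_min: float) -> AirState:
    """Apply one disturbance's additive offset at ``clock_min``."""
    off = item.offset(clock_min)
    if off == 0.0:
        return base
    if item.target == "ambient":
        return replace(base, ambient_temp_C=base.ambient_temp_C + off)
    idx = int(item.target[-1]) - 1
    hot = list(base.hot_air_C)
    hot[idx] += off
    return replace(base, hot_air_C=(hot[0], hot[1], hot[2]))


def effective_air(scenario: ScenarioSpec, clock_min: float) -> AirState:
    """All disturbances applied to the scenario's base setpoints."""
    air = AirState(scenario.hot_air_C, scenario.ambient_temp_C, scenario.ambient_rh)
    for item in scenario.disturbances:
        air = apply_disturbance(air, item, clock_min)
    return air


class DryerState:
    """Mutable bed state.  Slab arrays are ordered top (inlet) -> bottom.

    Not a public constructor surface: build via :func:`init_bed`.
    """

    def __init__(
        self,
        geom: DryerGeometry,
        scenario: ScenarioSpec,
        truth_map: ParamMapConfig,
        cae: CAEConstants,
        te_form: str,
        target_wb: float,
        Me_db: float,
        tau_g_min: float,
        rng: np.random.Generator,
    ) -> None:
        self.geom = geom
        self.scenario = scenario
        self.truth_map = truth_map
        self.cae = cae
        self.te_form = te_form
        self.target_wb = target_wb
        self.Me_db = Me_db
        self.tau_g_min = tau_g_min
        self.rng = rng
        self.clock_min = 0.0
        self.n_discharges = 0
        # one wet-corn lot per run: its mean moisture is drawn from the
        # stated delivery range; slabs fluctuate AR(1) around it
        if scenario.inlet_lot_range is not None:
            lo, hi = scenario.inlet_lot_range
            self.inlet_lot_mean = float(rng.uniform(lo, hi))
        else:
            self.inlet_lot_mean = scenario.inlet_wb_mean
        self._inlet_wb = self.inlet_lot_mean

        # section boundaries top-down, cumulative litres
        g = geom
        half2 = g.Vg2h1 / 2.0
        half3 = g.Vg3h2 / 2.0
        edges = np.cumsum([0.0, g.Vg1, half2, half2, half3, half3, g.Vl, g.Vpp])
        self.section_edges = edges  # 8 edges, 7 sections
        self.zone_edges = np.array([0.0, g.Vg1, g.Vg1 + g.Vg2h1,
                                    g.Vg1 + g.Vg2h1 + g.Vg3h2, g.total_volume])

        n_full = int(g.total_volume // g.Vp)
        frac = g.total_volume - n_full * g.Vp
        vols = [frac] + [g.Vp] * n_full if frac > 1e-9 else [g.Vp] * n_full
        n = len(vols)
        self.vol = np.array(vols)
        self.m0_db = np.empty(n)
        self.m_db = np.empty(n)
        self.temp = np.full(n, scenario.ambient_temp_C)
        self.eat = np.zeros(n)
        self.born_min = np.zeros(n)
        self.t_dry_h = np.zeros(n)
        for i in range(n):
            m0 = wb_to_db(self._draw_inlet_wb())
            self.m0_db[i] = m0
            self.m_db[i] = m0
        self._refresh_masks()

    # -- helpers ----------------------------------------------------------

    def _draw_inlet_wb(self) -> float:
        s = self.scenario
        mu = self.inlet_lot_mean
        if s.inlet_wb_sd == 0:
            return mu
        rho = s.inlet_ar1_rho
        innov_sd = s.inlet_wb_sd * math.sqrt(1.0 - rho * rho)
        x = mu + rho * (self._inlet_wb - mu) + self.rng.normal(0.0, innov_sd)
        if s.inlet_lot_range is not None:
            lo, hi = s.inlet_lot_range
        else:
            lo, hi = mu - 2.5 * s.inlet_wb_sd, mu + 2.5 * s.inlet_wb_sd
        self._inlet_wb = min(max(x, lo), hi)
        return self._inlet_wb

    def _refresh_masks(self) -> None:
        """Recompute per-slab section overlap weights; changes on discharge.

        Weights are volume-overlap fractions, so a slab straddling a section
        boundary dries (or cools) at the fractional rate of its overlap -
        this keeps the fractional boundary slab from quantizing every other
        slab's residence by a whole discharge period.
        """
        ends = np.cumsum(self.vol)
        starts = ends - self.vol
        self._starts, self._ends = starts, ends
        self.dry_weights = []   # per drying section: overlap fraction array
        cool_w = np.zeros(len(self.vol))
        for sec_idx, (kind, _air) in enumerate(_SECTION_KINDS):
            lo, hi = self.section_edges[sec_idx], self.section_edges[sec_idx + 1]
            w = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0.0, None) / self.vol
            if kind == _SECTION_DRY:
                self.dry_weights.append(w)
            elif kind == _SECTION_COOL:
                cool_w += w
        self.cool_weight = cool_w

    # -- observables ------------------------------------------------------

    @property
    def n_slabs(self) -> int:
        return len(self.vol)

    def exhaust_rh(self) -> float:
        rh = self.scenario.ambient_rh + self.scenario.exhaust_rh_pickup
        return min(max(rh, 0.02), 0.98)

    def equilibrium_temp(self) -> float:
        q = EquilibriumQuery(ERH=self.exhaust_rh(), EMC=wb_to_db(self.target_wb))
        return equilibrium_temperature(q, self.cae, self.te_form)

    def zone_mean_temps(self) -> tuple[float, float, float, float]:
        """Slab-volume-weighted mean grain temperature of the 4 EAT zones."""
        out = []
        for z0, z1 in zip(self.zone_edges[:-1], self.zone_edges[1:]):
            w = np.clip(np.minimum(self._ends, z1) - np.maximum(self._starts, z0), 0.0, None)
            out.append(float(np.sum(w * self.temp) / np.sum(w)))
        return tuple(out)  # type: ignore[return-value]


def init_bed(
    geom: DryerGeometry,
    scenario: ScenarioSpec,
    truth_map: ParamMapConfig,
    cae: CAEConstants | None = None,
    te_form: str = "default",
    target_wb: float = 14.5,
    Me_db: float = 5.0,
    tau_g_min: float = 15.0,
    seed: int | None = None,
) -> DryerState:
    """Fill the bed with slabs at inlet moisture (seeded AR(1) draws)."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    return DryerState(geom, scenario, truth_map, cae or CAEConstants(), te_form,
                      target_wb, Me_db, tau_g_min, rng)


def step_sim(state: DryerState, dt_min: float) -> DryerState:
    """Advance the bed by one time step (mutates and returns ``state``)."""
    if dt_min > 1.0 + 1e-12:
        raise DomainError(f"dt must be <= 1 min for stable equivalent-time tracking, got {dt_min}")
    s = state.scenario
    air = effective_air(s, state.clock_min)
    te = state.equilibrium_temp()
    dt_h = dt_min / 60.0
    lag = 1.0 - math.exp(-dt_min / state.tau_g_min)

    for sec, weights in enumerate(state.dry_weights):
        idx = np.flatnonzero(weights > 0.0)
        if idx.size == 0:
            continue
        w = weights[idx]
        T_air = air.hot_air_C[sec]
        cond = DryingConditions(T=T_air, RH=s.hot_air_rh, V=s.air_velocity_ms,
                                W0=s.inlet_wb_mean, gamma=0.0)
        p = params_for_conditions(cond, state.truth_map).params
        m = state.m_db[idx]
        m0 = state.m0_db[idx]
        mr = (m - state.Me_db) / (m0 - state.Me_db)
        shifted = mr - p.a
        live = shifted > 1e-12
        if np.any(live):
            j = idx[live]
            sh = np.clip(shifted[live], 1e-12, p.b)
            t_eq = ((math.log(p.b) - np.log(sh)) / p.k) ** (1.0 / p.N)
            t_new = t_eq + dt_h * w[live]
            mr_new = p.a + p.b * np.exp(-p.k * t_new ** p.N)
            state.m_db[j] = state.Me_db + (state.m0_db[j] - state.Me_db) * mr_new
        state.temp[idx] += w * lag * (T_air - state.temp[idx])
        state.t_dry_h[idx] += dt_h * w

    cw = state.cool_weight
    cm = np.flatnonzero(cw > 0.0)
    if cm.size:
        state.temp[cm] += cw[cm] * lag * (air.ambient_temp_C - state.temp[cm])
    # tempering overlap: moisture and temperature hold

    state.eat += np.maximum(state.temp - te, 0.0) * dt_min
    state.clock_min += dt_min
    return state


def discharge_event(state: DryerState) -> tuple[DryerState, GrainSlab]:
    """Turn the discharge wheel once: bottom slab out, fresh slab in.

    The outgoing slab's moisture is reported in percent wet basis (the
    capacitive outlet sensor's reading basis).  Bed volume is conserved: the
    incoming slab takes the outgoing slab's volume.
    """
    out = GrainSlab(
        moisture_db=float(state.m_db[-1]),
        moisture_wb=db_to_wb(float(state.m_db[-1])),
        temp=float(state.temp[-1]),
        residence_min=state.clock_min - float(state.born_min[-1]),
        eat=float(state.eat[-1]),
        effective_drying_time_h=float(state.t_dry_h[-1]),
        volume_l=float(state.vol[-1]),
    )
    for arr in (state.vol, state.m0_db, state.m_db, state.temp, state.eat,
                state.born_min, state.t_dry_h):
        arr[1:] = arr[:-1]
    m0 = wb_to_db(state._draw_inlet_wb())
    state.vol[0] = out.volume_l
    state.m0_db[0] = m0
    state.m_db[0] = m0
    state.temp[0] = effective_air(state.scenario, state.clock_min).ambient_temp_C
    state.eat[0] = 0.0
    state.born_min[0] = state.clock_min
    state.t_dry_h[0] = 0.0
    state.n_discharges += 1
    state._refresh_masks()
    return state, out


LOG_COLUMNS = ["clock_min", "event", "tx_min", "M_out_wb", "T1", "T2", "T3", "T4",
               "Te", "AT_set", "AT_realized", "mode"]


def run_open_loop(
    scenario: ScenarioSpec,
    geom: DryerGeometry,
    tx_min_interval: float,
    truth_map: ParamMapConfig | None = None,
    **bed_kw: object,
) -> pd.DataFrame:
    """Run the dryer at a fixed discharge interval; one log row per discharge."""
    if tx_min_interval <= 0:
        raise DomainError("tx must be positive")
    truth_map = truth_map or ParamMapConfig()
    state = init_bed(geom, scenario, truth_map, **bed_kw)  # type: ignore[arg-type]
    dt = scenario.dt_min
    period = tx_min_interval + DISCHARGE_DURATION_MIN
    next_discharge = round(period / dt) * dt
    total_min = scenario.duration_h * 60.0
    rows = []
    while state.clock_min < total_min - 1e-9:
        step_sim(state, dt)
        if state.clock_min >= next_discharge - 1e-9:
            state, slab = discharge_event(state)
            tz = state.zone_mean_temps()
            rows.append((state.clock_min, state.n_discharges, tx_min_interval,
                         slab.moisture_wb, *tz, state.equilibrium_temp(),
                         float("nan"), slab.eat, "open"))
            next_discharge += round(period / dt) * dt
    return pd.DataFrame(rows, columns=LOG_COLUMNS)
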