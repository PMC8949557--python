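"""EAT mutual-window controller for continuous grain drying.

The controller pairs an accumulated-temperature "control window" (grain
temperature x time) with an outlet-moisture "realization window" and runs
three nested actions, mechanism-driven first and data-driven on top:

* **window selection** - the initial window area (EAT setpoint) from the
  theoretical thin-layer model: AT_set = (Tf - Te) * 60 * (1+gamma) * t,
  with t the Weibull drying time to the target moisture.
* **window adaptation** - every discharge, keep the realized dryer EAT equal
  to the setpoint by re-solving the discharge interval tx from the measured
  zone temperatures (same window area, new aspect ratio).
* **window adjustment** - when the least-squares outlet-moisture prediction
  deviates from target by more than delta1, a seeded real-coded genetic
  algorithm corrects the four Weibull constants against recent observations
  and the window area is moved per the corrected model.

A small additive trim u(k) = kH*(Ti - T0) + kS*sum(Ti) + kI*dTi/dt on the
discharge interval is exposed as the explicit mutual-window control law;
with the default (small) gains the EAT inversion remains the primary
actuator path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .eat import (
    DISCHARGE_DURATION_MIN,
    DryerGeometry,
    SectionTemps,
    dryer_eat,
    section_pass_counts,
    solve_discharge_interval,
    theoretical_at,
)
from .errors import CannotActuateError, DomainError, UnreachableMoistureError
from .kinetics import (
    DryingConditions,
    MoistureState,
    ParamMapConfig,
    ThinLayerParams,
    params_for_conditions,
    time_for_moisture,
    time_for_mr,
    wb_to_db,
)
from .dryer_sim import (
    LOG_COLUMNS,
    ScenarioSpec,
    discharge_event,
    effective_air,
    init_bed,
    step_sim,
)

__all__ = [
    "Mode",
    "ControlGains",
    "ControlState",
    "ControlOutput",
    "WindowConfig",
    "GAConfig",
    "ObjectiveTerms",
    "Prediction",
    "ControllerConfig",
    "WindowAdjustment",
    "control_law",
    "select_window",
    "predict_outlet_moisture",
    "classify_deviation",
    "ga_objective",
    "ga_window_adjustment",
    "window_adaptation",
    "steady_zone_temps",
    "steady_period",
    "closed_loop_run",
]


class Mode(str, Enum):
    """Controller decision per discharge: the three window actions."""

    HOLD = "hold"
    ADAPT = "adapt"
    ADJUST = "adjust"


# ---------------------------------------------------------------------------
# Control law (window width / area / aspect-ratio terms)
# ---------------------------------------------------------------------------

@dataclass
class ControlState:
    """Aligned histories feeding the control law."""

    T0: float
    Ti: list[float] = field(default_factory=list)
    t_min: list[float] = field(default_factory=list)
    u_k: list[float] = field(default_factory=list)

    def observe(self, Ti: float, t_min: float) -> None:
        self.Ti.append(Ti)
        self.t_min.append(t_min)


@dataclass(frozen=True)
class ControlGains:
    """Width (kH), area (kS) and aspect-ratio/slope (kI) coefficients.

    Defaults are deliberately small: the control law is an additive trim on
    the discharge interval, the EAT inversion carries the loop.
    """

    kH: float = 0.01
    kS: float = 0.0
    kI: float = 0.02


@dataclass(frozen=True)
class ControlOutput:
    """u(k) with its three terms exposed for diagnostics."""

    u: float
    width_term: float
    area_term: float
    slope_term: float
    slope_valid: bool


def control_law(gains: ControlGains, state: ControlState) -> ControlOutput:
    """u(k) = kH*(Ti - T0) + kS*sum(Ti) + kI * dTi/dt.

    With a single temperature sample the slope term is zero and flagged
    ``slope_valid=False``.
    """
    if not state.Ti:
        raise DomainError("control law needs at least one temperature sample")
    Ti = state.Ti[-1]
    width = gains.kH * (Ti - state.T0)
    area = gains.kS * float(sum(state.Ti))
    if len(state.Ti) >= 2:
        dt = state.t_min[-1] - state.t_min[-2]
        slope = gains.kI * (state.Ti[-1] - state.Ti[-2]) / dt if dt > 0 else 0.0
        ok = dt > 0
    else:
        slope, ok = 0.0, False
    u = width + area + slope
    state.u_k.append(u)
    return ControlOutput(u=u, width_term=width, area_term=area, slope_term=slope, slope_valid=ok)


# ---------------------------------------------------------------------------
# Window selection
# ---------------------------------------------------------------------------

def select_window(
    cond: DryingConditions,
    params: ThinLayerParams,
    target_wb: float,
    Tf: float,
    Te: float,
    Me_db: float = 5.0,
) -> float:
    """Initial window area AT_set (degC.min) from the theoretical model."""
    if target_wb >= cond.W0:
        raise UnreachableMoistureError(
            f"target moisture {target_wb}% w.b. not below initial {cond.W0}% w.b."
        )
    boundaries = MoistureState(M0=wb_to_db(cond.W0), Me=Me_db, Mt=wb_to_db(target_wb))
    return theoretical_at(cond, params, boundaries, Tf, Te)


# ---------------------------------------------------------------------------
# Outlet-moisture prediction and deviation classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prediction:
    """OLS line extrapolation of the outlet-moisture (precipitation) curve."""

    value: float
    slope: float
    ok: bool


def predict_outlet_moisture(tail: Sequence[float], horizon: int) -> Prediction:
    """Least-squares line through the last W outlet samples, extrapolated
    ``horizon`` discharges ahead.  Fewer than 3 samples -> ``ok=False`` and
    the controller holds."""
    y = np.asarray(tail, dtype=float)
    if len(y) < 3:
        return Prediction(value=float("nan"), slope=float("nan"), ok=False)
    x = np.arange(len(y), dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return Prediction(value=float(intercept + slope * (len(y) - 1 + horizon)),
                      slope=float(slope), ok=True)


@dataclass(frozen=True)
class WindowConfig:
    """The controller's current window and its deviation thresholds.

    delta1 is the tight (target-band) threshold; predicted deviations beyond
    it trigger a window-area change.  delta2 is the coarse threshold within
    which adaptation alone is expected to hold the process.  epsilon is a
    dead band below which nothing is touched.
    """

    AT_set: float = 12000.0
    target_wb: float = 14.5
    delta1: float = 0.5
    delta2: float = 1.0
    epsilon: float = 0.05
    prediction_window: int = 30
    prediction_horizon: int | None = None  # None -> one bed turnover

    def __post_init__(self) -> None:
        if not (0 < self.delta1 <= self.delta2):
            raise DomainError("need 0 < delta1 <= delta2")
        if self.AT_set <= 0:
            raise DomainError("AT_set must be positive")


def classify_deviation(predicted: float, target: float, delta1: float,
                       delta2: float, epsilon: float = 0.05) -> Mode:
    """Map a predicted deviation onto the three window actions.

    |dev| > delta1 -> ADJUST (area change); epsilon < |dev| <= delta1 ->
    ADAPT (aspect-ratio change); |dev| <= epsilon -> HOLD.  Covers all reals,
    modes mutually exclusive.
    """
    dev = abs(predicted - target)
    if dev > delta1:
        return Mode.ADJUST
    if dev > epsilon:
        return Mode.ADAPT
    return Mode.HOLD


# ---------------------------------------------------------------------------
# GA objective and engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObjectiveTerms:
    """Series feeding the optimal-control objective."""

    e: Sequence[float]
    u: Sequence[float] = ()
    tr: float = 0.0
    sigma_pct: float | None = None


def ga_objective(terms: ObjectiveTerms, weights: tuple[float, float, float]) -> float:
    """KS = w1*sum|e| + w2*sum(u^2) + w3*tr, plus the overshoot percentage
    when one exists (piecewise definition)."""
    w1, w2, w3 = weights
    ks = (w1 * float(np.sum(np.abs(terms.e)))
          + w2 * float(np.sum(np.square(terms.u)))
          + w3 * terms.tr)
    if terms.sigma_pct is not None:
        ks += terms.sigma_pct
    return ks


@dataclass(frozen=True)
class GAConfig:
    """Real-coded GA settings for the window-adjustment model correction.

    Genes are corrections to the four Weibull constants: additive on ``a``
    (whose anchor is 0) and relative on ``b``, ``k``, ``N``.
    """

    weights: tuple[float, float, float] = (1.0, 0.01, 0.1)
    bounds_lo: tuple[float, float, float, float] = (-0.02, -0.08, -0.3, -0.05)
    bounds_hi: tuple[float, float, float, float] = (0.02, 0.08, 0.3, 0.05)
    population: int = 40
    generations: int = 50
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 4:
            raise DomainError("population must be >= 4")
        if any(w < 0 for w in self.weights) or not any(self.weights):
            raise DomainError("weights must be >= 0 and not all zero")


def _run_ga(
    fitness: Callable[[np.ndarray], float],
    cfg: GAConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, list[float]]:
    """Elitist real-coded GA: tournament(3) selection, blend crossover,
    Gaussian mutation.  Returns (best genes, best fitness, per-generation
    best history - non-increasing by elitism)."""
    lo = np.asarray(cfg.bounds_lo, dtype=float)
    hi = np.asarray(cfg.bounds_hi, dtype=float)
    d = len(lo)
    pop = rng.uniform(lo, hi, size=(cfg.population, d))
    pop[0] = 0.0  # seed the incumbent (zero correction)
    fit = np.array([fitness(x) for x in pop])
    history: list[float] = []
    sigma = 0.1 * (hi - lo)
    for _ in range(cfg.generations):
        order = np.argsort(fit)
        pop, fit = pop[order], fit[order]
        history.append(float(fit[0]))
        new = [pop[0].copy()]  # elite
        while len(new) < cfg.population:
            i = min(rng.integers(0, cfg.population, 3))
            j = min(rng.integers(0, cfg.population, 3))
            p1, p2 = pop[i], pop[j]
            if rng.random() < cfg.crossover_rate:
                alpha = rng.uniform(-0.5, 1.5, d)  # BLX blend
                child = alpha * p1 + (1.0 - alpha) * p2
            else:
                child = p1.copy()
            mut = rng.random(d) < cfg.mutation_rate
            child = np.where(mut, child + rng.normal(0.0, sigma), child)
            new.append(np.clip(child, lo, hi))
        pop = np.asarray(new)
        fit = np.array([fitness(x) for x in pop])
    best = int(np.argmin(fit))
    best_f = float(fit[best])
    if history and best_f > history[-1]:  # keep elitist guarantee
        return pop[0], history[-1], history + [history[-1]]
    return pop[best], best_f, history + [best_f]


def _apply_correction(params: ThinLayerParams, genes: np.ndarray) -> ThinLayerParams | None:
    da, rb, rk, rn = (float(g) for g in genes)
    try:
        return ThinLayerParams(a=params.a + da, b=params.b * (1.0 + rb),
                               k=params.k * (1.0 + rk), N=params.N * (1.0 + rn))
    except DomainError:
        return None


# ---------------------------------------------------------------------------
# Window adjustment (GA model correction + area change)
# ---------------------------------------------------------------------------

def _drying_volume_below(geom: DryerGeometry, v: float) -> float:
    """Litres of drying-section volume within the bottom ``v`` litres of the
    bed.  Bottom-up the sections are discharge, cooling, lower tempering,
    lower drying, middle tempering, middle drying, upper drying (tempering
    sits under its drying section; combined sections split 50/50)."""
    half2 = geom.Vg2h1 / 2.0
    half3 = geom.Vg3h2 / 2.0
    base = geom.Vpp + geom.Vl
    dry_intervals = (
        (base + half3, base + geom.Vg3h2),                     # lower drying
        (base + geom.Vg3h2 + half2, geom.total_volume),        # middle+upper drying
    )
    tot = 0.0
    for lo, hi in dry_intervals:
        tot += max(0.0, min(v, hi) - lo)
    return tot


@dataclass(frozen=True)
class EventRecord:
    """One discharge observation as the controller sees it."""

    event: int
    clock_min: float
    m_out_wb: float
    m_out_db: float
    period_min: float
    u_k: float


@dataclass(frozen=True)
class WindowAdjustment:
    """Outcome of one window-adjustment step."""

    params: ThinLayerParams
    genes: tuple[float, float, float, float]
    AT_set: float
    improved: bool
    fitness: float


def _dry_path_volumes(geom: DryerGeometry, v_top: float) -> tuple[float, float, float]:
    """Volumes of (upper, middle, lower) drying section within the bottom
    ``v_top`` litres of the bed, in the order a descending slab crosses
    them.  A slab starting mid-bed only ever sees the sections below its
    starting height."""
    half2 = geom.Vg2h1 / 2.0
    base = geom.Vpp + geom.Vl
    half3 = geom.Vg3h2 / 2.0
    lower = (base + half3, base + geom.Vg3h2)
    middle = (base + geom.Vg3h2 + half2, base + geom.Vg3h2 + geom.Vg2h1)
    upper = (base + geom.Vg3h2 + geom.Vg2h1, geom.total_volume)
    return tuple(max(0.0, min(v_top, hi) - lo) for lo, hi in (upper, middle, lower))  # type: ignore[return-value]


def _mr_after_path(
    params_seq: Sequence[ThinLayerParams],
    durations_h: np.ndarray,
) -> np.ndarray:
    """Moisture ratio after drying sequentially through phases that share
    a, b, N but have per-phase rate constants (one section per phase).

    The equivalent-time method carries the curve across each k switch.
    ``durations_h`` has shape (n_obs, n_phases); phase order must match
    ``params_seq``.
    """
    p0 = params_seq[0]
    s = np.zeros(durations_h.shape[0])  # accumulated exponent k * t^N
    for p, d in zip(params_seq, durations_h.T):
        t_eq = (s / p.k) ** (1.0 / p.N)
        s = p.k * (t_eq + d) ** p.N
    return p0.a + p0.b * np.exp(-s)


def path_period_for_mr(
    params_seq: Sequence[ThinLayerParams],
    geom: DryerGeometry,
    mr_target: float,
    p_lo: float = 0.6,
    p_hi: float = 180.0,
) -> float:
    """Discharge period (min) at which one full bed transit dries a slab to
    ``mr_target``, under the section-aware path model (bisection; MR is
    strictly decreasing in the period)."""
    passes = np.array(_dry_path_volumes(geom, geom.total_volume)) / geom.Vp

    def mr_at(period: float) -> float:
        return float(_mr_after_path(params_seq, (passes * period / 60.0)[None, :])[0])

    if mr_target >= mr_at(p_lo):
        return p_lo
    if mr_target <= mr_at(p_hi):
        return p_hi
    lo, hi = p_lo, p_hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mr_at(mid) > mr_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _replay_exposures(
    records: Sequence[EventRecord],
    geom: DryerGeometry,
    n_transit: int,
    tail: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Controller-side reconstruction of each observed slab's per-section
    drying exposure.

    A slab discharged at event j started j*Vp litres above the outlet (or
    at the top once j exceeds one turnover); its exposure in each drying
    section is the section volume below that height, times the mean
    discharge period during its transit.  Returns (durations_h of shape
    (n, 3) in upper/middle/lower order, m_obs_db, u_k) for the last
    ``tail`` events.
    """
    periods = np.array([r.period_min for r in records])
    cum = np.concatenate([[0.0], np.cumsum(periods)])
    events = np.array([r.event for r in records])
    sel = np.arange(max(0, len(records) - tail), len(records))
    durations = np.empty((len(sel), 3))
    for out, i in enumerate(sel):
        j = events[i]
        lo = max(0, i + 1 - min(j, n_transit))
        mean_period = (cum[i + 1] - cum[lo]) / (i + 1 - lo)
        v = min(j * geom.Vp, geom.total_volume)
        vols = _dry_path_volumes(geom, v)
        durations[out] = [vol / geom.Vp * mean_period / 60.0 for vol in vols]
    m_obs = np.array([records[i].m_out_db for i in sel])
    u_k = np.array([records[i].u_k for i in sel])
    return durations, m_obs, u_k


def ga_window_adjustment(
    params: ThinLayerParams,
    records: Sequence[EventRecord],
    ga: GAConfig,
    geom: DryerGeometry,
    window: WindowConfig,
    anchor_period_min: float,
    M0_db: float,
    Me_db: float = 5.0,
    params_sections: Sequence[ThinLayerParams] | None = None,
    observed_wb: float | None = None,
    fit_tail: int = 40,
    area_gain: float = 0.9,
    area_cap_frac: float = 0.15,
) -> WindowAdjustment:
    """Correct the drying constants by GA and move the window area.

    Fitness replays the controller's section-aware internal model against
    the recent observed outlet moistures: each slab's exposure in the
    upper/middle/lower drying section is reconstructed from the discharge
    history, the Weibull curve is advanced sequentially through the three
    sections at their own rate constants (``params_sections``; one shared
    correction gene vector applies to all), and the residuals are scored
    with :func:`ga_objective`.

    The window area then moves incrementally, anchored at the current
    setpoint, in discharge-period space where the theoretical and realized
    EAT scales cancel:

    * mechanism-driven (``observed_wb=None``):
      ``AT += gain * AT * (P_target - anchor_period) / anchor_period``
      with P_target the period at which a full transit reaches the target
      moisture per the corrected model - the one-shot window change;
    * data-driven (``observed_wb`` = a filtered recent outlet reading):
      the same with the anchor replaced by the period the corrected model
      assigns to the observed moisture - a feedback trim.

    Either move is capped at ``area_cap_frac`` of the current area.  If the
    GA cannot beat the incumbent (zero correction), the incumbent constants
    are kept and ``improved=False`` is flagged; the area still moves, since
    the deviation is real regardless.
    """
    if len(records) < 3:
        raise DomainError("window adjustment needs at least 3 observations")
    sections = tuple(params_sections) if params_sections is not None else (params,) * 3
    n_transit = max(1, round(geom.total_volume / geom.Vp))
    durations, m_obs, u_hist = _replay_exposures(records, geom, n_transit, fit_tail)

    def corrected(genes: np.ndarray) -> tuple[ThinLayerParams, ...] | None:
        out = []
        for p in sections:
            c = _apply_correction(p, genes)
            if c is None:
                return None
            out.append(c)
        return tuple(out)

    def fitness(genes: np.ndarray) -> float:
        secs = corrected(genes)
        if secs is None:
            return 1e9
        mr = _mr_after_path(secs, durations)
        pred = Me_db + (M0_db - Me_db) * mr
        return ga_objective(ObjectiveTerms(e=pred - m_obs, u=u_hist), ga.weights)

    rng = np.random.default_rng(ga.seed)
    genes, best_f, _hist = _run_ga(fitness, ga, rng)
    incumbent_f = fitness(np.zeros(4))
    improved = best_f < incumbent_f - 1e-12
    if not improved:
        genes = np.zeros(4)
    new_sections = corrected(genes)
    if new_sections is None:  # pragma: no cover - guarded by fitness penalty
        genes, improved = np.zeros(4), False
        new_sections = sections
    new_params = _apply_correction(params, genes) or params

    # incremental window-area move in period space, anchored at the
    # current setpoint; moisture ratios are clamped into the corrected
    # curve's reachable band
    p0 = new_sections[0]

    def _period_for_wb(m_wb: float) -> float:
        mr = (wb_to_db(min(max(m_wb, 0.0), 99.0)) - Me_db) / (M0_db - Me_db)
        mr = min(max(mr, p0.a + 1e-3), p0.a + p0.b - 1e-3)
        return path_period_for_mr(new_sections, geom, mr)

    p_target = _period_for_wb(window.target_wb)
    p_ref = anchor_period_min if observed_wb is None else _period_for_wb(observed_wb)
    delta = area_gain * window.AT_set * (p_target - p_ref) / p_ref
    cap = area_cap_frac * window.AT_set
    delta = min(max(delta, -cap), cap)
    new_at = max(window.AT_set + delta, 1000.0)
    return WindowAdjustment(params=new_params, genes=tuple(float(g) for g in genes),
                            AT_set=new_at, improved=improved, fitness=best_f)


def _moisture_per_at(params: ThinLayerParams, M0_db: float, Me_db: float,
                     target_wb: float, Tf: float, Te: float, gamma: float) -> float:
    """Model sensitivity of outlet moisture (%w.b.) to window area (degC.min)
    at the target operating point: dM/dAT = dM/dt * dt/dAT (negative)."""
    mr_tgt = (wb_to_db(target_wb) - Me_db) / (M0_db - Me_db)
    mr_tgt = min(max(mr_tgt, params.a + 1e-3), params.a + params.b - 1e-3)
    t_tar = time_for_mr(params, mr_tgt)
    dmr_dt = -params.k * params.N * t_tar ** (params.N - 1.0) * (mr_tgt - params.a)
    dm_db_dt = (M0_db - Me_db) * dmr_dt
    m_db = Me_db + (M0_db - Me_db) * mr_tgt
    dwb_ddb = 1e4 / (100.0 + m_db) ** 2
    dt_dat = 1.0 / ((Tf - Te) * 60.0 * (1.0 + gamma))
    return dm_db_dt * dwb_ddb * dt_dat


# ---------------------------------------------------------------------------
# Window adaptation
# ---------------------------------------------------------------------------

def window_adaptation(
    AT_set: float,
    temps: SectionTemps,
    geom: DryerGeometry,
    coefficients: Literal["printed", "geometry", "printed-literal"] = "printed",
    tx_min: float = 1.0,
) -> float:
    """Aspect-ratio change: the tx that keeps the realized EAT at AT_set."""
    return solve_discharge_interval(temps, geom, AT_set, coefficients=coefficients, tx_min=tx_min)


# ---------------------------------------------------------------------------
# Closed loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ControllerConfig:
    """Everything the controller needs besides the scenario and geometry."""

    window: WindowConfig = WindowConfig()
    gains: ControlGains = ControlGains()
    ga: GAConfig = GAConfig()
    ctrl_map: ParamMapConfig = ParamMapConfig()
    Me_db: float = 5.0
    gamma: float = 0.5389038
    coefficients: Literal["printed", "geometry", "printed-literal"] = "printed"
    tx_min: float = 1.0
    tx_max: float = 30.0
    tx_rate_limit: float = 0.2
    trim_limit_min: float = 0.3
    t0_ewma_alpha: float = 0.05
    adjust_cooldown_events: int = 20
    warmup_turnovers: float = 0.85
    fit_tail: int = 40
    tau_g_est: float = 15.0
    startup_period_margin: float = 1.05
    ff_temp_threshold: float = 1.0
    ff_confirm_events: int = 3
    n_oneshots: int = 1
    second_oneshot_gap: int = 15
    area_gain: float = 0.9
    area_gain_trim: float = 0.7
    area_cap_first: float = 0.30
    area_cap_trim: float = 0.05
    obs_filter_events: int = 15
    enabled: bool = True


def window_for_period(
    period_min: float,
    air_hot: tuple[float, float, float],
    ambient: float,
    Te: float,
    geom: DryerGeometry,
    tau_g_min: float,
    coefficients: Literal["printed", "geometry", "printed-literal"] = "printed",
) -> float:
    """Window area (degC.min) that settles to the given discharge period,
    per the internal steady-state heat model."""
    temps = steady_zone_temps(air_hot, ambient, Te, geom, tau_g_min, period_min)
    return dryer_eat(temps, geom, max(period_min - DISCHARGE_DURATION_MIN, 1e-6), coefficients)


def _nominal_temps(air_hot: tuple[float, float, float], ambient: float, Te: float) -> SectionTemps:
    """Assumed steady zone temperatures before the bed has warmed up: grain
    tracks the section air, the cooling/discharge zone sits at ambient."""
    return SectionTemps(air_hot[0], air_hot[1], air_hot[2], ambient, Te)


def steady_zone_temps(
    air_hot: tuple[float, float, float],
    ambient: float,
    Te: float,
    geom: DryerGeometry,
    tau_g_min: float,
    period_min: float,
) -> SectionTemps:
    """Steady-state zone mean grain temperatures from the controller's
    internal heat model: first-order lag toward the section air in drying
    sections, hold through tempering, relaxation to ambient below."""
    c = section_pass_counts(geom)
    tau = tau_g_min

    def _pass(T_in: float, T_air: float, dur: float) -> tuple[float, float]:
        if dur <= 0:
            return T_in, T_in
        mean = T_air - (T_air - T_in) * (tau / dur) * (1.0 - math.exp(-dur / tau))
        exit_ = T_air - (T_air - T_in) * math.exp(-dur / tau)
        return mean, exit_

    t1, t2, t3, t4 = (ci * period_min for ci in c)
    m1, e1 = _pass(ambient, air_hot[0], t1)
    # combined drying+tempering zones: drying half lags to air, tempering
    # half holds at the drying-exit temperature
    md2, e2 = _pass(e1, air_hot[1], t2 / 2.0)
    m2 = 0.5 * (md2 + e2)
    md3, e3 = _pass(e2, air_hot[2], t3 / 2.0)
    m3 = 0.5 * (md3 + e3)
    m4, _ = _pass(e3, ambient, t4)
    return SectionTemps(m1, m2, m3, m4, Te)


def steady_period(
    AT_set: float,
    air_hot: tuple[float, float, float],
    ambient: float,
    Te: float,
    geom: DryerGeometry,
    tau_g_min: float,
    coefficients: Literal["printed", "geometry", "printed-literal"] = "printed",
    tx_min: float = 1.0,
) -> tuple[float, SectionTemps]:
    """Discharge period the window area will settle to at steady state.

    The zone temperatures depend on the period and vice versa; a short
    fixed-point iteration resolves both.  Returns (period, zone temps).
    """
    period = 4.0
    temps = steady_zone_temps(air_hot, ambient, Te, geom, tau_g_min, period)
    for _ in range(12):
        temps = steady_zone_temps(air_hot, ambient, Te, geom, tau_g_min, period)
        tx = solve_discharge_interval(temps, geom, AT_set, coefficients=coefficients,
                                      tx_min=tx_min)
        new_period = tx + DISCHARGE_DURATION_MIN
        if abs(new_period - period) < 1e-9:
            period = new_period
            break
        period = new_period
    return period, temps


def closed_loop_run(
    scenario: ScenarioSpec,
    geom: DryerGeometry,
    ctl: ControllerConfig,
    truth_map: ParamMapConfig | None = None,
    cae=None,
    te_form: str = "default",
    tau_g_min: float = 15.0,
    fixed_tx: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the dryer under closed-loop mutual-window control.

    One controller pass per discharge: read the outlet sensor, predict,
    classify, adjust or adapt, set the next discharge interval.  With
    ``ctl.enabled=False`` (or ``fixed_tx``) the discharge interval is frozen
    after window selection - the controller-off baseline.

    Returns the per-discharge log and a summary with the maximum absolute
    deviation after settling (two bed turnovers), the settling clock time,
    and adjustment/adaptation counts.
    """
    truth_map = truth_map if truth_map is not None else ctl.ctrl_map.scaled(0.87)
    state = init_bed(geom, scenario, truth_map, cae=cae, te_form=te_form,
                     target_wb=ctl.window.target_wb, Me_db=ctl.Me_db, tau_g_min=tau_g_min)
    dt = scenario.dt_min
    n_slabs = state.n_slabs
    horizon = ctl.window.prediction_horizon or n_slabs
    warmup_events = int(round(ctl.warmup_turnovers * n_slabs))
    M0_db = wb_to_db(scenario.inlet_wb_mean)
    window = ctl.window

    air0 = effective_air(scenario, 0.0)
    Te0 = state.equilibrium_temp()
    Tf0 = float(np.mean(air0.hot_air_C))

    # learned corrections compose with the conditions->constants map, so a
    # hot-air setpoint change updates the model constants immediately
    corr = np.zeros(4)

    def current_params(Tf: float) -> ThinLayerParams:
        cond = DryingConditions(T=Tf, RH=scenario.hot_air_rh, V=scenario.air_velocity_ms,
                                W0=scenario.inlet_wb_mean, gamma=ctl.gamma)
        base = params_for_conditions(cond, ctl.ctrl_map).params
        p = _apply_correction(base, corr)
        return p if p is not None else base

    def section_params(hot: tuple[float, float, float]) -> tuple[ThinLayerParams, ...]:
        # path order: upper, middle, lower drying section
        return tuple(current_params(t) for t in hot)

    cond0 = DryingConditions(T=Tf0, RH=scenario.hot_air_rh, V=scenario.air_velocity_ms,
                             W0=scenario.inlet_wb_mean, gamma=ctl.gamma)
    params = current_params(Tf0)
    if window.AT_set <= 0 or fixed_tx is None:
        at_set = select_window(cond0, params, window.target_wb, Tf0, Te0, Me_db=ctl.Me_db)
        window = replace(window, AT_set=at_set)
    try:
        p0, _ = steady_period(window.AT_set, air0.hot_air_C, air0.ambient_temp_C, Te0,
                              geom, ctl.tau_g_est, ctl.coefficients, ctl.tx_min)
        tx = p0 - DISCHARGE_DURATION_MIN
    except CannotActuateError:
        tx = 5.0
    if fixed_tx is not None:
        tx = fixed_tx

    Tf_ref = Tf0
    air_ref = air0.hot_air_C
    last_ff = -10**9
    ff_pending = 0
    cstate = ControlState(T0=float(np.mean(state.temp)))
    records: list[EventRecord] = []
    at_moves: list[tuple[int, float]] = []  # (event, delta AT_set) in transit
    # slabs below the lowest drying section at start-up leave the dryer
    # undried: their readings measure the lot's inlet moisture directly
    n_zero_exposure = int((geom.Vpp + geom.Vl + geom.Vg3h2 / 2.0) // geom.Vp)
    m0_lot_db: float | None = None
    rows = []
    n_adjust = n_adapt = 0
    last_adjust = -10**9
    total_min = scenario.duration_h * 60.0
    next_discharge = round((tx + DISCHARGE_DURATION_MIN) / dt) * dt
    last_discharge_clock = 0.0

    while state.clock_min < total_min - 1e-9:
        step_sim(state, dt)
        if state.clock_min < next_discharge - 1e-9:
            continue
        period = state.clock_min - last_discharge_clock
        last_discharge_clock = state.clock_min
        state, slab = discharge_event(state)
        ev = state.n_discharges
        te_now = state.equilibrium_temp()
        tz = state.zone_mean_temps()
        temps = SectionTemps(*tz, te_now)
        air = effective_air(scenario, state.clock_min)
        Tf = float(np.mean(air.hot_air_C))

        # feedforward on measured hot-air setpoint changes: rescale the
        # window by the ratio of the model-required windows at the new and
        # old conditions (the ratio cancels persistent model biases).  The
        # change must persist a few events first - a short pulse (shorter
        # than a couple of discharge periods) barely touches any slab and
        # chasing it would only inject disturbance
        if abs(Tf - Tf_ref) > ctl.ff_temp_threshold:
            ff_pending += 1
        else:
            ff_pending = 0
        if ctl.enabled and fixed_tx is None and ff_pending >= ctl.ff_confirm_events:
            mr_t = (wb_to_db(window.target_wb) - ctl.Me_db) / (M0_db - ctl.Me_db)
            try:
                p_new = path_period_for_mr(section_params(air.hot_air_C), geom, mr_t)
                p_old = path_period_for_mr(section_params(air_ref), geom, mr_t)
                at_new = window_for_period(p_new, air.hot_air_C, air.ambient_temp_C,
                                           te_now, geom, ctl.tau_g_est, ctl.coefficients)
                at_old = window_for_period(p_old, air_ref, air.ambient_temp_C,
                                           te_now, geom, ctl.tau_g_est, ctl.coefficients)
                ratio = min(max(at_new / at_old, 0.5), 2.0)
            except (DomainError, ZeroDivisionError):
                ratio = 1.0
            # not entered in at_moves: the move's outlet effect is cancelled
            # by the plant-side setpoint change it feeds forward against
            window = replace(window, AT_set=window.AT_set * ratio)
            Tf_ref = Tf
            air_ref = air.hot_air_C
            last_ff = ev
            ff_pending = 0
        params = current_params(Tf)

        # control law trim on the bed-mean grain temperature
        bed_mean = float(np.sum(state.vol * state.temp) / np.sum(state.vol))
        cstate.observe(bed_mean, state.clock_min)
        out = control_law(ctl.gains, cstate)
        cstate.T0 += ctl.t0_ewma_alpha * (bed_mean - cstate.T0)
        trim = min(max(-out.u, -ctl.trim_limit_min), ctl.trim_limit_min)

        records.append(EventRecord(event=ev, clock_min=state.clock_min,
                                   m_out_wb=slab.moisture_wb, m_out_db=slab.moisture_db,
                                   period_min=period, u_k=out.u))

        mode = Mode.HOLD
        pred = predict_outlet_moisture([r.m_out_wb for r in records[-window.prediction_window:]],
                                       horizon)
        if ctl.enabled and fixed_tx is None:
            if pred.ok:
                mode = classify_deviation(pred.value, window.target_wb,
                                          window.delta1, window.delta2, window.epsilon)
            # the first (one-shot) window change waits out the warmup; a
            # second model-anchored change re-verifies it once full-transit
            # data exist; trims use the configured cooldown (in-flight
            # moves are compensated, so they need not wait a full transit)
            if 0 < n_adjust < ctl.n_oneshots:
                gap = ctl.second_oneshot_gap
            else:
                gap = ctl.adjust_cooldown_events
            if mode is Mode.ADJUST and (ev < warmup_events or ev - last_adjust < gap):
                mode = Mode.ADAPT
            if mode is Mode.ADJUST:
                ga = replace(ctl.ga, seed=(ctl.ga.seed * 100003 + ev) % 2**31)
                if m0_lot_db is None and len(records) >= n_zero_exposure:
                    m0_lot_db = float(np.median(
                        [r.m_out_db for r in records[:n_zero_exposure]]))
                m0_db_use = m0_lot_db if m0_lot_db is not None else M0_db
                if n_adjust < ctl.n_oneshots:
                    # model-anchored window change after a model
                    # correction: the move is the model's drying-time
                    # deficit under the *steady-state* period the current
                    # window implies (the instantaneous period is inflated
                    # while the bed is still warming), independent of
                    # not-yet-surfaced observations
                    cap = ctl.area_cap_first if n_adjust == 0 else 0.5 * ctl.area_cap_first
                    obs, gain = None, ctl.area_gain
                    try:
                        anchor_period, _ = steady_period(
                            window.AT_set, air.hot_air_C, air.ambient_temp_C, te_now,
                            geom, ctl.tau_g_est, ctl.coefficients, ctl.tx_min)
                    except CannotActuateError:
                        anchor_period = tx + DISCHARGE_DURATION_MIN
                else:
                    # feedback trim on the filtered measured deviation,
                    # compensated for window moves still in transit (their
                    # effect surfaces at the outlet only after a bed
                    # passage) - prevents integral windup on the delay
                    recent = [r.m_out_wb for r in records[-ctl.obs_filter_events:]]
                    # a move's effect surfaces once slabs that were still
                    # above the drying sections at the move reach the
                    # outlet: weight by the drying volume below the slab's
                    # position at the move
                    vdry_tot = _drying_volume_below(geom, geom.total_volume)
                    pending = sum(
                        d * (1.0 - _drying_volume_below(
                                geom, min((ev - e0) * geom.Vp, geom.total_volume)) / vdry_tot)
                        for e0, d in at_moves)
                    sens = _moisture_per_at(params, m0_db_use, ctl.Me_db,
                                            window.target_wb, Tf, te_now, ctl.gamma)
                    obs = float(np.median(recent)) + pending * sens
                    cap = ctl.area_cap_trim
                    gain = ctl.area_gain_trim
                    anchor_period = tx + DISCHARGE_DURATION_MIN
                adj = ga_window_adjustment(
                    params, records, ga, geom, window, anchor_period,
                    m0_db_use, Me_db=ctl.Me_db,
                    params_sections=section_params(air.hot_air_C),
                    observed_wb=obs, fit_tail=ctl.fit_tail, area_gain=gain,
                    area_cap_frac=cap)
                # observations spanning a setpoint change would corrupt
                # the fitted constants: keep the incumbent model until one
                # full transit of same-regime data has accumulated
                if adj.improved and ev - last_ff >= n_slabs:
                    g = adj.genes
                    corr[0] += g[0]
                    corr[1:] = (1.0 + corr[1:]) * (1.0 + np.asarray(g[1:])) - 1.0
                params = current_params(Tf)
                at_moves.append((ev, adj.AT_set - window.AT_set))
                window = replace(window, AT_set=adj.AT_set)
                last_adjust = ev
                n_adjust += 1
            if mode in (Mode.ADAPT, Mode.ADJUST):
                try:
                    target_tx = window_adaptation(window.AT_set, temps, geom,
                                                  ctl.coefficients, ctl.tx_min)
                except CannotActuateError:
                    target_tx = ctl.tx_max
                # a cold (warming-up) bed understates the steady zone
                # excesses, which would balloon the interval: during the
                # first bed turnover, cap the period near the internal
                # model's steady-state value
                if ev < n_slabs:
                    try:
                        sp, _ = steady_period(window.AT_set, air.hot_air_C,
                                              air.ambient_temp_C, te_now, geom,
                                              ctl.tau_g_est, ctl.coefficients, ctl.tx_min)
                        cap_tx = ctl.startup_period_margin * sp - DISCHARGE_DURATION_MIN
                        target_tx = min(target_tx, cap_tx)
                    except CannotActuateError:
                        pass
                target_tx += trim
                lo = tx * (1.0 - ctl.tx_rate_limit)
                hi = tx * (1.0 + ctl.tx_rate_limit)
                tx = min(max(min(max(target_tx, lo), hi), ctl.tx_min), ctl.tx_max)
                if mode is Mode.ADAPT:
                    n_adapt += 1

        rows.append((state.clock_min, ev, tx, slab.moisture_wb, *tz, te_now,
                     window.AT_set, slab.eat, mode.value))
        next_discharge = state.clock_min + round((tx + DISCHARGE_DURATION_MIN) / dt) * dt

    log = pd.DataFrame(rows, columns=LOG_COLUMNS)
    summary = summarize_run(log, window.target_wb, n_slabs)
    summary.update(n_adjustments=n_adjust, n_adaptations=n_adapt,
                   final_AT_set=float(window.AT_set), final_tx=float(tx))
    return log, summary


def summarize_run(log: pd.DataFrame, target_wb: float, n_slabs: int) -> dict:
    """Post-settling statistics of a run log.

    Settling is two bed turnovers (2 * n_slabs discharge events); the
    maximum absolute outlet-moisture deviation is taken over the rest.
    """
    settle_events = 2 * n_slabs
    post = log[log["event"] > settle_events]
    if len(post) == 0:
        return {"max_dev_post": float("nan"), "settle_time_min": float("nan"),
                "n_events": int(len(log))}
    dev = (post["M_out_wb"] - target_wb).abs()
    settle_clock = float(log.loc[log["event"] > settle_events, "clock_min"].iloc[0])
    return {"max_dev_post": float(dev.max()), "settle_time_min": settle_clock,
            "n_events": int(len(log))}
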