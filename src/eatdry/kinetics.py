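"""Thin-layer drying kinetics for shelled corn.

The two-parameter-offset Weibull form

    MR(t) = a + b * exp(-k * t**N)

describes the moisture ratio MR = (Mt - Me)/(M0 - Me) of a grain layer thin
enough (< 20 mm) that every kernel sees identical air.  ``a`` and ``b`` are a
dimensionless offset/amplitude pair with MR(0) = a + b ~= 1, ``k`` is the
drying rate constant (per hour**N) and ``N`` the dimensionless shape factor.

This module provides the forward curve, its time inverse, wet-/dry-basis
moisture conversions, bounded nonlinear fitting of the four constants from a
measured (t, Mt) curve, a configurable smooth map from drying conditions
(air temperature, humidity, velocity, initial moisture, tempering ratio) to
the constants, and a seeded synthetic thin-layer dataset generator.

Time is in **hours** throughout this module; the dryer simulator converts at
its boundary (its internals run in minutes).  Moisture is percent dry basis
except where a name says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, InvalidStateError, UnreachableMoistureError

__all__ = [
    "ThinLayerParams",
    "MoistureState",
    "DryingConditions",
    "FitReport",
    "ParamMapConfig",
    "ConditionedParams",
    "moisture_ratio",
    "moisture_at_time",
    "time_for_moisture",
    "wb_to_db",
    "db_to_wb",
    "convert_basis",
    "fit_weibull",
    "params_for_conditions",
    "generate_thinlayer_dataset",
]


@dataclass(frozen=True)
class ThinLayerParams:
    """Weibull drying constants ``a, b, k, N``.

    ``b``, ``k`` and ``N`` must be positive; ``a + b`` must lie in
    [0.9, 1.1] so that MR(0) is physically meaningful.
    """

    a: float
    b: float
    k: float
    N: float

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.k > 0 and self.N > 0):
            raise DomainError(f"b, k, N must be positive (got b={self.b}, k={self.k}, N={self.N})")
        if not (0.9 <= self.a + self.b <= 1.1):
            raise DomainError(f"a + b = {self.a + self.b:.4f} outside [0.9, 1.1]")

    def replace(self, **kw: float) -> "ThinLayerParams":
        d = {"a": self.a, "b": self.b, "k": self.k, "N": self.N}
        d.update(kw)
        return ThinLayerParams(**d)


@dataclass(frozen=True)
class MoistureState:
    """Moisture boundaries of a drying process, percent dry basis.

    ``M0`` initial, ``Me`` equilibrium; optionally a current value ``Mt``.
    """

    M0: float
    Me: float
    Mt: float | None = None

    def __post_init__(self) -> None:
        if not self.M0 > self.Me:
            raise InvalidStateError(f"M0={self.M0} must exceed Me={self.Me}")
        if self.Mt is not None and not (self.Me <= self.Mt <= self.M0):
            raise InvalidStateError(f"Mt={self.Mt} outside [Me={self.Me}, M0={self.M0}]")


@dataclass(frozen=True)
class DryingConditions:
    """Hot-air drying conditions for one thin layer.

    T: hot-air temperature, deg C.  RH: hot-air relative humidity, fraction.
    V: hot-air velocity, m/s.  W0: initial moisture, percent wet basis.
    gamma: tempering ratio (tempering time / drying time), dimensionless.
    """

    T: float
    RH: float
    V: float
    W0: float
    gamma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.RH < 1.0):
            raise DomainError(f"RH must be a fraction in (0,1), got {self.RH}")
        if self.V < 0:
            raise DomainError(f"V must be >= 0, got {self.V}")
        if not (0.0 < self.W0 < 100.0):
            raise DomainError(f"W0 must be in (0,100) %w.b., got {self.W0}")
        if self.gamma < 0:
            raise DomainError(f"gamma must be >= 0, got {self.gamma}")


@dataclass(frozen=True)
class FitReport:
    """Result of a thin-layer curve fit.

    ``chi2`` is the reduced residual sum of squares sum((obs-pred)^2)/(n-p)
    and ``rmse`` the root-mean-square error, both on moisture-ratio scale.
    ``success`` is False when the optimizer failed or the curve carries no
    drying signal; ``message`` then says why and ``params`` holds the best
    attempt (or None).
    """

    params: ThinLayerParams | None
    r2: float
    chi2: float
    rmse: float
    n_points: int
    success: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# Core curve
# ---------------------------------------------------------------------------

def moisture_ratio(params: ThinLayerParams, t: float) -> float:
    """Moisture ratio MR(t) = a + b*exp(-k t^N) at time ``t`` (hours)."""
    if t < 0:
        raise DomainError(f"time must be >= 0, got {t}")
    return params.a + params.b * math.exp(-params.k * t ** params.N)


def moisture_at_time(params: ThinLayerParams, state: MoistureState, t: float) -> float:
    """Moisture content (percent d.b.) after drying for ``t`` hours."""
    return state.Me + (state.M0 - state.Me) * moisture_ratio(params, t)


def time_for_moisture(params: ThinLayerParams, state: MoistureState) -> float:
    """Drying time (hours, tempering excluded) to reach ``state.Mt``.

    Inverts the Weibull curve:

        t = [ (ln b - ln(MR - a)) / k ] ** (1/N)

    Raises :class:`UnreachableMoistureError` when the target moisture ratio
    is not inside (a, a+b).
    """
    if state.Mt is None:
        raise InvalidStateError("MoistureState.Mt must be set to invert the curve")
    mr = (state.Mt - state.Me) / (state.M0 - state.Me)
    return time_for_mr(params, mr)


def time_for_mr(params: ThinLayerParams, mr: float) -> float:
    """Time (hours) at which the curve passes through moisture ratio ``mr``."""
    shifted = mr - params.a
    if not (0.0 < shifted <= params.b):
        raise UnreachableMoistureError(
            f"target MR={mr:.6g} outside reachable band ({params.a:.4g}, {params.a + params.b:.4g}]"
        )
    # MR = a + b exp(-k t^N)  =>  t^N = (ln b - ln(MR - a)) / k
    arg = (math.log(params.b) - math.log(shifted)) / params.k
    return arg ** (1.0 / params.N)


# ---------------------------------------------------------------------------
# Moisture basis conversions
# ---------------------------------------------------------------------------

def wb_to_db(wb: float) -> float:
    """Percent wet basis -> percent dry basis: db = 100*wb/(100-wb)."""
    if not (0.0 <= wb < 100.0):
        raise DomainError(f"wet-basis moisture must be in [0, 100), got {wb}")
    return 100.0 * wb / (100.0 - wb)


def db_to_wb(db: float) -> float:
    """Percent dry basis -> percent wet basis: wb = 100*db/(100+db)."""
    if db < 0:
        raise DomainError(f"dry-basis moisture must be >= 0, got {db}")
    return 100.0 * db / (100.0 + db)


def convert_basis(m: float, direction: Literal["wb->db", "db->wb"]) -> float:
    """Convert a moisture percentage between wet and dry basis."""
    if direction == "wb->db":
        return wb_to_db(m)
    if direction == "db->wb":
        return db_to_wb(m)
    raise DomainError(f"unknown conversion direction {direction!r}")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_FIT_BOUNDS_LO = np.array([-0.2, 0.5, 1e-6, 0.3])
_FIT_BOUNDS_HI = np.array([0.3, 1.5, 10.0, 3.0])


def fit_weibull(
    curve: Sequence[tuple[float, float]],
    boundaries: MoistureState,
    n_starts: int = 3,
    seed: int = 0,
) -> FitReport:
    """Fit the Weibull constants to a measured (t hours, Mt %d.b.) curve.

    Nonlinear least squares on moisture-ratio scale, with bounds
    a in [-0.2, 0.3], b in [0.5, 1.5], k in (0, 10], N in (0.3, 3] and
    ``n_starts`` seeded multi-starts to dodge local minima.  Degenerate or
    non-convergent inputs yield a :class:`FitReport` with ``success=False``
    rather than an exception.
    """
    pts = np.asarray(curve, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise DomainError("need at least 6 (t, Mt) points")
    t = pts[:, 0]
    if not np.all(np.diff(t) > 0):
        raise DomainError("time values must be strictly increasing")
    if t[0] < 0:
        raise DomainError("negative time in curve")
    mr_obs = (pts[:, 1] - boundaries.Me) / (boundaries.M0 - boundaries.Me)
    n = len(t)

    if float(np.ptp(mr_obs)) < 1e-9:
        return FitReport(None, 0.0, float("nan"), float("nan"), n,
                         success=False, message="no drying signal: moisture curve is constant")

    def resid(theta: np.ndarray) -> np.ndarray:
        a, b, k, nn = theta
        return a + b * np.exp(-k * np.power(np.maximum(t, 0.0), nn)) - mr_obs

    # crude rate guess from the time the curve crosses MR ~ exp(-1)
    lvl = mr_obs[0] - (1 - math.exp(-1)) * (mr_obs[0] - mr_obs[-1])
    idx = int(np.argmin(np.abs(mr_obs - lvl)))
    k_guess = 1.0 / max(t[idx], 1e-3) if t[idx] > 0 else 1.0

    rng = np.random.default_rng(seed)
    starts = [np.array([0.0, 1.0, min(max(k_guess, 1e-3), 9.0), 1.0])]
    for _ in range(max(0, n_starts - 1)):
        jitter = rng.uniform([-0.05, 0.8, 0.3, 0.6], [0.05, 1.2, 3.0, 1.8])
        starts.append(np.array([jitter[0], jitter[1], min(k_guess * jitter[2], 9.0), jitter[3]]))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, _FIT_BOUNDS_LO + 1e-9, _FIT_BOUNDS_HI - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=(_FIT_BOUNDS_LO, _FIT_BOUNDS_HI))
        except Exception:  # pragma: no cover - scipy failures are rare
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol

    if best is None:
        return FitReport(None, 0.0, float("nan"), float("nan"), n,
                         success=False, message="least-squares optimizer did not converge")

    a, b, k, nn = (float(v) for v in best.x)
    res = resid(best.x)
    ss_res = float(res @ res)
    ss_tot = float(np.sum((mr_obs - mr_obs.mean()) ** 2))
    p = 4
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    chi2 = ss_res / max(n - p, 1)
    rmse = math.sqrt(ss_res / n)
    try:
        params = ThinLayerParams(a=a, b=b, k=k, N=nn)
    except DomainError as exc:
        return FitReport(None, max(r2, 0.0), chi2, rmse, n,
                         success=False, message=f"fitted constants unphysical: {exc}")
    return FitReport(params, max(r2, 0.0), chi2, rmse, n)


# ---------------------------------------------------------------------------
# Conditions -> constants map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamMapConfig:
    """Smooth parametric map from drying conditions to Weibull constants.

    Stands in for lab-fitted regression surfaces: at the anchor conditions it
    returns the anchor constants, and the rate constant scales as

        k = k_ref * exp(cT*(T - T_ref)) * exp(-cRH*(RH - RH_ref))
                  * exp(cV*(V - V_ref)) * exp(-cW*(W0 - W0_ref))

    so k is strictly increasing in air temperature and velocity and
    decreasing in air humidity and initial moisture.  ``a``, ``b`` and ``N``
    stay at their anchors by default (cN = 0).  The anchor ``k_ref`` default
    is calibrated so the continuous-operation preset's theoretical window
    comes out at 12,000 degC.min (see docs/methods.md for the closed form).
    """

    a_ref: float = 0.0
    b_ref: float = 1.0
    k_ref: float = 0.5248852      # h^-N at the anchor conditions; calibrated
    N_ref: float = 1.1
    T_ref: float = 105.0          # deg C
    RH_ref: float = 0.10          # fraction
    V_ref: float = 0.6            # m/s
    W0_ref: float = 25.5          # % w.b.
    cT: float = 0.012             # 1/degC
    cRH: float = 0.8              # per RH fraction
    cV: float = 0.05              # s/m
    cW: float = 0.0               # per % w.b.
    cN: float = 0.0               # 1/degC, shape drift with temperature
    T_valid: tuple[float, float] = (40.0, 130.0)

    def scaled(self, k_scale: float = 1.0) -> "ParamMapConfig":
        """A copy with the anchor rate constant multiplied by ``k_scale``.

        Used to give the simulator ground truth a controlled mismatch against
        the controller's prior.
        """
        return ParamMapConfig(
            a_ref=self.a_ref, b_ref=self.b_ref, k_ref=self.k_ref * k_scale,
            N_ref=self.N_ref, T_ref=self.T_ref, RH_ref=self.RH_ref,
            V_ref=self.V_ref, W0_ref=self.W0_ref, cT=self.cT, cRH=self.cRH,
            cV=self.cV, cW=self.cW, cN=self.cN, T_valid=self.T_valid,
        )


@dataclass(frozen=True)
class ConditionedParams:
    """Weibull constants for given conditions plus an extrapolation flag."""

    params: ThinLayerParams
    extrapolated: bool = False


def params_for_conditions(cond: DryingConditions, pmap: ParamMapConfig) -> ConditionedParams:
    """Evaluate the conditions->constants map.  Deterministic and smooth.

    Conditions with air temperature outside ``pmap.T_valid`` are still
    evaluated but flagged ``extrapolated=True``.
    """
    log_k = (
        math.log(pmap.k_ref)
        + pmap.cT * (cond.T - pmap.T_ref)
        - pmap.cRH * (cond.RH - pmap.RH_ref)
        + pmap.cV * (cond.V - pmap.V_ref)
        - pmap.cW * (cond.W0 - pmap.W0_ref)
    )
    N = pmap.N_ref + pmap.cN * (cond.T - pmap.T_ref)
    params = ThinLayerParams(a=pmap.a_ref, b=pmap.b_ref, k=math.exp(log_k), N=N)
    extrap = not (pmap.T_valid[0] <= cond.T <= pmap.T_valid[1])
    return ConditionedParams(params=params, extrapolated=extrap)


# ---------------------------------------------------------------------------
# Synthetic thin-layer experiment
# ---------------------------------------------------------------------------

THINLAYER_COLUMNS = ["condition_id", "T_C", "RH_frac", "V_ms", "W0_wb", "gamma", "t_h", "Mt_db"]


def generate_thinlayer_dataset(
    true_params_map: ParamMapConfig,
    design: Sequence[DryingConditions],
    noise_sd: float = 0.005,
    seed: int = 0,
    Me_db: float = 5.0,
    t_grid_h: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Simulate a thin-layer drying experiment over a condition design.

    For each condition the true Weibull curve is sampled on ``t_grid_h``
    (default 0..8 h step 0.2) and Gaussian noise of ``noise_sd`` is added on
    moisture-ratio scale.  Reproducible under a fixed seed.  Returns a tidy
    frame with columns ``condition_id,T_C,RH_frac,V_ms,W0_wb,gamma,t_h,Mt_db``.
    """
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be >= 0, got {noise_sd}")
    if len(design) == 0:
        raise DomainError("empty condition design")
    if t_grid_h is None:
        t_grid_h = np.arange(0.0, 8.0 + 1e-9, 0.2)
    t = np.asarray(t_grid_h, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for cid, cond in enumerate(design):
        params = params_for_conditions(cond, true_params_map).params
        M0_db = wb_to_db(cond.W0)
        mr = params.a + params.b * np.exp(-params.k * np.power(t, params.N))
        if noise_sd > 0:
            mr = mr + rng.normal(0.0, noise_sd, size=mr.shape)
        mt = Me_db + (M0_db - Me_db) * mr
        for ti, mi in zip(t, mt):
            rows.append((cid, cond.T, cond.RH, cond.V, cond.W0, cond.gamma, float(ti), float(mi)))
    return pd.DataFrame(rows, columns=THINLAYER_COLUMNS)
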