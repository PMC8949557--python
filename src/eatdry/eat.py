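"""Accumulated-temperature (degree-minute) calculators.

Accumulated temperature AT is the time integral of the grain temperature
excess over the desorption equilibrium temperature Te,

    AT = integral_0^tn max(T(t) - Te(t), 0) dt          [degC.min]

and is this package's scalar proxy for drying progress.  Negative excess is
clipped: cooling below Te does not undo drying history.  Three specialised
calculators accompany the integral:

* ``theoretical_at`` - the window-selection value for a thin layer: constant
  air temperature, drying time from the Weibull inverse, tempering time
  folded in through the tempering ratio gamma.
* ``dryer_eat`` - the equivalent accumulated temperature of the mixed-flow
  dryer: because every parcel repeats the same journey at steady state, one
  parcel's time integral equals a volume-weighted sum of the instantaneous
  zone temperature excesses, with per-zone residence times derived from the
  discharge-wheel pass counts.
* ``solve_discharge_interval`` - the inverse of ``dryer_eat`` in the
  discharge interval tx, which is the dryer's only actuator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import CannotActuateError, DomainError
from .kinetics import DryingConditions, MoistureState, ThinLayerParams, time_for_moisture

__all__ = [
    "TemperatureTrace",
    "DryerGeometry",
    "SectionTemps",
    "DischargeSchedule",
    "DISCHARGE_DURATION_MIN",
    "PRINTED_COEFFS",
    "PRINTED_LITERAL_COEFFS",
    "accumulated_temperature",
    "theoretical_at",
    "section_pass_counts",
    "dryer_eat",
    "solve_discharge_interval",
]

#: Duration of one discharge-wheel rotation, minutes (fixed by the rig).
DISCHARGE_DURATION_MIN = 0.5

#: Zone pass counts as printed for the reference rig.  The zone-4 value 21.2
#: is inconsistent with the published geometry (which yields 20.2); the
#: printed set is kept as the default for fidelity and the geometry-derived
#: set is available via ``coefficients="geometry"``.
PRINTED_COEFFS = (11.5, 13.5, 13.5, 21.2)

#: The rig's closed-form EAT equation as literally printed multiplies the
#: *sum* of the middle and lower zone excesses by 27 (= 13.5 + 13.5), i.e.
#: each of those zones by 27 - double what the zone-passage-time derivation
#: gives.  Kept as a selectable path so the published arithmetic can be
#: reproduced bit-exactly; not the default.
PRINTED_LITERAL_COEFFS = (11.5, 27.0, 27.0, 21.2)


@dataclass(frozen=True)
class TemperatureTrace:
    """Sampled (t min, T degC, Te degC) history of one grain parcel."""

    samples: Sequence[tuple[float, float, float]]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
            raise DomainError("trace needs at least 2 (t, T, Te) samples")
        t = arr[:, 0]
        if not np.all(np.diff(t) > 0):
            raise DomainError("trace times must be strictly increasing")
        return t, arr[:, 1], arr[:, 2]


@dataclass(frozen=True)
class DryerGeometry:
    """Section volumes of the six-section mixed-flow dryer, litres.

    Vg1: upper drying.  Vg2h1: middle drying + tempering.  Vg3h2: lower
    drying + tempering.  Vl: cooling.  Vpp: discharge section.  Vp: grain
    volume discharged per wheel rotation.  Defaults are the reference rig.
    """

    Vg1: float = 92.382
    Vg2h1: float = 107.971
    Vg3h2: float = 107.971
    Vl: float = 92.382
    Vpp: float = 69.027
    Vp: float = 8.0

    def __post_init__(self) -> None:
        for name in ("Vg1", "Vg2h1", "Vg3h2", "Vl", "Vpp", "Vp"):
            if getattr(self, name) <= 0:
                raise DomainError(f"geometry volume {name} must be positive")

    @property
    def total_volume(self) -> float:
        return self.Vg1 + self.Vg2h1 + self.Vg3h2 + self.Vl + self.Vpp


@dataclass(frozen=True)
class SectionTemps:
    """Mean grain temperature of the four EAT zones plus Te, deg C."""

    Tbar1: float
    Tbar2: float
    Tbar3: float
    Tbar4: float
    Te: float

    def excesses(self) -> tuple[float, float, float, float]:
        return (self.Tbar1 - self.Te, self.Tbar2 - self.Te,
                self.Tbar3 - self.Te, self.Tbar4 - self.Te)


@dataclass(frozen=True)
class DischargeSchedule:
    """Discharge timing: interval tx plus the fixed 0.5-min discharge.

    ``t1..t4`` are zone passage times, t_i = count_i * (tx + 0.5) minutes.
    """

    tx: float
    t1: float
    t2: float
    t3: float
    t4: float
    discharge_duration: float = DISCHARGE_DURATION_MIN

    @classmethod
    def from_geometry(cls, geom: DryerGeometry, tx: float) -> "DischargeSchedule":
        if tx <= 0:
            raise DomainError(f"tx must be positive, got {tx}")
        c = section_pass_counts(geom)
        period = tx + DISCHARGE_DURATION_MIN
        return cls(tx=tx, t1=c[0] * period, t2=c[1] * period, t3=c[2] * period, t4=c[3] * period)


def accumulated_temperature(trace: TemperatureTrace) -> float:
    """Discretized effective accumulated temperature of a trace, degC.min.

    Left-rectangle rule on max(T - Te, 0); exact (dt-independent) for
    piecewise-constant traces.
    """
    t, T, Te = trace.arrays()
    excess = np.maximum(T - Te, 0.0)
    return float(np.sum(excess[:-1] * np.diff(t)))


def theoretical_at(
    cond: DryingConditions,
    params: ThinLayerParams,
    boundaries: MoistureState,
    Tf: float,
    Te: float,
) -> float:
    """Theoretical accumulated temperature AT0 to reach ``boundaries.Mt``.

    AT0 = (Tf - Te) * 60 * (1 + gamma) * t,  with the pure drying time t in
    hours from the Weibull inverse and the tempering ratio gamma stretching
    it to wall-clock process time.
    """
    if Tf <= Te:
        raise DomainError(f"air temperature Tf={Tf} must exceed Te={Te}")
    t_h = time_for_moisture(params, boundaries)
    return (Tf - Te) * 60.0 * (1.0 + cond.gamma) * t_h


def section_pass_counts(geom: DryerGeometry) -> tuple[float, float, float, float]:
    """Discharge events needed to traverse each EAT zone, one decimal.

    c1 = Vg1/Vp, c2 = Vg2h1/Vp, c3 = Vg3h2/Vp, c4 = (Vl+Vpp)/Vp.
    """
    return (
        round(geom.Vg1 / geom.Vp, 1),
        round(geom.Vg2h1 / geom.Vp, 1),
        round(geom.Vg3h2 / geom.Vp, 1),
        round((geom.Vl + geom.Vpp) / geom.Vp, 1),
    )


def _coeffs(
    geom: DryerGeometry,
    coefficients: Literal["printed", "geometry", "printed-literal"],
) -> tuple[float, ...]:
    if coefficients == "printed":
        return PRINTED_COEFFS
    if coefficients == "geometry":
        return section_pass_counts(geom)
    if coefficients == "printed-literal":
        return PRINTED_LITERAL_COEFFS
    raise DomainError(f"unknown coefficient set {coefficients!r}")


def dryer_eat(
    temps: SectionTemps,
    geom: DryerGeometry,
    tx: float,
    coefficients: Literal["printed", "geometry", "printed-literal"] = "printed",
) -> float:
    """Equivalent accumulated temperature of the dryer at one instant.

    AT1 = sum_i c_i * (Tbar_i - Te) * (tx + 0.5), degC.min.  Linear in
    (tx + 0.5) and in each temperature excess.
    """
    if tx <= 0:
        raise DomainError(f"tx must be positive, got {tx}")
    c = _coeffs(geom, coefficients)
    period = tx + DISCHARGE_DURATION_MIN
    return float(sum(ci * ei for ci, ei in zip(c, temps.excesses())) * period)


def solve_discharge_interval(
    temps: SectionTemps,
    geom: DryerGeometry,
    AT_set: float,
    coefficients: Literal["printed", "geometry", "printed-literal"] = "printed",
    tx_min: float = 1.0,
) -> float:
    """Discharge interval tx (min) that realizes ``AT_set``.

    Inverts ``dryer_eat``: tx = AT_set / sum_i c_i*(Tbar_i - Te) - 0.5,
    floored at ``tx_min``.  Raises :class:`CannotActuateError` when the
    temperature-excess sum is not positive (grain at or below equilibrium,
    no discharge interval can accumulate temperature).
    """
    if AT_set <= 0:
        raise DomainError(f"AT_set must be positive, got {AT_set}")
    c = _coeffs(geom, coefficients)
    denom = sum(ci * ei for ci, ei in zip(c, temps.excesses()))
    if denom <= 0:
        raise CannotActuateError(
            f"zone temperature excess sum {denom:.3g} <= 0: cannot realize AT_set={AT_set}"
        )
    tx = AT_set / denom - DISCHARGE_DURATION_MIN
    return max(tx, tx_min)
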