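"""Desorption equilibrium temperature of grain.

The equilibrium temperature Te is the temperature at which grain of a given
moisture content is in sorption equilibrium with air of a given relative
humidity.  It is the zero point of the effective accumulated temperature:
only grain heating above Te counts as drying effort.

The three-parameter model used here maps (ERH, EMC) -> Te with constants
A, B, C fitted to the corn desorption process (A=4.218, B=-32.013,
C=-0.0274).  The exact algebraic arrangement of the published model family
varies between sources, so the module keeps a small registry of model forms
selectable by id; every downstream consumer depends only on the Te contract
(finite, deterministic, decreasing in EMC under the default constants), not
on the particular form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .errors import DomainError

__all__ = [
    "CAEConstants",
    "EquilibriumQuery",
    "equilibrium_temperature",
    "register_form",
    "available_forms",
    "DEFAULT_FORM",
]

#: Relative-humidity fractions closer than this to 0 or 1 are rejected.
_ERH_EPS = 1e-9

DEFAULT_FORM = "default"


@dataclass(frozen=True)
class CAEConstants:
    """Constants of the three-parameter equilibrium model (corn desorption)."""

    A: float = 4.218
    B: float = -32.013
    C: float = -0.0274


@dataclass(frozen=True)
class EquilibriumQuery:
    """Equilibrium relative humidity (fraction) and moisture (% d.b.)."""

    ERH: float
    EMC: float

    def __post_init__(self) -> None:
        if not (_ERH_EPS < self.ERH < 1.0 - _ERH_EPS):
            raise DomainError(f"ERH must lie strictly inside (0, 1), got {self.ERH}")
        if self.EMC <= 0:
            raise DomainError(f"EMC must be positive, got {self.EMC}")


def _form_default(q: EquilibriumQuery, c: CAEConstants) -> float:
    # Te = ln[(1-ERH)/(-ln ERH)] - A - B*EMC^C
    return math.log((1.0 - q.ERH) / (-math.log(q.ERH))) - c.A - c.B * q.EMC ** c.C


def _form_plain(q: EquilibriumQuery, c: CAEConstants) -> float:
    # Te = ln(1-ERH) - ln(ERH) - A - B*EMC^C
    return math.log(1.0 - q.ERH) - math.log(q.ERH) - c.A - c.B * q.EMC ** c.C


_FORMS: dict[str, Callable[[EquilibriumQuery, CAEConstants], float]] = {
    "default": _form_default,
    "plain": _form_plain,
}


def register_form(name: str, fn: Callable[[EquilibriumQuery, CAEConstants], float]) -> None:
    """Register an alternative algebraic form under ``name``."""
    _FORMS[name] = fn


def available_forms() -> tuple[str, ...]:
    return tuple(sorted(_FORMS))


def equilibrium_temperature(
    q: EquilibriumQuery,
    c: CAEConstants | None = None,
    form: str = DEFAULT_FORM,
) -> float:
    """Desorption equilibrium temperature Te (deg C) for a query.

    Deterministic: same inputs give the same output.  Raises
    :class:`DomainError` for an unknown form or an out-of-domain query.
    """
    if c is None:
        c = CAEConstants()
    try:
        fn = _FORMS[form]
    except KeyError:
        raise DomainError(f"unknown equilibrium model form {form!r}; have {available_forms()}")
    te = fn(q, c)
    if not math.isfinite(te):
        raise DomainError(f"equilibrium temperature not finite for {q}")
    return te
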