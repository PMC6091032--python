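"""Weir-equation energy expenditure algebra.

Resting energy expenditure (REE, kcal/day) from gas exchange uses the
nitrogen-free two-term Weir equation

    REE = (3.941 * VO2 + 1.106 * VCO2) * 1440

with VO2 and VCO2 in L/min.  All *public* interfaces in this package take gas
rates in mL/min — the unit clinical devices report — and conversion to L/min
happens only inside this module, so the notorious 1000x unit errors cannot
occur elsewhere.

When only carbon dioxide production is available (e.g. from a ventilator), a
fixed respiratory quotient RQ = VCO2/VO2 is assumed and VO2 is replaced by
VCO2/RQ, giving the VCO2-only estimator

    REE = (3.941 / RQ + 1.106) * VCO2 * 1440.

The per-litre multiplier ``3.941/RQ + 1.106`` evaluates to 5.534 at RQ 0.89
(often presented rounded as ``5.5 * VCO2 * 1.44`` with VCO2 in mL/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RQ_SANITY_BOUNDS",
    "WeirCoefficients",
    "GasExchangeSample",
    "RQGrid",
    "SimplifiedFormula",
    "ree_weir",
    "vco2_multiplier",
    "ree_from_vco2",
    "compute_rq",
    "simplified_ree",
]

#: Physiologically plausible range for the respiratory quotient.  Values
#: outside (0.3, 2.0) indicate a measurement or unit error, not substrate
#: utilisation.  Configurable per call where it matters.
RQ_SANITY_BOUNDS: tuple[float, float] = (0.3, 2.0)


@dataclass(frozen=True)
class WeirCoefficients:
    """Caloric equivalents of the respiratory gases.

    Attributes
    ----------
    a_vo2 : float
        kcal per litre of O2 consumed (default 3.941).
    b_vco2 : float
        kcal per litre of CO2 produced (default 1.106).
    minutes_per_day : int
        Day-scaling constant; always 1440.
    """

    a_vo2: float = 3.941
    b_vco2: float = 1.106
    minutes_per_day: int = 1440

    def __post_init__(self) -> None:
        if not self.a_vo2 > 0:
            raise ValueError(f"a_vo2 must be positive, got {self.a_vo2}")
        if not self.b_vco2 > 0:
            raise ValueError(f"b_vco2 must be positive, got {self.b_vco2}")
        if self.minutes_per_day != 1440:
            raise ValueError(
                f"minutes_per_day is a day-scaling constant and must be 1440, "
                f"got {self.minutes_per_day}"
            )


DEFAULT_COEFFICIENTS = WeirCoefficients()


@dataclass(frozen=True)
class GasExchangeSample:
    """One indirect-calorimetry measurement for one patient.

    ``rq`` and ``ree_kcal_d`` are derived quantities, recomputed from the
    gases rather than stored, so a sample can never be internally
    inconsistent.
    """

    patient_id: str
    time: float  # minutes since cohort epoch
    vo2: float  # mL/min
    vco2: float  # mL/min

    def __post_init__(self) -> None:
        if not self.vo2 > 0:
            raise ValueError(f"vo2 must be positive, got {self.vo2}")
        if not self.vco2 > 0:
            raise ValueError(f"vco2 must be positive, got {self.vco2}")
        lo, hi = RQ_SANITY_BOUNDS
        rq = self.vco2 / self.vo2
        if not lo < rq < hi:
            raise ValueError(
                f"derived RQ {rq:.3f} outside sanity bounds ({lo}, {hi}) "
                f"for patient {self.patient_id!r}"
            )

    @property
    def rq(self) -> float:
        return compute_rq(self.vo2, self.vco2)

    @property
    def ree_kcal_d(self) -> float:
        return float(ree_weir(self.vo2, self.vco2))


@dataclass(frozen=True)
class RQGrid:
    """Ordered set of fixed RQ values at which the VCO2-only estimator is
    evaluated (default grid: 0.75, 0.80, 0.85, 0.89)."""

    values: tuple[float, ...] = (0.75, 0.80, 0.85, 0.89)

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("RQ grid must be non-empty")
        lo, hi = RQ_SANITY_BOUNDS
        for v in self.values:
            if not lo < v < hi:
                raise ValueError(f"grid RQ {v} outside sanity bounds ({lo}, {hi})")
        if any(b <= a for a, b in zip(self.values, self.values[1:])):
            raise ValueError(f"RQ grid must be strictly increasing, got {self.values}")

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SimplifiedFormula:
    """Linear bedside formula ``REE = intercept + slope * VCO2`` with VCO2 in
    mL/min (reference values: intercept 135, slope 8).  A zero slope is
    permitted only as a degenerate constant formula for evaluation."""

    intercept: float = 135.0
    slope: float = 8.0

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError(f"slope must be non-negative, got {self.slope}")

    def __str__(self) -> str:
        return f"REE = {self.intercept:g} + {self.slope:g} * VCO2"


def _check_nonnegative(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def _check_rq(rq, bounds: tuple[float, float] = RQ_SANITY_BOUNDS) -> np.ndarray:
    arr = np.asarray(rq, dtype=float)
    lo, hi = bounds
    if np.any((arr <= lo) | (arr >= hi)):
        raise ValueError(f"rq must lie in ({lo}, {hi})")
    return arr


def ree_weir(vo2, vco2, coeffs: WeirCoefficients = DEFAULT_COEFFICIENTS):
    """Resting energy expenditure (kcal/day) from the Weir equation.

    Parameters
    ----------
    vo2, vco2 : float or array-like
        Oxygen consumption and CO2 production in mL/min.

    Returns
    -------
    float or ndarray
        ``(a_vo2 * vo2/1000 + b_vco2 * vco2/1000) * 1440``, broadcast over
        the inputs.
    """
    vo2 = _check_nonnegative("vo2", vo2)
    vco2 = _check_nonnegative("vco2", vco2)
    ree = (coeffs.a_vo2 * vo2 / 1000.0 + coeffs.b_vco2 * vco2 / 1000.0) * coeffs.minutes_per_day
    return ree if ree.ndim else float(ree)


def vco2_multiplier(rq, coeffs: WeirCoefficients = DEFAULT_COEFFICIENTS):
    """Per-litre VCO2 coefficient ``a_vo2/rq + b_vco2`` of the fixed-RQ
    estimator (kcal per L of CO2, before the x1440 day scaling).

    Strictly decreasing in ``rq``; 5.534 at the default coefficients and
    RQ 0.89.
    """
    rq = _check_rq(rq)
    mult = coeffs.a_vo2 / rq + coeffs.b_vco2
    return mult if mult.ndim else float(mult)


def ree_from_vco2(vco2, rq, coeffs: WeirCoefficients = DEFAULT_COEFFICIENTS):
    """VCO2-only REE estimate (kcal/day) at a fixed assumed RQ.

    Algebraically identical to ``ree_weir(vco2/rq, vco2)``: the unmeasured
    VO2 is imputed as VCO2/RQ.
    """
    vco2 = _check_nonnegative("vco2", vco2)
    rq = _check_rq(rq)
    ree = vco2_multiplier(rq, coeffs) * (vco2 / 1000.0) * coeffs.minutes_per_day
    ree = np.asarray(ree)
    return ree if ree.ndim else float(ree)


def compute_rq(vo2, vco2):
    """Respiratory quotient VCO2/VO2 (dimensionless)."""
    vo2 = np.asarray(vo2, dtype=float)
    if np.any(vo2 <= 0):
        raise ValueError("vo2 must be positive to compute RQ")
    rq = np.asarray(vco2, dtype=float) / vo2
    return rq if rq.ndim else float(rq)


def simplified_ree(vco2, formula: SimplifiedFormula = SimplifiedFormula()):
    """Apply the linear bedside formula to VCO2 in mL/min."""
    vco2 = _check_nonnegative("vco2", vco2)
    ree = formula.intercept + formula.slope * vco2
    return ree if ree.ndim else float(ree)
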