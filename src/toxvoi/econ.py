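"""Monetisation of health outcomes and exposure controls over time.

Costs are tracked in $M over an integer horizon of years y = 1..y_TH, each
discounted by (1 + r)^-(y - 1). Two streams make up the total social cost:

* control cost — an annual cost ACC_k of holding mean exposure k% below
  baseline, following an exponential ramp between a fixed overhead ACC_F at
  k = 0 and a maximum ACC_max at k = 100;
* health cost — the monetised burden of the adverse effect,
  N * B_y * V * R per year, where N is the exposed population, B_y converts
  the risk measure to an annual incidence (1/80 for a lifetime risk, 365
  for a daily risk) and V values one case (e.g. a value of statistical
  life).

Health costs at the unmitigated risk accrue from year 1. Controls — and the
health savings they buy — begin only once testing, decision making, and
implementation are complete: with a decision delay of d years and an
implementation time t_imp, the first controlled year is
d + t_imp + ``impl_year_offset``. The offset (default 1: costs and savings
start the year *after* implementation completes) is the convention the
illustrative applications were calibrated under; 0 gives the alternative
reading in which implementation year itself is already controlled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import InvalidParameterError
from .risk import MitigationLevel

__all__ = [
    "EconTiming",
    "CostBreakdown",
    "control_cost",
    "discounted_sum",
    "total_social_cost",
    "annualized_social_cost",
]


@dataclass(frozen=True)
class EconTiming:
    """Economic valuation, discounting and timing constants.

    Attributes
    ----------
    population
        Exposed persons (constant over the horizon).
    valuation
        $M per case of the health outcome.
    annualization
        Converts the risk measure to an annual incidence per person
        (1/80 for lifetime risk with 80-year life expectancy; 365 for a
        daily risk).
    discount_rate
        Fraction per year, >= 0.
    horizon_years
        y_TH, integer >= 1.
    implement_years
        Years to implement a regulation once decided.
    acc_max, acc_fixed
        Annual control cost at complete elimination / at zero mitigation,
        $M per year.
    steepness
        Exponent of the control-cost ramp; 0 gives the linear limit.
    impl_year_offset
        0 or 1; see module docstring.
    """

    population: float
    valuation: float
    annualization: float
    discount_rate: float
    horizon_years: int
    implement_years: float = 0.0
    acc_max: float = 0.0
    acc_fixed: float = 0.0
    steepness: float = 2.0
    impl_year_offset: int = 1

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise InvalidParameterError("population must be positive")
        if self.valuation < 0 or self.annualization <= 0:
            raise InvalidParameterError("valuation must be >= 0 and annualization > 0")
        if self.discount_rate < 0:
            raise InvalidParameterError("discount_rate must be >= 0")
        if not (isinstance(self.horizon_years, int) and self.horizon_years >= 1):
            raise InvalidParameterError("horizon_years must be an integer >= 1")
        if self.implement_years < 0:
            raise InvalidParameterError("implement_years must be >= 0")
        if not self.acc_max >= self.acc_fixed >= 0:
            raise InvalidParameterError("need acc_max >= acc_fixed >= 0")
        if self.steepness < 0:
            raise InvalidParameterError("steepness must be >= 0")
        if self.impl_year_offset not in (0, 1):
            raise InvalidParameterError("impl_year_offset must be 0 or 1")

    @property
    def value_rate(self) -> float:
        """$M of health cost per unit of risk per year: N * B_y * V."""
        return self.population * self.annualization * self.valuation

    def first_controlled_year(self, delay_years: float) -> int:
        """First horizon year in which controls (and savings) operate."""
        first = delay_years + self.implement_years + self.impl_year_offset
        return max(1, int(math.ceil(first - 1e-9)))


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted control and health cost totals, $M."""

    tcc: float
    thc: float

    @property
    def tsc(self) -> float:
        """Total social cost: exactly tcc + thc."""
        return self.tcc + self.thc


def control_cost(level: MitigationLevel, econ: EconTiming) -> float:
    """Annual control cost ($M/year) of holding exposure ``level.k``% down.

    Exponential ramp ACC_F + (ACC_max - ACC_F) * (10**(eta*k/100) - 1) /
    (10**eta - 1); the eta -> 0 limit is the linear ramp.
    """
    frac = level.k / 100.0
    if econ.steepness == 0:
        ramp = frac
    else:
        ramp = (10.0 ** (econ.steepness * frac) - 1.0) / (10.0**econ.steepness - 1.0)
    return econ.acc_fixed + (econ.acc_max - econ.acc_fixed) * ramp


def discounted_sum(first_year: int, econ: EconTiming) -> float:
    """Sum of (1 + r)^-(y - 1) for y = first_year .. horizon, inclusive.

    Zero when ``first_year`` exceeds the horizon. Closed-form geometric sum.
    """
    if first_year < 1:
        raise InvalidParameterError("first_year must be >= 1")
    f, t = int(first_year), econ.horizon_years
    if f > t:
        return 0.0
    n = t - f + 1
    r = econ.discount_rate
    if r == 0:
        return float(n)
    q = 1.0 / (1.0 + r)
    return q ** (f - 1) * (1.0 - q**n) / (1.0 - q)


def total_social_cost(
    risk_unmitigated: float,
    risk_mitigated: float,
    level: MitigationLevel,
    delay_years: float,
    econ: EconTiming,
) -> CostBreakdown:
    """Discounted control + health cost over the horizon.

    Health cost runs at the unmitigated rate until controls take effect in
    year ``econ.first_controlled_year(delay_years)``, then at the mitigated
    rate; control cost accrues from that year on. Linear in both risks.
    """
    if delay_years + econ.implement_years > econ.horizon_years:
        warnings.warn(
            "decision delay plus implementation time exceeds the horizon: "
            "controls never operate within the costed period",
            stacklevel=2,
        )
    d_all = discounted_sum(1, econ)
    d_impl = discounted_sum(econ.first_controlled_year(delay_years), econ)
    tcc = control_cost(level, econ) * d_impl
    thc = econ.value_rate * (
        risk_unmitigated * d_all - (risk_unmitigated - risk_mitigated) * d_impl
    )
    return CostBreakdown(tcc=tcc, thc=thc)


def annualized_social_cost(
    level: MitigationLevel, risk_mitigated: float, year: int, econ: EconTiming
) -> float:
    """Single-year social cost (C_k + N*B_y*V*R_k) / (1 + r)^(year - 1)."""
    if year < 1:
        raise InvalidParameterError("year must be >= 1")
    undiscounted = control_cost(level, econ) + econ.value_rate * risk_mitigated
    return undiscounted / (1.0 + econ.discount_rate) ** (year - 1)
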