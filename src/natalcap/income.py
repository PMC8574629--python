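"""Net present value of lifetime income and income gains from schooling.

Average annual income is taken as a fixed share (default two-thirds) of GDP
per capita.  The NPV of one worker's lifetime income discounts a 40-year
working period (ages 20-59) at a 3%/y rate with 2%/y real wage growth,
weighting each working year by the cumulative probability of surviving to
that age:

    NPV = sum_{a=20}^{59} s * g * (1+w)^(a-r) * S(a) / (1+d)^(a-r)

with s the income share, g GDP per capita (2010 constant USD; optionally
PPP-adjusted), w wage growth, d the discount rate, S(a) survival from birth
to age a, and r the reference age for discounting (default 0 = birth).

The cohort income gain is linear: school years gained x returns-to-schooling
rate x NPV of baseline lifetime income.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EconConfig:
    """Economic constants for NPV and income projection.

    All rates are per year; ``income_share_of_gdp`` is the assumed ratio of
    average annual income to GDP per capita.  ``npv_reference_age`` fixes the
    age (relative to birth) from which both discounting and wage growth are
    counted.
    """

    discount_rate: float = 0.03
    wage_growth: float = 0.02
    income_share_of_gdp: float = 2.0 / 3.0
    work_start_age: int = 20
    work_end_age: int = 59
    ppp: bool = False
    npv_reference_age: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.discount_rate < 1.0 and 0.0 <= self.wage_growth < 1.0):
            raise ValueError("rates must lie in [0, 1)")
        if self.work_start_age >= self.work_end_age:
            raise ValueError("work_start_age must precede work_end_age")
        if self.income_share_of_gdp < 0:
            raise ValueError("income_share_of_gdp must be non-negative")


def npv_lifetime_income(gdp_pc: float, surv_age, econ: EconConfig, ppp_factor: float = 1.0) -> float:
    """NPV at the reference age of one person's lifetime income, in USD.

    ``surv_age`` gives cumulative survival from birth for each integer age in
    ``[econ.work_start_age, econ.work_end_age]``; a wrong-length or
    non-finite vector is an error.
    """
    if gdp_pc < 0:
        raise ValueError("gdp_pc must be non-negative")
    ages = np.arange(econ.work_start_age, econ.work_end_age + 1)
    surv = np.asarray(surv_age, dtype=float)
    if surv.shape != ages.shape:
        raise ValueError(f"surv_age must cover ages {ages[0]}-{ages[-1]} ({ages.size} entries), got {surv.shape}")
    if not np.all(np.isfinite(surv)):
        raise ValueError("surv_age contains non-finite entries")
    if econ.ppp:
        gdp_pc = gdp_pc * ppp_factor
    t = ages - econ.npv_reference_age
    annual = econ.income_share_of_gdp * gdp_pc
    return float(np.sum(annual * (1.0 + econ.wage_growth) ** t * surv / (1.0 + econ.discount_rate) ** t))


def income_gain(total_years, returns_rate, npv_base):
    """Cohort income gain: school years x returns per year x lifetime NPV."""
    return total_years * returns_rate * npv_base


def income_per_child(total_income, births, targeted_fraction):
    """Average income gain per child born to targeted women.

    Undefined (raises) when no births are targeted.
    """
    denom = np.asarray(births, dtype=float) * np.asarray(targeted_fraction, dtype=float)
    if np.any(denom <= 0):
        raise ZeroDivisionError("no targeted births: per-child income is undefined")
    out = total_income / denom
    return out if np.ndim(out) else float(out)
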