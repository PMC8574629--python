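"""Population attributable fraction (PAF) engine and scenario logic.

The model converts a coverage scale-up of a prenatal nutrition intervention
into a proportional reduction (PAF) in its mediating birth outcome:

    PAF = (p_target - p_current) * (1 - RR) / (1 + p_current * (RR - 1))

where RR is the relative risk of the outcome among supplemented versus
unsupplemented pregnancies and p_* are coverage proportions.  Multiplying by
the national mediator prevalence gives the absolute prevalence reduction.

Intervention-specific rules:

* **IFA** (mediator LBW): scale-up from the country's current self-reported
  coverage to the target.
* **Calcium** (mediator PTB): zero baseline coverage assumed.
* **BEP** (mediator LBW): restricted to underweight women (BMI < 18.5), so
  the effective target coverage is ``target x underweight_prev``.
* **MMS** (mediator LBW): effect sizes are anemia-stratified and relative to
  IFA.  Women switching from IFA to MMS experience the stratum RR directly;
  women newly covered experience the multiplicative combined effect
  ``RR_MMS|stratum x RR_IFA`` versus no supplementation.  The overall PAF is
  the anemia-prevalence-weighted average of the stratum reductions.

All arithmetic is numpy-vectorised, so the same code path serves both point
evaluation and bootstrap draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .country_inputs import CountryRecord
from .effects import EffectRegistry
from .income import EconConfig

INTERVENTIONS = ("IFA", "CALCIUM", "MMS", "BEP")

#: mediating birth outcome for each intervention
MEDIATOR = {"IFA": "LBW", "CALCIUM": "PTB", "MMS": "LBW", "BEP": "LBW"}


@dataclass
class ScenarioConfig:
    """One intervention scale-up scenario plus run conventions."""

    intervention: str
    target_coverage: float
    ppp: bool = False
    per_child: bool = True
    grade11_fraction: float = 1.0 / 6.0
    econ: EconConfig = field(default_factory=EconConfig)
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.intervention = self.intervention.upper()
        if self.intervention not in INTERVENTIONS:
            raise ValueError(f"unknown intervention {self.intervention!r}; expected one of {INTERVENTIONS}")
        if not (0.0 <= self.target_coverage <= 1.0):
            raise ValueError("target_coverage must be in [0, 1]")
        if not (0.0 <= self.grade11_fraction <= 1.0):
            raise ValueError("grade11_fraction must be in [0, 1]")
        if self.n_boot < 2:
            raise ValueError("n_boot must be at least 2")

    @property
    def mediator(self) -> str:
        return MEDIATOR[self.intervention]


@dataclass
class ReductionResult:
    """Scenario output for one country: proportional and absolute reduction.

    ``paf`` is the proportional reduction in the mediator's prevalence,
    ``abs_reduction`` the reduction in prevalence points, and
    ``targeted_fraction`` the fraction of births born to women targeted by
    the scenario (denominator for per-child income).
    """

    paf: float | np.ndarray
    abs_reduction: float | np.ndarray
    targeted_fraction: float | np.ndarray


def compute_paf(rr, p_current, p_target, clamp: bool = True):
    """PAF of moving coverage from ``p_current`` to ``p_target`` at risk ratio ``rr``.

    With ``clamp`` (default), a scenario that would *reduce* coverage
    (``p_current > p_target``) returns 0 with a warning — the model never
    projects dis-scaling.  Raises if the baseline-prevalence denominator
    ``1 + p_current (rr - 1)`` is non-positive, which can only occur for
    extreme rr > 1 at high baseline coverage.
    """
    rr = np.asarray(rr, dtype=float)
    p_current = np.asarray(p_current, dtype=float)
    p_target = np.asarray(p_target, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("rr must be strictly positive")
    if np.any((p_current < 0) | (p_current > 1) | (p_target < 0) | (p_target > 1)):
        raise ValueError("coverage proportions must be in [0, 1]")
    denom = 1.0 + p_current * (rr - 1.0)
    if np.any(denom <= 0):
        raise ValueError("non-positive baseline prevalence denominator (rr too large for this coverage)")
    paf = (p_target - p_current) * (1.0 - rr) / denom
    if clamp:
        down = p_current > p_target
        if np.any(down):
            warnings.warn("current coverage exceeds target; PAF clamped to 0 (no dis-scaling)", stacklevel=2)
            paf = np.where(down, 0.0, paf)
    return paf if paf.ndim else float(paf)


# -- vector kernels: plain arithmetic over scalars or draw arrays ------------

def ifa_kernel(rr_ifa, ifa_coverage, lbw_prev, target):
    paf = compute_paf(rr_ifa, ifa_coverage, target)
    targeted = np.maximum(0.0, np.asarray(target, dtype=float) - ifa_coverage)
    return paf, paf * lbw_prev, targeted


def calcium_kernel(rr_ca, ptb_prev, target):
    paf = compute_paf(rr_ca, 0.0, target)
    return paf, paf * ptb_prev, np.asarray(target, dtype=float)


def bep_kernel(rr_bep, underweight_prev, lbw_prev, target):
    eff_target = np.asarray(target, dtype=float) * np.asarray(underweight_prev, dtype=float)
    paf = compute_paf(rr_bep, 0.0, eff_target)
    return paf, paf * lbw_prev, eff_target


def mms_kernel(rr_mms_anemic, rr_mms_nonanemic, rr_ifa, anemia_prev, ifa_coverage, lbw_prev, target):
    t = np.asarray(target, dtype=float)
    w_switch = np.minimum(np.asarray(ifa_coverage, dtype=float), t)
    w_new = np.maximum(0.0, t - np.asarray(ifa_coverage, dtype=float))
    red_anemic = w_switch * (1.0 - rr_mms_anemic) + w_new * (1.0 - rr_mms_anemic * rr_ifa)
    red_nonanemic = w_switch * (1.0 - rr_mms_nonanemic) + w_new * (1.0 - rr_mms_nonanemic * rr_ifa)
    paf = anemia_prev * red_anemic + (1.0 - np.asarray(anemia_prev, dtype=float)) * red_nonanemic
    return paf, paf * lbw_prev, t


# -- record-level API at registry point values -------------------------------

def _require(c: CountryRecord, fields: tuple[str, ...]) -> None:
    for f in fields:
        if getattr(c, f) is None:
            raise ValueError(f"{c.country_id}: {f} is missing; impute before running scenarios")


def ifa_reduction(c: CountryRecord, s: ScenarioConfig, reg: EffectRegistry) -> ReductionResult:
    """IFA scale-up from current coverage to target; mediator LBW."""
    if s.intervention != "IFA":
        raise ValueError("scenario intervention must be IFA")
    _require(c, ("lbw_prev",))
    paf, absr, targ = ifa_kernel(reg.rr_ifa_lbw.point, c.ifa_coverage, c.lbw_prev, s.target_coverage)
    return ReductionResult(float(paf), float(absr), float(targ))


def calcium_reduction(c: CountryRecord, s: ScenarioConfig, reg: EffectRegistry) -> ReductionResult:
    """Calcium scale-up from zero baseline; mediator PTB."""
    if s.intervention != "CALCIUM":
        raise ValueError("scenario intervention must be CALCIUM")
    _require(c, ("ptb_prev",))
    paf, absr, targ = calcium_kernel(reg.rr_ca_ptb.point, c.ptb_prev, s.target_coverage)
    return ReductionResult(float(paf), float(absr), float(targ))


def bep_reduction(c: CountryRecord, s: ScenarioConfig, reg: EffectRegistry) -> ReductionResult:
    """BEP for underweight women; effective coverage target x underweight prevalence."""
    if s.intervention != "BEP":
        raise ValueError("scenario intervention must be BEP")
    _require(c, ("lbw_prev",))
    paf, absr, targ = bep_kernel(reg.rr_bep_lbw.point, c.underweight_prev, c.lbw_prev, s.target_coverage)
    return ReductionResult(float(paf), float(absr), float(targ))


def mms_reduction(c: CountryRecord, s: ScenarioConfig, reg: EffectRegistry) -> ReductionResult:
    """MMS with anemia-stratified effects; switchers from IFA plus newly covered."""
    if s.intervention != "MMS":
        raise ValueError("scenario intervention must be MMS")
    _require(c, ("lbw_prev",))
    paf, absr, targ = mms_kernel(
        reg.rr_mms_lbw_anemic.point, reg.rr_mms_lbw_nonanemic.point, reg.rr_ifa_lbw.point,
        c.anemia_prev, c.ifa_coverage, c.lbw_prev, s.target_coverage,
    )
    return ReductionResult(float(paf), float(absr), float(targ))


_REDUCERS = {
    "IFA": ifa_reduction,
    "CALCIUM": calcium_reduction,
    "BEP": bep_reduction,
    "MMS": mms_reduction,
}


def reduction(c: CountryRecord, s: ScenarioConfig, reg: EffectRegistry) -> ReductionResult:
    """Dispatch to the intervention-specific reduction rule."""
    return _REDUCERS[s.intervention](c, s, reg)
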