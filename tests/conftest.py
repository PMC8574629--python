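"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from natalcap.country_inputs import REGIONS, WORK_AGES, CountryRecord
from natalcap.effects import EffectEstimate, EffectRegistry


def microsim_paf(rr: float, p_current: float, p_target: float,
                 n_births: int = 10**7, baseline_risk: float = 0.1,
                 seed: int = 0) -> tuple[float, float]:
    """Individual-level microsimulation oracle for the PAF formula.

    Simulates ``n_births`` births twice (current and target coverage):
    each birth is covered with the scenario probability and experiences the
    adverse outcome at ``baseline_risk`` (untreated) or
    ``baseline_risk * rr`` (treated).  Returns the simulated proportional
    reduction in outcome prevalence and its delta-method Monte-Carlo SE.
    """
    rng = np.random.default_rng(seed)

    def outcome_prev(coverage: float) -> float:
        n_treated = rng.binomial(n_births, coverage)
        events = rng.binomial(n_treated, baseline_risk * rr) + \
            rng.binomial(n_births - n_treated, baseline_risk)
        return events / n_births

    y_cur = outcome_prev(p_current)
    y_tar = outcome_prev(p_target)
    paf = (y_cur - y_tar) / y_cur
    var_cur = y_cur * (1 - y_cur) / n_births
    var_tar = y_tar * (1 - y_tar) / n_births
    se = np.sqrt(var_tar / y_cur**2 + y_tar**2 * var_cur / y_cur**4)
    return float(paf), float(se)


def npv_geometric(gdp_pc: float, income_share: float, wage_growth: float,
                  discount_rate: float, a0: int = 20, a1: int = 59) -> float:
    """Closed-form NPV oracle for survival == 1: a geometric series."""
    r = (1.0 + wage_growth) / (1.0 + discount_rate)
    n_terms = a1 - a0 + 1
    if r == 1.0:
        series = float(n_terms)
    else:
        series = r**a0 * (1.0 - r**n_terms) / (1.0 - r)
    return income_share * gdp_pc * series


def flat_survival(value: float = 1.0) -> np.ndarray:
    return np.full(len(WORK_AGES), value)


def make_record(**overrides) -> CountryRecord:
    """A fully-specified country record with simple defaults."""
    base = dict(
        country_id="TST", region=REGIONS[3],
        lbw_prev=0.20, lbw_se=0.02, ptb_prev=0.10, ptb_se=0.01,
        anemia_prev=0.40, anemia_se=0.04, underweight_prev=0.20, underweight_se=0.02,
        ifa_coverage=0.30, ifa_coverage_se=0.0,
        incomplete_secondary_prev=0.60, incomplete_secondary_se=0.06,
        births=1_000_000.0, surv_to_25=0.95, surv_age=flat_survival(0.95),
        gdp_pc=3000.0, ppp_factor=2.5, returns_rate=0.09, returns_se=0.009,
    )
    base.update(overrides)
    return CountryRecord(**base)


def degenerate_registry() -> EffectRegistry:
    """Registry whose CIs collapse to the point (all effect SEs zero)."""
    reg = EffectRegistry.default()
    updates = {
        name: EffectEstimate(e.point, e.point, e.point, e.scale, e.label)
        for name, e in ((f, getattr(reg, f)) for f in (
            "rr_ifa_lbw", "rr_ca_ptb", "rr_bep_lbw", "rr_mms_lbw_anemic",
            "rr_mms_lbw_nonanemic", "schooling_lbw", "schooling_ptb"))
    }
    return dataclasses.replace(reg, **updates)


def zero_se_record(**overrides) -> CountryRecord:
    """A record whose every uncertainty is zero."""
    zeros = {k: 0.0 for k in (
        "lbw_se", "ptb_se", "anemia_se", "underweight_se",
        "ifa_coverage_se", "incomplete_secondary_se", "returns_se")}
    zeros.update(overrides)
    return make_record(**zeros)


@pytest.fixture
def record():
    return make_record()


@pytest.fixture
def registry():
    return EffectRegistry.default()
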