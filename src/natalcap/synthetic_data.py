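"""Synthetic country worlds with known ground truth.

The study-shaped input is a table of 132 low- and middle-income countries
across six GBD super-regions, each with birth-outcome prevalences (plus
sampling uncertainty and occasional missingness), maternal anemia and
underweight prevalence, current IFA coverage, a 5-year birth cohort,
survival probabilities, GDP per capita and returns to schooling.  This
module draws such worlds from realistic ranges, records the latent truth,
and emits an observed table whose values are noisy measurements of that
truth — so every pipeline stage can be tested for recovery against a known
answer without any external data.

Observed prevalences are drawn normally around the latent truth with an SE
set by a coefficient of variation (default 10%), then truncated to [0, 1];
the same SE is reported in the table, as a measurement model would.
Survival curves follow a Gompertz-like adult hazard so cumulative survival
is monotone non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .country_inputs import REGIONS, WORK_AGES, CountryRecord, write_country_table
from .effects import EffectRegistry

#: region weights proportional to the country counts of the six super-regions
DEFAULT_REGION_WEIGHTS = (20 / 132, 24 / 132, 14 / 132, 5 / 132, 47 / 132, 22 / 132)


@dataclass(frozen=True)
class WorldSpec:
    """Generative ranges and conventions for one synthetic world."""

    n_countries: int = 132
    region_weights: tuple = DEFAULT_REGION_WEIGHTS
    lbw_range: tuple = (0.03, 0.30)
    ptb_range: tuple = (0.04, 0.18)
    anemia_range: tuple = (0.10, 0.70)
    underweight_range: tuple = (0.02, 0.35)
    ifa_range: tuple = (0.0, 0.9)
    births_range: tuple = (1e4, 1e7)
    surv25_range: tuple = (0.85, 0.999)
    gdp_range: tuple = (500.0, 15000.0)
    returns_range: tuple = (0.05, 0.15)
    incomplete_secondary_range: tuple = (0.2, 0.9)
    ppp_range: tuple = (1.5, 3.5)
    missingness: float = 0.05
    cv: float = 0.10
    observation_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be positive")
        if len(self.region_weights) != len(REGIONS):
            raise ValueError(f"region_weights needs {len(REGIONS)} entries")
        if abs(sum(self.region_weights) - 1.0) > 1e-9:
            raise ValueError("region_weights must sum to 1")
        if not (0.0 <= self.missingness <= 1.0):
            raise ValueError("missingness must be in [0, 1]")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        for name, (lo, hi), bound in (
            ("lbw_range", self.lbw_range, 1.0), ("ptb_range", self.ptb_range, 1.0),
            ("anemia_range", self.anemia_range, 1.0), ("underweight_range", self.underweight_range, 1.0),
            ("ifa_range", self.ifa_range, 1.0), ("surv25_range", self.surv25_range, 1.0),
            ("returns_range", self.returns_range, 1.0),
            ("incomplete_secondary_range", self.incomplete_secondary_range, 1.0),
        ):
            if not (0.0 <= lo <= hi <= bound):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi <= {bound}")
        for name, (lo, hi) in (("births_range", self.births_range),
                               ("gdp_range", self.gdp_range), ("ppp_range", self.ppp_range)):
            if not (0.0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")


@dataclass(frozen=True)
class WorldTruth:
    """Latent truth for a generated world: per-country parameters plus the
    true effect registry the world was built under."""

    countries: pd.DataFrame
    registry: EffectRegistry = field(default_factory=EffectRegistry)


def _scaled_beta(rng, lo, hi, size, a=2.0, b=2.0):
    return lo + (hi - lo) * rng.beta(a, b, size=size)


def _survival_curve(rng, surv25):
    """Cumulative survival for ages 20-59 with Gompertz-like adult hazard."""
    gamma = rng.uniform(0.07, 0.10)
    k = rng.uniform(0.0005, 0.003)
    ages = np.array(WORK_AGES, dtype=float)
    surv = np.empty_like(ages)
    young = ages <= 25
    # ages 20-25: geometric interpolation of survival from birth
    surv[young] = surv25 ** ((ages[young] - 15.0) / 10.0)
    older = ~young
    cum_haz = k * (np.exp(gamma * (ages[older] - 25.0)) - 1.0) / gamma
    surv[older] = surv25 * np.exp(-cum_haz)
    return surv


def _observe(rng, truth, se, noisy):
    if not noisy or se == 0.0:
        return truth
    return float(np.clip(rng.normal(truth, se), 0.0, 1.0))


def generate_world(spec: WorldSpec) -> tuple[list[CountryRecord], WorldTruth]:
    """Draw one world: observed country records plus the latent truth ledger.

    Reproducible under ``spec.seed``.  Missing LBW/PTB prevalences are
    injected at ``spec.missingness`` per field (flagged, values None) to
    exercise regional imputation downstream.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_countries
    region_idx = rng.choice(len(REGIONS), size=n, p=np.asarray(spec.region_weights))

    truth = pd.DataFrame({
        "country_id": [f"SYN{i:03d}" for i in range(n)],
        "region": [REGIONS[j] for j in region_idx],
        "lbw_prev": _scaled_beta(rng, *spec.lbw_range, n),
        "ptb_prev": _scaled_beta(rng, *spec.ptb_range, n),
        "anemia_prev": _scaled_beta(rng, *spec.anemia_range, n),
        "underweight_prev": _scaled_beta(rng, *spec.underweight_range, n),
        "ifa_coverage": rng.uniform(*spec.ifa_range, size=n),
        "incomplete_secondary_prev": rng.uniform(*spec.incomplete_secondary_range, size=n),
        "births": np.exp(rng.uniform(np.log(spec.births_range[0]), np.log(spec.births_range[1]), size=n)).round(),
        "surv_to_25": rng.uniform(*spec.surv25_range, size=n),
        "gdp_pc": np.exp(rng.uniform(np.log(spec.gdp_range[0]), np.log(spec.gdp_range[1]), size=n)).round(2),
        "ppp_factor": rng.uniform(*spec.ppp_range, size=n).round(3),
        "returns_rate": rng.uniform(*spec.returns_range, size=n),
    })

    miss_lbw = rng.random(n) < spec.missingness
    miss_ptb = rng.random(n) < spec.missingness

    records: list[CountryRecord] = []
    surv_rows = []
    for i, row in enumerate(truth.to_dict("records")):
        surv = _survival_curve(rng, row["surv_to_25"])
        surv_rows.append(surv)
        flags: set[str] = set()

        def prev(name):
            se = spec.cv * row[name]
            return _observe(rng, row[name], se, spec.observation_noise), se

        lbw, lbw_se = prev("lbw_prev")
        ptb, ptb_se = prev("ptb_prev")
        anemia, anemia_se = prev("anemia_prev")
        underweight, uw_se = prev("underweight_prev")
        inc_sec, inc_se = prev("incomplete_secondary_prev")
        returns_se = spec.cv * row["returns_rate"]
        returns = row["returns_rate"]
        if spec.observation_noise and returns_se > 0:
            returns = float(max(0.0, rng.normal(returns, returns_se)))
        if miss_lbw[i]:
            lbw, lbw_se = None, float("nan")
            flags.add("missing_lbw")
        if miss_ptb[i]:
            ptb, ptb_se = None, float("nan")
            flags.add("missing_ptb")
        records.append(CountryRecord(
            country_id=row["country_id"], region=row["region"],
            lbw_prev=lbw, lbw_se=lbw_se, ptb_prev=ptb, ptb_se=ptb_se,
            anemia_prev=anemia, anemia_se=anemia_se,
            underweight_prev=underweight, underweight_se=uw_se,
            ifa_coverage=row["ifa_coverage"], ifa_coverage_se=0.0,
            incomplete_secondary_prev=inc_sec, incomplete_secondary_se=inc_se,
            births=row["births"], surv_to_25=row["surv_to_25"], surv_age=surv,
            gdp_pc=row["gdp_pc"], ppp_factor=row["ppp_factor"],
            returns_rate=returns, returns_se=returns_se,
            flags=flags,
        ))
    for a_i, age in enumerate(WORK_AGES):
        truth[f"surv_{age}"] = [s[a_i] for s in surv_rows]
    return records, WorldTruth(countries=truth, registry=EffectRegistry.default())


def generate_null_world(spec: WorldSpec, keep_effect_se: bool = True) -> tuple[list[CountryRecord], WorldTruth]:
    """World whose true intervention relative risks are all 1 (no effect).

    Every downstream gain evaluated at the truth registry is exactly zero;
    with ``keep_effect_se`` the RR uncertainty is preserved so bootstrap
    draws straddle the null.
    """
    records, truth = generate_world(spec)
    return records, replace(truth, registry=truth.registry.null_risks(keep_se=keep_effect_se))


def write_world(records: list[CountryRecord], truth: WorldTruth, countries_path, truth_path) -> None:
    """Write the observed table and the truth ledger as CSV."""
    write_country_table(records, countries_path)
    truth.countries.to_csv(truth_path, index=False)
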