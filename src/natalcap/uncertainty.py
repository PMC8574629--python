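"""Bootstrap propagation of parameter uncertainty through the model chain.

The chain itself is deterministic; uncertainty enters only through the
inputs.  Each replicate draws every uncertain parameter once — relative
risks (log-normal), schooling effects (normal), prevalences (normal,
truncated to [0, 1]) and the returns-to-schooling rate (normal, floored at
0) — evaluates the chain, and the 95% uncertainty interval (UI) is the
2.5th/97.5th percentile of the replicate outputs (linear interpolation
between order statistics).  The reported point estimate is the chain
evaluated at the parameter point values, not the draw mean.

Effect-size draws are *global*: within a replicate every country sees the
same draw of each relative risk and schooling effect, so that summed totals
have coherent intervals.  Country prevalences and returns rates are drawn
per country.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .country_inputs import CountryRecord
from .effects import EffectRegistry, sample_effect

log = logging.getLogger(__name__)

#: registry fields drawn once per replicate, shared across countries
GLOBAL_PARAMS = (
    "rr_ifa_lbw", "rr_ca_ptb", "rr_bep_lbw",
    "rr_mms_lbw_anemic", "rr_mms_lbw_nonanemic",
    "schooling_lbw", "schooling_ptb",
)


@dataclass(frozen=True)
class UncertainValue:
    """A point estimate with a 95% bootstrap uncertainty interval."""

    point: float
    ui_low: float
    ui_high: float
    n_draws: int

    def __post_init__(self) -> None:
        if self.ui_low > self.ui_high:
            raise ValueError("ui_low must not exceed ui_high")


def percentile_interval(draws: np.ndarray, level: float = 95.0) -> tuple[float, float]:
    """Equal-tailed empirical percentile interval (linear interpolation)."""
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(draws, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def sample_registry(reg: EffectRegistry, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """One array of ``n`` draws per registry effect (replicate-shared)."""
    return {name: np.asarray(sample_effect(getattr(reg, name), rng, size=n)) for name in GLOBAL_PARAMS}


def _trunc_normal01(point: float, se: float, rng: np.random.Generator, n: int) -> np.ndarray:
    if se == 0.0:
        return np.full(n, point)
    return np.clip(rng.normal(point, se, size=n), 0.0, 1.0)


def sample_country(c: CountryRecord, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Per-replicate draws of a country's uncertain inputs.

    Prevalence draws are truncated to [0, 1]; the returns rate is floored at
    0.  Demography (births, survival) and GDP are treated as fixed.  A
    missing birth-outcome prevalence yields NaN draws — impute first.
    """
    out: dict[str, np.ndarray] = {}
    for name, se_name in (
        ("lbw_prev", "lbw_se"), ("ptb_prev", "ptb_se"),
        ("anemia_prev", "anemia_se"), ("underweight_prev", "underweight_se"),
        ("incomplete_secondary_prev", "incomplete_secondary_se"),
    ):
        p = getattr(c, name)
        if p is None:
            out[name] = np.full(n, np.nan)
        else:
            out[name] = _trunc_normal01(p, getattr(c, se_name), rng, n)
    out["ifa_coverage"] = np.full(n, c.ifa_coverage)
    if c.returns_se == 0.0:
        out["returns_rate"] = np.full(n, c.returns_rate)
    else:
        out["returns_rate"] = np.maximum(0.0, rng.normal(c.returns_rate, c.returns_se, size=n))
    return out


def summarize(point: float, draws: np.ndarray, max_bad_frac: float = 0.01) -> UncertainValue:
    """Build an :class:`UncertainValue` from a point and replicate draws.

    Non-finite replicates are excluded with a logged count; more than
    ``max_bad_frac`` of them is an error.
    """
    draws = np.asarray(draws, dtype=float)
    finite = np.isfinite(draws)
    n_bad = int(draws.size - finite.sum())
    if n_bad:
        if n_bad > max_bad_frac * draws.size:
            raise RuntimeError(f"{n_bad}/{draws.size} non-finite bootstrap replicates")
        log.warning("excluded %d/%d non-finite bootstrap replicates", n_bad, draws.size)
        draws = draws[finite]
    lo, hi = percentile_interval(draws)
    return UncertainValue(float(point), lo, hi, int(draws.size))


def propagate(
    model: Callable[[Mapping[str, np.ndarray]], Mapping[str, np.ndarray]],
    point_params: Mapping[str, float],
    sampler: Callable[[np.random.Generator, int], Mapping[str, np.ndarray]],
    n: int = 1000,
    seed: int = 0,
) -> dict[str, UncertainValue]:
    """Propagate uncertainty through an arbitrary deterministic chain.

    ``model`` maps a parameter mapping (scalars or draw arrays) to a mapping
    of named outputs; ``sampler(rng, n)`` supplies ``n`` draws of each
    parameter.  Returns one :class:`UncertainValue` per output.
    """
    if n < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    draws_in = sampler(rng, n)
    draws_out = model(draws_in)
    point_out = model(point_params)
    return {
        name: summarize(float(np.asarray(point_out[name])), np.broadcast_to(np.asarray(arr, dtype=float), (n,)))
        for name, arr in draws_out.items()
    }
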