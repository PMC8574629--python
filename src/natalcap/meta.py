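"""Random-effects meta-analysis (DerSimonian–Laird).

Used in two places: pooling trial effect sizes (e.g. the balanced energy
protein trials) and pooling national prevalence estimates within a region to
impute countries with missing data.  Pooling is delegated to
``statsmodels.stats.meta_analysis.combine_effects`` with the
DerSimonian–Laird moment estimator of the between-study variance τ²:

    τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)),   w = 1/se²

with random-effects weights 1/(se² + τ²) and a normal-approximation 95% CI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.meta_analysis import combine_effects

from .effects import ADDITIVE, RATIO, Z95, EffectEstimate

LOG = "log"
_SCALES = (ADDITIVE, LOG)


@dataclass(frozen=True)
class StudyEstimate:
    """One study's effect on the analysis scale (log-RR or additive)."""

    effect: float
    se: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"study {self.label!r}: se must be strictly positive")


@dataclass(frozen=True)
class PooledResult:
    """Pooled effect with heterogeneity diagnostics, on the analysis scale."""

    effect: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    k: int


def _dl_pool(effects: np.ndarray, ses: np.ndarray) -> PooledResult:
    with warnings.catch_warnings():
        # statsmodels takes sqrt of its unfloored (possibly negative) tau2
        # internally; the floored recomputation below supersedes those values
        warnings.simplefilter("ignore", RuntimeWarning)
        res = combine_effects(effects, ses**2, method_re="dl")
    # statsmodels reports the raw moment estimate, which can go negative for
    # homogeneous studies; DL truncates it at zero
    tau2 = max(0.0, float(res.tau2))
    w_fe = 1.0 / ses**2
    q = float(np.sum(w_fe * (effects - float(np.sum(w_fe * effects) / np.sum(w_fe))) ** 2))
    w_re = 1.0 / (ses**2 + tau2)
    eff = float(np.sum(w_re * effects) / np.sum(w_re))
    se = float(np.sqrt(1.0 / np.sum(w_re)))
    return PooledResult(
        effect=eff,
        se=se,
        ci_low=eff - Z95 * se,
        ci_high=eff + Z95 * se,
        tau2=tau2,
        q=q,
        k=len(effects),
    )


def pool_random_effects(studies: list[StudyEstimate], scale: str = ADDITIVE) -> EffectEstimate:
    """DerSimonian–Laird pool of ≥2 study estimates.

    Parameters
    ----------
    studies
        Study-level effects with strictly positive SEs, all on the same
        analysis scale.
    scale
        ``"additive"`` — effects pooled and returned as-is; ``"log"`` —
        inputs are log relative risks, output is exponentiated to a
        ratio-scale :class:`~natalcap.effects.EffectEstimate`.

    Raises
    ------
    ValueError
        Fewer than two studies; single estimates should be passed through by
        the caller unchanged.
    """
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {_SCALES}")
    if len(studies) < 2:
        raise ValueError("need at least 2 studies to pool; pass a single estimate through unchanged")
    eff = np.array([s.effect for s in studies], dtype=float)
    ses = np.array([s.se for s in studies], dtype=float)
    pooled = _dl_pool(eff, ses)
    if scale == LOG:
        return EffectEstimate(
            math.exp(pooled.effect), math.exp(pooled.ci_low), math.exp(pooled.ci_high),
            scale=RATIO, label=f"DL pool of {pooled.k} studies",
        )
    return EffectEstimate(
        pooled.effect, pooled.ci_low, pooled.ci_high,
        scale=ADDITIVE, label=f"DL pool of {pooled.k} studies",
    )


def pool_details(studies: list[StudyEstimate]) -> PooledResult:
    """Pool on the analysis scale and return heterogeneity diagnostics (τ², Q)."""
    if len(studies) < 2:
        raise ValueError("need at least 2 studies to pool")
    eff = np.array([s.effect for s in studies], dtype=float)
    ses = np.array([s.se for s in studies], dtype=float)
    return _dl_pool(eff, ses)


def read_study_table(path) -> list[StudyEstimate]:
    """Read a study table CSV with columns label, effect, se."""
    df = pd.read_csv(path)
    missing = {"label", "effect", "se"} - set(df.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    return [
        StudyEstimate(float(r.effect), float(r.se), str(r.label))
        for r in df.itertuples(index=False)
    ]
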