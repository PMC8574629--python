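"""Effect-size estimates and the default evidence registry.

Every piece of evidence the model consumes — relative risks of an adverse
birth outcome under an intervention, and the additive schooling deficits
associated with low birthweight (LBW) or preterm birth (PTB) — is carried as
an :class:`EffectEstimate`: a point value with a 95% confidence interval on a
declared scale.  Ratio-scale estimates (relative risks) are handled on the
log scale; additive estimates (years of schooling) on the natural scale.

:class:`EffectRegistry` bundles the default published estimates used by the
scale-up model and can be overridden field-by-field from a run configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace

import numpy as np

#: two-sided 95% normal quantile used throughout for CI <-> SE conversion
Z95 = 1.959964

RATIO = "ratio"
ADDITIVE = "additive"
_SCALES = (RATIO, ADDITIVE)


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate with 95% CI on a declared scale.

    Parameters
    ----------
    point, ci_low, ci_high
        Estimate and confidence bounds, all on the same (natural) scale.
    scale
        ``"ratio"`` for relative risks (log-normal sampling law) or
        ``"additive"`` for effects in years (normal sampling law).
    label
        Free-text description used in logs and reports.
    """

    point: float
    ci_low: float
    ci_high: float
    scale: str = ADDITIVE
    label: str = ""

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"{self.label or 'effect'}: require ci_low <= point <= ci_high, "
                f"got ({self.ci_low}, {self.point}, {self.ci_high})"
            )
        if self.scale == RATIO and self.ci_low <= 0:
            raise ValueError(f"{self.label or 'effect'}: ratio-scale bounds must be positive")
        if not math.isfinite(self.se):
            raise ValueError(f"{self.label or 'effect'}: derived SE is not finite")

    @property
    def se(self) -> float:
        """Standard error on the analysis scale (log scale for ratios)."""
        if self.scale == RATIO:
            return (math.log(self.ci_high) - math.log(self.ci_low)) / (2.0 * Z95)
        return (self.ci_high - self.ci_low) / (2.0 * Z95)

    @classmethod
    def from_se(cls, point: float, se: float, scale: str = ADDITIVE, label: str = "") -> "EffectEstimate":
        """Build an estimate from a point and an analysis-scale SE."""
        if se < 0:
            raise ValueError("se must be non-negative")
        if scale == RATIO:
            lo = math.exp(math.log(point) - Z95 * se)
            hi = math.exp(math.log(point) + Z95 * se)
        else:
            lo, hi = point - Z95 * se, point + Z95 * se
        return cls(point, lo, hi, scale=scale, label=label)


def sample_effect(e: EffectEstimate, rng: np.random.Generator, size: int | None = None):
    """Draw from the sampling law of an effect estimate.

    Ratio-scale estimates are drawn log-normally around ``ln(point)`` with the
    CI-derived log-SE, so draws are strictly positive; additive estimates are
    drawn normally around the point.  A degenerate CI (zero width) returns the
    point itself with a warning.
    """
    se = e.se
    if se == 0.0:
        if e.ci_low == e.ci_high:
            warnings.warn(f"degenerate CI for {e.label or 'effect'}; returning point", stacklevel=2)
        return e.point if size is None else np.full(size, e.point)
    if e.scale == RATIO:
        return np.exp(rng.normal(math.log(e.point), se, size=size))
    return rng.normal(e.point, se, size=size)


@dataclass(frozen=True)
class EffectRegistry:
    """Default evidence base for the four interventions and schooling links.

    Relative risks are intervention-vs-control on the named mediator; the MMS
    risks are stratified by maternal anemia status and are relative to IFA
    (not placebo).  Schooling effects are additive years per affected birth,
    negative meaning fewer years.
    """

    rr_ifa_lbw: EffectEstimate = EffectEstimate(0.84, 0.69, 1.03, RATIO, "IFA vs placebo on LBW")
    rr_ca_ptb: EffectEstimate = EffectEstimate(0.76, 0.60, 0.97, RATIO, "calcium vs placebo on PTB")
    rr_bep_lbw: EffectEstimate = EffectEstimate(0.83, 0.61, 1.12, RATIO, "BEP vs placebo on LBW, underweight women")
    rr_mms_lbw_anemic: EffectEstimate = EffectEstimate(0.81, 0.74, 0.89, RATIO, "MMS vs IFA on LBW, anemic")
    rr_mms_lbw_nonanemic: EffectEstimate = EffectEstimate(0.91, 0.85, 0.98, RATIO, "MMS vs IFA on LBW, non-anemic")
    schooling_lbw: EffectEstimate = EffectEstimate(-0.29, -0.48, -0.10, ADDITIVE, "school years per LBW birth")
    schooling_ptb: EffectEstimate = EffectEstimate(-0.32, -0.57, -0.06, ADDITIVE, "school years per PTB birth")

    @classmethod
    def default(cls) -> "EffectRegistry":
        return cls()

    @classmethod
    def from_dict(cls, overrides: dict) -> "EffectRegistry":
        """Build a registry with selected fields replaced.

        ``overrides`` maps field names to ``{point, ci_low, ci_high}``
        mappings (scale and label inherited from the default field).
        """
        reg = cls()
        valid = {f.name for f in fields(cls)}
        updates = {}
        for name, spec in overrides.items():
            if name not in valid:
                raise KeyError(f"unknown effect registry field {name!r}")
            base: EffectEstimate = getattr(reg, name)
            updates[name] = EffectEstimate(
                float(spec["point"]), float(spec["ci_low"]), float(spec["ci_high"]),
                scale=base.scale, label=base.label,
            )
        return replace(reg, **updates)

    def null_risks(self, keep_se: bool = True) -> "EffectRegistry":
        """Registry with every intervention RR forced to 1 (no effect).

        With ``keep_se`` the log-scale SE of each RR is preserved (CIs become
        symmetric around 1), so bootstrap draws still scatter on both sides of
        the null; otherwise the CIs collapse to the point.
        """
        updates = {}
        for f in fields(self):
            e: EffectEstimate = getattr(self, f.name)
            if e.scale != RATIO:
                continue
            se = e.se if keep_se else 0.0
            updates[f.name] = EffectEstimate.from_se(1.0, se, RATIO, e.label + " (null)")
        return replace(self, **updates)
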