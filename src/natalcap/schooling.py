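"""Schooling gains from reductions in adverse birth outcomes.

A reduction of ``abs_reduction`` prevalence points in low birthweight (or
preterm birth) translates into an expected per-child schooling gain of
``abs_reduction x |effect|`` years, where the effect is the pooled additive
association between the birth outcome and completed school years (entered as
negative years lost).  Population totals scale by the 5-year birth-cohort
size and survival to age 25 (secondary completion is often delayed).

Additional secondary-school completers follow the marginal-grade rule: under
a 12-year system only pupils in the penultimate secondary grade (grade 11)
can cross the completion threshold from a marginal attendance gain, and
students are assumed uniformly distributed over the secondary grades, so a
``grade11_fraction`` (default 1/6 for a six-grade secondary phase) of the
incomplete-secondary population is eligible.
"""

from __future__ import annotations

import numpy as np


def school_years_per_child(abs_reduction, effect_years):
    """Expected school-year gain per live birth.

    ``effect_years`` is the additive schooling effect of the birth outcome
    (negative = years lost); the gain is its magnitude times the prevalence
    reduction.
    """
    if np.any(np.asarray(abs_reduction) < -1) or np.any(np.asarray(abs_reduction) > 1):
        raise ValueError("abs_reduction must be within [-1, 1] prevalence points")
    # sign conventions: a negative reduction (harmful draw) yields a negative
    # gain; the effect's magnitude is used so callers may pass years lost.
    return abs_reduction * np.abs(effect_years)


def total_school_years(per_child, births, surv25):
    """Cohort-level school years: per-child gain x births x survival to 25."""
    return per_child * births * surv25


def secondary_completers(per_child, incomplete_secondary_prev, births, surv25,
                         grade11_fraction: float = 1.0 / 6.0):
    """Additional youths completing secondary school per cohort."""
    if not (0.0 <= grade11_fraction <= 1.0):
        raise ValueError("grade11_fraction must be in [0, 1]")
    return births * surv25 * incomplete_secondary_prev * grade11_fraction * per_child
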