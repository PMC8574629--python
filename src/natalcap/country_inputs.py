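"""Country-level data model: reading, validation, and regional imputation.

One :class:`CountryRecord` holds everything the scale-up model needs about a
country: birth-outcome prevalences (low birthweight, preterm birth), maternal
anemia and underweight prevalence, current iron–folic acid (IFA) coverage,
the 5-year birth-cohort size, survival probabilities, income parameters, and
a region label from the six GBD super-regions.  Every prevalence carries a
standard error; inputs supplied as 95% CIs are normalised to SEs at read time
(half-width / 1.959964).

Countries missing a birth-outcome prevalence are flagged (never dropped) and
can be imputed with the region's random-effects pooled prevalence.  Pooling
is on the logit scale so the imputed value is always a valid proportion.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import meta
from .effects import Z95

log = logging.getLogger(__name__)

#: the six GBD super-region labels used for aggregation and imputation
REGIONS = (
    "Central Europe, Eastern Europe, and Central Asia",
    "Latin America and Caribbean",
    "North Africa and Middle East",
    "South Asia",
    "Sub-Saharan Africa",
    "Southeast Asia, East Asia, and Oceania",
)

WORK_AGES = tuple(range(20, 60))

# prevalence-type fields: (name, se-field, may be missing)
_PREV_FIELDS = (
    ("lbw_prev", "lbw_se", True),
    ("ptb_prev", "ptb_se", True),
    ("anemia_prev", "anemia_se", False),
    ("underweight_prev", "underweight_se", False),
    ("ifa_coverage", "ifa_coverage_se", False),
    ("incomplete_secondary_prev", "incomplete_secondary_se", False),
)


class CountryTableError(ValueError):
    """Raised for malformed or out-of-bounds rows in a country table."""


@dataclass
class CountryRecord:
    """Validated inputs for one country.

    ``surv_age`` holds cumulative survival from birth to each integer working
    age 20–59 (40 entries); ``gdp_pc`` is GDP per capita in 2010 constant
    USD; ``returns_rate`` is the proportional income gain per additional
    school year.  Missing birth-outcome prevalences are ``None`` with a flag
    in :attr:`flags` (``missing_lbw`` / ``missing_ptb``).
    """

    country_id: str
    region: str
    lbw_prev: float | None
    lbw_se: float
    ptb_prev: float | None
    ptb_se: float
    anemia_prev: float
    anemia_se: float
    underweight_prev: float
    underweight_se: float
    ifa_coverage: float
    ifa_coverage_se: float
    incomplete_secondary_prev: float
    incomplete_secondary_se: float
    births: float
    surv_to_25: float
    surv_age: np.ndarray
    gdp_pc: float
    ppp_factor: float
    returns_rate: float
    returns_se: float
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.surv_age = np.asarray(self.surv_age, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise CountryTableError(f"{self.country_id}: unknown region {self.region!r}")
        for name, _, optional in _PREV_FIELDS:
            v = getattr(self, name)
            if v is None:
                if not optional:
                    raise CountryTableError(f"{self.country_id}: {name} may not be missing")
                continue
            if not (0.0 <= v <= 1.0):
                raise CountryTableError(f"{self.country_id}: {name}={v} outside [0, 1]")
        if not (0.0 <= self.surv_to_25 <= 1.0):
            raise CountryTableError(f"{self.country_id}: surv_to_25 outside [0, 1]")
        if self.births < 0:
            raise CountryTableError(f"{self.country_id}: births must be >= 0")
        if self.gdp_pc < 0:
            raise CountryTableError(f"{self.country_id}: gdp_pc must be >= 0")
        if self.returns_rate < 0:
            raise CountryTableError(f"{self.country_id}: returns_rate must be >= 0")
        if self.ppp_factor <= 0:
            raise CountryTableError(f"{self.country_id}: ppp_factor must be positive")
        if self.surv_age.shape != (len(WORK_AGES),):
            raise CountryTableError(
                f"{self.country_id}: surv_age needs {len(WORK_AGES)} entries (ages 20-59)"
            )
        if np.any((self.surv_age < 0) | (self.surv_age > 1)):
            raise CountryTableError(f"{self.country_id}: surv_age entries outside [0, 1]")
        if np.any(np.diff(self.surv_age) > 1e-12):
            raise CountryTableError(f"{self.country_id}: cumulative survival must be non-increasing in age")

    @property
    def missing_lbw(self) -> bool:
        return "missing_lbw" in self.flags

    @property
    def missing_ptb(self) -> bool:
        return "missing_ptb" in self.flags


_SURV_COLS = [f"surv_{a}" for a in WORK_AGES]

_SCALAR_COLS = [
    "country_id", "region",
    "lbw_prev", "lbw_se", "ptb_prev", "ptb_se",
    "anemia_prev", "anemia_se", "underweight_prev", "underweight_se",
    "ifa_coverage", "ifa_coverage_se",
    "incomplete_secondary_prev", "incomplete_secondary_se",
    "births", "surv_to_25", "gdp_pc", "ppp_factor",
    "returns_rate", "returns_se",
]


def _num(row, col, row_idx, *, optional=False):
    raw = row.get(col)
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or (isinstance(raw, str) and raw.strip() == ""):
        if optional:
            return None
        raise CountryTableError(f"row {row_idx}: missing required value in column {col!r}")
    try:
        return float(raw)
    except (TypeError, ValueError) as exc:
        raise CountryTableError(f"row {row_idx}: malformed numeric cell {raw!r} in column {col!r}") from exc


def _se_for(row, base, se_col, row_idx, point):
    """SE from an SE column, or from 95% CI columns, normalised to SE."""
    if se_col in row and not pd.isna(row.get(se_col)):
        se = _num(row, se_col, row_idx)
    elif f"{base}_ci_low" in row and f"{base}_ci_high" in row:
        lo = _num(row, f"{base}_ci_low", row_idx)
        hi = _num(row, f"{base}_ci_high", row_idx)
        if hi < lo:
            raise CountryTableError(f"row {row_idx}: {base} CI bounds reversed")
        se = (hi - lo) / (2.0 * Z95)
    elif point is None:
        return float("nan")
    else:
        se = 0.0
    if se < 0:
        raise CountryTableError(f"row {row_idx}: negative SE for {base}")
    return se


def read_country_table(
    path,
    column_map: dict[str, str] | None = None,
    default_ifa_coverage: float = 0.0,
) -> list[CountryRecord]:
    """Read and validate a country table CSV into :class:`CountryRecord` s.

    ``column_map`` maps canonical column names to the names actually present
    in the file.  Rows with a missing LBW or PTB prevalence are flagged, not
    dropped.  Countries without IFA coverage data are assigned
    ``default_ifa_coverage`` (0 by default) with a logged warning.
    """
    df = pd.read_csv(path, dtype=str)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    required = {"country_id", "region", "anemia_prev", "underweight_prev",
                "incomplete_secondary_prev", "births", "surv_to_25", "gdp_pc",
                "ppp_factor", "returns_rate"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise CountryTableError(f"country table missing columns: {sorted(missing_cols)}")
    missing_surv = [c for c in _SURV_COLS if c not in df.columns]
    if missing_surv:
        raise CountryTableError(f"country table missing survival columns: {missing_surv[:3]}...")

    records: list[CountryRecord] = []
    n_flagged = 0
    for i, row in enumerate(df.to_dict("records")):
        flags: set[str] = set()
        lbw = _num(row, "lbw_prev", i, optional=True)
        ptb = _num(row, "ptb_prev", i, optional=True)
        if lbw is None:
            flags.add("missing_lbw")
        if ptb is None:
            flags.add("missing_ptb")
        ifa_raw = _num(row, "ifa_coverage", i, optional=True)
        if ifa_raw is None:
            log.warning("row %d (%s): no IFA coverage; defaulting to %.3f",
                        i, row.get("country_id"), default_ifa_coverage)
            ifa_raw = default_ifa_coverage
            flags.add("default_ifa")
        rec = CountryRecord(
            country_id=str(row["country_id"]),
            region=str(row["region"]),
            lbw_prev=lbw, lbw_se=_se_for(row, "lbw", "lbw_se", i, lbw),
            ptb_prev=ptb, ptb_se=_se_for(row, "ptb", "ptb_se", i, ptb),
            anemia_prev=_num(row, "anemia_prev", i),
            anemia_se=_se_for(row, "anemia", "anemia_se", i, 0.0),
            underweight_prev=_num(row, "underweight_prev", i),
            underweight_se=_se_for(row, "underweight", "underweight_se", i, 0.0),
            ifa_coverage=ifa_raw,
            ifa_coverage_se=_se_for(row, "ifa_coverage", "ifa_coverage_se", i, 0.0),
            incomplete_secondary_prev=_num(row, "incomplete_secondary_prev", i),
            incomplete_secondary_se=_se_for(row, "incomplete_secondary", "incomplete_secondary_se", i, 0.0),
            births=_num(row, "births", i),
            surv_to_25=_num(row, "surv_to_25", i),
            surv_age=np.array([_num(row, c, i) for c in _SURV_COLS]),
            gdp_pc=_num(row, "gdp_pc", i),
            ppp_factor=_num(row, "ppp_factor", i),
            returns_rate=_num(row, "returns_rate", i),
            returns_se=_se_for(row, "returns", "returns_se", i, 0.0),
            flags=flags,
        )
        n_flagged += bool(flags & {"missing_lbw", "missing_ptb"})
        records.append(rec)
    log.info("parsed %d countries from %s (%d flagged with missing birth-outcome prevalence)",
             len(records), path, n_flagged)
    return records


def write_country_table(records: list[CountryRecord], path) -> None:
    """Write records to the canonical CSV layout (round-trips exactly)."""
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in _SCALAR_COLS}
        d.update({c: s for c, s in zip(_SURV_COLS, r.surv_age)})
        rows.append(d)
    pd.DataFrame(rows, columns=_SCALAR_COLS + _SURV_COLS).to_csv(path, index=False)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def impute_regional_prevalence(
    records: list[CountryRecord],
    prev_field: str,
    fallback_global: bool = False,
) -> list[CountryRecord]:
    """Fill missing prevalences with the region's random-effects pool.

    Pooling is on the logit scale (delta-method SEs), so the pooled value is
    guaranteed to be a valid proportion, and lies within the range of the
    region's observed values.  Imputed records carry the pooled SE
    (back-transformed) and gain an ``imputed_<field>`` flag; all other
    records are returned unchanged.

    A region whose missing countries cannot be pooled (fewer than two
    informative countries) raises unless ``fallback_global`` is set, in which
    case the pool over all informative countries is used.
    """
    if prev_field not in ("lbw_prev", "ptb_prev"):
        raise ValueError("imputation supports lbw_prev and ptb_prev")
    se_field = {"lbw_prev": "lbw_se", "ptb_prev": "ptb_se"}[prev_field]
    short = prev_field.split("_")[0]

    def studies_of(recs):
        out = []
        for r in recs:
            p = getattr(r, prev_field)
            if p is None:
                continue
            p = min(max(p, 1e-9), 1 - 1e-9)
            se_p = getattr(r, se_field)
            se_l = max(se_p, 1e-9) / (p * (1.0 - p))
            out.append(meta.StudyEstimate(_logit(p), se_l, r.country_id))
        return out

    global_studies = studies_of(records)
    out: list[CountryRecord] = []
    for r in records:
        if getattr(r, prev_field) is not None:
            out.append(r)
            continue
        regional = studies_of([x for x in records if x.region == r.region])
        if len(regional) < 2:
            if not fallback_global:
                raise ValueError(
                    f"region {r.region!r} has {len(regional)} informative countries for "
                    f"{prev_field}; set fallback_global=True to pool across all regions"
                )
            regional = global_studies
        pooled = meta.pool_details(regional)
        p_hat = _expit(pooled.effect)
        se_hat = pooled.se * p_hat * (1.0 - p_hat)
        r2 = dataclasses.replace(
            r,
            **{prev_field: p_hat, se_field: se_hat},
            flags=(r.flags - {f"missing_{short}"}) | {f"imputed_{short}"},
        )
        log.info("imputed %s for %s from %d countries in %s: %.4f (SE %.4f)",
                 prev_field, r.country_id, pooled.k, r.region, p_hat, se_hat)
        out.append(r2)
    return out
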