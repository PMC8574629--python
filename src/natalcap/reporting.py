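"""Pipeline driver, per-replicate aggregation, and formatted tables.

``run_scenarios`` evaluates the full deterministic chain — coverage
scale-up → PAF → absolute birth-outcome reduction → school years →
secondary completers → lifetime-income NPV — for every country and
scenario, once at parameter point values and once per bootstrap replicate.
Replicates share effect-size draws across countries, so regional and
all-country totals are aggregated *per replicate* (sum the draws, then take
percentiles), never by summing interval endpoints.

Headline units follow convention: school years and completers in thousands,
income in USD billions, per-child income in USD — applied only at the
formatting layer; everything internal is in natural units.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import schooling
from .country_inputs import (REGIONS, CountryRecord, impute_regional_prevalence,
                             read_country_table, write_country_table)
from .effects import EffectRegistry
from .income import EconConfig, income_gain, npv_lifetime_income
from .paf_engine import (MEDIATOR, ScenarioConfig, bep_kernel, calcium_kernel,
                         ifa_kernel, mms_kernel)
from .synthetic_data import WorldSpec, generate_world
from .uncertainty import sample_country, sample_registry, summarize

log = logging.getLogger(__name__)

QUANTITIES = ("paf", "abs_reduction", "years_per_child", "total_years",
              "completers", "total_income", "income_per_child")
#: quantities that add across countries (per-child income is a ratio of sums)
SUMMABLE = ("total_years", "completers", "total_income")

DEFAULT_TARGETS: dict[str, tuple[float, ...]] = {
    "IFA": (0.9,),
    "CALCIUM": (0.5, 0.9),
    "MMS": (0.5, 0.9),
    "BEP": (0.5, 0.9),
}

ALL_LABEL = "ALL"


def country_chain(params: Mapping[str, object], scenario: ScenarioConfig,
                  births: float, surv25: float, npv_base: float) -> dict[str, object]:
    """Evaluate the whole chain for one country at scalar or array parameters."""
    iv = scenario.intervention
    t = scenario.target_coverage
    if iv == "IFA":
        paf, absr, targ = ifa_kernel(params["rr_ifa_lbw"], params["ifa_coverage"], params["lbw_prev"], t)
    elif iv == "CALCIUM":
        paf, absr, targ = calcium_kernel(params["rr_ca_ptb"], params["ptb_prev"], t)
    elif iv == "BEP":
        paf, absr, targ = bep_kernel(params["rr_bep_lbw"], params["underweight_prev"], params["lbw_prev"], t)
    else:
        paf, absr, targ = mms_kernel(
            params["rr_mms_lbw_anemic"], params["rr_mms_lbw_nonanemic"], params["rr_ifa_lbw"],
            params["anemia_prev"], params["ifa_coverage"], params["lbw_prev"], t,
        )
    effect = params["schooling_ptb"] if MEDIATOR[iv] == "PTB" else params["schooling_lbw"]
    per_child = schooling.school_years_per_child(absr, effect)
    total_years = schooling.total_school_years(per_child, births, surv25)
    completers = schooling.secondary_completers(
        per_child, params["incomplete_secondary_prev"], births, surv25, scenario.grade11_fraction)
    total_income = income_gain(total_years, params["returns_rate"], npv_base)
    targeted_births = births * np.asarray(targ, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ipc = np.where(targeted_births > 0, total_income / targeted_births, np.nan)
    return {
        "paf": paf, "abs_reduction": absr, "years_per_child": per_child,
        "total_years": total_years, "completers": completers,
        "total_income": total_income, "income_per_child": ipc,
        "targeted_births": targeted_births,
    }


@dataclass
class ScenarioRun:
    """Point estimates and bootstrap draws for one scenario over all countries."""

    scenario: ScenarioConfig
    country_ids: list[str]
    regions: list[str]
    points: dict[str, np.ndarray]   # quantity -> (n_countries,)
    draws: dict[str, np.ndarray]    # quantity -> (n_countries, n_boot)

    @property
    def n_boot(self) -> int:
        return self.draws["total_years"].shape[1]


def _point_params(reg: EffectRegistry, c: CountryRecord) -> dict[str, float]:
    p = {name: getattr(reg, name).point for name in (
        "rr_ifa_lbw", "rr_ca_ptb", "rr_bep_lbw", "rr_mms_lbw_anemic",
        "rr_mms_lbw_nonanemic", "schooling_lbw", "schooling_ptb")}
    p.update(
        lbw_prev=np.nan if c.lbw_prev is None else c.lbw_prev,
        ptb_prev=np.nan if c.ptb_prev is None else c.ptb_prev,
        anemia_prev=c.anemia_prev, underweight_prev=c.underweight_prev,
        ifa_coverage=c.ifa_coverage,
        incomplete_secondary_prev=c.incomplete_secondary_prev,
        returns_rate=c.returns_rate,
    )
    return p


def run_scenarios(
    records: list[CountryRecord],
    registry: EffectRegistry,
    scenarios: list[ScenarioConfig],
    n_boot: int = 1000,
    seed: int = 0,
) -> list[ScenarioRun]:
    """Evaluate all scenarios on all countries with shared parameter draws.

    All uncertain parameters are drawn once up front (effect sizes globally,
    country inputs per country), then reused across scenarios, so scenario
    outputs are coherent within a replicate and the draw stream does not
    depend on which scenarios are requested.
    """
    if not records:
        raise ValueError("no country records")
    needed = {MEDIATOR[s.intervention] for s in scenarios}
    for c in records:
        if "LBW" in needed and c.lbw_prev is None:
            raise ValueError(f"{c.country_id}: LBW prevalence missing; impute before running")
        if "PTB" in needed and c.ptb_prev is None:
            raise ValueError(f"{c.country_id}: PTB prevalence missing; impute before running")

    rng = np.random.default_rng(seed)
    global_draws = sample_registry(registry, rng, n_boot)
    country_draws = [sample_country(c, rng, n_boot) for c in records]

    runs: list[ScenarioRun] = []
    for scen in scenarios:
        pts = {q: np.empty(len(records)) for q in QUANTITIES + ("targeted_births",)}
        drw = {q: np.empty((len(records), n_boot)) for q in QUANTITIES + ("targeted_births",)}
        for i, c in enumerate(records):
            npv_base = npv_lifetime_income(c.gdp_pc, c.surv_age, scen.econ, c.ppp_factor)
            out_p = country_chain(_point_params(registry, c), scen, c.births, c.surv_to_25, npv_base)
            out_d = country_chain({**global_draws, **country_draws[i]}, scen, c.births, c.surv_to_25, npv_base)
            for q in pts:
                pts[q][i] = float(np.asarray(out_p[q]))
                drw[q][i] = np.broadcast_to(np.asarray(out_d[q], dtype=float), (n_boot,))
        runs.append(ScenarioRun(
            scenario=scen,
            country_ids=[c.country_id for c in records],
            regions=[c.region for c in records],
            points=pts, draws=drw,
        ))
    return runs


def _summary_row(base: dict, quantity: str, point: float, draws: np.ndarray) -> dict:
    if not np.isfinite(point) and not np.any(np.isfinite(draws)):
        return {**base, "quantity": quantity, "point": np.nan,
                "ui_low": np.nan, "ui_high": np.nan, "n_draws": 0}
    uv = summarize(point, draws)
    return {**base, "quantity": quantity, "point": uv.point,
            "ui_low": uv.ui_low, "ui_high": uv.ui_high, "n_draws": uv.n_draws}


def country_results(run: ScenarioRun) -> pd.DataFrame:
    """Tidy per-country results: one row per (country, quantity) with UI."""
    rows = []
    for i, cid in enumerate(run.country_ids):
        base = {"country_id": cid, "region": run.regions[i],
                "intervention": run.scenario.intervention,
                "target_coverage": run.scenario.target_coverage}
        for q in QUANTITIES:
            rows.append(_summary_row(base, q, run.points[q][i], run.draws[q][i]))
    return pd.DataFrame(rows)


def aggregate(run: ScenarioRun, level: str = "region") -> pd.DataFrame:
    """Regional (and all-country) totals with per-replicate UIs.

    ``level`` is ``"region"`` (six region rows plus an ALL row) or ``"all"``
    (the ALL row only).  Totals are sums over member countries; per-child
    income is total income over total targeted births, computed replicate by
    replicate.
    """
    if level not in ("region", "all"):
        raise ValueError("level must be 'region' or 'all'")
    regions = np.asarray(run.regions)
    unknown = set(regions) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown region labels: {sorted(unknown)}")
    groups = [(ALL_LABEL, np.ones(len(regions), dtype=bool))]
    if level == "region":
        groups = [(reg, regions == reg) for reg in REGIONS if np.any(regions == reg)] + groups
    rows = []
    for name, mask in groups:
        base = {"intervention": run.scenario.intervention,
                "target_coverage": run.scenario.target_coverage, "region": name}
        for q in SUMMABLE:
            rows.append(_summary_row(base, q, float(run.points[q][mask].sum(axis=0)),
                                     run.draws[q][mask].sum(axis=0)))
        tb_p = run.points["targeted_births"][mask].sum()
        tb_d = run.draws["targeted_births"][mask].sum(axis=0)
        inc_p = run.points["total_income"][mask].sum()
        inc_d = run.draws["total_income"][mask].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ipc_p = inc_p / tb_p if tb_p > 0 else np.nan
            ipc_d = np.where(tb_d > 0, inc_d / tb_d, np.nan)
        rows.append(_summary_row(base, "income_per_child", ipc_p, ipc_d))
    return pd.DataFrame(rows)


#: display scaling for headline tables: (divisor, printed unit)
DISPLAY_UNITS = {
    "total_years": (1e3, "school years (thousands)"),
    "completers": (1e3, "secondary completers (thousands)"),
    "total_income": (1e9, "lifetime income (USD billions)"),
    "income_per_child": (1.0, "income per targeted child (USD)"),
}


def format_aggregates(agg: pd.DataFrame) -> pd.DataFrame:
    """Apply display units and render `point (ui_low, ui_high)` strings."""
    df = agg[agg["quantity"].isin(DISPLAY_UNITS)].copy()
    scale = df["quantity"].map({k: v[0] for k, v in DISPLAY_UNITS.items()})
    for col in ("point", "ui_low", "ui_high"):
        df[col] = df[col] / scale
    df["quantity"] = df["quantity"].map({k: v[1] for k, v in DISPLAY_UNITS.items()})
    df["display"] = [
        f"{p:.3g} ({lo:.3g}, {hi:.3g})"
        for p, lo, hi in zip(df["point"], df["ui_low"], df["ui_high"])
    ]
    return df


def plot_per_child_income(agg: pd.DataFrame, path) -> None:
    """Bar chart of per-child income gains by intervention and region."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = agg[agg["quantity"] == "income_per_child"]
    fig, ax = plt.subplots(figsize=(9, 5))
    interventions = sorted(df["intervention"].unique())
    region_order = [r for r in REGIONS if r in set(df["region"])] + [ALL_LABEL]
    width = 0.8 / max(len(interventions), 1)
    for k, iv in enumerate(interventions):
        sub = df[df["intervention"] == iv].set_index("region").reindex(region_order)
        x = np.arange(len(region_order)) + k * width
        ax.bar(x, sub["point"], width=width, label=iv,
               yerr=[sub["point"] - sub["ui_low"], sub["ui_high"] - sub["point"]], capsize=2)
    ax.set_xticks(np.arange(len(region_order)) + 0.4 - width / 2)
    ax.set_xticklabels([r.split(",")[0] for r in region_order], rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("income gain per targeted child (USD)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# -- configuration and end-to-end driver -------------------------------------

DEFAULT_CONFIG: dict = {
    "input": None,                      # path to a country CSV; None -> synthetic
    "synthetic": {"n_countries": 132, "seed": 2015, "missingness": 0.05},
    "interventions": ["IFA", "CALCIUM", "MMS", "BEP"],
    "targets": {k: list(v) for k, v in DEFAULT_TARGETS.items()},
    "n_boot": 1000,
    "seed": 1,
    "ppp": False,
    "grade11_fraction": 1.0 / 6.0,
    "econ": {},                         # EconConfig overrides
    "effects": {},                      # EffectRegistry overrides
    "default_ifa_coverage": 0.0,
    "outdir": "natalcap_out",
}


def load_config(path_or_dict) -> dict:
    """Merge a YAML/JSON config file (or dict) over the defaults."""
    if path_or_dict is None:
        user = {}
    elif isinstance(path_or_dict, Mapping):
        user = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **user}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _load_records(cfg: dict) -> tuple[list[CountryRecord], str]:
    if cfg["input"]:
        data = Path(cfg["input"]).read_bytes()
        digest = hashlib.sha256(data).hexdigest()
        return read_country_table(cfg["input"], default_ifa_coverage=cfg["default_ifa_coverage"]), digest
    spec = WorldSpec(**cfg["synthetic"])
    records, _ = generate_world(spec)
    digest = hashlib.sha256(repr(spec).encode()).hexdigest()
    return records, digest


def build_scenarios(cfg: dict) -> list[ScenarioConfig]:
    econ_kwargs = dict(cfg["econ"])
    econ_kwargs.setdefault("ppp", bool(cfg["ppp"]))
    econ = EconConfig(**econ_kwargs)
    scens = []
    for iv in cfg["interventions"]:
        if iv.upper() not in DEFAULT_TARGETS:
            raise ValueError(f"unknown intervention {iv!r}; expected one of {sorted(DEFAULT_TARGETS)}")
        for t in cfg["targets"].get(iv.upper(), DEFAULT_TARGETS[iv.upper()]):
            scens.append(ScenarioConfig(
                intervention=iv, target_coverage=float(t), ppp=bool(cfg["ppp"]),
                grade11_fraction=float(cfg["grade11_fraction"]), econ=econ,
                n_boot=int(cfg["n_boot"]), seed=int(cfg["seed"]),
            ))
    return scens


def run_pipeline(config=None, outdir=None) -> Path:
    """End-to-end run: load or simulate inputs, impute, propagate, write outputs.

    Writes ``countries.csv`` (validated canonical inputs),
    ``country_results.csv``, ``aggregates.csv`` and ``run_log.txt`` into the
    output directory, which is returned.
    """
    cfg = load_config(config)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)

    records, digest = _load_records(cfg)
    n_missing = sum(bool(c.flags & {"missing_lbw", "missing_ptb"}) for c in records)
    records = impute_regional_prevalence(records, "lbw_prev", fallback_global=True)
    records = impute_regional_prevalence(records, "ptb_prev", fallback_global=True)

    registry = EffectRegistry.from_dict(cfg["effects"]) if cfg["effects"] else EffectRegistry.default()
    scenarios = build_scenarios(cfg)
    runs = run_scenarios(records, registry, scenarios, n_boot=int(cfg["n_boot"]), seed=int(cfg["seed"]))

    write_country_table(records, out / "countries.csv")
    pd.concat([country_results(r) for r in runs], ignore_index=True).to_csv(
        out / "country_results.csv", index=False)
    pd.concat([aggregate(r) for r in runs], ignore_index=True).to_csv(
        out / "aggregates.csv", index=False)

    with open(out / "run_log.txt", "w") as fh:
        fh.write("natalcap pipeline run\n")
        fh.write(f"input sha256: {digest}\n")
        fh.write(f"countries: {len(records)} ({n_missing} had missing birth-outcome prevalence, imputed)\n")
        fh.write(f"scenarios: {[(s.intervention, s.target_coverage) for s in scenarios]}\n")
        fh.write("config:\n")
        fh.write(json.dumps(cfg, indent=2, default=str))
        fh.write("\n")
    log.info("pipeline outputs written to %s", out)
    return out
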