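"""Pipeline driver, per-replicate aggregation, and the CLI surface."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from conftest import make_record
from natalcap.cli import main as cli_main
from natalcap.country_inputs import REGIONS
from natalcap.effects import EffectRegistry
from natalcap.paf_engine import ScenarioConfig
from natalcap.reporting import (ALL_LABEL, aggregate, country_results,
                                format_aggregates, load_config, run_pipeline,
                                run_scenarios)


def two_country_run(n_boot=200, seed=0):
    recs = [make_record(country_id="A", region=REGIONS[3]),
            make_record(country_id="B", region=REGIONS[4])]
    return run_scenarios(recs, EffectRegistry.default(),
                         [ScenarioConfig("CALCIUM", 0.9)], n_boot=n_boot, seed=seed)[0]


class TestAggregate:
    def test_single_country_region_row_equals_country_row(self):
        recs = [make_record(country_id="A", region=REGIONS[3])]
        run = run_scenarios(recs, EffectRegistry.default(),
                            [ScenarioConfig("MMS", 0.9)], n_boot=100, seed=1)[0]
        agg = aggregate(run)
        row = agg[(agg.region == REGIONS[3]) & (agg.quantity == "total_years")].iloc[0]
        assert row.point == pytest.approx(run.points["total_years"][0])
        all_row = agg[(agg.region == ALL_LABEL) & (agg.quantity == "total_years")].iloc[0]
        assert all_row.point == row.point

    def test_two_equal_countries_double_the_total(self):
        run = two_country_run()
        agg = aggregate(run)
        total = agg[(agg.region == ALL_LABEL) & (agg.quantity == "total_income")].iloc[0]
        assert total.point == pytest.approx(2 * run.points["total_income"][0])

    def test_all_row_equals_sum_of_region_rows(self):
        from natalcap.synthetic_data import WorldSpec, generate_world
        records, truth = generate_world(WorldSpec(n_countries=60, seed=8, missingness=0.0))
        run = run_scenarios(records, truth.registry, [ScenarioConfig("CALCIUM", 0.5)],
                            n_boot=50, seed=2)[0]
        agg = aggregate(run)
        for q in ("total_years", "completers", "total_income"):
            sub = agg[agg.quantity == q]
            regions_sum = sub[sub.region != ALL_LABEL].point.sum()
            assert sub[sub.region == ALL_LABEL].point.iloc[0] == pytest.approx(regions_sum, rel=1e-12)

    def test_interval_is_per_replicate_not_endpoint_sum(self):
        """Summed-draw UI of A+B is no wider than the sum of the endpoint
        widths and equals the percentile of the summed replicate draws."""
        run = two_country_run()
        agg = aggregate(run)
        total = agg[(agg.region == ALL_LABEL) & (agg.quantity == "total_years")].iloc[0]
        draws_sum = run.draws["total_years"].sum(axis=0)
        lo, hi = np.percentile(draws_sum, [2.5, 97.5])
        assert total.ui_low == pytest.approx(lo)
        assert total.ui_high == pytest.approx(hi)
        per_country = country_results(run)
        widths = per_country[per_country.quantity == "total_years"]
        endpoint_width = (widths.ui_high - widths.ui_low).sum()
        assert (total.ui_high - total.ui_low) <= endpoint_width + 1e-9

    def test_unknown_region_rejected(self):
        run = two_country_run(n_boot=50)
        run.regions[0] = "Atlantis"
        with pytest.raises(ValueError, match="unknown region"):
            aggregate(run)


class TestPipeline:
    def test_run_pipeline_writes_outputs_and_is_deterministic(self, tmp_path):
        cfg = {"synthetic": {"n_countries": 20, "seed": 3, "missingness": 0.1},
               "interventions": ["CALCIUM"], "targets": {"CALCIUM": [0.5, 0.9]},
               "n_boot": 100, "seed": 7}
        out1 = run_pipeline(cfg, outdir=tmp_path / "r1")
        out2 = run_pipeline(cfg, outdir=tmp_path / "r2")
        for name in ("countries.csv", "country_results.csv", "aggregates.csv", "run_log.txt"):
            assert (out1 / name).exists()
        assert (out1 / "aggregates.csv").read_bytes() == (out2 / "aggregates.csv").read_bytes()
        agg = pd.read_csv(out1 / "aggregates.csv")
        years = agg[(agg.region == ALL_LABEL) & (agg.quantity == "total_years")]
        v50 = years[years.target_coverage == 0.5].point.iloc[0]
        v90 = years[years.target_coverage == 0.9].point.iloc[0]
        assert v90 == pytest.approx(1.8 * v50, rel=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="unknown config"):
            load_config({"bogus_key": 1})
        with pytest.raises(ValueError, match="unknown intervention"):
            run_pipeline({"interventions": ["ZINC"], "synthetic": {"n_countries": 5, "seed": 1}})

    def test_effect_overrides_flow_through(self, tmp_path):
        base = {"synthetic": {"n_countries": 8, "seed": 5, "missingness": 0.0},
                "interventions": ["CALCIUM"], "targets": {"CALCIUM": [0.9]},
                "n_boot": 60, "seed": 2}
        strong = {**base, "effects": {"rr_ca_ptb": {"point": 0.5, "ci_low": 0.4, "ci_high": 0.6}}}
        a1 = pd.read_csv(run_pipeline(base, outdir=tmp_path / "a") / "aggregates.csv")
        a2 = pd.read_csv(run_pipeline(strong, outdir=tmp_path / "b") / "aggregates.csv")
        y1 = a1[(a1.region == ALL_LABEL) & (a1.quantity == "total_years")].point.iloc[0]
        y2 = a2[(a2.region == ALL_LABEL) & (a2.quantity == "total_years")].point.iloc[0]
        assert y2 > y1  # RR 0.5 beats RR 0.76

    def test_ppp_scales_income_only(self, tmp_path):
        base = {"synthetic": {"n_countries": 6, "seed": 9, "missingness": 0.0},
                "interventions": ["MMS"], "targets": {"MMS": [0.9]}, "n_boot": 60, "seed": 2}
        nom = pd.read_csv(run_pipeline(base, outdir=tmp_path / "nom") / "aggregates.csv")
        ppp = pd.read_csv(run_pipeline({**base, "ppp": True}, outdir=tmp_path / "ppp") / "aggregates.csv")
        years_n = nom[(nom.region == ALL_LABEL) & (nom.quantity == "total_years")].point.iloc[0]
        years_p = ppp[(ppp.region == ALL_LABEL) & (ppp.quantity == "total_years")].point.iloc[0]
        inc_n = nom[(nom.region == ALL_LABEL) & (nom.quantity == "total_income")].point.iloc[0]
        inc_p = ppp[(ppp.region == ALL_LABEL) & (ppp.quantity == "total_income")].point.iloc[0]
        assert years_p == pytest.approx(years_n, rel=1e-12)  # schooling unaffected
        assert inc_p > inc_n                                  # PPP factors > 1


class TestFormattingAndCli:
    def test_display_units(self):
        run = two_country_run(n_boot=50)
        df = format_aggregates(aggregate(run))
        raw = aggregate(run)
        raw_total = raw[(raw.region == ALL_LABEL) & (raw.quantity == "total_income")].point.iloc[0]
        disp = df[(df.region == ALL_LABEL) & (df.quantity.str.contains("billions"))].point.iloc[0]
        assert disp == pytest.approx(raw_total / 1e9)

    def test_cli_simulate_run_report(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["simulate", "--out", str(tmp_path / "world"),
                                     "--n", "12", "--seed", "2"])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "world" / "countries.csv").exists()
        assert (tmp_path / "world" / "truth.csv").exists()

        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "input: {}\ninterventions: [CALCIUM]\n"
            "targets: {{CALCIUM: [0.9]}}\nn_boot: 50\nseed: 3\n".format(
                tmp_path / "world" / "countries.csv"))
        r = runner.invoke(cli_main, ["run", "--config", str(cfg), "--out", str(tmp_path / "res")])
        assert r.exit_code == 0, r.output

        r = runner.invoke(cli_main, ["report", "--aggregates", str(tmp_path / "res" / "aggregates.csv"),
                                     "--plot", str(tmp_path / "fig.png")])
        assert r.exit_code == 0, r.output
        assert "CALCIUM" in r.output
        assert (tmp_path / "fig.png").exists()

        r = runner.invoke(cli_main, ["aggregate", "--results",
                                     str(tmp_path / "res" / "country_results.csv")])
        assert r.exit_code == 0, r.output

    def test_cli_run_requires_config_or_synthetic(self):
        r = CliRunner().invoke(cli_main, ["run"])
        assert r.exit_code != 0
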