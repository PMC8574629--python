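"""PAF formula, intervention scenario rules, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record, microsim_paf
from natalcap.effects import EffectRegistry
from natalcap.paf_engine import (MEDIATOR, ScenarioConfig, bep_reduction,
                                 calcium_reduction, compute_paf, ifa_reduction,
                                 mms_kernel, mms_reduction, reduction)


class TestComputePaf:
    @pytest.mark.parametrize("rr,pc,pt,expected", [
        (1.0, 0.0, 0.9, 0.0),                      # null effect
        (1.0, 0.3, 0.5, 0.0),
        (0.7, 0.5, 0.5, 0.0),                      # no scale-up
        (0.76, 0.0, 0.9, 0.216),                   # zero baseline
        (0.84, 0.3, 0.9, 0.10084033613445378),     # 30% baseline coverage
    ])
    def test_known_values(self, rr, pc, pt, expected):
        assert compute_paf(rr, pc, pt) == pytest.approx(expected, rel=1e-12)

    def test_coverage_reduction_clamped_to_zero(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert compute_paf(0.8, 0.9, 0.5) == 0.0
        # unclamped value is the raw (negative) formula output
        raw = compute_paf(0.8, 0.9, 0.5, clamp=False)
        assert raw == pytest.approx((0.5 - 0.9) * 0.2 / (1 + 0.9 * -0.2))

    @pytest.mark.parametrize("bad", [
        dict(rr=0.0, p_current=0.1, p_target=0.9),
        dict(rr=0.8, p_current=-0.1, p_target=0.9),
        dict(rr=0.8, p_current=0.1, p_target=1.2),
    ])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            compute_paf(**bad)

    @pytest.mark.parametrize("rr", [0.5, 0.84, 1.0])
    @pytest.mark.parametrize("pc,pt", [(0.0, 0.9), (0.3, 0.5)])
    def test_matches_microsimulation(self, rr, pc, pt):
        """Eq-level check: PAF formula agrees with an individual-level
        microsimulation of 2e6 births within 3 Monte-Carlo SEs."""
        sim, se = microsim_paf(rr, pc, pt, n_births=2_000_000, seed=hash((rr, pc, pt)) % 2**31)
        assert abs(compute_paf(rr, pc, pt, clamp=False) - sim) < 3 * se

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(rr=st.floats(0.3, 1.2), pc=st.floats(0, 1), pt=st.floats(0, 1))
    def test_monotonicity_properties(self, rr, pc, pt):
        """PAF is non-increasing in RR and non-decreasing in target coverage."""
        with np.errstate(all="ignore"):
            base = compute_paf(rr, pc, pt, clamp=False)
            if pt >= pc:
                assert compute_paf(rr + 0.05, pc, pt, clamp=False) <= base + 1e-12
            if pt <= 0.95:
                higher = compute_paf(rr, pc, pt + 0.05, clamp=False)
                if rr <= 1:
                    assert higher >= base - 1e-12


class TestInterventionRules:
    def test_ifa_no_gap_gives_zero(self, registry):
        rec = make_record(ifa_coverage=0.9)
        res = ifa_reduction(rec, ScenarioConfig("IFA", 0.9), registry)
        assert res.paf == 0.0 and res.abs_reduction == 0.0 and res.targeted_fraction == 0.0

    def test_ifa_zero_baseline_hand_chain(self, registry):
        rec = make_record(ifa_coverage=0.0, lbw_prev=0.20)
        res = ifa_reduction(rec, ScenarioConfig("IFA", 0.9), registry)
        assert res.paf == pytest.approx(0.9 * 0.16)
        assert res.abs_reduction == pytest.approx(0.9 * 0.16 * 0.20)
        assert res.targeted_fraction == pytest.approx(0.9)

    def test_ifa_null_rr_gives_zero_reduction(self):
        rec = make_record(ifa_coverage=0.0)
        res = ifa_reduction(rec, ScenarioConfig("IFA", 0.9), EffectRegistry.default().null_risks())
        assert res.abs_reduction == 0.0

    def test_calcium_hand_chain_and_zero_prevalence(self, registry):
        rec = make_record(ptb_prev=0.10)
        res = calcium_reduction(rec, ScenarioConfig("CALCIUM", 0.9), registry)
        assert res.abs_reduction == pytest.approx(0.9 * 0.24 * 0.10)  # 0.0216
        assert res.targeted_fraction == 0.9
        rec0 = make_record(ptb_prev=0.0)
        assert calcium_reduction(rec0, ScenarioConfig("CALCIUM", 0.9), registry).abs_reduction == 0.0

    def test_calcium_linear_in_target(self, registry):
        rec = make_record()
        r50 = calcium_reduction(rec, ScenarioConfig("CALCIUM", 0.5), registry)
        r90 = calcium_reduction(rec, ScenarioConfig("CALCIUM", 0.9), registry)
        assert r90.abs_reduction == pytest.approx(1.8 * r50.abs_reduction, rel=1e-12)

    def test_bep_hand_chain_and_underweight_scaling(self, registry):
        rec = make_record(underweight_prev=0.2, lbw_prev=0.20)
        res = bep_reduction(rec, ScenarioConfig("BEP", 0.9), registry)
        assert res.targeted_fraction == pytest.approx(0.18)
        assert res.abs_reduction == pytest.approx(0.9 * 0.2 * 0.17 * 0.20)  # 0.00612
        rec0 = make_record(underweight_prev=0.0)
        res0 = bep_reduction(rec0, ScenarioConfig("BEP", 0.9), registry)
        assert res0.paf == 0.0 and res0.abs_reduction == 0.0 and res0.targeted_fraction == 0.0
        r50 = bep_reduction(rec, ScenarioConfig("BEP", 0.5), registry)
        assert res.abs_reduction == pytest.approx(1.8 * r50.abs_reduction, rel=1e-12)

    def test_mms_pure_switching_limit(self):
        """All women anemic and already on IFA: scaling MMS to t replaces IFA,
        so the PAF is t * (1 - RR_anemic)."""
        paf, _, _ = mms_kernel(0.81, 0.91, 0.84, anemia_prev=1.0, ifa_coverage=1.0,
                               lbw_prev=0.2, target=0.9)
        assert paf == pytest.approx(0.9 * 0.19)

    def test_mms_pure_new_coverage_limit(self):
        """No baseline IFA, nobody anemic: newly covered women get the
        multiplicative combined MMS x IFA effect."""
        paf, _, _ = mms_kernel(0.81, 0.91, 0.84, anemia_prev=0.0, ifa_coverage=0.0,
                               lbw_prev=0.2, target=0.9)
        assert paf == pytest.approx(0.9 * (1 - 0.91 * 0.84))  # 0.21204

    def test_mms_zero_target_gives_zero(self, registry):
        res = mms_reduction(make_record(), ScenarioConfig("MMS", 0.0), registry)
        assert res.paf == 0.0 and res.abs_reduction == 0.0

    def test_mms_anemia_weighting(self, registry):
        rec_an = make_record(anemia_prev=1.0)
        rec_no = make_record(anemia_prev=0.0)
        rec_mid = make_record(anemia_prev=0.4)
        s = ScenarioConfig("MMS", 0.9)
        pa = mms_reduction(rec_an, s, registry).paf
        pn = mms_reduction(rec_no, s, registry).paf
        pm = mms_reduction(rec_mid, s, registry).paf
        assert pm == pytest.approx(0.4 * pa + 0.6 * pn)

    def test_mms_superlinear_when_baseline_ifa_present(self, registry):
        """With baseline IFA coverage in [0.5, 0.9), doubling the target from
        50% to 90% more than 1.8x-es the PAF: newly covered women carry the
        larger combined effect."""
        for cov in (0.5, 0.6, 0.8):
            rec = make_record(ifa_coverage=cov)
            p50 = mms_reduction(rec, ScenarioConfig("MMS", 0.5), registry).paf
            p90 = mms_reduction(rec, ScenarioConfig("MMS", 0.9), registry).paf
            assert p90 > 1.8 * p50

    def test_mediator_pairing_and_dispatch(self, registry):
        assert MEDIATOR == {"IFA": "LBW", "CALCIUM": "PTB", "MMS": "LBW", "BEP": "LBW"}
        rec = make_record()
        for iv in ("IFA", "CALCIUM", "MMS", "BEP"):
            res = reduction(rec, ScenarioConfig(iv, 0.9), registry)
            prev = rec.ptb_prev if MEDIATOR[iv] == "PTB" else rec.lbw_prev
            assert res.abs_reduction <= prev

    def test_missing_mediator_prevalence_rejected(self, registry):
        rec = make_record(lbw_prev=None, lbw_se=float("nan"))
        with pytest.raises(ValueError, match="missing"):
            ifa_reduction(rec, ScenarioConfig("IFA", 0.9), registry)

    def test_scenario_validation(self):
        with pytest.raises(ValueError, match="unknown intervention"):
            ScenarioConfig("ZINC", 0.9)
        with pytest.raises(ValueError):
            ScenarioConfig("IFA", 1.2)
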