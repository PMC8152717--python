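import math

import pytest
from hypothesis import given, settings, strategies as st

from coroflow.physiology import (CaseRecord, analyze_case, cfr,
                                 cfr_pressure_derived, ffr_and_pdpa, mvr,
                                 percent_delta, sr)

press = st.floats(20.0, 200.0)
flow = st.floats(5.0, 400.0)


class TestIndexFormulas:
    @pytest.mark.parametrize("pd, q, expect", [
        (85.6, 67.7, 1.26),    # published case: baseline
        (62.2, 119.7, 0.52),   # published case: hyperaemic
        (50.0, 50.0, 1.0),
    ])
    def test_mvr(self, pd, q, expect):
        assert mvr(pd, q) == pytest.approx(expect, abs=0.005)

    def test_mvr_with_venous_pressure(self):
        assert mvr(79.5, 27.1, pv_mmHg=5.0) == pytest.approx(2.75, abs=0.005)

    @pytest.mark.parametrize("pa, pd, q, expect", [
        (89.1, 66.4, 93.2, 0.24),
        (65.0, 32.9, 65.8, 0.49),
        (90.0, 90.0, 50.0, 0.0),
    ])
    def test_sr(self, pa, pd, q, expect):
        assert sr(pa, pd, q) == pytest.approx(expect, abs=0.005)

    @pytest.mark.parametrize("qh, qb, expect", [
        (165.3, 89.8, 1.84), (36.3, 36.6, 0.99), (70.0, 70.0, 1.0),
    ])
    def test_cfr(self, qh, qb, expect):
        assert cfr(qh, qb) == pytest.approx(expect, abs=0.005)

    @pytest.mark.parametrize("pa, pd, expect", [
        (78.0, 61.0, 0.78), (88.0, 79.4, 0.90), (90.0, 90.0, 1.0),
    ])
    def test_pd_over_pa(self, pa, pd, expect):
        assert ffr_and_pdpa(pa, pd) == pytest.approx(expect, abs=0.005)

    @pytest.mark.parametrize("dph, dpb, expect", [
        (1.7, 0.7, 1.56), (56.5, 52.7, 1.04), (9.0, 9.0, 1.0),
    ])
    def test_cfr_pressure_derived_sqrt(self, dph, dpb, expect):
        assert cfr_pressure_derived(dph, dpb) == pytest.approx(expect, abs=0.005)

    def test_cfr_pressure_derived_ratio_form(self):
        assert cfr_pressure_derived(8.0, 2.0, form="ratio") == pytest.approx(4.0)
        assert cfr_pressure_derived(8.0, 2.0, form="sqrt") == pytest.approx(2.0)

    @pytest.mark.parametrize("base, hyp, expect", [
        (3.49, 1.70, -51), (22.7, 35.8, 58), (7.0, 7.0, 0),
    ])
    def test_percent_delta(self, base, hyp, expect):
        assert round(percent_delta(base, hyp)) == expect

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mvr(80.0, 0.0)
        with pytest.raises(ValueError):
            sr(90.0, 80.0, -1.0)
        with pytest.raises(ValueError):
            cfr(100.0, 0.0)
        with pytest.raises(ValueError):
            ffr_and_pdpa(0.0, 50.0)
        with pytest.raises(ValueError):
            cfr_pressure_derived(5.0, 0.0)
        with pytest.raises(ValueError):
            percent_delta(0.0, 5.0)


class TestAlgebraicProperties:
    @settings(derandomize=True, max_examples=100)
    @given(press, press, flow)
    def test_ohm_identity(self, pa, pd, q):
        """MVR + SR = Pa/Q: the series decomposition of total resistance."""
        assert mvr(pd, q) + sr(pa, pd, q) == pytest.approx(pa / q, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(press, flow, st.floats(1.01, 3.0))
    def test_resistances_decrease_with_flow(self, pd, q, factor):
        pa = pd + 10.0
        assert mvr(pd, q * factor) < mvr(pd, q)
        assert sr(pa, pd, q * factor) < sr(pa, pd, q)
        assert mvr(pd + 5.0, q) > mvr(pd, q)


def _record(**kw):
    base = dict(case_id="2", artery="LAD", pa_bl=92.7, pd_bl=85.6,
                pa_hyp=75.7, pd_hyp=61.5, q_bl_mL_min=67.7,
                q_hyp_mL_min=109.2)
    base.update(kw)
    return CaseRecord(**base)


class TestAnalyzeCase:
    def test_published_case_panel(self):
        """Case with externally supplied flows reproduces its printed panel."""
        panel = analyze_case(_record())
        assert panel.baseline.mvr == pytest.approx(1.26, abs=0.01)
        assert panel.baseline.sr == pytest.approx(0.10, abs=0.005)
        assert panel.cfr == pytest.approx(1.61, abs=0.005)
        assert panel.ffr == pytest.approx(0.81, abs=0.005)
        assert panel.valid

    def test_low_baseline_gradient_flagged(self):
        panel = analyze_case(_record(pa_bl=90.0, pd_bl=87.0))
        assert "gradient-below-4mmHg-baseline" in panel.flags
        assert not panel.valid

    def test_high_ffr_flagged(self):
        panel = analyze_case(_record(pa_hyp=100.0, pd_hyp=96.0))
        assert panel.ffr == pytest.approx(0.96)
        assert "ffr-outside-validated-range" in panel.flags

    def test_negative_gradient_flagged_not_clamped(self):
        panel = analyze_case(_record(pa_bl=80.0, pd_bl=82.0))
        assert "negative-gradient-baseline" in panel.flags
        assert panel.baseline.dp_mmHg == pytest.approx(-2.0)

    def test_missing_flow_and_geometry_rejected(self):
        with pytest.raises(ValueError):
            analyze_case(_record(q_bl_mL_min=None))

    def test_panel_dict_round_trip(self):
        d = analyze_case(_record()).as_dict()
        assert d["ffr"] == pytest.approx(0.8124, abs=1e-3)
        assert math.isclose(d["mvr_bl"] + d["sr_bl"], 92.7 / 67.7)
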