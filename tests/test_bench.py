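import numpy as np
import pandas as pd
import pytest

from coroflow.bench import (BenchProtocol, agreement_report, default_phantoms,
                            run_bench, subset_by_reynolds)
from coroflow.geometry import synth_stenosis_geometry
from coroflow.solver import reynolds_number


@pytest.fixture(scope="module")
def tiny_result():
    """Small self-inversion bench: matched meshes, zero noise."""
    g = synth_stenosis_geometry(3.0, 68.0, 46.0, label="T1")
    protocol = BenchProtocol(flow_rates_mL_min=(60.0, 90.0, 120.0), repeats=2,
                             models=(g,), seed=11,
                             truth_resolution="coarse",
                             recovery_resolution="coarse")
    return run_bench(protocol)


class TestProtocol:
    def test_default_protocol_shape(self):
        p = BenchProtocol()
        assert len(p.flow_rates_mL_min) == 14
        assert p.flow_rates_mL_min[0] == 50.0 and p.flow_rates_mL_min[-1] == 180.0
        assert p.repeats == 3
        assert len(p.resolved_models()) == 5

    def test_default_phantoms_span_bench_envelope(self):
        from coroflow.geometry import percent_diameter_stenosis
        phantoms = default_phantoms()
        ds = sorted(percent_diameter_stenosis(g) for g in phantoms)
        lengths = sorted(g.length_mm for g in phantoms)
        assert ds[0] == pytest.approx(46.0, abs=1.0)
        assert ds[-1] == pytest.approx(72.0, abs=1.0)
        assert lengths[0] == 68.0 and lengths[-1] == 84.0

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            BenchProtocol(flow_rates_mL_min=(90.0, 60.0))
        with pytest.raises(ValueError):
            BenchProtocol(repeats=0)


class TestRunBench:
    def test_record_count(self, tiny_result):
        p = tiny_result.protocol
        assert len(tiny_result.records) == 1 * 3 * p.repeats

    def test_self_inversion_recovers_imposed_flow(self, tiny_result):
        """Matched truth/recovery meshes, zero noise: Q_CFD = Q_exp."""
        rec = tiny_result.records
        assert rec["error"].isna().all()
        err = (rec["q_cfd"] - rec["q_exp"]).abs()
        assert (err <= np.maximum(0.1, 0.001 * rec["q_exp"]) + 1e-9).all()

    def test_repeats_identical_without_noise(self, tiny_result):
        per_cell = tiny_result.records.groupby("q_exp")["q_cfd"].nunique()
        assert (per_cell == 1).all()

    def test_reproducible_with_seed(self, tiny_result):
        again = run_bench(tiny_result.protocol)
        pd.testing.assert_frame_equal(tiny_result.records, again.records)

    def test_doppler_underestimates(self, tiny_result):
        assert tiny_result.records["q_dop"].mean() < \
            tiny_result.records["q_exp"].mean()

    def test_means_table_shape(self, tiny_result):
        assert len(tiny_result.means) == 3  # 1 model x 3 rates


class TestSubset:
    def test_identity_when_all_below_threshold(self, tiny_result):
        assert len(subset_by_reynolds(tiny_result, 1e9).records) == \
            len(tiny_result.records)

    def test_zero_threshold_empties(self, tiny_result):
        assert len(subset_by_reynolds(tiny_result, 0.0).records) == 0

    def test_matches_brute_force_recount(self, tiny_result):
        g = synth_stenosis_geometry(3.0, 68.0, 46.0, label="T1")
        fluid = tiny_result.protocol.fluid
        expected = sum(
            tiny_result.protocol.repeats
            for q in tiny_result.protocol.flow_rates_mL_min
            if reynolds_number(g, fluid, q) < 300.0)
        assert len(subset_by_reynolds(tiny_result, 300.0).records) == expected


class TestAgreement:
    def test_exact_method_has_zero_bias(self, tiny_result):
        rec = tiny_result.records.copy()
        rec["q_cfd"] = rec["q_exp"]
        exact = type(tiny_result)(records=rec, protocol=tiny_result.protocol)
        s = agreement_report(exact, "q_cfd")
        assert s.bias == 0.0 and s.loa_high - s.loa_low == 0.0
        assert s.r2 == pytest.approx(1.0)

    def test_constant_offset_shows_as_bias(self, tiny_result):
        rec = tiny_result.records.copy()
        rec["q_cfd"] = rec["q_exp"] + 5.0
        shifted = type(tiny_result)(records=rec, protocol=tiny_result.protocol)
        s = agreement_report(shifted, "q_cfd")
        assert s.bias == pytest.approx(5.0) and s.sd_delta == pytest.approx(0.0)

    def test_unknown_method_rejected(self, tiny_result):
        with pytest.raises(ValueError):
            agreement_report(tiny_result, "thermo")

    def test_requires_two_means(self, tiny_result):
        one = type(tiny_result)(
            records=tiny_result.records[tiny_result.records["q_exp"] == 60.0],
            protocol=tiny_result.protocol)
        with pytest.raises(ValueError):
            agreement_report(one, "q_cfd")
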