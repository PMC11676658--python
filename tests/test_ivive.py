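"""In-vitro kinetics and IVIVE chain against published reference values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spt07a_pbpk as pk
from spt07a_pbpk.ivive import DepletionAssay, build_clearance_table, mean_ratio


def _assay(times, concs, mic=0.25, fu_mic=0.60):
    return DepletionAssay(times=tuple(times), concentrations=tuple(concs),
                          mic=mic, fu_mic=fu_mic)


class TestDepletionFitting:
    def test_two_point_rate_matches_single_point_formula(self):
        # 40.2% remaining at 60 min -> k = -ln(0.402)/60
        k = pk.fit_depletion_rate(_assay([0, 60], [100.0, 40.2]))
        assert k == pytest.approx(-math.log(0.402) / 60, rel=1e-12)
        assert k == pytest.approx(0.01518, abs=2e-5)

    def test_flat_series_gives_zero_rate(self):
        assert pk.fit_depletion_rate(_assay([0, 10, 20, 30], [50.0] * 4)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_noiseless_log_linear_recovery_to_machine_precision(self):
        t = np.array([0, 10, 20, 30, 45, 60], float)
        k_true = 0.05
        assay = _assay(t, 100.0 * np.exp(-k_true * t))
        assert pk.fit_depletion_rate(assay) == pytest.approx(k_true, rel=1e-12)

    def test_increasing_concentration_warns_and_reports_negative_k(self):
        with pytest.warns(UserWarning, match="not depleting"):
            k = pk.fit_depletion_rate(_assay([0, 30, 60], [100, 110, 120]))
        assert k < 0

    def test_rejects_single_point_and_nonpositive_concentrations(self):
        with pytest.raises(ValueError):
            _assay([0], [100.0])
        with pytest.raises(ValueError):
            _assay([0, 60], [100.0, -1.0])


class TestClintU:
    def test_reference_recombinant_ugt2b7_value(self):
        k = -math.log(0.402) / 60
        assert pk.clint_u(k, 0.25, 0.60) == pytest.approx(101, rel=0.01)

    def test_single_point_recombinant_ugt1a1_value(self):
        # 75.2% remaining at 60 min, fu_mic 0.61: close to the printed 31.6
        k = -math.log(0.752) / 60
        assert pk.clint_u(k, 0.25, 0.61) == pytest.approx(31.6, rel=0.05)

    def test_zero_rate_gives_zero_clearance(self):
        assert pk.clint_u(0.0, 0.25, 0.60) == 0.0

    def test_zero_protein_rejected(self):
        with pytest.raises(ValueError):
            pk.clint_u(0.01, 0.0, 0.6)


class TestOrganScaling:
    @pytest.mark.parametrize("clint, mppgx, ow, expected", [
        (2060.0, 44.8, 36.6, 3380.0),   # rat liver UGT
        (1500.0, 17.9, 7.32, 196.0),    # rat kidney UGT
        (79.1, 9.7, 22.4, 17.2),        # rat intestine UGT
        (745.0, 48.8, 25.7, 934.0),     # human liver UGT
        (0.0, 48.8, 25.7, 0.0),
    ])
    def test_scaled_in_vivo_clearances(self, clint, mppgx, ow, expected):
        assert pk.scale_to_in_vivo(clint, mppgx, ow) == pytest.approx(
            expected, rel=0.005)


class TestWellStirred:
    def test_human_liver_blood_clearance(self):
        assert pk.well_stirred_cl(1518.33 / 70, 0.3264 / 0.92, 938.0) == \
            pytest.approx(20.4, rel=0.005)

    def test_rat_kidney_blood_clearance(self):
        assert pk.well_stirred_cl(11.71 / 0.25, 0.2870 / 1.10, 196.0) == \
            pytest.approx(24.4, rel=0.005)

    def test_zero_intrinsic_clearance(self):
        assert pk.well_stirred_cl(20.0, 0.3, 0.0) == 0.0

    def test_flow_limit_and_restrictive_limit(self):
        q, fu_b = 21.7, 0.35
        assert pk.well_stirred_cl(q, fu_b, 1e9) == pytest.approx(q, rel=0.01)
        small = 1e-4
        assert pk.well_stirred_cl(q, fu_b, small) == pytest.approx(
            fu_b * small, rel=0.01)

    @given(clint=st.floats(0.0, 1e5), fu_b=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_flow_and_monotone(self, clint, fu_b):
        q = 50.0
        cl = pk.well_stirred_cl(q, fu_b, clint)
        assert 0 <= cl < q
        assert pk.well_stirred_cl(q, fu_b, clint + 10.0) >= cl


class TestFractionsAndExtraction:
    def test_rat_organ_contributions(self):
        f = pk.organ_fractions({"liver": 46.6, "kidney": 24.4, "intestine": 3.90})
        assert f["liver"] == pytest.approx(0.622, abs=0.001)
        assert f["kidney"] == pytest.approx(0.326, abs=0.001)
        assert f["intestine"] == pytest.approx(0.052, abs=0.001)

    def test_single_organ_is_everything(self):
        assert pk.organ_fractions({"liver": 5.0}) == {"liver": 1.0}

    def test_all_zero_clearances_rejected(self):
        with pytest.raises(ValueError):
            pk.organ_fractions({"liver": 0.0, "kidney": 0.0})

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        base = {"liver": 46.6, "kidney": 24.4, "intestine": 3.9}
        scaled = {k: v * scale for k, v in base.items()}
        for organ in base:
            assert pk.organ_fractions(scaled)[organ] == pytest.approx(
                pk.organ_fractions(base)[organ], rel=1e-9)

    @pytest.mark.parametrize("cl_b, q, expected", [
        (46.6, 49.2, 0.95), (20.4, 21.69, 0.94), (0.0, 49.2, 0.0),
    ])
    def test_extraction_ratios(self, cl_b, q, expected):
        assert pk.extraction_ratio(cl_b, q) == pytest.approx(expected, abs=0.005)

    def test_extraction_ratio_rejects_cl_above_flow(self):
        with pytest.raises(ValueError):
            pk.extraction_ratio(50.0, 49.2)


class TestRafPhenotyping:
    def test_zidovudine_and_estradiol_rafs(self):
        assert pk.raf(193.0, 85.8) == pytest.approx(2.25, abs=0.005)
        assert pk.raf(61.9, 50.0) == pytest.approx(1.24, abs=0.005)
        assert pk.raf(85.8, 85.8) == 1.0

    def test_ugt2b7_liver_contribution(self):
        res = pk.raf_contribution(pk.raf(193.0, 85.8), 101.0, 745.0)
        assert res.fm == pytest.approx(0.305, abs=0.002)

    def test_ugt1a1_liver_contribution(self):
        res = pk.raf_contribution(pk.raf(61.9, 50.0), 31.6, 745.0)
        assert res.fm == pytest.approx(0.053, abs=0.002)

    def test_predicted_total_microsomal_clearances(self):
        hlm = (pk.raf_contribution(pk.raf(193.0, 85.8), 101.0, 745.0).predicted_clint_u
               + pk.raf_contribution(pk.raf(61.9, 50.0), 31.6, 745.0).predicted_clint_u)
        assert hlm == pytest.approx(265, rel=0.01)
        hkm = pk.raf_contribution(pk.raf(138.0, 85.8), 101.0, 339.0)
        assert hkm.predicted_clint_u == pytest.approx(162, rel=0.01)
        assert hkm.fm == pytest.approx(0.477, abs=0.005)


class TestBindingUtilities:
    def test_rat_blood_plasma_ratio_mean(self):
        assert mean_ratio([1.11, 1.09, 1.11], [1.0, 1.0, 1.0]) == \
            pytest.approx(1.10, abs=0.005)

    def test_human_unbound_fraction_from_bound_percentages(self):
        bound = np.array([63.35, 69.30, 68.04, 68.76])
        fu = np.mean(1 - bound / 100)
        assert fu == pytest.approx(0.3264, abs=0.0005)

    def test_receiver_equals_donor_gives_unity(self):
        assert pk.unbound_fraction(5.0, 5.0) == 1.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            pk.blood_plasma_ratio(0.0, 1.0)


class TestClearanceTableAssembly:
    @pytest.mark.parametrize("species, expected_total", [
        ("rat", 75.0), ("dog", 43.3), ("human", 26.6),
    ])
    def test_total_blood_clearances(self, species, expected_total):
        table = build_clearance_table(pk.load_species(species))
        assert table.cl_b_tot == pytest.approx(expected_total, rel=0.005)

    def test_human_fractions_and_extraction(self, human_cfg):
        table = build_clearance_table(human_cfg)
        assert table.f_cl["liver"] == pytest.approx(0.765, abs=0.002)
        assert table.f_cl["kidney"] == pytest.approx(0.231, abs=0.002)
        assert table.f_cl["intestine"] == pytest.approx(0.004, abs=0.001)
        assert table.er["liver"] == pytest.approx(0.94, abs=0.005)

    def test_fractions_sum_to_one(self):
        for species in ("rat", "dog", "human"):
            table = build_clearance_table(pk.load_species(species))
            assert sum(table.f_cl.values()) == pytest.approx(1.0, abs=1e-9)

    def test_dog_intestine_inactive(self, dog_cfg):
        table = build_clearance_table(dog_cfg)
        assert table.cl_b["intestine"] == 0.0
        assert table.f_cl["intestine"] == 0.0

    def test_frame_layout(self, rat_cfg):
        frame = build_clearance_table(rat_cfg).to_frame()
        assert {"organ", "pathway", "clint_u_ul_min_mg",
                "cl_b_ml_min_kg"} <= set(frame.columns)
        assert len(frame) == 4  # liver UGT+CYP, kidney UGT, intestine UGT
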