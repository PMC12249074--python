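from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from ctdoseaudit.errors import (
    CalibrationRangeError,
    DiameterRangeError,
    MapNotConfiguredError,
    NegativeDoseWarning,
    RegionLookupError,
    WeightMissingError,
    WeightRangeError,
)
from ctdoseaudit.metrics import (
    DwaterMap,
    MartinRegion,
    MartinSegment,
    SsdeModel,
    WeightCorrectionModel,
    compute_ed,
    compute_sed,
    compute_wkg,
    sed_from_ssde,
    ssde_from_deff,
    ssde_to_dwater_basis,
    study_ed_total,
)
from ctdoseaudit.records import Phantom, SeriesRegion
from ctdoseaudit.regions import emulate_fixed_region


class TestWkg:
    def test_reference_weight_70kg(self):
        assert compute_wkg(70.0) == pytest.approx(0.99696, rel=1e-9)

    def test_constant_term_at_zero_weight(self):
        assert compute_wkg(0.0, check_range=False) == pytest.approx(1.73)

    def test_100kg(self):
        assert compute_wkg(100.0) == pytest.approx(0.804, rel=1e-9)

    def test_out_of_range_weight_names_value(self):
        with pytest.raises(WeightRangeError, match="250"):
            compute_wkg(250.0)

    def test_strictly_decreasing_up_to_vertex(self):
        # vertex of the quadratic sits at -c1/(2 c2) ~ 164.6 kg
        grid = np.linspace(20.0, 164.6, 500)
        values = [compute_wkg(w) for w in grid]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert all(v > 0 for v in values)

    def test_crosses_unity_near_69_6_kg(self):
        # brute-force bisection oracle on wkg(w) - 1
        lo, hi = 20.0, 164.0
        assert (compute_wkg(lo) - 1) > 0 > (compute_wkg(hi) - 1)
        for _ in range(80):
            mid = (lo + hi) / 2
            if compute_wkg(mid) - 1 > 0:
                lo = mid
            else:
                hi = mid
        assert lo == pytest.approx(69.6, abs=0.1)

    def test_custom_coefficients(self):
        model = WeightCorrectionModel(c0=2.0, c1=0.0, c2=0.0)
        assert compute_wkg(80.0, model) == 2.0


class TestComputeEd:
    def test_chest_product(self, factor_table):
        assert compute_ed(100.0, SeriesRegion.CHEST, factor_table) == \
            pytest.approx(1.4)

    def test_zero_dlp(self, factor_table):
        assert compute_ed(0.0, SeriesRegion.CHEST, factor_table) == 0.0

    def test_head_product(self, factor_table):
        assert compute_ed(1000.0, SeriesRegion.HEAD, factor_table) == \
            pytest.approx(2.1)

    def test_undefined_region_is_lookup_error(self, factor_table):
        with pytest.raises(RegionLookupError, match="undefined"):
            compute_ed(100.0, SeriesRegion.UNDEFINED, factor_table)

    @given(dlp=st.floats(min_value=0, max_value=5000),
           scale=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=100, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_linearity_in_dlp(self, factor_table, dlp, scale):
        base = compute_ed(dlp, SeriesRegion.CHEST, factor_table)
        scaled = compute_ed(dlp * scale, SeriesRegion.CHEST, factor_table)
        assert scaled == pytest.approx(base * scale, rel=1e-12, abs=1e-12)


class TestComputeSed:
    def test_70kg(self, factor_table):
        sed = compute_sed(100.0, SeriesRegion.CHEST, factor_table, 70.0)
        assert sed == pytest.approx(1.4 * 0.99696, rel=1e-9)  # = 1.395744

    def test_100kg(self, factor_table):
        sed = compute_sed(100.0, SeriesRegion.CHEST, factor_table, 100.0)
        assert sed == pytest.approx(1.1256, rel=1e-9)

    def test_missing_weight_error_is_distinct(self, factor_table):
        with pytest.raises(WeightMissingError):
            compute_sed(100.0, SeriesRegion.CHEST, factor_table, None)

    @given(dlp=st.floats(min_value=0, max_value=3000),
           w=st.floats(min_value=20, max_value=200))
    @settings(max_examples=150, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_sed_equals_wkg_times_ed(self, factor_table, dlp, w):
        sed = compute_sed(dlp, SeriesRegion.ABDOMEN_PELVIS, factor_table, w)
        ed = compute_ed(dlp, SeriesRegion.ABDOMEN_PELVIS, factor_table)
        assert sed == pytest.approx(compute_wkg(w) * ed, rel=1e-12, abs=1e-12)

    def test_at_70kg_sed_within_031_pct_of_ed(self, factor_table):
        sed = compute_sed(500.0, SeriesRegion.CHEST, factor_table, 70.0)
        ed = compute_ed(500.0, SeriesRegion.CHEST, factor_table)
        assert abs(sed - ed) / ed < 0.0031


class TestSsde:
    def test_unity_point(self):
        model = SsdeModel()
        a_e, b_e = model.coefficients[Phantom.BODY32]
        d_unity = math.log(a_e) / b_e
        assert model.unity_diameter(Phantom.BODY32) == pytest.approx(d_unity)
        assert ssde_from_deff(10.0, d_unity) == pytest.approx(10.0, rel=1e-12)

    def test_body32_at_30cm(self):
        # cross-checked against the published lookup value near 30 cm
        assert ssde_from_deff(10.0, 30.0) == pytest.approx(12.31, abs=0.005)

    def test_zero_ctdi(self):
        assert ssde_from_deff(0.0, 30.0) == 0.0

    @pytest.mark.parametrize("d_eff", [5.0, 60.0, 300.0])
    def test_implausible_diameter_guard(self, d_eff):
        with pytest.raises(DiameterRangeError):
            ssde_from_deff(10.0, d_eff)

    def test_factor_strictly_decreasing_and_positive(self):
        diams = np.linspace(8.0, 55.0, 200)
        factors = [ssde_from_deff(1.0, d) for d in diams]
        assert all(f > 0 for f in factors)
        assert all(a > b for a, b in zip(factors, factors[1:]))

    def test_head_phantom_uses_its_own_coefficients(self):
        body = ssde_from_deff(10.0, 17.0, Phantom.BODY32)
        head = ssde_from_deff(10.0, 17.0, Phantom.HEAD16)
        assert head != pytest.approx(body)


class TestDwaterBasis:
    def test_identity_map(self):
        m = DwaterMap(slope=1.0, intercept=0.0)
        assert ssde_to_dwater_basis(8.5, m, "chest") == 8.5

    def test_affine_map(self):
        m = DwaterMap(slope=1.1, intercept=-0.5)
        assert ssde_to_dwater_basis(10.0, m, "chest") == pytest.approx(10.5)

    def test_head_not_applicable(self):
        m = DwaterMap(slope=1.0, intercept=0.0)
        with pytest.raises(RegionLookupError):
            ssde_to_dwater_basis(8.5, m, "head")

    def test_unconfigured_map_never_silent_identity(self):
        with pytest.raises(MapNotConfiguredError, match="coefficients required"):
            ssde_to_dwater_basis(8.5, None, "chest")


class TestSedFromSsde:
    def test_abdomen_pelvis_example(self, segments):
        sed = sed_from_ssde(10.0, MartinRegion.ABDOMEN_PELVIS, 45.0, segments)
        assert sed == pytest.approx(4.4509, rel=1e-9)

    def test_root_of_linear_map_is_zero(self, segments):
        sed = sed_from_ssde(2.3621 / 0.6813, MartinRegion.ABDOMEN_PELVIS,
                            45.0, segments)
        assert sed == pytest.approx(0.0, abs=1e-12)

    def test_scan_length_outside_window(self, segments):
        with pytest.raises(CalibrationRangeError, match="out of calibrated range"):
            sed_from_ssde(10.0, MartinRegion.ABDOMEN_PELVIS, 60.0, segments)

    def test_negative_result_warns_not_clamps(self, segments):
        with pytest.warns(NegativeDoseWarning):
            sed = sed_from_ssde(0.5, MartinRegion.ABDOMEN_PELVIS, 45.0, segments)
        assert sed < 0

    def test_ambiguous_segments_rejected(self):
        seg = MartinSegment(MartinRegion.CHEST, (30.0, 37.0), 0.5, 1.0)
        with pytest.raises(CalibrationRangeError, match="ambiguous"):
            sed_from_ssde(10.0, MartinRegion.CHEST, 33.0, [seg, seg])

    def test_plus_b_convention(self):
        from ctdoseaudit.metrics import SignConvention
        seg = MartinSegment(MartinRegion.CHEST, (30.0, 37.0), 0.5, 1.0,
                            sign_convention=SignConvention.A_X_PLUS_B)
        assert sed_from_ssde(10.0, MartinRegion.CHEST, 33.0, [seg]) == \
            pytest.approx(6.0)

    @given(ssde=st.floats(min_value=5, max_value=40),
           scale=st.floats(min_value=0.5, max_value=2))
    @settings(max_examples=80, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_affine_against_brute_force(self, segments, ssde, scale):
        # independent recomputation straight from the segment constants
        seg = next(s for s in segments
                   if s.scanned_region is MartinRegion.CHEST)
        expected = seg.a * (ssde * scale) - seg.b
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", NegativeDoseWarning)
            got = sed_from_ssde(ssde * scale, MartinRegion.CHEST, 33.0, segments)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestStudyEdTotal:
    def test_head_plus_chest(self, make_study, factor_table):
        study = make_study(regions=(SeriesRegion.HEAD, SeriesRegion.CHEST),
                           dlps=(900.0, 350.0))
        assert study_ed_total(study, factor_table) == pytest.approx(6.79)

    def test_fixed_region_inflates_to_17_5(self, make_study, factor_table):
        study = make_study(regions=(SeriesRegion.HEAD, SeriesRegion.CHEST),
                           dlps=(900.0, 350.0))
        fixed = emulate_fixed_region(study)
        assert study_ed_total(fixed, factor_table) == pytest.approx(17.5)

    def test_singleton_equals_compute_ed(self, make_study, factor_table):
        study = make_study(regions=(SeriesRegion.CHEST,), dlps=(123.0,))
        assert study_ed_total(study, factor_table) == pytest.approx(
            compute_ed(123.0, SeriesRegion.CHEST, factor_table)
        )

    def test_lookup_error_names_series(self, make_study, factor_table):
        study = make_study(regions=(SeriesRegion.UNDEFINED,))
        with pytest.raises(RegionLookupError, match=study.series[0].series_uid):
            study_ed_total(study, factor_table)

    def test_weight_corrected_total(self, make_study, factor_table):
        study = make_study(regions=(SeriesRegion.CHEST,), dlps=(100.0,),
                           weight=100.0)
        total = study_ed_total(study, factor_table, weight_corrected=True)
        assert total == pytest.approx(1.1256, rel=1e-9)

    @given(
        dlp_low=st.floats(min_value=10, max_value=2000),
        dlp_high=st.floats(min_value=10, max_value=2000),
    )
    @settings(max_examples=100, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_misassignment_never_deflates(self, factor_table, dlp_low, dlp_high):
        # low-f region first, high-f region last -> fixed-region ED >= correct
        from tests_support import build_study
        study = build_study(
            [SeriesRegion.HEAD, SeriesRegion.CHEST], dlps=[dlp_low, dlp_high]
        )
        correct = study_ed_total(study, factor_table)
        fixed = study_ed_total(emulate_fixed_region(study), factor_table)
        assert fixed >= correct
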