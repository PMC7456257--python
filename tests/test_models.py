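import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from saplingcrown.models import (CrownMetrics, ProfileDomainError, ProfileParams,
                                 crown_metrics, crown_volume, eval_profile,
                                 grid_argmax_radius, inflection_point,
                                 is_monotone, largest_crown_radius,
                                 load_reference_params)

from conftest import CUT_SELECTED, UNCUT_SELECTED


class TestEvalProfile:
    def test_zero_at_tip_for_positive_exponent(self):
        assert eval_profile(CUT_SELECTED, dbh=2.0, cr=0.8, rdinc=0.0) == 0.0

    def test_hand_evaluation_selected_cut_row(self):
        r = eval_profile(CUT_SELECTED, dbh=2.0, cr=0.80, rdinc=0.8088)
        assert r == pytest.approx(0.2290, abs=5e-5)

    def test_basic_form_identity_reduction(self):
        p = ProfileParams("power_exp_basic", (1.0, 1.0, 0.0))
        assert eval_profile(p, rdinc=0.5) == pytest.approx(0.5)

    def test_increasing_in_dbh(self):
        r1 = eval_profile(CUT_SELECTED, dbh=1.0, cr=0.8, rdinc=0.5)
        r2 = eval_profile(CUT_SELECTED, dbh=3.0, cr=0.8, rdinc=0.5)
        assert r2 > r1

    def test_kozak_mod_crown_base_limit(self):
        p = ProfileParams("kozak_mod", (0.5, 0.6, 0.5, 0.5, 1.2))
        assert eval_profile(p, dbh=2.0, cr=0.8, rdinc=1.0) == \
            pytest.approx(0.5 * 2.0 ** 0.6)

    def test_kozak_domain_errors(self):
        with pytest.raises(ProfileDomainError):
            eval_profile(ProfileParams("kozak_basic", (1.0, 1.0, 1.5)), rdinc=0.5)
        with pytest.raises(ProfileDomainError):
            eval_profile(ProfileParams("kozak_mod", (1.0, 1.0, 2.0, 1.0, 1.0)),
                         dbh=2.0, cr=0.9, rdinc=0.5)

    def test_rdinc_outside_unit_interval_rejected(self):
        with pytest.raises(ProfileDomainError):
            eval_profile(CUT_SELECTED, dbh=2.0, cr=0.8, rdinc=1.2)

    @given(st.floats(0.01, 1.0))
    def test_continuous_nonnegative(self, t):
        assert eval_profile(CUT_SELECTED, dbh=2.0, cr=0.8, rdinc=t) >= 0.0


class TestInflection:
    @pytest.mark.parametrize("params,expected", [
        (CUT_SELECTED, 0.8088), (UNCUT_SELECTED, 0.6448)])
    def test_closed_form_selected_rows(self, params, expected):
        assert inflection_point(params, cr=0.80) == pytest.approx(expected, abs=5e-5)

    def test_unit_ratio_boundary(self):
        p = ProfileParams("power_exp_full", (1.0, 0.5, 1.0, 0.0, -1.0))
        assert inflection_point(p, cr=0.5) == 1.0

    def test_nonnegative_rate_means_monotone(self):
        p = ProfileParams("power_exp_full", (1.0, 0.5, 1.0, 0.0, 0.2))
        assert inflection_point(p, cr=0.5) == 1.0
        assert is_monotone(p, cr=0.5)

    def test_matches_fine_grid_argmax(self):
        for params in (CUT_SELECTED, UNCUT_SELECTED):
            t_grid, r_grid = grid_argmax_radius(params, 2.0, 0.80, n=1_000_001)
            t_cf = inflection_point(params, cr=0.80)
            assert abs(t_cf - t_grid) < 2e-6
            assert largest_crown_radius(params, 2.0, 0.80) >= r_grid - 1e-10

    def test_linear_in_crown_ratio(self):
        a3, a4, a5 = CUT_SELECTED.coefficients[2:]
        slope = a4 / (-a5)
        t1 = inflection_point(CUT_SELECTED, cr=0.6)
        t2 = inflection_point(CUT_SELECTED, cr=0.7)
        assert (t2 - t1) / 0.1 == pytest.approx(slope, rel=1e-9)


class TestLargestRadius:
    def test_selected_cut_value(self):
        assert largest_crown_radius(CUT_SELECTED, 2.0, 0.80) == \
            pytest.approx(0.2290, abs=5e-5)

    def test_monotone_profile_peaks_at_crown_base(self):
        p = ProfileParams("power_exp_full", (1.0, 0.5, 0.5, 0.0, -0.2))
        assert inflection_point(p, cr=0.8) == 1.0
        assert largest_crown_radius(p, 2.0, 0.8) == \
            pytest.approx(eval_profile(p, dbh=2.0, cr=0.8, rdinc=1.0))

    def test_dominates_grid(self):
        for params in (CUT_SELECTED, UNCUT_SELECTED):
            t = np.linspace(0, 1, 10_001)
            r = eval_profile(params, dbh=2.0, cr=0.8, rdinc=t)
            assert largest_crown_radius(params, 2.0, 0.8) >= r.max() - 1e-12


class TestCrownVolume:
    def test_cone(self):
        v = crown_volume(lambda t: 0.3 * t, cl=2.0, region=(0, 1))
        assert v == pytest.approx(np.pi * 0.09 * 2 / 3, rel=1e-8)

    def test_cylinder(self):
        v = crown_volume(lambda t: np.full_like(t, 0.3), cl=2.0, region=(0, 1))
        assert v == pytest.approx(np.pi * 0.09 * 2, rel=1e-8)

    def test_quadrature_refinement(self):
        fn = lambda t: eval_profile(CUT_SELECTED, dbh=2.0, cr=0.8, rdinc=t)
        v1 = crown_volume(fn, cl=2.0, region=(0, 0.8), n=2001)
        v2 = crown_volume(fn, cl=2.0, region=(0, 0.8), n=200_001)
        assert v1 == pytest.approx(v2, rel=1e-8)

    def test_empty_region(self):
        assert crown_volume(lambda t: t, cl=2.0, region=(0.5, 0.5)) == 0.0

    @given(st.floats(0.1, 3.0))
    def test_scales_quadratically_in_radius(self, k):
        v1 = crown_volume(lambda t: 0.2 + 0.1 * t, cl=1.5)
        vk = crown_volume(lambda t: k * (0.2 + 0.1 * t), cl=1.5)
        assert vk == pytest.approx(k ** 2 * v1, rel=1e-9)


def test_crown_metrics_bundle():
    m = crown_metrics(CUT_SELECTED, dbh=2.0, cr=0.80, cl=1.85)
    assert isinstance(m, CrownMetrics)
    assert 0 < m.inflection_rdinc <= 1
    assert m.largest_radius == pytest.approx(0.2290, abs=5e-5)
    assert m.upper_volume > 0


def test_profile_params_json_round_trip():
    text = CUT_SELECTED.to_json()
    assert ProfileParams.from_json(text) == CUT_SELECTED
    assert json.loads(text)["form"] == "power_exp_full"


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ProfileParams("power_exp_full", (1.0, 2.0))
    with pytest.raises(ValueError):
        ProfileParams("nope", (1.0,))


def test_reference_params_selected_rows():
    ref = load_reference_params()
    assert ref["crown_ratio_reference"] == 0.80
    cut = ref["strips"]["shelterwood_cut"]
    assert cut["fits"][cut["selected"]] == CUT_SELECTED
    unc = ref["strips"]["uncut"]
    assert unc["fits"][unc["selected"]] == UNCUT_SELECTED
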