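import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from micellekit import (
    APFO,
    SDS,
    UREA_4M,
    WATER,
    DomainError,
    MicelleRegime,
    ResponseKind,
    TitrationSeries,
    TruthParams,
    cosolvent_count,
    fit_virial,
    gen_viscosity,
    hydration_budget,
    j_from_nu,
    nu_from_j,
    relative_viscosity,
    shape_factor,
)


class TestRelativeViscosity:
    @pytest.mark.parametrize("args, expected", [
        ((100, 100, 0.004, 0.004), 1.0),
        ((110, 100, 0.004, 0.004), 1.1),
        ((105, 100, 0.004, 0.008), 0.525),
    ])
    def test_calibration_arithmetic(self, args, expected):
        assert relative_viscosity(*args) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(DomainError):
            relative_viscosity(0.0, 100.0)


class TestFitVirial:
    def test_noiseless_forward_model_recovered_to_six_figures(self, noiseless_params):
        fit = fit_virial(gen_viscosity(noiseless_params), cmc_mM=26.5, nu=2.97)
        assert fit.v_shyd == pytest.approx(0.710, rel=1e-6)
        assert fit.k1 == pytest.approx(1.0, rel=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(nu=st.floats(min_value=2.5, max_value=6.0),
           v_shyd=st.floats(min_value=0.2, max_value=3.0),
           k1=st.floats(min_value=0.1, max_value=5.0),
           cmc=st.floats(min_value=5.0, max_value=40.0))
    def test_forward_generation_is_self_inverse(self, nu, v_shyd, k1, cmc):
        params = TruthParams(nu=nu, v_shyd=v_shyd, k1=k1, cmc=cmc).noiseless()
        conc = np.linspace(cmc + 5.0, cmc + 150.0, 8)
        fit = fit_virial(gen_viscosity(params, conc), cmc_mM=cmc, nu=nu)
        assert fit.v_shyd == pytest.approx(v_shyd, rel=1e-8)
        assert fit.k1 == pytest.approx(k1, rel=1e-6)

    def test_unit_viscosity_flagged_no_micellar_contribution(self):
        c = np.linspace(30.0, 150.0, 8)
        s = TitrationSeries(c, np.ones_like(c), ResponseKind.RELATIVE_VISCOSITY, 20.0)
        fit = fit_virial(s, cmc_mM=26.5, nu=2.5)
        assert fit.p1 == 0.0 and fit.p2 == 0.0
        assert "no micellar contribution" in fit.flags

    def test_too_few_points_above_cmc_rejected(self):
        c = np.array([10.0, 20.0, 30.0, 40.0])
        s = TitrationSeries(c, np.ones(4) * 1.01, ResponseKind.RELATIVE_VISCOSITY, 20.0)
        with pytest.raises(Exception):
            fit_virial(s, cmc_mM=26.5, nu=2.5)

    def test_case_scenario_vshyd_ratio_is_nu_ratio(self, noiseless_params):
        # the same fitted p1 read under cylindrical (2.97) vs spherical (2.5)
        # shape factors gives Vshyd in the exact ratio 2.97/2.5
        series = gen_viscosity(noiseless_params)
        f_cyl = fit_virial(series, cmc_mM=26.5, nu=2.97)
        f_sph = fit_virial(series, cmc_mM=26.5, nu=2.5)
        assert f_sph.v_shyd / f_cyl.v_shyd == pytest.approx(2.97 / 2.5, rel=1e-12)


class TestShapeFactor:
    def test_sphere_limit_is_exactly_two_and_a_half(self):
        model = shape_factor(1.0)
        assert model.j == 1.0
        assert model.nu == 2.5
        assert model.regime is MicelleRegime.SPHERE

    def test_short_rod_inversion_matches_root_finder(self):
        # invert ν = 2.5 + 0.407 (J−1)^1.508 at ν = 2.97
        j_oracle = brentq(lambda j: nu_from_j(j) - 2.97, 1.0 + 1e-12, 15.0)
        assert j_from_nu(2.97) == pytest.approx(j_oracle, abs=1e-9)
        assert j_from_nu(2.97) == pytest.approx(2.10, abs=0.01)

    def test_long_rod_formula_against_direct_arithmetic(self):
        j = 20.0
        expected = 1.6 + (400.0 / 15.0) * (
            1.0 / (np.log(40.0) - 1.5) + 3.0 / (np.log(40.0) - 0.5))
        assert nu_from_j(j) == pytest.approx(expected, rel=1e-12)

    def test_continuous_at_sphere_limit_and_increasing(self):
        ratios = np.linspace(1.0, 50.0, 200)
        nus = np.array([shape_factor(r).nu for r in ratios])
        assert nus[0] == 2.5
        assert np.all(np.diff(nus) > 0)
        assert shape_factor(1.0 + 1e-9).nu == pytest.approx(2.5, abs=1e-6)

    def test_axial_ratio_below_one_rejected(self):
        with pytest.raises(DomainError):
            shape_factor(0.9)


class TestHydrationBudget:
    def test_apfo_in_water_eleven_waters(self):
        b = hydration_budget(0.710, APFO, WATER)
        assert b.n_water == 11
        assert b.v_water_total == pytest.approx(0.334, abs=1e-12)
        assert b.v_water_total / 0.030 == pytest.approx(11.13, abs=0.01)

    def test_apfo_case_ii_urea_count(self):
        b = hydration_budget(0.910, APFO, UREA_4M, v_water_total_reference=0.334)
        assert b.v_cosolvent_total == pytest.approx(0.200, abs=1e-12)
        assert b.n_cosolvent == 2.7

    def test_sds_urea_count(self):
        b = hydration_budget(2.240, SDS, UREA_4M, v_water_total_reference=1.200)
        assert b.v_cosolvent_total == pytest.approx(0.630, abs=1e-12)
        assert b.n_cosolvent == 8.4

    def test_budget_identity_holds_pre_rounding(self):
        for v_shyd, ref in [(0.710, None), (0.910, 0.334), (2.0, 0.5)]:
            b = hydration_budget(v_shyd, APFO, UREA_4M, v_water_total_reference=ref)
            assert b.v_molecule + b.v_water_total + b.v_cosolvent_total == pytest.approx(
                b.v_shyd, abs=1e-12)

    def test_dehydration_floored_with_warning(self):
        with pytest.warns(UserWarning, match="dehydration"):
            b = hydration_budget(0.5, APFO, UREA_4M, v_water_total_reference=0.334)
        assert b.n_cosolvent == 0.0
        assert "dehydration relative to reference" in b.flags

    def test_hydrated_volume_below_molecular_rejected(self):
        with pytest.raises(DomainError):
            hydration_budget(0.2, APFO, WATER)

    def test_cosolvent_count_one_decimal(self):
        assert cosolvent_count(0.064, 0.075) == 0.9
        assert cosolvent_count(0.204, 0.075) == 2.7
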