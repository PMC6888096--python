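import numpy as np
import pytest

from micellekit import (
    AVOGADRO,
    DomainError,
    TruthParams,
    analyze_tension,
    cmc_from_ratio_curve,
    fit_two_segments,
    fit_virial,
    fluorocarbon_tail,
    gen_conductivity,
    gen_pyrene,
    gen_tension,
    gen_viscosity,
    vibronic_ratio,
)


class TestDeterminism:
    @pytest.mark.parametrize("gen", [gen_conductivity, gen_tension, gen_viscosity])
    def test_same_seed_same_series(self, gen, default_params):
        a = gen(default_params, seed=42)
        b = gen(default_params, seed=42)
        assert np.array_equal(a.response, b.response)

    def test_same_seed_same_ratio_curve(self, default_params):
        a = gen_pyrene(default_params, seed=42)
        b = gen_pyrene(default_params, seed=42)
        assert np.array_equal(a.response, b.response)

    def test_different_seeds_differ(self, default_params):
        a = gen_conductivity(default_params, seed=1)
        b = gen_conductivity(default_params, seed=2)
        assert not np.array_equal(a.response, b.response)


class TestNoiselessInversion:
    """At zero noise each generator is inverted by its paired stage."""

    def test_conductivity(self, noiseless_params):
        fit = fit_two_segments(gen_conductivity(noiseless_params))
        assert fit.cmc == pytest.approx(noiseless_params.cmc, abs=1e-9)
        assert fit.alpha == pytest.approx(noiseless_params.alpha, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_conductivity_simple_grid(self):
        params = TruthParams(cmc=25.0, s1=50.0, alpha=0.5).noiseless()
        fit = fit_two_segments(gen_conductivity(params, np.arange(2.0, 50.1, 2.0)))
        assert (fit.cmc, fit.alpha) == (25.0, pytest.approx(0.5, abs=1e-12))

    def test_tension(self, noiseless_params):
        res = analyze_tension(gen_tension(noiseless_params), n_prefactor=2,
                              tail=fluorocarbon_tail(7))
        assert res.slope == pytest.approx(noiseless_params.tension_slope, abs=1e-9)
        assert res.cmc_tension == pytest.approx(noiseless_params.cmc, rel=1e-9)
        assert res.a_min == pytest.approx(63.84, abs=0.01)

    def test_tension_flat_curve_flagged(self):
        params = TruthParams(tension_slope=0.0, gamma0=72.0).noiseless()
        res = analyze_tension(gen_tension(params))
        assert "non-surface-active" in res.flags

    def test_pyrene_ratio_limits(self, noiseless_params):
        below = gen_pyrene(noiseless_params, np.linspace(1.0, 26.0, 8))
        assert np.allclose(below.response, noiseless_params.ratio_water)
        far = gen_pyrene(noiseless_params, np.array([26.5, 1e4, 2e4, 5e4, 1e5, 1e6]))
        assert far.response[-1] == pytest.approx(noiseless_params.ratio_micelle, abs=1e-3)

    def test_pyrene_spectra_round_trip(self, noiseless_params):
        spectra = gen_pyrene(noiseless_params, full_spectra=True)
        scalar = gen_pyrene(noiseless_params)
        ratios = [vibronic_ratio(s).ratio for s in spectra]
        assert np.allclose(ratios, scalar.response, atol=0.02)

    def test_viscosity_forward_value(self, noiseless_params):
        # direct arithmetic oracle at 150 mM
        s = gen_viscosity(noiseless_params, np.array([30.0, 60.0, 90.0, 120.0, 150.0]))
        phi = 0.710 * AVOGADRO * 1e-24 * (150.0 - 26.5) * 1e-3
        assert phi == pytest.approx(0.0528, abs=0.0001)
        expected = 1.0 + 2.97 * phi + 1.0 * (2.97 * phi) ** 2
        assert s.response[-1] == pytest.approx(expected, rel=1e-12)

    def test_viscosity_is_one_below_cmc(self, noiseless_params):
        s = gen_viscosity(noiseless_params, np.array([5.0, 10.0, 20.0, 26.5, 30.0, 40.0]))
        assert np.all(s.response[s.concentration <= 26.5] == 1.0)

    def test_viscosity_inverted(self, noiseless_params):
        fit = fit_virial(gen_viscosity(noiseless_params), cmc_mM=26.5, nu=2.97)
        assert fit.v_shyd == pytest.approx(0.710, rel=1e-6)


class TestParameterValidation:
    def test_negative_transition_width_rejected(self):
        with pytest.raises(DomainError):
            TruthParams(transition_width=-1.0)

    def test_ratio_ordering_enforced(self):
        with pytest.raises(DomainError):
            TruthParams(ratio_water=1.2, ratio_micelle=1.8)

    def test_inconsistent_tension_plateau_rejected(self):
        params = TruthParams(plateau_gamma=60.0)  # above the descent at the CMC
        with pytest.raises(DomainError):
            gen_tension(params)


def test_smoothed_break_recovered_within_half_width():
    params = TruthParams(transition_width=4.0).noiseless()
    fit = fit_two_segments(gen_conductivity(params))
    assert abs(fit.cmc - params.cmc) <= params.transition_width / 2
    assert "broad transition" in fit.flags
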