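import numpy as np
import pytest

from micellekit import (
    InsufficientDataError,
    ResponseKind,
    TitrationSeries,
    TruthParams,
    fit_two_segments,
    gen_conductivity,
)


def two_segment_oracle(conc, resp):
    """Exhaustive break search with an independent parametrization:
    κ = κ_b + s1·(C−b) on C ≤ b and κ_b + s2·(C−b) on C > b."""
    cands = np.unique(np.concatenate([conc[1:-1], 0.5 * (conc[:-1] + conc[1:])]))
    best = (np.inf, None)
    for b in cands:
        below = conc <= b
        if below.sum() < 3 or (~below).sum() < 3:
            continue
        dx = conc - b
        X = np.column_stack([np.ones_like(conc), np.where(below, dx, 0.0),
                             np.where(below, 0.0, dx)])
        coef, _, _, _ = np.linalg.lstsq(X, resp, rcond=None)
        rss = float(np.sum((resp - X @ coef) ** 2))
        if rss < best[0]:
            best = (rss, float(b))
    return best[1], best[0]


def series(conc, resp):
    return TitrationSeries(np.asarray(conc, float), np.asarray(resp, float),
                           ResponseKind.CONDUCTIVITY, 24.0)


def test_noiseless_piecewise_recovered_exactly():
    c = np.arange(2.0, 50.1, 2.0)
    kappa = np.where(c <= 25.0, 50.0 * c, 1250.0 + 25.0 * (c - 25.0))
    fit = fit_two_segments(series(c, kappa))
    assert fit.cmc == pytest.approx(25.0, abs=1e-9)
    assert fit.alpha == pytest.approx(0.50, abs=1e-12)
    assert fit.rss == pytest.approx(0.0, abs=1e-15)
    assert fit.s1 == pytest.approx(50.0)
    assert fit.s2 == pytest.approx(25.0)


def test_matches_exhaustive_oracle_on_noisy_series():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n = rng.integers(8, 41)
        c = np.sort(rng.uniform(1.0, 50.0, size=n))
        c += np.arange(n) * 1e-6  # enforce strict increase
        cmc = rng.uniform(c[3], c[-4])
        s1 = rng.uniform(20.0, 80.0)
        alpha = rng.uniform(0.2, 0.9)
        kappa = 5.0 + s1 * np.minimum(c, cmc) + alpha * s1 * np.maximum(c - cmc, 0)
        kappa *= 1.0 + 0.01 * rng.standard_normal(n)
        fit = fit_two_segments(series(c, kappa))
        b_o, rss_o = two_segment_oracle(c, kappa)
        assert fit.cmc == pytest.approx(b_o, rel=1e-9)
        assert fit.rss == pytest.approx(rss_o, rel=1e-6)


def test_response_scaling_leaves_cmc_and_alpha_unchanged():
    s = gen_conductivity(TruthParams(seed=3))
    fit = fit_two_segments(s)
    fit_scaled = fit_two_segments(s.scaled(3.7))
    assert fit_scaled.cmc == fit.cmc
    assert fit_scaled.alpha == pytest.approx(fit.alpha, rel=1e-9)
    assert fit_scaled.s1 == pytest.approx(3.7 * fit.s1, rel=1e-9)
    assert fit_scaled.rss == pytest.approx(3.7**2 * fit.rss, rel=1e-6)


def test_constant_offset_leaves_slopes_and_cmc_unchanged():
    s = gen_conductivity(TruthParams(seed=4))
    fit = fit_two_segments(s)
    shifted = TitrationSeries(s.concentration, s.response + 123.0,
                              ResponseKind.CONDUCTIVITY, s.temperature_c)
    fit2 = fit_two_segments(shifted)
    assert fit2.cmc == fit.cmc
    assert fit2.s1 == pytest.approx(fit.s1, rel=1e-9)
    assert fit2.s2 == pytest.approx(fit.s2, rel=1e-9)


def test_alpha_invariant_under_concentration_unit_change():
    s = gen_conductivity(TruthParams(seed=5))
    fit = fit_two_segments(s)
    molar = TitrationSeries(s.concentration * 1e-3, s.response,
                            ResponseKind.CONDUCTIVITY, s.temperature_c)
    assert fit_two_segments(molar).alpha == pytest.approx(fit.alpha, rel=1e-9)


def test_no_break_data_flagged_not_crashed():
    c = np.arange(1.0, 13.0)
    fit = fit_two_segments(series(c, 10.0 + 5.0 * c + np.linspace(0, 0.1, 12)))
    # a pure line has no micellization signature; alpha still reported
    assert np.isfinite(fit.alpha)


def test_increasing_slope_flagged_as_no_micellization():
    c = np.arange(1.0, 13.0)
    kappa = np.where(c <= 6, 10.0 * c, 60.0 + 30.0 * (c - 6))
    fit = fit_two_segments(series(c, kappa))
    assert "no micellization signature" in fit.flags
    assert fit.alpha > 1


def test_too_few_points_is_ill_posed():
    with pytest.raises(InsufficientDataError):
        fit_two_segments(series([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]))


def test_broad_transition_flagged_for_smoothed_break():
    params = TruthParams(transition_width=4.0).noiseless()
    fit = fit_two_segments(gen_conductivity(params))
    assert "broad transition" in fit.flags
    assert fit.cmc == pytest.approx(params.cmc, abs=params.transition_width / 2)


def test_bootstrap_sd_is_reported_and_reproducible():
    s = gen_conductivity(TruthParams(seed=11))
    f1 = fit_two_segments(s, n_bootstrap=50, seed=1)
    f2 = fit_two_segments(s, n_bootstrap=50, seed=1)
    assert f1.cmc_bootstrap_sd == f2.cmc_bootstrap_sd
    assert f1.cmc_bootstrap_sd >= 0
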