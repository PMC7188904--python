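"""Log-normal CE-response analytics, fitting, CE selection and spectra."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from lipidbench.ce import (
    CEModelParams,
    CEProfile,
    FitResult,
    InstrumentConfig,
    ce_response,
    fit_ce_profile,
    load_instruments,
    lognormal_density,
    model_aic,
    model_mse,
    optimal_collision_energy,
    predict_spectrum,
)
from lipidbench.fixtures import SimulationConfig, draw_true_params, simulate_ce_profile


def test_lognormal_density_analytics():
    assert lognormal_density(1.0, 0.0, 1.0) == pytest.approx(
        1.0 / math.sqrt(2 * math.pi), abs=1e-9
    )
    # closed-form argmax at exp(mu - sigma^2)
    mu, sigma = 3.0, 0.3
    xs = np.linspace(0.1, 100, 200000)
    argmax = xs[np.argmax(lognormal_density(xs, mu, sigma))]
    assert argmax == pytest.approx(math.exp(mu - sigma**2), rel=1e-3)
    # unit integral (quadrature oracle)
    integral, _ = quad(lambda x: lognormal_density(x, 3.0, 0.3), 1e-9, 200)
    assert integral == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ValueError):
        lognormal_density(0.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        lognormal_density(1.0, 0.0, -1.0)


def test_ce_response_shift_and_rescale():
    p = CEModelParams(mu=0.0, sigma=1.0, s=3.0, delta=-1.0)
    assert ce_response(2.0, p) == pytest.approx(
        3.0 * lognormal_density(1.0, 0.0, 1.0), abs=1e-9
    )
    ident = CEModelParams(mu=2.0, sigma=0.4, s=1.0, delta=0.0)
    xs = np.linspace(1, 40, 50)
    assert np.allclose(ce_response(xs, ident), lognormal_density(xs, 2.0, 0.4))
    assert CEModelParams(3.0, 0.5, 1.0, 0.0).mode == pytest.approx(
        math.exp(2.75), abs=1e-3
    )


def test_ce_response_left_of_front_is_zero_with_warning():
    p = CEModelParams(mu=3.0, sigma=0.5, s=1.0, delta=-20.0)
    with pytest.warns(UserWarning, match="front"):
        vals = ce_response(np.array([10.0, 30.0]), p)
    assert vals[0] == 0.0 and vals[1] > 0


def test_noiseless_fit_recovers_parameters_exactly():
    truth = CEModelParams(3.2, 0.45, 5.0, -6.0)
    cfg = SimulationConfig(seed=1, noise_sd=0.0, reps_per_ce=1)
    fit = fit_ce_profile(simulate_ce_profile(truth, cfg), seed=0)
    for name in ("mu", "sigma", "s", "delta"):
        assert getattr(fit.params, name) == pytest.approx(
            getattr(truth, name), rel=1e-3
        )


def test_noisy_fit_within_five_percent():
    truth = CEModelParams(3.2, 0.45, 5.0, -6.0)
    cfg = SimulationConfig(seed=7, noise_sd=0.01, reps_per_ce=16)
    fit = fit_ce_profile(simulate_ce_profile(truth, cfg), seed=0)
    for name in ("mu", "sigma", "s", "delta"):
        rel = abs(getattr(fit.params, name) - getattr(truth, name)) / abs(
            getattr(truth, name)
        )
        assert rel < 0.05, name


def test_fit_determinism():
    truth = CEModelParams(3.0, 0.5, 4.0, -5.0)
    cfg = SimulationConfig(seed=3, noise_sd=0.02, reps_per_ce=4)
    prof = simulate_ce_profile(truth, cfg)
    a = fit_ce_profile(prof, seed=11)
    b = fit_ce_profile(prof, seed=11)
    assert a.params == b.params and a.aic == b.aic


def test_fit_requires_eight_distinct_ce():
    obs = [(float(ce), 0.1) for ce in range(10, 17) for _ in range(3)]
    prof = CEProfile("l", "f", obs)
    with pytest.raises(ValueError, match="8"):
        fit_ce_profile(prof)


def test_model_mse_conventions():
    assert model_mse(0.0, 50) == 0.0
    assert model_mse(0.9, 50) == pytest.approx(0.02)
    lit, alt = model_mse(0.9, 50, convention="literal"), model_mse(
        0.9, 50, convention="per-parameter"
    )
    assert lit / alt == pytest.approx((50 - 4) / (50 - 5))
    with pytest.raises(ValueError):
        model_mse(1.0, 5)


def test_aic_prefers_lower_ssr_at_equal_k():
    assert model_aic(0.5, 100) < model_aic(1.0, 100)


def _mk_fit(params, fragment="f", mz=None):
    return FitResult(
        lipid="l",
        fragment=fragment,
        params=params,
        aic=0.0,
        mse=0.0,
        ssr=0.0,
        n_points=10,
        residuals=np.zeros(1),
        fragment_mz=mz,
    )


@pytest.fixture(scope="module")
def hcd():
    return load_instruments()["hcd-orbitrap-nce"]


def test_optimal_ce_single_fragment_is_analytic_mode(hcd):
    p = CEModelParams(3.4, 0.5, 5.0, -3.0)
    ce = optimal_collision_energy([_mk_fit(p)], hcd)
    assert abs(ce - p.mode) <= hcd.step / 10 + 1e-9


def test_optimal_ce_two_identical_models_unchanged(hcd):
    p = CEModelParams(3.4, 0.5, 5.0, -3.0)
    one = optimal_collision_energy([_mk_fit(p, "a")], hcd)
    two = optimal_collision_energy([_mk_fit(p, "a"), _mk_fit(p, "b")], hcd)
    assert one == two


def test_optimal_ce_product_between_modes_matches_dense_grid(hcd):
    # equal sigma and s, modes ~20 and ~30
    sigma, s = 0.4, 5.0
    pa = CEModelParams(math.log(25.0) + sigma**2, sigma, s, 5.0)
    pb = CEModelParams(math.log(35.0) + sigma**2, sigma, s, 5.0)
    assert pa.mode == pytest.approx(20.0, abs=1e-9)
    models = [_mk_fit(pa, "a"), _mk_fit(pb, "b")]
    ce = optimal_collision_energy(models, hcd)
    assert 20.0 < ce < 30.0
    # 10,000-point brute-force oracle
    grid = np.linspace(10, 60, 10_000)
    prod = ce_response(grid, pa) * ce_response(grid, pb)
    assert abs(ce - grid[np.argmax(prod)]) <= hcd.step / 10 + (50 / 10_000)


def test_optimal_ce_random_pairs_match_oracle(hcd):
    rng = np.random.default_rng(42)
    for _ in range(100):
        pa, pb = draw_true_params(rng), draw_true_params(rng)
        models = [_mk_fit(pa, "a"), _mk_fit(pb, "b")]
        ce = optimal_collision_energy(models, hcd)
        grid = np.linspace(*hcd.ce_range, 60_000)
        prod = ce_response(grid, pa) * ce_response(grid, pb)
        oracle = max(grid[np.argmax(prod)], hcd.min_reporting_ce)
        assert abs(ce - oracle) <= hcd.step / 10 + 1e-3


def test_optimal_ce_clips_to_min_reporting(hcd):
    # profile peaking below the reporting floor gets clipped up to it
    p = CEModelParams(math.log(12.0) + 0.25, 0.5, 5.0, 0.0)
    assert p.mode == pytest.approx(12.0)
    assert optimal_collision_energy([_mk_fit(p)], hcd) == hcd.min_reporting_ce


def test_optimal_ce_empty_selection_rejected(hcd):
    with pytest.raises(ValueError):
        optimal_collision_energy([], hcd)
    with pytest.raises(ValueError):
        optimal_collision_energy(
            [_mk_fit(CEModelParams(3, 0.5, 1, 0), "a")], hcd, selected=["zzz"]
        )


def test_predict_spectrum_normalization(hcd):
    pa = CEModelParams(3.4, 0.5, 5.0, -3.0)
    pb = CEModelParams(3.1, 0.45, 2.0, -2.0)
    models = [_mk_fit(pa, "a", 184.07), _mk_fit(pb, "b", 577.52)]
    ce = pa.mode
    spec = predict_spectrum(models, ce, hcd)
    by = {name: rel for name, _, rel in spec}
    assert by["a"] == pytest.approx(1.0)
    # brute-force: direct kernel evaluation then max-normalization
    raw = np.array([float(ce_response(ce, pa)), float(ce_response(ce, pb))])
    assert by["b"] == pytest.approx(raw[1] / raw.max(), abs=1e-12)
    # all-equal models give a flat spectrum
    flat = predict_spectrum([_mk_fit(pa, "x"), _mk_fit(pa, "y")], ce, hcd)
    assert all(rel == pytest.approx(1.0) for _, _, rel in flat)


def test_predict_spectrum_respects_reporting_floor(hcd):
    models = [_mk_fit(CEModelParams(3.4, 0.5, 5.0, -3.0))]
    with pytest.raises(ValueError, match="minimum reporting"):
        predict_spectrum(models, hcd.min_reporting_ce - 1, hcd)
    with pytest.raises(ValueError, match="range"):
        predict_spectrum(models, 200.0, hcd)


def test_shipped_instrument_profiles():
    table = load_instruments()
    hcd = table["hcd-orbitrap-nce"]
    assert hcd.ce_range == (10.0, 60.0) and hcd.min_reporting_ce == 18.0
    qtof = table["cid-qtof-volts"]
    assert qtof.ce_range == (10.0, 100.0) and qtof.ce_unit == "volts"
    with pytest.raises(ValueError):
        InstrumentConfig("bad", "NCE", (10.0, 60.0), 1.0, 5.0)


def test_shapiro_wilk_passes_for_well_specified_fits():
    """Standardized residuals of well-specified fits look normal: SW p > 0.01
    in >= 95% of seeded runs (noise window chosen so clipping never fires)."""
    truth = CEModelParams(3.4, 0.5, 5.0, -5.0)  # mode ~28.3, peak ~0.43
    lo, hi = 20.0, 40.0  # response stays >= 5*noise_sd on this window
    passes = 0
    runs = 200
    for i in range(runs):
        cfg = SimulationConfig(
            seed=20_000 + i, ce_min=lo, ce_max=hi, noise_sd=0.02, reps_per_ce=4
        )
        prof = simulate_ce_profile(truth, cfg)
        assert min(y for _, y in prof.observations) > 0.0  # no clipping
        fit = fit_ce_profile(prof, n_starts=2, seed=i)
        if fit.shapiro_wilk_p > 0.01:
            passes += 1
    assert passes / runs >= 0.95
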