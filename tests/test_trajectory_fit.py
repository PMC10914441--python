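"""Fitting contracts: exact interpolation, oracle agreement, gates, BIC
selection, fallback, and confidence-band geometry/scaling."""

import numpy as np
import pytest

import brainstages as bs
from brainstages.trajectory_fit import FitError, fit_constant

from oracles import exact_ols


def _poly(ages, coefs):
    return np.polynomial.polynomial.polyval(np.asarray(ages, float), coefs)


def test_exact_linear_data_is_interpolated_to_machine_precision():
    ages = np.linspace(1, 100, 40)
    cand = bs.fit_polynomial(ages, 1.0 + 2.0 * ages, 1)
    np.testing.assert_allclose(cand.coefficients, [1.0, 2.0], rtol=1e-10)
    assert cand.rss == pytest.approx(0.0, abs=1e-16)


def test_fit_matches_exact_normal_equations_oracle(rng):
    for _ in range(10):
        n = int(rng.integers(20, 80))
        deg = int(rng.integers(1, 4))
        ages = rng.uniform(1, 100, n)
        y = _poly(ages / 50 - 1, rng.normal(0, 1, deg + 1)) + rng.normal(0, 1, n)
        cand = bs.fit_polynomial(ages, y, deg)
        coefs, se, pvals, f_p, rss, bic = exact_ols(ages, y, deg)
        np.testing.assert_allclose(cand.coefficients, coefs, rtol=1e-8)
        np.testing.assert_allclose(cand.coefficient_se, se, rtol=1e-8)
        np.testing.assert_allclose(cand.coefficient_p, pvals, rtol=1e-8, atol=1e-300)
        assert cand.f_p == pytest.approx(f_p, rel=1e-8, abs=1e-300)
        assert cand.rss == pytest.approx(rss, rel=1e-8)
        assert cand.bic == pytest.approx(bic, rel=1e-8, abs=1e-8)


@pytest.mark.parametrize("degree", [1, 2, 3])
def test_too_few_points_is_an_error(degree):
    ages = np.arange(degree + 1, dtype=float)
    with pytest.raises(FitError):
        bs.fit_polynomial(ages, ages, degree)


def test_zero_age_spread_is_an_error():
    with pytest.raises(FitError):
        bs.fit_polynomial(np.full(10, 50.0), np.arange(10.0), 1)


# ------------------------------------------------------------ model selection

def _candidate(degree, bic, eligible):
    k = degree + 1
    return bs.FitCandidate(
        degree=degree, coefficients=np.zeros(k), coefficient_se=np.ones(k),
        coefficient_p=np.full(k, 0.01 if eligible else 0.5), f_p=0.01,
        rss=1.0, n=100, k_params=degree + 2, bic=bic, eligible=eligible,
        cov=np.eye(k),
    )


def test_only_eligible_candidates_can_win_regardless_of_bic():
    linear = _candidate(1, bic=10.0, eligible=True)
    cubic = _candidate(3, bic=-50.0, eligible=False)
    assert bs.select_model([linear, cubic]) is linear
    assert bs.select_model([_candidate(1, 0.0, False)]) is None


def test_bic_ties_break_toward_the_lower_degree():
    a, b = _candidate(1, bic=5.0, eligible=True), _candidate(2, bic=5.0, eligible=True)
    assert bs.select_model([b, a]).degree == 1


def test_pure_noise_falls_back_to_constant_model(rng):
    ages = rng.uniform(1, 100, 50)
    model = bs.fit_trajectory(ages, rng.normal(0, 1, 50), "s", "control")
    assert model.degree == 0
    assert not model.selected.eligible


def test_adding_a_useless_regressor_increases_bic_on_average(rng):
    diffs = []
    for _ in range(50):
        ages = rng.uniform(1, 100, 200)
        y = 0.5 + 0.02 * ages + rng.normal(0, 1, 200)
        diffs.append(bs.fit_polynomial(ages, y, 2).bic - bs.fit_polynomial(ages, y, 1).bic)
    assert np.mean(diffs) > 0


# ------------------------------------------------------------------- bands

def _fitted_model(rng, n=300, noise=0.8):
    ages = rng.uniform(1, 100, n)
    y = _poly(ages, (0.3, 0.04, -0.0006)) + rng.normal(0, noise, n)
    cand = bs.fit_polynomial(ages, y, 2)
    return bs.TrajectoryModel("s", "control", cand, ages.min(), ages.max())


def test_band_is_symmetric_and_ordered(rng):
    model = _fitted_model(rng)
    grid = np.linspace(model.age_min, model.age_max, 50)
    band = bs.confidence_band(model, grid)
    np.testing.assert_allclose(band.upper - band.mean, band.mean - band.lower, rtol=1e-10)
    assert (band.lower < band.mean).all() and (band.mean < band.upper).all()


def test_observation_band_contains_mean_band(rng):
    model = _fitted_model(rng)
    grid = np.linspace(model.age_min, model.age_max, 20)
    mean_b = bs.confidence_band(model, grid, mode="mean")
    obs_b = bs.confidence_band(model, grid, mode="observation")
    assert (obs_b.upper > mean_b.upper).all() and (obs_b.lower < mean_b.lower).all()


def test_grid_outside_training_window_is_an_error_listing_ages(rng):
    model = _fitted_model(rng)
    with pytest.raises(ValueError, match="outside"):
        bs.confidence_band(model, [model.age_max + 10.0])
    # the same age is fine once the extrapolation window covers it
    bs.confidence_band(model, [model.age_max + 10.0], extrapolation=10.0)


def test_band_halfwidth_shrinks_like_one_over_sqrt_n(rng):
    ages = rng.uniform(1, 100, 4000)
    y = _poly(ages, (0.3, 0.04, -0.0006)) + rng.normal(0, 0.8, 4000)

    def halfwidth(k):
        cand = bs.fit_polynomial(ages[:k], y[:k], 2)
        m = bs.TrajectoryModel("s", "control", cand, 1.0, 100.0)
        b = bs.confidence_band(m, [50.0], extrapolation=5.0)
        return (b.upper - b.lower)[0]

    ratio = halfwidth(1000) / halfwidth(4000)
    assert 1.6 < ratio < 2.5  # ideal ratio 2


def test_models_round_trip_through_json(tmp_path, rng):
    model = _fitted_model(rng)
    path = tmp_path / "models.json"
    bs.save_models([model], path)
    back = bs.load_models(path)[0]
    np.testing.assert_allclose(back.selected.coefficients, model.selected.coefficients)
    np.testing.assert_allclose(back.selected.cov, model.selected.cov)
    grid = np.linspace(1, 100, 17)
    np.testing.assert_allclose(back.predict(grid), model.predict(grid))


def test_constant_fallback_reports_sample_mean(rng):
    vals = rng.normal(2.0, 1.0, 40)
    cand = fit_constant(np.arange(40.0) + 1, vals)
    assert cand.degree == 0
    assert cand.coefficients[0] == pytest.approx(vals.mean())
    assert cand.k_params == 2
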