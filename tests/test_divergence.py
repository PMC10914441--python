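"""Divergence contracts: distance curves, onset rules, directions, and the
hinge-recovery behaviour of the fitted distance."""

import numpy as np
import pytest

import brainstages as bs
from brainstages.divergence import detect_divergence, distance_at_reference
from brainstages.trajectory_fit import Band, FitCandidate, TrajectoryModel

from oracles import sustained_onset_by_hand

GRID = np.arange(1.0, 91.0, 0.5)


def _const_model(name, value, se=0.05, n=100):
    cand = FitCandidate(
        degree=0, coefficients=np.array([value]), coefficient_se=np.array([se]),
        coefficient_p=np.array([0.5]), f_p=np.nan, rss=(n - 1) * se**2 * n,
        n=n, k_params=2, bic=0.0, eligible=False, cov=np.array([[se**2]]),
    )
    return TrajectoryModel(name, "control", cand, 1.0, 100.0)


def test_identical_models_give_zero_curve_and_no_divergence():
    m = _const_model("thalamus", 0.0)
    assert (bs.distance_curve(m, m, GRID) == 0.0).all()
    r = bs.analyse_structure(m, m, GRID)
    assert not r.diverged and r.onset_age is None and r.direction == "none"
    assert r.distance_at_ref == 0.0


def test_constant_offset_models_have_constant_distance():
    h = _const_model("thalamus", 0.0)
    d = _const_model("thalamus", -1.0)
    np.testing.assert_allclose(bs.distance_curve(h, d, GRID), 1.0)
    assert distance_at_reference(h, d, 90.0) == pytest.approx(1.0)


def test_structure_mismatch_is_an_error():
    with pytest.raises(ValueError, match="mismatch"):
        bs.distance_curve(_const_model("a", 0.0), _const_model("b", 0.0), GRID)


def test_full_separation_reports_onset_at_first_grid_age():
    h = _const_model("s", 0.0, se=0.01)
    d = _const_model("s", -1.0, se=0.01)
    r = bs.analyse_structure(h, d, GRID)
    assert r.diverged and r.direction == "case_smaller"
    assert r.onset_age == GRID[0]


def test_case_larger_direction_is_detected_but_distinct():
    h = _const_model("s", 0.0, se=0.01)
    d = _const_model("s", +1.0, se=0.01)
    r = bs.analyse_structure(h, d, GRID)
    assert r.diverged and r.direction == "case_larger"
    assert r.distance_at_ref == pytest.approx(-1.0)


def _bands_from_gap(gap):
    """Build a band pair whose separation pattern follows `gap` (>0 means
    the disease upper bound sits below the healthy lower bound)."""
    grid = np.arange(len(gap), dtype=float) + 1
    h = Band(grid, np.zeros_like(grid), np.zeros_like(grid) + 0.1,
             np.zeros_like(grid) + 0.2, 0.95, "mean")
    dis_upper = np.where(np.asarray(gap) > 0, -0.1, 0.1)
    d = Band(grid, dis_upper - 0.2, dis_upper - 0.1, dis_upper, 0.95, "mean")
    return h, d, grid


def test_sustained_rule_ignores_transient_early_crossings():
    gap = [0, 1, 0, 1, 1, 1]
    h, d, grid = _bands_from_gap(gap)
    sustained = detect_divergence(h, d, "s", rule="sustained")
    first = detect_divergence(h, d, "s", rule="first")
    assert sustained.onset_age == grid[3]
    assert first.onset_age == grid[1]
    assert sustained.onset_age == sustained_onset_by_hand(h.lower, d.upper, grid)


def test_separation_not_reaching_grid_end_is_not_sustained_divergence():
    h, d, _ = _bands_from_gap([0, 1, 1, 0])
    assert not detect_divergence(h, d, "s", rule="sustained").diverged
    assert detect_divergence(h, d, "s", rule="first").diverged


def test_mismatched_grids_are_rejected():
    h, d, _ = _bands_from_gap([1, 1, 1])
    d2 = Band(d.ages + 0.5, d.lower, d.mean, d.upper, 0.95, "mean")
    with pytest.raises(ValueError, match="grid"):
        detect_divergence(h, d2, "s")


def test_reference_age_outside_grid_is_an_error():
    h = _const_model("s", 0.0)
    d = _const_model("s", -1.0)
    with pytest.raises(ValueError, match="reference age"):
        distance_at_reference(h, d, 120.0, grid=GRID)


def test_fitted_distance_tracks_the_true_hinge_up_to_smoothing_floor(rng):
    """The fitted healthy-minus-disease curve recovers a hinge deficit
    (onset 60, 0.1 z/yr) up to the error floor of approximating a kink with
    cubic polynomials: largest error at the kink itself, small elsewhere."""
    coefs = (0.124, 0.028, -0.00051)
    a_c = rng.uniform(1, 100, 50000)
    y_c = np.polynomial.polynomial.polyval(a_c, coefs) + rng.normal(0, 0.05, 50000)
    a_d = rng.uniform(55, 86, 5000)
    y_d = (np.polynomial.polynomial.polyval(a_d, coefs)
           - 0.1 * np.maximum(0, a_d - 60) + rng.normal(0, 0.05, 5000))
    keep = a_c < 55
    healthy = bs.fit_trajectory(a_c, y_c, "s", "control")
    disease = bs.fit_trajectory(np.concatenate([a_c[keep], a_d]),
                                np.concatenate([y_c[keep], y_d]), "s", "case")
    grid = np.arange(1.0, 86.5, 0.5)
    err = bs.distance_curve(healthy, disease, grid) - 0.1 * np.maximum(0, grid - 60)
    assert np.max(np.abs(err)) < 0.4
    away_from_kink = np.abs(grid - 60.0) > 10
    assert np.max(np.abs(err[away_from_kink])) < 0.25
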