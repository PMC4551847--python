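import numpy as np
import pandas as pd
import pytest

from lmmspline import (SplineBasis, TimeCourseExperiment, derivative,
                       fit_model, knot_count, model_all, predict_curve,
                       select_model, truncated_line_basis)
from conftest import simulate_profiles

TIMES6 = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)


@pytest.mark.parametrize("T,expected", [(6, 5), (24, 6), (200, 40),
                                        (2, 5), (160, 40)])
def test_knot_count_rule(T, expected):
    assert knot_count(T) == expected


def test_knot_count_rejects_single_time():
    with pytest.raises(ValueError):
        knot_count(1)


def test_truncated_line_basis_values():
    np.testing.assert_allclose(truncated_line_basis(5.0, (2, 4, 6))[0],
                               [3.0, 1.0, 0.0])
    # at a knot the component is exactly zero
    assert truncated_line_basis(4.0, (2, 4, 6))[0][1] == 0.0
    # below all knots: zero vector
    np.testing.assert_array_equal(truncated_line_basis(1.0, (2, 4, 6))[0],
                                  [0.0, 0.0, 0.0])


def test_basis_knots_interior_and_sorted():
    t = np.tile(TIMES6, 10)
    basis = SplineBasis.from_times(t)
    knots = np.asarray(basis.knots)
    assert np.all(np.diff(knots) > 0)
    assert knots.min() > min(TIMES6) and knots.max() < max(TIMES6)


def _line_profile(n_subj=4, noise=0.0, seed=0):
    return simulate_profiles(1, n_subj, TIMES6, lambda t: 2.0 + 3.0 * t,
                             noise, seed)


def test_noiseless_line_class0():
    fit = fit_model(_line_profile(), 0)
    assert fit.beta0 == pytest.approx(2.0, abs=1e-9)
    assert fit.beta1 == pytest.approx(3.0, abs=1e-9)
    assert fit.sigma2_eps == pytest.approx(0.0, abs=1e-12)


def test_noiseless_line_class1_has_null_spline():
    fit = fit_model(_line_profile(), 1)
    assert np.max(np.abs(fit.u)) < 1e-6
    t = np.linspace(0, 5, 50)
    np.testing.assert_allclose(predict_curve(fit, t), 2.0 + 3.0 * t,
                               atol=1e-6)


def test_class1_matches_penalized_least_squares_oracle():
    """The mixed-model spline equals ridge regression at lambda =
    sigma_eps^2 / sigma_u^2 (independent direct solve)."""
    prof = simulate_profiles(1, 6, TIMES6,
                             lambda t: np.sin(1.2 * t) + 0.5 * t,
                             0.2, seed=42)
    fit = fit_model(prof, 1)
    assert fit.sigma2_u > 0
    lam = fit.sigma2_eps / fit.sigma2_u
    t = prof["time"].to_numpy(float)
    y = prof["value"].to_numpy(float)
    C = np.column_stack([np.ones_like(t), t, fit.basis.design(t)])
    P = np.zeros(C.shape[1])
    P[2:] = lam
    coef = np.linalg.solve(C.T @ C + np.diag(P), C.T @ y)
    assert fit.beta0 == pytest.approx(coef[0], abs=1e-6)
    assert fit.beta1 == pytest.approx(coef[1], abs=1e-6)
    np.testing.assert_allclose(fit.u, coef[2:], atol=1e-6)


@pytest.mark.parametrize("model_class", [1, 2, 3])
def test_derivative_matches_finite_differences(model_class):
    prof = simulate_profiles(1, 6, TIMES6,
                             lambda t: np.sin(1.3 * t) + 0.3 * t,
                             0.15, seed=model_class, subject_sd=0.4)
    fit = fit_model(prof, model_class)
    knots = np.asarray(fit.basis.knots)
    grid = np.linspace(0.05, 4.95, 301)
    # stay away from knots so the two-sided difference is exact
    grid = grid[np.min(np.abs(grid[:, None] - knots[None, :]), axis=1)
                > 0.02]
    eps = 1e-6
    fd = (predict_curve(fit, grid + eps)
          - predict_curve(fit, grid - eps)) / (2 * eps)
    np.testing.assert_allclose(derivative(fit, grid), fd, atol=1e-6)


def test_derivative_piecewise_limits():
    prof = simulate_profiles(1, 5, TIMES6, lambda t: np.sin(t), 0.1,
                             seed=1)
    fit = fit_model(prof, 1)
    knots = np.asarray(fit.basis.knots)
    assert derivative(fit, knots.min() - 0.5)[0] == pytest.approx(fit.beta1)
    assert derivative(fit, knots.max() + 0.5)[0] == \
        pytest.approx(fit.beta1 + fit.u.sum())
    fit0 = fit_model(prof, 0)
    np.testing.assert_allclose(derivative(fit0, np.linspace(0, 5, 7)),
                               fit0.beta1)


def test_curve_continuity_at_knots():
    prof = simulate_profiles(1, 5, TIMES6, lambda t: np.cos(t), 0.1,
                             seed=2)
    fit = fit_model(prof, 1)
    for k in fit.basis.knots:
        eps = 1e-9
        left, right = predict_curve(fit, [k - eps, k + eps])
        assert abs(left - right) < 1e-6


def test_prediction_below_first_knot_is_linear():
    prof = simulate_profiles(1, 5, TIMES6, lambda t: np.cos(t), 0.1,
                             seed=3)
    fit = fit_model(prof, 1)
    t0 = min(fit.basis.knots) - 0.3
    assert predict_curve(fit, t0)[0] == pytest.approx(
        fit.beta0 + fit.beta1 * t0)


def test_loglik_monotone_in_model_class():
    for seed in range(8):
        prof = simulate_profiles(1, 6, TIMES6,
                                 lambda t: 0.5 * t + np.sin(t), 0.3,
                                 seed=seed, subject_sd=0.5)
        lls = []
        for cls in range(4):
            fit = fit_model(prof, cls)
            if fit.converged:
                lls.append(fit.loglik_ml)
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))


def test_serial_selection_recovers_planted_classes():
    """Reduced-replicate version of the three planted scenarios."""
    n_rep = 40
    hits0 = hits1 = hits2 = 0
    for r in range(n_rep):
        line = simulate_profiles(1, 10, TIMES6, lambda t: 1.0 + 0.5 * t,
                                 0.05, seed=r)
        if select_model(line).chosen.model_class == 0:
            hits0 += 1
        curved = simulate_profiles(1, 10, TIMES6,
                                   lambda t: np.sin(1.5 * t), 0.05,
                                   seed=1000 + r)
        if select_model(curved).chosen.model_class == 1:
            hits1 += 1
        shifted = simulate_profiles(1, 10, TIMES6,
                                    lambda t: np.sin(1.5 * t), 0.1,
                                    seed=2000 + r, subject_sd=0.5)
        if select_model(shifted).chosen.model_class >= 2:
            hits2 += 1
    assert hits0 / n_rep >= 0.9
    assert hits1 / n_rep >= 0.9
    assert hits2 / n_rep >= 0.9


def test_selection_steps_are_consistent():
    prof = simulate_profiles(1, 8, TIMES6, lambda t: np.sin(1.5 * t),
                             0.05, seed=5)
    sel = select_model(prof)
    # chosen class is the last accepted alternative (or 0)
    accepted = [alt for (_, alt, _, _, p) in sel.steps if p < sel.alpha]
    expected = accepted[-1] if accepted else 0
    if sel.steps and sel.steps[-1][4] < sel.alpha:
        expected = sel.steps[-1][1]
    assert sel.chosen.model_class == expected


def _experiment_from_long(long: pd.DataFrame) -> TimeCourseExperiment:
    long = long.copy()
    long["sample"] = long["subject"] + "_" + long["time"].astype(str)
    values = long.pivot_table(index="molecule", columns="sample",
                              values="value")
    samples = (long[["sample", "subject", "time"]]
               .drop_duplicates("sample").set_index("sample"))
    return TimeCourseExperiment(values.loc[:, samples.index], samples)


def test_model_all_linear_data_concentrates_on_lin():
    long = simulate_profiles(20, 8, TIMES6, lambda t: 1.0 - 0.8 * t,
                             0.05, seed=9)
    exp = _experiment_from_long(long)
    out = model_all(exp)
    assert out.class_counts["LIN"] >= 18
    # default grid is the sorted distinct observed times
    np.testing.assert_array_equal(out.curves.columns.to_numpy(float),
                                  np.asarray(TIMES6))
    assert not out.failed


def test_single_subject_never_gets_subject_effects():
    long = simulate_profiles(3, 1, tuple(np.linspace(0, 5, 12)),
                             lambda t: np.sin(t), 0.1, seed=4)
    exp = _experiment_from_long(long)
    out = model_all(exp)
    assert all(sel.chosen.model_class <= 1
               for sel in out.selections.values())
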