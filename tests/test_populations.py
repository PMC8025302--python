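"""E*/S arithmetic, bivariate Gaussian fitting and probabilistic assignment."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from smalex import (
    PopulationFit,
    assign_probabilities,
    compute_es,
    es_points,
    fit_populations,
    simulate_bursts,
)
from smalex.populations import FitError

from conftest import make_config


# ------------------------------------------------------------ compute_es

@pytest.mark.parametrize(
    "counts, e, s",
    [
        ((60, 40, 100), 0.40, 0.50),
        ((26, 74, 100), 0.74, 0.50),
        ((100, 0, 50), 0.0, 2 / 3),
    ],
)
def test_es_ratios_exact(counts, e, s):
    pt = compute_es(*counts)
    assert pt.e_app == pytest.approx(e)
    assert pt.s_app == pytest.approx(s)
    assert pt.n_dexc == counts[0] + counts[1]


def test_zero_denominator_is_flagged_not_nan():
    with pytest.raises(FitError):
        compute_es(0, 0, 100)


def test_es_points_drops_nonfinite_rows():
    import pandas as pd
    df = pd.DataFrame({"e_app": [0.5, np.nan], "s_app": [0.5, 0.4]})
    assert es_points(df).shape == (1, 2)


# ------------------------------------------------------------ fitting

def _gaussian_sample(rng, n, mu_e, mu_s, w_e, w_s, rho):
    cov = [[w_e**2, rho * w_e * w_s], [rho * w_e * w_s, w_s**2]]
    return rng.multivariate_normal([mu_e, mu_s], cov, size=n)


def test_single_population_recovery_within_2se():
    rng = np.random.default_rng(0)
    pts = _gaussian_sample(rng, 5000, 0.33, 0.45, 0.04, 0.04, 0.0)
    fit = fit_populations(pts, 1, seed=0)[0]
    se = 0.04 / np.sqrt(5000)
    assert abs(fit.mu_e - 0.33) < 2 * se * 2  # 2 SE with slack for width error
    assert abs(fit.mu_s - 0.45) < 2 * se * 2
    assert fit.w_e == pytest.approx(0.04, rel=0.1)


def test_correlated_population_recovers_rho():
    rng = np.random.default_rng(1)
    pts = _gaussian_sample(rng, 8000, 0.5, 0.5, 0.05, 0.03, 0.6)
    fit = fit_populations(pts, 1, seed=0)[0]
    assert fit.rho == pytest.approx(0.6, abs=0.05)


def test_two_well_separated_populations_recovered():
    # the apo/holo state pair: generating E* 0.58 and 0.74
    cfg_a = make_config(e_app=0.58, seed=2)
    cfg_b = make_config(e_app=0.74, seed=3)
    ta, _ = simulate_bursts(cfg_a, 5000)
    tb, _ = simulate_bursts(cfg_b, 5000)
    pts = np.vstack([es_points(ta), es_points(tb)])
    fit = fit_populations(pts, 2, seed=0)
    assert fit[0].mu_e == pytest.approx(0.58, abs=0.01)
    assert fit[1].mu_e == pytest.approx(0.74, abs=0.01)
    assert fit[0].weight == pytest.approx(0.5, abs=0.03)


def test_degenerate_identical_points_fail_loudly():
    pts = np.tile([0.5, 0.5], (200, 1))
    with pytest.raises(FitError):
        fit_populations(pts, 1)


def test_too_few_points_rejected():
    with pytest.raises(FitError):
        fit_populations(np.random.default_rng(0).random((30, 2)), 1)


def test_fit_invariant_to_point_order():
    rng = np.random.default_rng(4)
    pts = _gaussian_sample(rng, 3000, 0.4, 0.5, 0.05, 0.05, 0.0)
    f1 = fit_populations(pts, 1, seed=0)[0]
    f2 = fit_populations(pts[::-1], 1, seed=0)[0]
    assert f1.mu_e == pytest.approx(f2.mu_e, abs=1e-9)
    assert f1.w_s == pytest.approx(f2.w_s, abs=1e-9)


def test_fit_axis_swap_transposes_parameters():
    rng = np.random.default_rng(5)
    pts = _gaussian_sample(rng, 3000, 0.3, 0.6, 0.03, 0.07, 0.2)
    f = fit_populations(pts, 1, seed=0)[0]
    g = fit_populations(pts[:, ::-1], 1, seed=0)[0]
    assert g.mu_e == pytest.approx(f.mu_s, abs=1e-9)
    assert g.w_e == pytest.approx(f.w_s, abs=1e-9)
    assert g.rho == pytest.approx(f.rho, abs=1e-9)


def test_parameter_recovery_median_error_below_half_percent():
    # over 20 seeded replicates of 5000 points, median |mu_E error| < 0.005
    errs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        pts = _gaussian_sample(rng, 5000, 0.58, 0.5, 0.05, 0.05, 0.0)
        fit = fit_populations(pts, 1, seed=0)[0]
        errs.append(abs(fit.mu_e - 0.58))
    assert np.median(errs) < 0.005


def test_histogram_backend_agrees_with_em():
    rng = np.random.default_rng(6)
    pts = np.vstack([
        _gaussian_sample(rng, 4000, 0.58, 0.5, 0.05, 0.05, 0.0),
        _gaussian_sample(rng, 4000, 0.74, 0.5, 0.05, 0.05, 0.0),
    ])
    em = fit_populations(pts, 2, backend="em", seed=0)
    hist = fit_populations(pts, 2, backend="histogram", seed=0)
    assert hist.backend == "histogram"
    for a, b in zip(em, hist):
        assert a.mu_e == pytest.approx(b.mu_e, abs=0.01)
        assert a.mu_s == pytest.approx(b.mu_s, abs=0.01)


# ------------------------------------------------------------ assignment

def _fit(weight=1.0, mu_e=0.5, mu_s=0.5, w_e=0.05, w_s=0.05, rho=0.0):
    return PopulationFit(weight, mu_e, mu_s, w_e, w_s, rho)


def test_probabilities_sum_to_one():
    fits = [_fit(0.4, 0.3), _fit(0.6, 0.7)]
    rng = np.random.default_rng(7)
    pts = rng.random((500, 2))
    p = assign_probabilities(pts, fits)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


def test_single_population_assignment_is_unity():
    p = assign_probabilities([[0.2, 0.9]], [_fit()])
    assert p[0, 0] == pytest.approx(1.0)


def test_equidistant_point_splits_evenly():
    fits = [_fit(0.5, mu_e=0.4), _fit(0.5, mu_e=0.6)]
    p = assign_probabilities([[0.5, 0.5]], fits)
    np.testing.assert_allclose(p[0], [0.5, 0.5], atol=1e-12)


def test_assignment_matches_direct_density_evaluation():
    # independent oracle: scipy multivariate normal densities
    fits = [_fit(0.3, 0.35, 0.45, 0.04, 0.06, 0.2),
            _fit(0.7, 0.7, 0.5, 0.05, 0.04, -0.3)]
    rng = np.random.default_rng(8)
    pts = rng.random((200, 2))
    dens = []
    for f in fits:
        cov = [[f.w_e**2, f.rho * f.w_e * f.w_s],
               [f.rho * f.w_e * f.w_s, f.w_s**2]]
        dens.append(f.weight * multivariate_normal([f.mu_e, f.mu_s], cov).pdf(pts))
    expected = np.column_stack(dens)
    expected /= expected.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(assign_probabilities(pts, fits), expected, atol=1e-12)


def test_all_zero_density_assigned_uniformly_with_warning():
    fits = [_fit(w_e=0.001, w_s=0.001), _fit(mu_e=0.9, w_e=0.001, w_s=0.001)]
    with pytest.warns(RuntimeWarning):
        p = assign_probabilities([[0.5, 0.0]], fits)
    np.testing.assert_allclose(p[0], [0.5, 0.5])
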