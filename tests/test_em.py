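"""The nearest-neighbour mixture EM: component densities, update equations,
likelihood monotonicity, and parameter recovery on a known mixture."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial import cKDTree

from invasionkit import (
    EmpiricalNNDensity,
    classify,
    em_fit,
    estimate_g,
    half_normal_pdf,
    sample_uniform_in_window,
)
from invasionkit.em import _m_step

from conftest import make_series


class TestHalfNormal:
    def test_values_at_origin_and_one(self):
        assert half_normal_pdf(0.0, 1.0) == pytest.approx(0.7978845608, abs=1e-9)
        assert half_normal_pdf(1.0, 1.0) == pytest.approx(0.4839414, abs=1e-6)

    def test_unit_integral(self):
        val, _ = quad(lambda d: half_normal_pdf(d, 2.7), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_negative_support_and_bad_sigma(self):
        assert half_normal_pdf(-1.0, 1.0) == 0.0
        with pytest.raises(ValueError):
            half_normal_pdf(1.0, 0.0)


class TestEmpiricalDensity:
    def test_single_record_matches_mc_oracle(self, big_square_window):
        # one record at the centre: g is the distance-to-fixed-point density
        s = make_series([(500.0, 500.0)], [1], big_square_window)
        g = estimate_g(s, 1, n_mc=10000, rng=np.random.default_rng(0))
        grid = np.linspace(0, 800, 4001)
        dens = g(grid)
        mean_g = np.trapezoid(grid * dens, grid) / np.trapezoid(dens, grid)
        # independent MC oracle
        rng = np.random.default_rng(99)
        pts = sample_uniform_in_window(big_square_window, 20000, rng)
        mean_ref = np.hypot(pts[:, 0] - 500, pts[:, 1] - 500).mean()
        assert mean_g == pytest.approx(mean_ref, rel=0.02)

    def test_dense_tiling_concentrates_near_zero(self, big_square_window):
        xs = np.linspace(50, 950, 10)
        grid_pts = [(x, y) for x in xs for y in xs]
        dense = make_series(grid_pts, [1] * len(grid_pts), big_square_window)
        single = make_series([(500.0, 500.0)], [1], big_square_window)
        g_dense = estimate_g(dense, 1, n_mc=4000, rng=np.random.default_rng(1))
        g_single = estimate_g(single, 1, n_mc=4000, rng=np.random.default_rng(1))
        assert g_dense.sample.mean() < g_single.sample.mean()

    def test_zero_for_negative_distances(self):
        g = EmpiricalNNDensity(np.abs(np.random.default_rng(0).normal(5, 1, 500)))
        assert g(-0.5) == 0.0

    def test_integrates_to_one(self):
        sample = np.abs(np.random.default_rng(3).normal(10, 3, 5000))
        g = EmpiricalNNDensity(sample)
        grid = np.linspace(0, 2 * sample.max(), 5000)
        assert np.trapezoid(g(grid), grid) == pytest.approx(1.0, abs=1e-2)

    def test_error_when_no_records_before_year(self, big_square_window):
        s = make_series([(1.0, 1.0)], [5], big_square_window)
        with pytest.raises(ValueError):
            estimate_g(s, 4, n_mc=100)


def _fixed_g_mixture(n_nat, n_anth, sigma_true, seed):
    """A known mixture: half-normal natural distances plus anthropogenic
    distances drawn from the uniform-window nearest-neighbour distribution
    around a single seed record in a 100x100 window."""
    from shapely.geometry import box

    from invasionkit import SpatialWindow

    rng = np.random.default_rng(seed)
    win = SpatialWindow(box(0, 0, 100, 100))
    centre = np.array([[50.0, 50.0]])
    mc = sample_uniform_in_window(win, 10000, rng)
    g = EmpiricalNNDensity(cKDTree(centre).query(mc)[0])
    d_nat = np.abs(rng.normal(0, sigma_true, n_nat))
    anth_pts = sample_uniform_in_window(win, n_anth, rng)
    d_anth = cKDTree(centre).query(anth_pts)[0]
    d = np.concatenate([d_nat, d_anth])
    return d, np.ones(d.size, dtype=int), {1: g}


class TestEMFit:
    def test_w_equals_pi_when_components_agree(self):
        # if f(d_i, sigma) == g(d_i) the E-step gives W_i = pi exactly
        d = np.array([1.0, 2.0, 3.0])
        years = np.ones(3, dtype=int)
        g = {1: lambda dd: half_normal_pdf(dd, 2.0)}
        res = em_fit(d, years, g, pi0=0.37, sigma0=2.0, max_iter=1)
        np.testing.assert_allclose(res.W, 0.37, atol=1e-12)

    def test_update_equations(self):
        pi, _ = _m_step(np.array([1.0, 1.0, 0.0]), np.array([1.0, 1.0, 1.0]))
        assert pi == pytest.approx(2.0 / 3.0)
        _, sigma = _m_step(np.array([1.0, 1.0]), np.array([3.0, 4.0]))
        assert sigma == pytest.approx(np.sqrt(12.5))

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            _m_step(np.zeros(3), np.ones(3))

    def test_log_likelihood_monotone(self):
        d, years, g = _fixed_g_mixture(280, 120, 2.0, seed=5)
        res = em_fit(d, years, g)
        ll = res.log_likelihood
        assert np.all(np.diff(ll) >= -1e-9)
        assert res.converged

    def test_parameter_recovery_single_seed(self):
        d, years, g = _fixed_g_mixture(280, 120, 2.0, seed=11)
        res = em_fit(d, years, g)
        assert res.pi == pytest.approx(0.70, abs=0.10)
        assert res.sigma == pytest.approx(2.0, rel=0.20)

    def test_robust_to_initialisation(self):
        d, years, g = _fixed_g_mixture(280, 120, 2.0, seed=21)
        fits = [em_fit(d, years, g, pi0=p0) for p0 in (0.1, 0.5, 0.9)]
        pis = [f.pi for f in fits]
        sigmas = [f.sigma for f in fits]
        assert max(pis) - min(pis) < 1e-3
        assert max(sigmas) - min(sigmas) < 1e-3

    def test_parameters_stay_in_range(self):
        d, years, g = _fixed_g_mixture(100, 50, 2.0, seed=2)
        res = em_fit(d, years, g)
        assert 0.0 <= res.pi <= 1.0
        assert res.sigma > 0
        assert np.all((res.W >= 0) & (res.W <= 1))

    def test_too_few_distances(self):
        with pytest.raises(ValueError):
            em_fit(np.array([1.0]), np.array([1]), {1: lambda d: 1.0})


class TestClassify:
    def test_threshold_and_tie(self):
        labels = classify(np.array([0.9, 0.1, 0.5]))
        assert labels.tolist() == ["natural", "anthropogenic", "natural"]
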