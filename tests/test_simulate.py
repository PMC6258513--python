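"""Conditional simulation, HSM thinning, and forecasting."""

import numpy as np
import pytest
from scipy.stats import kstest, norm
from shapely.geometry import box

from invasionkit import (
    KernelSpec,
    SimulationConfig,
    SpatialWindow,
    SuitabilityRaster,
    forecast,
    hsm_filter_generate,
    natural_points,
    simulate_conditional,
)
from invasionkit.simulate import fit_yearly_counts

from conftest import make_series


def truncated_halfnorm_cdf(alpha, dmax):
    scale = alpha / np.sqrt(2)
    z = 2 * norm.cdf(dmax / scale) - 1

    def cdf(d):
        return (2 * norm.cdf(np.minimum(d, dmax) / scale) - 1) / z

    return cdf


class TestConditionalSimulation:
    def test_counts_and_anthropogenic_copying(self, small_invasion):
        cfg = SimulationConfig(
            kernel=KernelSpec(alpha=15.0), window=small_invasion.window, n_init=10
        )
        sim = simulate_conditional(small_invasion, cfg, np.random.default_rng(0))
        assert len(sim) == len(small_invasion)
        # per-year totals and per-year label counts match exactly
        for year in np.unique(small_invasion.years):
            obs = small_invasion.frame[small_invasion.frame["year"] == year]
            rep = sim.frame[sim.frame["year"] == year]
            assert len(rep) == len(obs)
            assert (rep["origin"] == "natural").sum() == (obs["origin"] == "natural").sum()
        # anthropogenic coordinates outside the seed are copied bit-exactly
        obs_a = small_invasion.frame.iloc[10:]
        obs_a = obs_a[obs_a["origin"] == "anthropogenic"][["x", "y"]].to_numpy()
        sim_a = sim.frame.iloc[10:]
        sim_a = sim_a[sim_a["origin"] == "anthropogenic"][["x", "y"]].to_numpy()
        assert np.array_equal(np.sort(obs_a, axis=0), np.sort(sim_a, axis=0))

    def test_generated_points_inside_window(self, small_invasion):
        cfg = SimulationConfig(
            kernel=KernelSpec(alpha=15.0), window=small_invasion.window
        )
        sim = simulate_conditional(small_invasion, cfg, np.random.default_rng(1))
        w = small_invasion.window
        assert np.all(w.covers_xy(sim.xy[:, 0], sim.xy[:, 1]))

    def test_reproducible_given_seed(self, small_invasion):
        cfg = SimulationConfig(
            kernel=KernelSpec(alpha=15.0), window=small_invasion.window
        )
        a = simulate_conditional(small_invasion, cfg, np.random.default_rng(9))
        b = simulate_conditional(small_invasion, cfg, np.random.default_rng(9))
        assert a.frame.equals(b.frame)

    def test_unlabelled_records_rejected(self, big_square_window):
        s = make_series(
            [(10, 10), (11, 10), (12, 10)], [1, 2, 3], big_square_window,
            origin=["natural", "unknown", "natural"],
        )
        cfg = SimulationConfig(kernel=KernelSpec(alpha=2.0), window=big_square_window,
                               n_init=1)
        with pytest.raises(ValueError, match="labelled"):
            simulate_conditional(s, cfg, np.random.default_rng(0))

    def test_sampled_distances_match_truncated_kernel(self, big_square_window):
        # aggregate offspring distances from a single source against the
        # closed-form truncated half-normal
        pool = np.array([[500.0, 500.0]])
        kernel = KernelSpec(alpha=4.5, C=2.0, dmax=30.0)
        pts, srcs = natural_points(
            pool, 5000, kernel, big_square_window, np.random.default_rng(3)
        )
        d = np.hypot(*(pts - srcs).T)
        stat = kstest(d, truncated_halfnorm_cdf(4.5, 30.0))
        assert stat.pvalue > 0.001


class TestHsmFiltering:
    def test_full_suitability_passthrough(self, rng):
        ones = SuitabilityRaster(values=np.ones((10, 10)), xll=0, yll=0, cell_size=100)
        gen_calls = []

        def gen(m):
            gen_calls.append(m)
            return rng.uniform(0, 1000, (m, 2))

        pts = hsm_filter_generate(10, gen, ones, oversample=30, rng=rng)
        assert pts.shape == (10, 2)
        assert gen_calls == [300]  # one cycle suffices when everything survives

    def test_half_suitability_one_cycle(self, rng):
        half = SuitabilityRaster(values=np.full((5, 5), 0.5), xll=0, yll=0,
                                 cell_size=200)
        pts = hsm_filter_generate(
            10, lambda m: rng.uniform(0, 1000, (m, 2)), half, 30, rng
        )
        assert pts.shape == (10, 2)

    def test_thinning_proportional_to_suitability(self, two_cell_raster, rng):
        # uniform generator over both cells: survivors should split ~1:4
        def gen(m):
            return np.column_stack([rng.uniform(0, 2, m), rng.uniform(0, 1, m)])

        pts = hsm_filter_generate(4000, gen, two_cell_raster, 30, rng)
        right = (pts[:, 0] >= 1.0).mean()
        assert right == pytest.approx(0.8, abs=0.03)

    def test_zero_suitability_errors(self, rng):
        zero = SuitabilityRaster(values=np.zeros((2, 2)), xll=0, yll=0, cell_size=1)
        with pytest.raises(RuntimeError):
            hsm_filter_generate(
                5, lambda m: rng.uniform(0, 2, (m, 2)), zero, 5, rng, max_cycles=5
            )

    def test_unit_suitability_distributionally_neutral(self, big_square_window):
        # with suitability == 1 the HSM path must match the direct path
        ones = SuitabilityRaster(values=np.ones((10, 10)), xll=0, yll=0,
                                 cell_size=100)
        pool = np.array([[500.0, 500.0]])
        kernel = KernelSpec(alpha=10.0, C=2.0, dmax=30.0)
        d_direct, d_hsm = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p1, s1 = natural_points(pool, 100, kernel, big_square_window, rng)
            rng = np.random.default_rng(1000 + seed)
            p2, s2 = natural_points(
                pool, 100, kernel, big_square_window, rng, hsm=ones
            )
            d_direct.append(np.hypot(*(p1 - s1).T))
            d_hsm.append(np.hypot(*(p2 - s2).T))
        stat = kstest(np.concatenate(d_direct), np.concatenate(d_hsm))
        assert stat.pvalue > 0.001


class TestForecast:
    def _series(self, window):
        return make_series(
            [(500, 500), (505, 500), (510, 500)], [1, 2, 3], window,
            origin=["natural"] * 3,
        )

    def test_counts_match_exactly(self, big_square_window):
        s = self._series(big_square_window)
        fut = forecast(
            s, KernelSpec(alpha=5.0), pi=0.6, yearly_counts=[10, 12, 7],
            rng=np.random.default_rng(0),
        )
        counts = fut.frame.groupby("year").size()
        assert counts.loc[4] == 10 and counts.loc[5] == 12 and counts.loc[6] == 7

    def test_pi_one_means_no_anthropogenic(self, big_square_window):
        s = self._series(big_square_window)
        fut = forecast(
            s, KernelSpec(alpha=5.0), pi=1.0, yearly_counts=[20],
            rng=np.random.default_rng(1),
        )
        assert (fut.origin == "anthropogenic").sum() == 0

    def test_pi_zero_is_uniform(self, unit_square_window):
        s = make_series([(0.5, 0.5), (0.51, 0.5)], [1, 2], unit_square_window,
                        origin=["natural", "natural"])
        fut = forecast(
            s, KernelSpec(alpha=0.1, dmax=0.5), pi=0.0, yearly_counts=[3000],
            rng=np.random.default_rng(2),
        )
        assert set(fut.origin) == {"anthropogenic"}
        stat = kstest(fut.xy[:, 0], "uniform")
        assert stat.pvalue > 0.001

    def test_trend_helper_projects_counts(self, big_square_window):
        years = [1] * 2 + [2] * 4 + [3] * 6 + [4] * 8
        pts = [(500 + i, 500) for i in range(len(years))]
        s = make_series(pts, years, big_square_window)
        counts = fit_yearly_counts(s, 2)
        assert counts.tolist() == [10, 12]
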