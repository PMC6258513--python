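"""Dissimilarity profiles, grid extension, and the jackknife wrapper."""

import numpy as np
import pytest

from invasionkit import (
    DispersalKernelEstimator,
    DissimilarityProfile,
    OriginClassifier,
    VirtualInvasionParams,
    estimate_alpha,
    extend_grid,
    generate_virtual_invasion,
    jackknife_estimate,
)


def make_profile(means_by_alpha, evaluator=None):
    return DissimilarityProfile(
        candidates=np.array(sorted(means_by_alpha)),
        replicates={a: np.array([m]) for a, m in means_by_alpha.items()},
        _evaluator=evaluator,
    )


class TestProfile:
    def test_interior_minimum_is_u_shaped(self):
        p = make_profile({2.0: 5.0, 4.0: 1.0, 8.0: 3.0})
        assert p.u_shaped and p.alpha_hat == 4.0

    def test_endpoint_minimum_not_u_shaped(self):
        p = make_profile({2.0: 5.0, 4.0: 3.0, 8.0: 1.0})
        assert not p.u_shaped and p.alpha_hat == 8.0

    def test_strictly_decreasing_means_flag(self):
        p = make_profile({2.0: 9.0, 4.0: 5.0, 8.0: 2.0, 16.0: 1.0})
        assert not p.u_shaped

    def test_tie_breaks_toward_smaller_alpha(self):
        p = make_profile({2.0: 5.0, 4.0: 1.0, 8.0: 1.0, 16.0: 9.0})
        assert p.alpha_hat == 4.0

    def test_means_invariant_to_replicate_order(self):
        reps = {2.0: np.array([3.0, 1.0, 2.0]), 4.0: np.array([5.0, 6.0, 4.0])}
        a = DissimilarityProfile(candidates=np.array([2.0, 4.0]), replicates=reps)
        rev = {k: v[::-1] for k, v in reps.items()}
        b = DissimilarityProfile(candidates=np.array([2.0, 4.0]), replicates=rev)
        np.testing.assert_allclose(a.means, b.means)


class TestExtendGrid:
    def test_precondition_rejects_u_shaped(self):
        p = make_profile({2.0: 5.0, 4.0: 1.0, 8.0: 3.0})
        with pytest.raises(ValueError):
            extend_grid(p, [16.0])

    def test_cache_hit_for_repeated_candidates(self):
        calls = []

        def evaluator(alpha):
            calls.append(alpha)
            return np.array([100.0 / alpha])

        p = make_profile({2.0: 5.0, 4.0: 3.0, 8.0: 1.0}, evaluator)
        with pytest.warns(UserWarning, match="not U-shaped"):
            merged = extend_grid(p, [2.0, 4.0, 8.0])
        assert calls == []  # all candidates were already evaluated
        np.testing.assert_array_equal(merged.candidates, p.candidates)
        np.testing.assert_allclose(merged.means, p.means)

    def test_extension_finds_interior_minimum(self):
        def evaluator(alpha):
            return np.array([(alpha - 20.0) ** 2 + 1.0])

        p = make_profile({2.0: 325.0, 4.0: 257.0, 8.0: 145.0}, evaluator)
        merged = extend_grid(p, [16.0, 24.0, 32.0])
        assert merged.u_shaped
        assert merged.alpha_hat == 16.0


class TestEndToEnd:
    def test_true_alpha_beats_most_distant_candidate(self, coastline):
        # replicate mechanism == observed mechanism: dissimilarity at the
        # true alpha should not exceed that at the far end of the grid
        p = VirtualInvasionParams(alpha=15.0, n_total=150, anthro_frac=0.1,
                                  n_years=40, window=coastline)
        wins = 0
        for seed in range(5):
            s = generate_virtual_invasion(p, np.random.default_rng(80 + seed))
            prof = estimate_alpha(
                s, candidates=(4.5, 15.0), n_reps=10, random_state=90 + seed
            )
            means = dict(zip(prof.ok_candidates, prof.means))
            if means[15.0] <= means[4.5]:
                wins += 1
        assert wins >= 4

    def test_profile_deterministic_given_seed(self, small_invasion):
        kwargs = dict(candidates=(7.5, 15.0), n_reps=5, random_state=7)
        a = estimate_alpha(small_invasion, **kwargs)
        b = estimate_alpha(small_invasion, **kwargs)
        np.testing.assert_array_equal(a.means, b.means)
        assert a.alpha_hat == b.alpha_hat

    def test_estimator_class_interface(self, small_invasion):
        est = DispersalKernelEstimator(
            candidates=(7.5, 11.0, 15.0, 20.0), n_reps=5, random_state=3
        )
        est.fit(small_invasion)
        assert est.alpha_ in {7.5, 11.0, 15.0, 20.0}
        assert est.kernel_.alpha == est.alpha_
        params = est.get_params()
        assert params["n_reps"] == 5

    def test_requires_natural_records(self, coastline, small_invasion):
        s = small_invasion.with_origin(["anthropogenic"] * len(small_invasion))
        with pytest.raises(ValueError, match="natural"):
            estimate_alpha(s, candidates=(4.5,), n_reps=2, random_state=0)


class TestJackknife:
    def test_subsample_count_and_spread_fields(self, small_invasion):
        jk = jackknife_estimate(
            small_invasion,
            n_jack=3,
            random_state=1,
            classifier=OriginClassifier(n_mc=2000),
            candidates=(7.5, 15.0, 25.0),
            n_reps=4,
        )
        assert len(jk.alphas) == 3
        lo, hi = jk.spread
        assert lo <= jk.mean <= hi

    def test_planted_artefact_inflates_spread_and_drags_alpha(self, coastline):
        import pandas as pd

        p = VirtualInvasionParams(alpha=15.0, n_total=120, anthro_frac=0.1,
                                  n_years=40, window=coastline)
        clean = generate_virtual_invasion(p, np.random.default_rng(55))
        # a dense collinear survey artefact: 50 points 0.3 km apart along
        # a line, all in one late year
        x0, y0 = clean.xy[clean.years == clean.years.max()][0]
        art = pd.DataFrame({
            "x": x0 + 0.3 * np.arange(50), "y": np.full(50, y0),
            "year": clean.years.max(), "origin": "natural",
        })
        frame = pd.concat([clean.frame, art], ignore_index=True)
        frame["id"] = np.arange(len(frame))
        dirty = type(clean)(frame, clean.window, validate=False)

        kwargs = dict(
            n_jack=4, random_state=9,
            classifier=OriginClassifier(n_mc=2000),
            candidates=(2.0, 4.5, 11.0, 20.0), n_reps=5,
        )
        jk_clean = jackknife_estimate(clean, **kwargs)
        jk_dirty = jackknife_estimate(dirty, **kwargs)
        assert jk_dirty.mean <= jk_clean.mean
        s_clean = jk_clean.spread[1] - jk_clean.spread[0]
        s_dirty = jk_dirty.spread[1] - jk_dirty.spread[0]
        assert s_dirty >= s_clean
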