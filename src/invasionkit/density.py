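"""Mixture components for the origin classification.

The anthropogenic component g_y(d) is the empirical density of the
nearest-neighbour distance of a uniformly random point to the series records
up to year y, estimated from Monte-Carlo replicates (10,000 by default) with
a Gaussian kernel density estimate reflected at zero. A yearly density is
needed because short distances become more frequent as populations accrue.
The natural component f(d, sigma) is a half-Gaussian on d >= 0.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .window import sample_uniform_in_window

__all__ = ["EmpiricalNNDensity", "estimate_g", "estimate_g_all", "half_normal_pdf"]

_G_FLOOR = 1e-12  # keeps the E-step ratio finite where the KDE underflows


def half_normal_pdf(d, sigma):
    """Half-Gaussian density 2/(sigma*sqrt(2*pi)) * exp(-d^2 / (2*sigma^2))
    on d >= 0 (zero for negative d)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    out = np.sqrt(2.0 / np.pi) / sigma * np.exp(-(d**2) / (2.0 * sigma**2))
    return np.where(d < 0, 0.0, out)


class EmpiricalNNDensity:
    """Smoothed density of nearest-neighbour distances of random points.

    Callable: evaluates the reflected-KDE density at distances d (zero for
    d < 0, floored at a tiny positive constant on the support).
    """

    def __init__(self, sample, year=None):
        sample = np.asarray(sample, dtype=float)
        if sample.size < 2:
            raise ValueError("need at least two Monte-Carlo distances")
        self.year = year
        self.sample = sample
        if np.ptp(sample) == 0:
            self._kde = None  # degenerate: all MC distances identical
            self._at = float(sample[0])
        else:
            self._kde = gaussian_kde(sample)  # rule-of-thumb bandwidth

    def __call__(self, d):
        d = np.asarray(d, dtype=float)
        scalar = d.ndim == 0
        d = np.atleast_1d(d)
        if self._kde is None:
            width = max(abs(self._at), 1.0) * 1e-3
            dens = np.where(np.abs(d - self._at) <= width, 1.0 / (2 * width), 0.0)
        else:
            dens = self._kde(d) + self._kde(-d)  # reflect at 0
        dens = np.where(d < 0, 0.0, np.maximum(dens, _G_FLOOR))
        return float(dens[0]) if scalar else dens


def estimate_g(series, year, n_mc=10000, rng=None, window=None):
    """Monte-Carlo estimate of g_y for one survey year.

    Draws `n_mc` uniform points in the window (or in `window` when the
    random points must be restricted to a sub-region) and measures each
    point's distance to its nearest series record with year <= `year`.
    """
    rng = np.random.default_rng(rng)
    window = window or series.window
    mask = series.years <= year
    if not mask.any():
        raise ValueError(f"no records up to year {year}")
    tree = cKDTree(series.xy[mask])
    pts = sample_uniform_in_window(window, n_mc, rng)
    dists, _ = tree.query(pts)
    return EmpiricalNNDensity(dists, year=year)


def estimate_g_all(series, n_mc=10000, rng=None, window=None):
    """One EmpiricalNNDensity per distinct year label of the series."""
    rng = np.random.default_rng(rng)
    return {
        int(y): estimate_g(series, int(y), n_mc=n_mc, rng=rng, window=window)
        for y in np.unique(series.years)
    }
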