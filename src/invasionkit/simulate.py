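"""Sequential conditional simulation of invasions and forward forecasting.

Simulated series reproduce the bookkeeping of the observed one year by
year: anthropogenic records are copied verbatim (their placement carries no
information about the dispersal kernel), while the recorded number of
natural records per year is regenerated from the points already present —
a source is chosen uniformly among the pool of earlier years' points, a
dispersal distance is drawn from the candidate kernel and an angle uniformly
on [0, 2*pi), and out-of-window placements are redrawn. An optional habitat
suitability raster thins candidate points with probability equal to their
cell's suitability, with oversampling so the required count is always met.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import KernelSpec, sample_distance
from .series import ANTHROPOGENIC, NATURAL, OccurrenceSeries
from .window import sample_uniform_in_window

__all__ = [
    "SimulationConfig",
    "simulate_conditional",
    "hsm_filter_generate",
    "natural_points",
    "forecast",
    "fit_yearly_counts",
    "sample_intensity_weighted",
]


@dataclass
class SimulationConfig:
    """Settings shared by conditional simulation and forecasting.

    kernel : candidate dispersal kernel
    window : spatial window for placement and the K-function
    n_init : records of iteration zero (the oldest rows of the observed
        series; 10 in the reference protocol)
    hsm : optional SuitabilityRaster used to thin natural points
    oversample : candidate multiplier for HSM filtering (30 by default)
    max_retries : per-point redraw cap for out-of-window placements
    """

    kernel: KernelSpec
    window: object
    n_init: int = 10
    hsm: object = None
    oversample: int = 30
    max_retries: int = 1000

    def __post_init__(self):
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


def _kernel_offspring(pool, n, kernel, window, rng, max_retries=1000):
    """Generate n points from the pool via the kernel; returns (points,
    sources). Out-of-window placements redraw distance and angle (the
    source is kept)."""
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("cannot generate natural points from an empty pool")
    src_idx = rng.integers(0, pool.shape[0], n)
    srcs = pool[src_idx]
    pts = np.empty((n, 2), dtype=float)
    pending = np.arange(n)
    for _ in range(max_retries):
        m = pending.size
        dist = np.atleast_1d(sample_distance(kernel, rng, size=m))
        theta = rng.uniform(0.0, 2.0 * np.pi, m)
        cand = srcs[pending] + np.column_stack(
            [dist * np.cos(theta), dist * np.sin(theta)]
        )
        ok = window.contains_xy(cand[:, 0], cand[:, 1])
        pts[pending[ok]] = cand[ok]
        pending = pending[~ok]
        if pending.size == 0:
            return pts, srcs
    raise RuntimeError("window rejection exceeded the retry cap")


def hsm_filter_generate(n_needed, generator, hsm, oversample, rng, max_cycles=100):
    """Oversample-and-thin generation against a habitat suitability raster.

    Each cycle generates `oversample * n_needed` candidate rows from
    `generator(m)` and keeps each with probability equal to its cell's
    suitability (out-of-extent and no-data cells count as 0, i.e.
    uninhabitable); cycles repeat until at least `n_needed` survive, then a
    uniform subsample of exactly `n_needed` is returned. Rows may carry
    extra columns beyond (x, y); they are thinned and subsampled together.
    """
    if n_needed < 1:
        raise ValueError("n_needed must be >= 1")
    survivors = []
    total = 0
    for _ in range(max_cycles):
        cand = np.asarray(generator(int(oversample * n_needed)), dtype=float)
        s = hsm.lookup_or(cand[:, 0], cand[:, 1], fill=0.0)
        keep = rng.random(cand.shape[0]) < s
        if np.any(keep):
            survivors.append(cand[keep])
            total += int(keep.sum())
        if total >= n_needed:
            rows = np.vstack(survivors)
            pick = rng.choice(rows.shape[0], size=n_needed, replace=False)
            return rows[pick]
    raise RuntimeError(
        "HSM filtering produced too few survivors; suitability may be zero "
        "everywhere reachable"
    )


def natural_points(pool, n, kernel, window, rng, hsm=None, oversample=30,
                   max_retries=1000):
    """Generate n natural points from the pool, optionally HSM-thinned.

    Returns (points, sources), both (n, 2).
    """
    if hsm is None:
        return _kernel_offspring(pool, n, kernel, window, rng, max_retries)

    def gen(m):
        pts, srcs = _kernel_offspring(pool, m, kernel, window, rng, max_retries)
        return np.hstack([pts, srcs])

    rows = hsm_filter_generate(n, gen, hsm, oversample, rng)
    return rows[:, :2], rows[:, 2:]


def simulate_conditional(labeled, cfg, rng=None):
    """Simulate one replicate of an observed, origin-labelled series.

    The oldest `cfg.n_init` records are copied as iteration zero. For each
    later year in ascending order, anthropogenic records are copied with
    identical coordinates, and exactly as many natural records as observed
    are generated from the pool of previous years' points (same-year points
    are not sources). Generated points join the pool for later years.
    """
    rng = np.random.default_rng(rng)
    frame = labeled.frame
    n_init = min(cfg.n_init, len(frame))
    seed = frame.iloc[:n_init]
    rest = frame.iloc[n_init:]
    bad = set(rest["origin"].unique()) - {NATURAL, ANTHROPOGENIC} if len(rest) else set()
    if bad:
        raise ValueError(
            f"records after the seed must be labelled natural/anthropogenic, got {sorted(bad)}"
        )

    pool = seed[["x", "y"]].to_numpy(dtype=float)
    out = [seed.copy()]
    for year in np.sort(rest["year"].unique()):
        yr = rest[rest["year"] == year]
        anth = yr[yr["origin"] == ANTHROPOGENIC]
        n_nat = int((yr["origin"] == NATURAL).sum())
        new_rows = [anth.copy()]
        if n_nat:
            if pool.size == 0:
                raise ValueError(f"year {year} needs natural points but the pool is empty")
            pts, _ = natural_points(
                pool, n_nat, cfg.kernel, cfg.window, rng,
                hsm=cfg.hsm, oversample=cfg.oversample, max_retries=cfg.max_retries,
            )
            new_rows.append(
                pd.DataFrame(
                    {"x": pts[:, 0], "y": pts[:, 1],
                     "year": int(year), "origin": NATURAL}
                )
            )
        added = pd.concat(new_rows, ignore_index=True)
        out.append(added)
        pool = np.vstack([pool, added[["x", "y"]].to_numpy(dtype=float)])

    frame_out = pd.concat(out, ignore_index=True)
    frame_out["id"] = np.arange(len(frame_out))
    return OccurrenceSeries(frame_out, labeled.window, validate=False)


def sample_intensity_weighted(window, raster, n, rng, max_cycles=1000):
    """Draw n points in the window with density proportional to a raster
    (rejection against the raster maximum)."""
    vals = raster.values[raster.values != raster.nodata]
    vmax = vals.max() if vals.size else 0.0
    if vmax <= 0:
        raise ValueError("intensity raster has no positive values")
    out = np.empty((n, 2), dtype=float)
    got = 0
    for _ in range(max_cycles):
        cand = sample_uniform_in_window(window, max(2 * (n - got), 32), rng)
        v = raster.lookup_or(cand[:, 0], cand[:, 1], fill=0.0)
        keep = rng.random(cand.shape[0]) < v / vmax
        k = min(int(keep.sum()), n - got)
        if k:
            out[got : got + k] = cand[keep][:k]
            got += k
        if got == n:
            return out
    raise RuntimeError("intensity-weighted sampling exceeded the cycle cap")


def forecast(labeled, kernel, pi, yearly_counts, window=None, hsm=None,
             oversample=30, intensity=None, rng=None, max_retries=1000):
    """Project an invasion forward.

    For each future year, round((1 - pi) * count) anthropogenic points are
    sampled uniformly in the window (or proportionally to an intensity
    raster) and the remainder are natural points generated from the pool of
    all existing records via the kernel (HSM-thinned when `hsm` is given).

    Parameters
    ----------
    labeled : the observed series (its records seed the pool)
    kernel : fitted natural dispersal kernel
    pi : probability that a new record is of natural origin
    yearly_counts : total new records per future year (a required input;
        see `fit_yearly_counts` for a convenience trend fit)

    Returns
    -------
    OccurrenceSeries of the future records only.
    """
    rng = np.random.default_rng(rng)
    window = window or labeled.window
    pool = labeled.xy
    start = int(labeled.years.max()) + 1
    rows = []
    for k, count in enumerate(yearly_counts):
        count = int(count)
        if count < 0:
            raise ValueError("yearly counts must be non-negative")
        if count == 0:
            continue
        year = start + k
        n_anth = int(np.floor((1.0 - pi) * count + 0.5))
        n_nat = count - n_anth
        pts, origins = [], []
        if n_anth:
            if intensity is not None:
                a = sample_intensity_weighted(window, intensity, n_anth, rng)
            else:
                a = sample_uniform_in_window(window, n_anth, rng)
            pts.append(a)
            origins += [ANTHROPOGENIC] * n_anth
        if n_nat:
            if pool.size == 0:
                raise ValueError(f"year {year} needs natural points but the pool is empty")
            npts, _ = natural_points(
                pool, n_nat, kernel, window, rng,
                hsm=hsm, oversample=oversample, max_retries=max_retries,
            )
            pts.append(npts)
            origins += [NATURAL] * n_nat
        pts = np.vstack(pts)
        rows.append(
            pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "year": year,
                          "origin": origins})
        )
        pool = np.vstack([pool, pts])
    if not rows:
        raise ValueError("no future records requested")
    frame = pd.concat(rows, ignore_index=True)
    frame["id"] = np.arange(len(frame))
    return OccurrenceSeries(frame, window, validate=False)


def fit_yearly_counts(series, n_years):
    """Convenience helper (not part of the estimation method): linear trend
    fit to the historical records-per-year, projected `n_years` forward and
    clipped at zero."""
    years = series.years
    lo, hi = years.min(), years.max()
    grid = np.arange(lo, hi + 1)
    counts = np.array([(years == y).sum() for y in grid], dtype=float)
    slope, intercept = np.polyfit(grid, counts, 1)
    future = np.arange(hi + 1, hi + 1 + n_years)
    pred = slope * future + intercept
    return np.maximum(np.round(pred), 0).astype(int)
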