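"""Generator of labelled virtual invasions with known parameters.

Virtual datasets emulate an invasion recorded as an annual time series:
each year a scheduled number of anthropogenic populations appears uniformly
in the window (or proportionally to an intensity raster, emulating e.g.
road-density-driven releases) and a scheduled number of natural populations
disperses from the existing ones with a known exponential-power kernel.
Every record carries its true origin label, so classification accuracy and
kernel recovery can be scored exactly. Year labels can be aggregated into
bins to emulate periodic survey effort, and an optional habitat-suitability
raster thins new points of both origins.

The bundled windows and rasters are synthetic fixtures: a unit square, and
a two-island coastline-like region of roughly the land area of a large
temperate archipelago (~2.7e5 km^2), so tests run with no downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, box

from .kernels import KernelSpec
from .raster import SuitabilityRaster
from .series import ANTHROPOGENIC, NATURAL, OccurrenceSeries
from .simulate import hsm_filter_generate, natural_points, sample_intensity_weighted
from .window import SpatialWindow, sample_uniform_in_window

__all__ = [
    "VirtualInvasionParams",
    "generate_virtual_invasion",
    "aggregate_years",
    "unit_square",
    "coastline_window",
    "synthetic_intensity_raster",
    "synthetic_suitability_raster",
]


# ---------------------------------------------------------------------------
# fixture windows and rasters
# ---------------------------------------------------------------------------

def unit_square():
    """The [0, 1] x [0, 1] window."""
    return SpatialWindow(box(0.0, 0.0, 1.0, 1.0))


def _island(cx, cy, rx, ry, phases):
    t = np.linspace(0.0, 2.0 * np.pi, 72, endpoint=False)
    r = 1.0 + 0.12 * np.sin(3 * t + phases[0]) + 0.08 * np.sin(7 * t + phases[1])
    return Polygon(np.column_stack([cx + rx * r * np.cos(t), cy + ry * r * np.sin(t)]))


def coastline_window():
    """Synthetic two-island study area (~2.7e5 km^2, km coordinates)."""
    north = _island(300.0, 900.0, 150.0, 330.0, (0.7, 2.1))
    south = _island(560.0, 240.0, 130.0, 280.0, (1.9, 0.4))
    return SpatialWindow(MultiPolygon([north, south]))


def _raster_grid(window, cell_size):
    xmin, ymin, xmax, ymax = window.bounds
    ncols = int(np.ceil((xmax - xmin) / cell_size))
    nrows = int(np.ceil((ymax - ymin) / cell_size))
    xs = xmin + (np.arange(ncols) + 0.5) * cell_size
    ys = ymin + (np.arange(nrows) + 0.5) * cell_size
    X, Yup = np.meshgrid(xs, ys)  # row 0 = bottom here
    return X, Yup, xmin, ymin, cell_size, nrows, ncols


def synthetic_intensity_raster(window=None, cell_size=10.0):
    """Synthetic road-density-like intensity surface in [0, 1]: a few urban
    bumps joined by corridors, on the window's bounding box."""
    window = window or coastline_window()
    X, Y, xll, yll, cs, nrows, ncols = _raster_grid(window, cell_size)
    hubs = [(300.0, 1050.0, 90.0), (340.0, 720.0, 80.0), (560.0, 330.0, 90.0),
            (600.0, 120.0, 70.0)]
    v = np.zeros_like(X)
    for hx, hy, s in hubs:
        v += np.exp(-(((X - hx) ** 2 + (Y - hy) ** 2) / (2 * s**2)))
    # a north-south corridor of elevated intensity
    v += 0.4 * np.exp(-(((X - (300 + 0.2 * (Y - 900))) ** 2) / (2 * 60.0**2)))
    v = v / v.max()
    return SuitabilityRaster(values=v[::-1], xll=xll, yll=yll, cell_size=cs)


def synthetic_suitability_raster(window=None, cell_size=3.0, patchy=0.05,
                                 scale=6.0):
    """Synthetic patchy habitat-suitability surface: high-suitability bands
    (0.95) in a sea of barely suitable habitat (`patchy`), emulating a
    narrow ecological niche. The band period (~pi*scale km) is of the order
    of a dispersal distance, as in a fine-resolution habitat model, so
    habitat — not only the kernel — shapes the aggregation of spread."""
    window = window or coastline_window()
    X, Y, xll, yll, cs, nrows, ncols = _raster_grid(window, cell_size)
    bands = np.sin(X / scale) * np.sin(Y / scale)
    v = np.where(bands > 0.15, 0.95, patchy)
    return SuitabilityRaster(values=v[::-1], xll=xll, yll=yll, cell_size=cs)


# ---------------------------------------------------------------------------
# virtual invasions
# ---------------------------------------------------------------------------

@dataclass
class VirtualInvasionParams:
    """Settings of a labelled virtual invasion.

    alpha, C, dmax : dispersal kernel (defaults 15 km, Gaussian shape,
        30 km maximum natural dispersal distance)
    n_total : total records (reference levels 100, 400, 1000, 2000)
    anthro_frac : fraction of anthropogenic records (levels 0, 0.05, 0.1,
        0.3); the anthropogenic count is round(anthro_frac * n_total)
    n_years : generations (80 by default)
    window : sampling window (the synthetic coastline by default)
    yearly_schedule : optional records per year (must sum to n_total);
        when omitted a growth profile is used
    growth : "geometric" (invasions accelerate; default) or "constant"
    rate : yearly multiplier of the geometric profile
    intensity : optional raster; anthropogenic points are placed with
        density proportional to it instead of uniformly
    hsm : optional suitability raster; new points of both origins are
        oversampled and thinned against it
    aggregate_bin : optional year-bin width (5 emulates periodic surveys)
    """

    alpha: float = 15.0
    C: float = 2.0
    dmax: float = 30.0
    n_total: int = 400
    anthro_frac: float = 0.1
    n_years: int = 80
    window: object = None
    yearly_schedule: np.ndarray = None
    growth: str = "geometric"
    rate: float = 1.05
    intensity: object = None
    hsm: object = None
    oversample: int = 30
    aggregate_bin: int = None

    def __post_init__(self):
        if not 0.0 <= self.anthro_frac <= 1.0:
            raise ValueError("anthro_frac must be in [0, 1]")
        if self.n_total < 1 or self.n_years < 1:
            raise ValueError("n_total and n_years must be >= 1")

    @property
    def kernel(self):
        return KernelSpec(alpha=self.alpha, C=self.C, dmax=self.dmax)


def _largest_remainder(weights, total):
    """Integer allocation of `total` proportional to `weights`."""
    weights = np.asarray(weights, dtype=float)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def _yearly_schedule(p):
    if p.yearly_schedule is not None:
        sched = np.asarray(p.yearly_schedule, dtype=int)
        if sched.sum() != p.n_total:
            raise ValueError("yearly_schedule must sum to n_total")
        if len(sched) != p.n_years:
            raise ValueError("yearly_schedule length must equal n_years")
        return sched
    if p.growth == "constant":
        weights = np.ones(p.n_years)
    elif p.growth == "geometric":
        weights = p.rate ** np.arange(p.n_years)
    else:
        raise ValueError("growth must be 'geometric' or 'constant'")
    sched = _largest_remainder(weights, p.n_total)
    if sched[0] == 0:  # the introduction year must hold at least one record
        sched[int(np.argmax(sched))] -= 1
        sched[0] += 1
    return sched


def generate_virtual_invasion(p, rng=None):
    """Generate a fully labelled virtual invasion.

    Year by year, the scheduled anthropogenic points are placed uniformly
    (or intensity-weighted) and the scheduled natural points disperse from
    the pool of earlier years' points with the known kernel. The first
    natural record — the introduction — is placed uniformly in the window
    in the earliest year with natural records and seeds all later natural
    dispersal. Returns an OccurrenceSeries whose `origin` column holds the
    true labels (year-aggregated when `aggregate_bin` is set).
    """
    rng = np.random.default_rng(rng)
    window = p.window or coastline_window()
    sched = _yearly_schedule(p)
    n_anth_total = int(np.floor(p.anthro_frac * p.n_total + 0.5))
    if n_anth_total:
        anth_sched = np.minimum(_largest_remainder(sched + 1e-9, n_anth_total), sched)
        # cap at the yearly schedule; push any clipped remainder to later years
        short = n_anth_total - anth_sched.sum()
        y = 0
        while short > 0:
            room = sched[y] - anth_sched[y]
            take = min(room, short)
            anth_sched[y] += take
            short -= take
            y += 1
    else:
        anth_sched = np.zeros_like(sched)
    nat_sched = sched - anth_sched

    nat_years = np.flatnonzero(nat_sched > 0)
    seed_year = int(nat_years[0]) if nat_years.size else None

    def uniform_or_intensity(m):
        if p.intensity is not None:
            return sample_intensity_weighted(window, p.intensity, m, rng)
        return sample_uniform_in_window(window, m, rng)

    def anth_generate(m):
        if p.hsm is not None:
            return hsm_filter_generate(m, uniform_or_intensity, p.hsm,
                                       p.oversample, rng)
        return uniform_or_intensity(m)

    pool = np.empty((0, 2), dtype=float)
    rows = []
    for yi in range(p.n_years):
        year = yi + 1
        new = []
        if anth_sched[yi]:
            pts = anth_generate(int(anth_sched[yi]))
            new.append((pts, ANTHROPOGENIC))
        n_nat = int(nat_sched[yi])
        if n_nat:
            local_pool = pool
            if yi == seed_year:
                seed_pt = anth_generate(1)  # the introduction: uniform (HSM-thinned)
                new.append((seed_pt, NATURAL))
                n_nat -= 1
                local_pool = np.vstack([pool, seed_pt])
            if n_nat:
                if local_pool.size == 0:
                    raise ValueError(
                        f"year {year} schedules natural points before any source exists"
                    )
                pts, _ = natural_points(
                    local_pool, n_nat, p.kernel, window, rng,
                    hsm=p.hsm, oversample=p.oversample,
                )
                new.append((pts, NATURAL))
        for pts, origin in new:
            rows.append(pd.DataFrame(
                {"x": pts[:, 0], "y": pts[:, 1], "year": year, "origin": origin}
            ))
            pool = np.vstack([pool, pts])

    frame = pd.concat(rows, ignore_index=True)
    frame["id"] = np.arange(len(frame))
    series = OccurrenceSeries(frame, window, validate=False)
    if p.aggregate_bin:
        series = aggregate_years(series, p.aggregate_bin)
    return series


def aggregate_years(series, bin=5):
    """Aggregate year labels into bins of width `bin`: year y becomes
    ceil(y / bin) * bin (so 1..5 -> 5, 6..10 -> 10, ...). Coordinates and
    record order are untouched; the operation is idempotent."""
    if bin < 1:
        raise ValueError("bin must be >= 1")
    frame = series.frame.copy()
    years = frame["year"].to_numpy(dtype=int)
    frame["year"] = -(-years // bin) * bin  # integer ceiling
    return OccurrenceSeries(frame, series.window, validate=False)
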