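"""Planar spatial windows: sampling regions and K-function observation windows.

All coordinates are kilometres in a planar projected CRS. A window is one or
more simple polygons (multi-island study areas are supported; distances are
plain Euclidean and may cross the gaps between polygons). Windows double as
the observation window for Ripley's K-function, so they also know how to
compute the fraction of a circle that lies inside them (the isotropic edge
correction needs it).
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Point, Polygon

__all__ = ["SpatialWindow", "sample_uniform_in_window"]


class SpatialWindow:
    """A sampling region made of one or more simple planar polygons.

    Parameters
    ----------
    polygon : shapely Polygon or MultiPolygon
        Boundary of the study area, in km.

    Attributes
    ----------
    polygon : shapely MultiPolygon
        The (possibly repaired) geometry.
    """

    def __init__(self, polygon, _disc=None):
        if isinstance(polygon, Polygon):
            polygon = MultiPolygon([polygon])
        if not isinstance(polygon, MultiPolygon):
            raise TypeError("window polygon must be a shapely Polygon or MultiPolygon")
        if not polygon.is_valid:
            fixed = polygon.buffer(0)
            if isinstance(fixed, Polygon):
                fixed = MultiPolygon([fixed])
            polygon = fixed
        if polygon.area <= 0:
            raise ValueError("window has zero area")
        self.polygon = polygon
        self._disc = _disc  # (cx, cy, R) when the window is an exact disc
        self._boundary = polygon.boundary
        self._segments = None

    # -- constructors ----------------------------------------------------
    @classmethod
    def disc(cls, center, radius, n_vertices=256):
        """An exact disc window; edge corrections use the closed form."""
        if radius <= 0:
            raise ValueError("disc radius must be positive")
        poly = Point(*center).buffer(radius, quad_segs=max(n_vertices // 4, 8))
        return cls(poly, _disc=(float(center[0]), float(center[1]), float(radius)))

    @classmethod
    def from_wkt(cls, text):
        return cls(shapely.from_wkt(text))

    @classmethod
    def from_geojson(cls, text):
        geom = shapely.from_geojson(text)
        if geom.geom_type == "GeometryCollection":
            polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
            geom = shapely.unary_union(polys)
        return cls(geom)

    @classmethod
    def from_file(cls, path):
        """Read a window from a GeoJSON or WKT file (format sniffed)."""
        with open(path) as fh:
            text = fh.read()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            return cls.from_geojson(text)
        return cls.from_wkt(text)

    # -- basic geometry --------------------------------------------------
    @property
    def area(self):
        """Window area in km^2 (exact pi*R^2 for disc windows)."""
        if self._disc is not None:
            return float(np.pi * self._disc[2] ** 2)
        return float(self.polygon.area)

    @property
    def bounds(self):
        return self.polygon.bounds

    def contains_xy(self, x, y):
        """Strict interior containment test, vectorised."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self._disc is not None:
            cx, cy, R = self._disc
            return (x - cx) ** 2 + (y - cy) ** 2 < R**2
        return shapely.contains_xy(self.polygon, x, y)

    def covers_xy(self, x, y):
        """Containment including the boundary, vectorised."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self._disc is not None:
            cx, cy, R = self._disc
            return (x - cx) ** 2 + (y - cy) ** 2 <= R**2 * (1 + 1e-12)
        return shapely.intersects_xy(self.polygon, x, y)

    def boundary_distance(self, x, y):
        """Distance from in-window points to the window boundary (km)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if self._disc is not None:
            cx, cy, R = self._disc
            return R - np.hypot(x - cx, y - cy)
        pts = shapely.points(x, y)
        return shapely.distance(pts, self._boundary)

    def segments(self):
        """All boundary segments as an (E, 4) array (x1, y1, x2, y2)."""
        if self._segments is None:
            segs = []
            for poly in self.polygon.geoms:
                rings = [poly.exterior, *poly.interiors]
                for ring in rings:
                    coords = np.asarray(ring.coords)
                    segs.append(
                        np.column_stack([coords[:-1], coords[1:]])
                    )
            self._segments = np.vstack(segs)
        return self._segments

    # -- isotropic edge-correction support -------------------------------
    def circle_inside_fraction(self, cx, cy, r):
        """Fraction of the circle centred at (cx, cy) with radius r inside
        the window.

        Disc windows use the closed-form lens angle; polygonal windows clip
        the circle against every boundary segment exactly (intersection
        angles plus an inside test of each arc midpoint).
        """
        cx = np.atleast_1d(np.asarray(cx, dtype=float))
        cy = np.atleast_1d(np.asarray(cy, dtype=float))
        r = np.atleast_1d(np.asarray(r, dtype=float))
        if self._disc is not None:
            ox, oy, R = self._disc
            rho = np.hypot(cx - ox, cy - oy)
            with np.errstate(divide="ignore", invalid="ignore"):
                u = (rho**2 + r**2 - R**2) / (2.0 * rho * r)
            u = np.where(r <= 0, -1.0, u)  # zero radius: fully inside
            u = np.clip(u, -1.0, 1.0)
            return np.arccos(u) / np.pi
        out = np.empty(cx.shape, dtype=float)
        chunk = 4096  # bounds the (pairs x segments) broadcast memory
        for lo in range(0, cx.size, chunk):
            hi = min(lo + chunk, cx.size)
            out[lo:hi] = self._polygon_circle_fractions(cx[lo:hi], cy[lo:hi], r[lo:hi])
        return out

    def _segment_data(self):
        if not hasattr(self, "_segcache"):
            segs = self.segments()
            dx = segs[:, 2] - segs[:, 0]
            dy = segs[:, 3] - segs[:, 1]
            a = dx * dx + dy * dy
            keep = a > 0  # drop degenerate zero-length segments
            self._segcache = (
                segs[keep, 0], segs[keep, 1], dx[keep], dy[keep], a[keep]
            )
        return self._segcache

    def _polygon_circle_fractions(self, cx, cy, r):
        """Batched exact arc clipping: intersection angles of each circle
        with every boundary segment, then an inside test of each arc
        midpoint (one vectorised containment call for the whole batch).
        Only actual circle-segment intersections are materialised."""
        P = cx.size
        x1, y1, dx, dy, a = self._segment_data()
        fx = x1[None, :] - cx[:, None]  # (P, E)
        fy = y1[None, :] - cy[:, None]
        b = 2.0 * (fx * dx + fy * dy)
        c = fx * fx + fy * fy - r[:, None] ** 2
        disc = b * b - 4.0 * a * c
        rows, cols = np.nonzero(disc > 0)

        if rows.size:
            bo = b[rows, cols]
            sq = np.sqrt(disc[rows, cols])
            ao = a[cols]
            t = np.concatenate([(-bo - sq) / (2 * ao), (-bo + sq) / (2 * ao)])
            rr = np.concatenate([rows, rows])
            cc = np.concatenate([cols, cols])
            hit = (t >= 0.0) & (t <= 1.0)
            t, rr, cc = t[hit], rr[hit], cc[hit]
        else:
            t = rr = cc = np.empty(0, dtype=int)

        out = np.empty(P, dtype=float)
        has = np.zeros(P, dtype=bool)
        has[rr] = True
        none = ~has
        if np.any(none):
            # no boundary crossing: circle wholly inside or wholly outside
            out[none] = np.where(
                self.covers_xy(cx[none] + r[none], cy[none]), 1.0, 0.0
            )
        if rr.size:
            px = x1[cc] + t * dx[cc]
            py = y1[cc] + t * dy[cc]
            theta = np.arctan2(py - cy[rr], px - cx[rr])
            order = np.lexsort((theta, rr))
            rr, theta = rr[order], theta[order]
            starts = np.flatnonzero(np.r_[True, rr[1:] != rr[:-1]])
            ends = np.r_[starts[1:], rr.size] - 1
            # successor angle within each circle, wrapping past 2*pi
            nxt = np.empty_like(theta)
            nxt[:-1] = theta[1:]
            nxt[ends] = theta[starts] + 2.0 * np.pi
            arc = nxt - theta
            mid = theta + arc / 2.0
            inside = self.covers_xy(
                cx[rr] + r[rr] * np.cos(mid), cy[rr] + r[rr] * np.sin(mid)
            )
            frac = np.add.reduceat(np.where(inside, arc, 0.0), starts)
            out[rr[starts]] = frac / (2.0 * np.pi)
        out[r <= 0] = 1.0
        return out

    def __repr__(self):  # pragma: no cover
        kind = "disc" if self._disc is not None else f"{len(self.polygon.geoms)}-polygon"
        return f"SpatialWindow({kind}, area={self.area:.1f} km^2)"


def sample_uniform_in_window(window, n, rng=None):
    """Draw `n` points uniformly inside the window by rejection from its
    bounding box.

    Parameters
    ----------
    window : SpatialWindow
    n : int
        Number of points, >= 1.
    rng : numpy Generator or seed, optional

    Returns
    -------
    (n, 2) float array of (x, y), all strictly inside the polygon.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if window.area <= 0:
        raise ValueError("degenerate window: zero area")
    rng = np.random.default_rng(rng)
    xmin, ymin, xmax, ymax = window.bounds
    accept = window.area / ((xmax - xmin) * (ymax - ymin))
    out = np.empty((n, 2), dtype=float)
    got = 0
    for _ in range(1000):
        m = int((n - got) / max(accept, 1e-6) * 1.2) + 16
        x = rng.uniform(xmin, xmax, m)
        y = rng.uniform(ymin, ymax, m)
        keep = window.contains_xy(x, y)
        k = min(int(keep.sum()), n - got)
        if k:
            out[got : got + k, 0] = x[keep][:k]
            out[got : got + k, 1] = y[keep][:k]
            got += k
        if got == n:
            return out
    raise RuntimeError("rejection sampling failed; window area may be degenerate")
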