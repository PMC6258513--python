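"""Occurrence time series: ordered spatio-temporal records of an invasion.

Records carry planar coordinates (km), an integer survey-year label and an
optional origin label ("natural", "anthropogenic" or "unknown"). The CSV
dialect is comma-separated with a header and columns x,y,year[,origin].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["OccurrenceSeries", "NATURAL", "ANTHROPOGENIC", "UNKNOWN"]

NATURAL = "natural"
ANTHROPOGENIC = "anthropogenic"
UNKNOWN = "unknown"
_VALID_ORIGINS = {NATURAL, ANTHROPOGENIC, UNKNOWN}


class OccurrenceSeries:
    """An invasion time series inside a spatial window.

    Parameters
    ----------
    records : pandas DataFrame with columns x, y, year and optionally
        id and origin. Rows are stably sorted by year on construction, so
        record order within a year is preserved.
    window : SpatialWindow
        All records must lie inside it (boundary included).
    """

    def __init__(self, records, window, validate=True):
        if not isinstance(records, pd.DataFrame):
            records = pd.DataFrame(records)
        for col in ("x", "y", "year"):
            if col not in records.columns:
                raise ValueError(f"occurrence records are missing column '{col}'")
        if len(records) == 0:
            raise ValueError("occurrence series needs at least one record")
        frame = records.copy()
        frame["year"] = frame["year"].astype(int)
        if "id" not in frame.columns:
            frame["id"] = np.arange(len(frame))
        if "origin" in frame.columns:
            bad = set(frame["origin"].dropna().unique()) - _VALID_ORIGINS
            if bad:
                raise ValueError(f"unknown origin labels: {sorted(bad)}")
        frame = frame.sort_values("year", kind="stable").reset_index(drop=True)
        if validate:
            inside = window.covers_xy(frame["x"].to_numpy(), frame["y"].to_numpy())
            if not np.all(inside):
                k = int(np.argmin(inside))
                raise ValueError(
                    f"record {frame['id'].iloc[k]} at "
                    f"({frame['x'].iloc[k]:.3f}, {frame['y'].iloc[k]:.3f}) "
                    "lies outside the window"
                )
        self.frame = frame
        self.window = window

    # -- views -----------------------------------------------------------
    def __len__(self):
        return len(self.frame)

    @property
    def xy(self):
        return self.frame[["x", "y"]].to_numpy(dtype=float)

    @property
    def years(self):
        return self.frame["year"].to_numpy(dtype=int)

    @property
    def origin(self):
        if "origin" in self.frame.columns:
            return self.frame["origin"].to_numpy(dtype=object)
        return np.full(len(self.frame), UNKNOWN, dtype=object)

    def with_origin(self, labels):
        """Copy of the series with a replaced origin column."""
        frame = self.frame.copy()
        frame["origin"] = np.asarray(labels, dtype=object)
        return OccurrenceSeries(frame, self.window, validate=False)

    def subset(self, index):
        """Sub-series of the given positional rows (order re-sorted by year)."""
        frame = self.frame.iloc[np.asarray(index)].reset_index(drop=True)
        return OccurrenceSeries(frame, self.window, validate=False)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, window, coord_scale=1.0):
        """Read a points CSV (columns x,y,year[,origin]); `coord_scale`
        multiplies coordinates on input (e.g. 0.001 for metres to km)."""
        frame = pd.read_csv(path)
        for col in ("x", "y", "year"):
            if col not in frame.columns:
                raise ValueError(f"points CSV is missing column '{col}'")
        if coord_scale != 1.0:
            frame["x"] = frame["x"] * coord_scale
            frame["y"] = frame["y"] * coord_scale
        return cls(frame, window)

    def to_csv(self, path):
        cols = ["id", "x", "y", "year"]
        if "origin" in self.frame.columns:
            cols.append("origin")
        extra = [c for c in self.frame.columns if c not in cols]
        self.frame[cols + extra].to_csv(path, index=False)

    def __repr__(self):  # pragma: no cover
        yr = self.years
        return (
            f"OccurrenceSeries(n={len(self)}, years={yr.min()}..{yr.max()})"
        )
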