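"""Inverse-distance-weighted (IDW) interpolation of station values.

Each grid value is a distance-decay weighted average of the station values,

    v(g) = sum_i w_i v_i / sum_i w_i,   w_i = d(g, s_i)^(-power),

so the surface is exact at stations, continuous elsewhere, and always a
convex combination of the station values.  Planar coordinates are assumed
(at the extent of a single lake, geodesic corrections are negligible).
The default power of 2 and an all-station neighborhood are the customary
GIS defaults; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = ["GridSpec", "idw_points", "idw_grid", "write_esri_ascii"]


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: bounding box, cell size, optional boundary polygon.

    ``mask`` is a shapely polygon; cells whose centers fall outside it get
    NaN (no value is emitted for them).
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    cell_size: float
    mask: object | None = None

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigurationError("cell size must be > 0")
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ConfigurationError("bounding box is degenerate")

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = np.arange(self.xmin + self.cell_size / 2, self.xmax, self.cell_size)
        ys = np.arange(self.ymin + self.cell_size / 2, self.ymax, self.cell_size)
        return xs, ys


def _validate_stations(stations: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    xy = stations[["x", "y"]].to_numpy(dtype=float)
    v = stations["value"].to_numpy(dtype=float)
    if len(xy) < 1:
        raise ValidationError("at least one station is required")
    if not np.isfinite(xy).all() or not np.isfinite(v).all():
        raise ValidationError("station coordinates and values must be finite")
    # duplicate coordinates with conflicting values make the surface ill-defined
    df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "v": v})
    dup = df.groupby(["x", "y"])["v"].nunique()
    if (dup > 1).any():
        raise ValidationError("duplicate station coordinates with different values")
    df = df.drop_duplicates()
    return df[["x", "y"]].to_numpy(), df["v"].to_numpy()


def idw_points(stations: pd.DataFrame, points: np.ndarray,
               power: float = 2.0) -> np.ndarray:
    """IDW estimate at arbitrary (n, 2) points.

    A point coinciding with a station returns that station's value exactly.
    """
    if power <= 0:
        raise ConfigurationError("power must be > 0")
    xy, v = _validate_stations(stations)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    d = np.sqrt(((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    out = np.empty(len(pts))
    at_station = d == 0.0
    hits = at_station.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[hits] = 0.0  # avoid inf arithmetic; exact values assigned below
    out = (w @ v) / np.where(hits, 1.0, w.sum(axis=1))
    for i in np.nonzero(hits)[0]:
        out[i] = v[int(np.argmax(at_station[i]))]
    return out


def idw_grid(stations: pd.DataFrame, grid: GridSpec,
             power: float = 2.0) -> pd.DataFrame:
    """IDW surface on a regular grid; returns long (x, y, value) rows.

    Masked cells carry NaN values.
    """
    xs, ys = grid.centers()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    vals = idw_points(stations, pts, power=power)
    if grid.mask is not None:
        from shapely.geometry import Point

        inside = np.array([grid.mask.contains(Point(x, y)) for x, y in pts])
        vals = np.where(inside, vals, np.nan)
    return pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "value": vals})


def write_esri_ascii(grid_values: pd.DataFrame, grid: GridSpec, path,
                     nodata: float = -9999.0) -> None:
    """Write a long (x, y, value) grid table as an ESRI ASCII raster."""
    xs, ys = grid.centers()
    pivot = grid_values.pivot(index="y", columns="x", values="value")
    pivot = pivot.reindex(index=ys, columns=xs)
    arr = pivot.to_numpy(dtype=float)[::-1]  # rasters are written north-first
    with open(path, "w") as fh:
        fh.write(f"ncols {len(xs)}\n")
        fh.write(f"nrows {len(ys)}\n")
        fh.write(f"xllcorner {grid.xmin}\n")
        fh.write(f"yllcorner {grid.ymin}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in arr:
            vals = np.where(np.isnan(row), nodata, row)
            fh.write(" ".join(f"{v:.6g}" for v in vals) + "\n")
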