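"""Backscatter raster handling: scale conversion, speckle filtering, plot extraction.

Rasters are plain 2-D float arrays on a north-up affine grid (origin at the
top-left corner, square pixels). File I/O uses the ESRI ASCII grid text
format, which round-trips the grid, cell size and nodata; footprints travel
as CSV (plot_id, x, y) or GeoJSON points with a ``side_m`` property.

Physics conventions: speckle filtering and window averaging operate in
linear power (averaging dB values underestimates the mean by Jensen's
inequality); the dB-domain mean is also computed for sensitivity checks but
the linear-domain value is authoritative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .wcm_core import Scale, ScaleMismatchError

__all__ = [
    "BackscatterRaster",
    "PlotFootprint",
    "PlotExtraction",
    "db_to_linear",
    "linear_to_db",
    "speckle_filter",
    "extract_plot_sigma0",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_footprints_csv",
    "write_footprints_csv",
    "read_footprints_geojson",
    "write_footprints_geojson",
]


def db_to_linear(x):
    """dB -> linear power: 10^(x/10)."""
    out = np.power(10.0, np.asarray(x, dtype=float) / 10.0)
    return float(out) if np.isscalar(x) else out


def linear_to_db(x):
    """Linear power -> dB: 10*log10(x). Non-positive input is a domain error."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("linear_to_db requires strictly positive input")
    out = 10.0 * np.log10(arr)
    return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class BackscatterRaster:
    """A single-band sigma0 raster on a north-up grid.

    ``origin_x``/``origin_y`` are the world coordinates of the grid's
    top-left corner; world x grows with columns, world y shrinks with rows
    (pixel-centre of cell (row, col) is at origin + (col+0.5, -(row+0.5)) *
    pixel_size). ``nodata`` cells are ignored by every statistic.
    """

    data: np.ndarray
    scale: Scale
    pixel_size: float = 0.3
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs: str = "local"
    nodata: Optional[float] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got shape {arr.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "scale", Scale(self.scale))
        if self.scale is Scale.LINEAR and np.any(self.valid_mask() & (arr < 0)):
            raise ValueError("linear-power raster contains negative values")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape

    def valid_mask(self) -> np.ndarray:
        mask = np.isfinite(self.data)
        if self.nodata is not None:
            mask &= self.data != self.nodata
        return mask

    def world_to_rowcol(self, x: float, y: float) -> Tuple[int, int]:
        """Index of the pixel whose cell contains world point (x, y)."""
        col = int(math.floor((x - self.origin_x) / self.pixel_size))
        row = int(math.floor((self.origin_y - y) / self.pixel_size))
        return row, col

    def to_linear(self) -> "BackscatterRaster":
        if self.scale is Scale.LINEAR:
            return self
        out = np.where(self.valid_mask(), db_to_linear(self.data), np.nan)
        return replace(self, data=out, scale=Scale.LINEAR, nodata=None)

    def to_db(self) -> "BackscatterRaster":
        if self.scale is Scale.DB:
            return self
        valid = self.valid_mask() & (self.data > 0)
        out = np.full(self.data.shape, np.nan)
        out[valid] = 10.0 * np.log10(self.data[valid])
        return replace(self, data=out, scale=Scale.DB, nodata=None)


@dataclass(frozen=True)
class PlotFootprint:
    """A square sampling plot identified by its centre, default 1.5 m side."""

    plot_id: str
    x: float
    y: float
    side_m: float = 1.5

    def __post_init__(self) -> None:
        if self.side_m <= 0:
            raise ValueError("side_m must be positive")


@dataclass(frozen=True)
class PlotExtraction:
    """Windowed plot statistic: linear-domain mean (authoritative) plus the
    dB-domain mean for sensitivity, and the valid-pixel count."""

    plot_id: str
    sigma0_db: float
    sigma0_db_of_db_mean: float
    n_valid: int
    window: int


def speckle_filter(
    raster: BackscatterRaster,
    method: str = "lee",
    window: int = 5,
    looks: float = 1.0,
) -> BackscatterRaster:
    """Reduce multiplicative speckle on a linear-power raster.

    ``lee`` (default): local-statistics minimum-MSE filter. With noise
    variation coefficient Cu^2 = 1/looks, each output pixel is
    mean + k*(x - mean), k = var_signal / var_local where
    var_signal = max(0, (var_local - Cu^2*mean^2) / (1 + Cu^2)).
    Homogeneous regions collapse toward the local mean (preserved within
    estimation error); edges with var >> noise pass through.

    ``boxcar``: plain moving-average; preserves homogeneous means exactly.

    dB input is rejected — the multiplicative noise model only holds in
    linear power.
    """
    if raster.scale is not Scale.LINEAR:
        raise ScaleMismatchError("speckle filtering is defined on linear-power rasters")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    data = raster.data

    if method == "boxcar":
        out = ndimage.uniform_filter(data, size=window, mode="reflect")
    elif method == "lee":
        if looks < 1:
            raise ValueError("looks must be >= 1")
        mean = ndimage.uniform_filter(data, size=window, mode="reflect")
        mean_sq = ndimage.uniform_filter(data**2, size=window, mode="reflect")
        var = np.maximum(mean_sq - mean**2, 0.0)
        cu2 = 1.0 / looks
        var_signal = np.maximum((var - cu2 * mean**2) / (1.0 + cu2), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(var > 0, var_signal / var, 0.0)
        out = mean + k * (data - mean)
        out = np.maximum(out, 0.0)
    else:
        raise ValueError(f"unknown speckle filter method: {method!r}")
    return replace(raster, data=out)


def extract_plot_sigma0(raster: BackscatterRaster, footprint: PlotFootprint) -> PlotExtraction:
    """Mean backscatter (dB) over the pixel window covering a plot footprint.

    The window spans ceil(side/pixel) pixels per axis (5x5 for a 1.5 m plot
    at 0.3 m), centred on the pixel containing the footprint centre; no
    sub-pixel interpolation. Averaging is done in linear power over valid
    pixels; the result is returned in dB alongside the dB-domain mean.
    """
    n = math.ceil(footprint.side_m / raster.pixel_size - 1e-9)
    half = n // 2
    row, col = raster.world_to_rowcol(footprint.x, footprint.y)
    r0, r1 = row - half, row - half + n
    c0, c1 = col - half, col - half + n
    nrow, ncol = raster.shape
    if r0 < 0 or c0 < 0 or r1 > nrow or c1 > ncol:
        raise ValueError(
            f"plot {footprint.plot_id}: {n}x{n} window [{r0}:{r1}, {c0}:{c1}] "
            f"falls outside raster of shape {raster.shape}"
        )
    window_vals = raster.data[r0:r1, c0:c1]
    window_mask = raster.valid_mask()[r0:r1, c0:c1]
    if not window_mask.any():
        raise ValueError(f"plot {footprint.plot_id}: window contains no valid pixels")
    vals = window_vals[window_mask]
    if raster.scale is Scale.DB:
        lin = db_to_linear(vals)
        db_vals = vals
    else:
        lin = vals
        db_vals = linear_to_db(np.maximum(vals, np.finfo(float).tiny))
    return PlotExtraction(
        plot_id=footprint.plot_id,
        sigma0_db=linear_to_db(float(lin.mean())),
        sigma0_db_of_db_mean=float(db_vals.mean()),
        n_valid=int(vals.size),
        window=n,
    )


# ---------------------------------------------------------------------------
# text I/O: ESRI ASCII grid + footprint CSV / GeoJSON


def write_ascii_grid(raster: BackscatterRaster, path: Union[str, Path]) -> None:
    """Write as an ESRI ASCII grid (scale recorded in a trailing comment line
    tolerated by common readers is avoided; scale travels out-of-band via the
    filename or caller — the format itself has no metadata slot)."""
    nrow, ncol = raster.shape
    nodata = raster.nodata if raster.nodata is not None else -9999.0
    data = np.where(raster.valid_mask(), raster.data, nodata)
    header = (
        f"ncols {ncol}\n"
        f"nrows {nrow}\n"
        f"xllcorner {raster.origin_x}\n"
        f"yllcorner {raster.origin_y - nrow * raster.pixel_size}\n"
        f"cellsize {raster.pixel_size}\n"
        f"NODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(f"{v:.6f}" for v in row) for row in data)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(
    path: Union[str, Path],
    scale: Scale = Scale.DB,
    crs: str = "local",
) -> BackscatterRaster:
    """Read an ESRI ASCII grid; the backscatter scale must be supplied."""
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, val = lines[i].split(maxsplit=1)
        hdr[key.lower()] = float(val)
        i += 1
    data = np.loadtxt(lines[i:], dtype=float)
    data = np.atleast_2d(data)
    nrows, ncols = int(hdr["nrows"]), int(hdr["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"grid body shape {data.shape} disagrees with header ({nrows}, {ncols})")
    cell = hdr["cellsize"]
    return BackscatterRaster(
        data=data,
        scale=scale,
        pixel_size=cell,
        origin_x=hdr.get("xllcorner", 0.0),
        origin_y=hdr.get("yllcorner", 0.0) + nrows * cell,
        crs=crs,
        nodata=hdr.get("nodata_value"),
    )


def write_footprints_csv(footprints: List[PlotFootprint], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [{"plot_id": f.plot_id, "x": f.x, "y": f.y, "side_m": f.side_m} for f in footprints]
    ).to_csv(path, index=False)


def read_footprints_csv(path: Union[str, Path]) -> List[PlotFootprint]:
    df = pd.read_csv(path)
    side = df["side_m"] if "side_m" in df else pd.Series(1.5, index=df.index)
    return [
        PlotFootprint(plot_id=str(r.plot_id), x=float(r.x), y=float(r.y), side_m=float(s))
        for r, s in zip(df.itertuples(), side)
    ]


def write_footprints_geojson(footprints: List[PlotFootprint], path: Union[str, Path]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [f.x, f.y]},
            "properties": {"plot_id": f.plot_id, "side_m": f.side_m},
        }
        for f in footprints
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=2))


def read_footprints_geojson(path: Union[str, Path]) -> List[PlotFootprint]:
    obj = json.loads(Path(path).read_text())
    out = []
    for feat in obj["features"]:
        x, y = feat["geometry"]["coordinates"]
        props = feat.get("properties", {})
        out.append(
            PlotFootprint(
                plot_id=str(props.get("plot_id", len(out))),
                x=float(x),
                y=float(y),
                side_m=float(props.get("side_m", 1.5)),
            )
        )
    return out
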