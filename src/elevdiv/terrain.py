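"""DEM handling: band areas, topographic ruggedness, region summaries.

Grids are geographic (lon/lat, degrees).  Cell areas use the spherical
cosine approximation: a cell of side ``c`` degrees centred at latitude
``phi`` covers ``(c * 111.32 km)^2 * cos(phi)`` — adequate for the
*relative* band areas the regressions consume.

The topographic ruggedness index (TRI) of a cell is the square root of the
summed squared elevation differences to its 8 neighbours (Riley et al.).
Cells with an incomplete neighbourhood (grid edges, nodata neighbours) are
excluded from all TRI statistics rather than padded, to avoid biased edge
ruggedness.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ranges import BandScheme

logger = logging.getLogger("elevdiv")

KM_PER_DEGREE = 111.32

__all__ = [
    "DemGrid",
    "BandMetrics",
    "read_dem",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "band_area",
    "tri_grid",
    "band_mean_tri",
    "region_summary",
    "compute_band_metrics",
]


@dataclass(frozen=True)
class DemGrid:
    """An elevation raster on a regular lon/lat grid.

    ``values`` rows run north to south; nodata cells are stored as NaN.
    ``xll``/``yll`` are the lon/lat of the grid's lower-left corner,
    ``cellsize`` the cell side in degrees.
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("DEM values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        object.__setattr__(self, "values", v)

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-centre latitudes per row, north to south."""
        top = self.yll + self.nrows * self.cellsize
        return top - self.cellsize * (np.arange(self.nrows) + 0.5)

    @property
    def cell_area_km2(self) -> np.ndarray:
        """Per-row cell area (km^2), cosine-weighted by latitude."""
        base = (self.cellsize * KM_PER_DEGREE) ** 2
        return base * np.cos(np.radians(self.lat_centers))


def read_ascii_grid(path: str | Path) -> DemGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0][:1].isalpha():
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ASCII grid header missing {key}")
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape {values.shape} does not match header")
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # xllcenter variant
        xll = header["xllcenter"] - header["cellsize"] / 2
        yll = header["yllcenter"] - header["cellsize"] / 2
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return DemGrid(values, xll, yll, header["cellsize"])


def write_ascii_grid(dem: DemGrid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a DEM as an ESRI ASCII grid."""
    vals = np.where(np.isnan(dem.values), nodata, dem.values)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {dem.ncols}\nnrows {dem.nrows}\n"
            f"xllcorner {dem.xll}\nyllcorner {dem.yll}\n"
            f"cellsize {dem.cellsize}\nNODATA_value {nodata}\n"
        )
        np.savetxt(fh, vals, fmt="%.3f")


def read_geotiff(path: str | Path, nodata: float | None = None) -> DemGrid:
    """Read a single-band GeoTIFF DEM in geographic coordinates."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        try:
            scale = tags["ModelPixelScaleTag"].value
            tie = tags["ModelTiepointTag"].value
        except KeyError as e:
            raise ValueError(f"{path}: not a georeferenced GeoTIFF") from e
    sx, sy = float(scale[0]), float(scale[1])
    if not np.isclose(sx, sy, rtol=1e-6):
        raise ValueError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
    # tiepoint maps raster (i, j) to (lon, lat) of the upper-left corner
    i, j = float(tie[0]), float(tie[1])
    lon0, lat0 = float(tie[3]), float(tie[4])
    west = lon0 - i * sx
    north = lat0 + j * sy
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    nrows = values.shape[0]
    return DemGrid(values, west, north - nrows * sy, sx)


def read_dem(path: str | Path, nodata: float | None = None) -> DemGrid:
    """Read a DEM, dispatching on extension (.asc/.txt -> ASCII, .tif -> GeoTIFF)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return read_geotiff(path, nodata=nodata)
    return read_ascii_grid(path)


def band_area(dem: DemGrid, scheme: BandScheme) -> np.ndarray:
    """Land area (km^2) of each elevational band.

    A cell belongs to the band whose half-open interval contains its
    elevation (same convention as species interpolation).  Cells below the
    scheme base or above its top contribute to no band.
    """
    v = dem.values
    if np.isnan(v).all():
        warnings.warn("all-nodata DEM: band areas are zero")
        return np.zeros(scheme.n_bands)
    cell_areas = np.broadcast_to(dem.cell_area_km2[:, None], v.shape)
    with np.errstate(invalid="ignore"):
        idx = np.floor((v - scheme.base) / scheme.width)
    areas = np.zeros(scheme.n_bands)
    for i in range(scheme.n_bands):
        areas[i] = cell_areas[idx == i].sum()
    return areas


def tri_grid(dem: DemGrid) -> np.ndarray:
    """Per-cell TRI (metres): sqrt of summed squared differences to 8 neighbours.

    Edge cells and cells with any nodata neighbour are NaN.
    """
    v = dem.values
    if v.shape[0] < 3 or v.shape[1] < 3:
        raise ValueError("TRI needs a grid of at least 3x3 cells")
    out = np.full(v.shape, np.nan)
    center = v[1:-1, 1:-1]
    ssq = np.zeros_like(center)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            neigh = v[1 + di : v.shape[0] - 1 + di, 1 + dj : v.shape[1] - 1 + dj]
            ssq = ssq + (center - neigh) ** 2
    out[1:-1, 1:-1] = np.sqrt(ssq)
    return out


def band_mean_tri(dem: DemGrid, scheme: BandScheme) -> np.ndarray:
    """Mean TRI over interior cells whose elevation falls in each band.

    Bands with no contributing cells are NaN (dropped pairwise downstream).
    """
    tri = tri_grid(dem)
    v = dem.values
    out = np.full(scheme.n_bands, np.nan)
    with np.errstate(invalid="ignore"):
        idx = np.floor((v - scheme.base) / scheme.width)
    for i in range(scheme.n_bands):
        sel = (idx == i) & ~np.isnan(tri)
        if sel.any():
            out[i] = tri[sel].mean()
    return out


def region_summary(dem: DemGrid) -> tuple[float, float]:
    """Region-level (mean TRI, mid-latitude).

    Mean TRI is over all interior land cells; mid-latitude is the midpoint
    of the latitudinal extent of land cells (signed decimal degrees — take
    the absolute value at the regression layer if desired).
    """
    land = ~np.isnan(dem.values)
    if not land.any():
        raise ValueError("DEM has no land cells")
    tri = tri_grid(dem)
    valid = ~np.isnan(tri)
    mean_tri = float(tri[valid].mean()) if valid.any() else float("nan")
    lats = dem.lat_centers[land.any(axis=1)]
    mid_lat = float(0.5 * (lats.min() + lats.max()))
    return mean_tri, mid_lat


@dataclass(frozen=True)
class BandMetrics:
    """Per-band area and ruggedness for one region's DEM."""

    scheme: BandScheme
    area: np.ndarray  # km^2 per band
    mean_tri: np.ndarray  # metres per band (NaN where empty)
    region_mean_tri: float
    mid_latitude: float

    def to_frame(self) -> pd.DataFrame:
        edges = self.scheme.edges
        return pd.DataFrame(
            {
                "band_low": edges[:-1],
                "band_high": edges[1:],
                "area_km2": self.area,
                "mean_tri": self.mean_tri,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_band_metrics(dem: DemGrid, scheme: BandScheme) -> BandMetrics:
    """Band areas, band mean TRI, and region summary in one pass."""
    mean_tri, mid_lat = region_summary(dem)
    return BandMetrics(
        scheme=scheme,
        area=band_area(dem, scheme),
        mean_tri=band_mean_tri(dem, scheme),
        region_mean_tri=mean_tri,
        mid_latitude=mid_lat,
    )
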