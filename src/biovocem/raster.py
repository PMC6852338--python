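"""Georeferenced raster grids and land-cover maps.

The carrier types for every gridded quantity in the pipeline: reflectance
bands, NDVI, hourly temperature surfaces and per-cell emissions.  A grid is
a plain 2-D array plus an affine georeference (upper-left origin, square
pixels) and a nodata sentinel.  The CRS is carried as an opaque identifier
string (the study area uses UTM zone 17 South); no reprojection is done.

Rasters are persisted as Esri ASCII grids (``.asc``), a plain-text
interchange format every GIS reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RasterGrid", "LandCoverMap", "read_ascii_grid", "write_ascii_grid"]

_DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class RasterGrid:
    """A single-band georeferenced raster.

    Parameters
    ----------
    values : 2-D ndarray
        Cell values, row 0 at the top (north).
    origin : (float, float)
        (x, y) of the upper-left corner of the upper-left pixel.
    pixel_size : float
        Side length of a square pixel in CRS units (m for UTM); > 0.
    crs : str
        Opaque CRS identifier, e.g. ``"EPSG:32717"`` (UTM 17S).
    nodata : float
        Sentinel marking cells excluded from all statistics.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 30.0
    crs: str = "EPSG:32717"
    nodata: float = _DEFAULT_NODATA

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got ndim={arr.ndim}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area(self) -> float:
        """Area of one cell in CRS units squared (m² for UTM)."""
        return self.pixel_size ** 2

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        v = self.values
        valid = v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            valid &= np.isfinite(v)
        return valid

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.pixel_size, other.pixel_size)
            and self.crs == other.crs
        )

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """New grid sharing this grid's georeference."""
        kwargs = {"values": np.asarray(values)}
        if nodata is not None:
            kwargs["nodata"] = nodata
        return replace(self, **kwargs)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of pixel centers, each of grid shape."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.pixel_size
        ys = y0 - (np.arange(nrows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)


def _require_alignment(a: RasterGrid, b: RasterGrid) -> None:
    if not a.aligned_with(b):
        raise ValueError(
            "rasters are not aligned (shape/origin/pixel size/CRS must match): "
            f"{a.shape}@{a.origin} vs {b.shape}@{b.origin}"
        )


@dataclass(frozen=True)
class LandCoverMap:
    """Per-pixel integer class labels with a legend.

    ``labels`` is a :class:`RasterGrid` of integer class ids; ``legend`` maps
    each id to a class (species) name.  Pixel area comes from the grid
    geometry.  Nodata cells never enter area tabulations.
    """

    labels: RasterGrid
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = self.class_ids()
        missing = [c for c in present if c not in self.legend]
        if missing:
            raise ValueError(f"classes {missing} present in map but absent from legend")

    def class_ids(self) -> list[int]:
        v = self.labels.values[self.labels.mask()]
        return sorted(int(c) for c in np.unique(v))

    @property
    def pixel_area(self) -> float:
        return self.labels.pixel_area

    def area_by_class(self) -> pd.Series:
        """Hectares per class; classes in the legend but absent map to 0."""
        valid = self.labels.values[self.labels.mask()].astype(int)
        counts = {cid: 0 for cid in self.legend}
        ids, n = np.unique(valid, return_counts=True)
        counts.update(dict(zip((int(i) for i in ids), (int(c) for c in n))))
        ha = {self.legend.get(cid, str(cid)): cnt * self.pixel_area / 1e4
              for cid, cnt in sorted(counts.items())}
        return pd.Series(ha, name="area_ha")


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> Path:
    """Write a grid as an Esri ASCII raster (text). CRS goes to a ``.crs`` sidecar."""
    path = Path(path)
    nrows, ncols = grid.shape
    x0, y0 = grid.origin
    yll = y0 - nrows * grid.pixel_size
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.pixel_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt="%.10g")
    path.with_suffix(path.suffix + ".crs").write_text(grid.crs + "\n")
    return path


def read_ascii_grid(path: str | Path, dtype=float) -> RasterGrid:
    """Read an Esri ASCII raster written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=dtype)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    values = values.reshape(nrows, ncols)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    crs_file = path.with_suffix(path.suffix + ".crs")
    crs = crs_file.read_text().strip() if crs_file.exists() else "unknown"
    return RasterGrid(values=values, origin=origin, pixel_size=cell, crs=crs,
                      nodata=header["nodata_value"])
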