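"""Raster containers and GeoTIFF I/O for canopy height and terrain grids.

Every layer in the pipeline (CHMs, DTMs, quality rasters, class maps) is
carried by :class:`RasterGrid`: a single-band, north-up, square-pixel grid
with an explicit nodata sentinel. Files are single-band GeoTIFFs; heights
are float32, class maps uint8 with nodata 255.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import tifffile

__all__ = [
    "RasterGrid",
    "ChmPair",
    "QualityThresholds",
    "CellIndex",
    "CellWindow",
    "read_raster",
    "write_raster",
    "align_pair",
    "decimal_years",
    "apply_quality_mask",
    "tile_cells",
    "cell_validity",
]

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """Georeferenced single-band grid.

    Pixel (0, 0) is the top-left corner; ``(x_origin, y_origin)`` is the map
    coordinate of that corner, with y decreasing down rows (north-up).
    ``nodata`` marks invalid pixels and is never treated as a height.
    """

    values: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size: float = 1.0
    nodata: float = -9999.0
    crs_id: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got {self.values.ndim}-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def transform(self) -> tuple[float, float, float, float, float, float]:
        """Affine (a, b, c, d, e, f): x = a*col + b*row + c, y = d*col + e*row + f."""
        p = self.pixel_size
        return (p, 0.0, self.x_origin, 0.0, -p, self.y_origin)

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of pixels that carry data."""
        v = self.values
        if np.issubdtype(v.dtype, np.floating):
            return ~(np.isnan(v) | (v == self.nodata))
        return v != self.nodata

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, ~self.valid_mask())

    def with_values(self, values: np.ndarray, nodata: Optional[float] = None) -> "RasterGrid":
        """New grid sharing this grid's georeferencing."""
        return RasterGrid(
            values=values,
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            pixel_size=self.pixel_size,
            nodata=self.nodata if nodata is None else nodata,
            crs_id=self.crs_id,
        )

    def copy(self) -> "RasterGrid":
        return self.with_values(self.values.copy())

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
            and self.crs_id == other.crs_id
        )

    def pixel_center(self, row: float, col: float) -> tuple[float, float]:
        return (
            self.x_origin + (col + 0.5) * self.pixel_size,
            self.y_origin - (row + 0.5) * self.pixel_size,
        )


@dataclass
class QualityThresholds:
    """Acquisition-quality and cell-validity rules.

    Defaults: pixels with pulse density < 2 m^-2 or scan angle > 20 deg are
    masked; 1-ha cells with > 5% missing pixels or without a single forest
    type covering >= 75% of their area are excluded.
    """

    min_pulse_density: float = 2.0
    max_scan_angle: float = 20.0
    max_missing_fraction: float = 0.05
    min_type_purity: float = 0.75

    def __post_init__(self) -> None:
        if self.min_pulse_density < 0 or self.max_scan_angle < 0:
            raise ValueError("quality thresholds must be non-negative")
        if not (0 <= self.max_missing_fraction <= 1 and 0 < self.min_type_purity <= 1):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class CellIndex:
    """Index of one analysis cell in the regular (default 1-ha) grid."""

    row: int
    col: int
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)

    def centroid(self) -> tuple[float, float]:
        x0, y0 = self.origin
        return (
            x0 + (self.col + 0.5) * self.cell_size,
            y0 - (self.row + 0.5) * self.cell_size,
        )


@dataclass(frozen=True)
class CellWindow:
    """Pixel window of a cell in a particular raster: half-open slices."""

    cell: CellIndex
    row_slice: slice
    col_slice: slice
    partial: bool = False

    def extract(self, grid: RasterGrid) -> np.ndarray:
        return grid.values[self.row_slice, self.col_slice]


@dataclass
class ChmPair:
    """Two co-registered CHM epochs and their time separation."""

    chm_t1: RasterGrid
    chm_t2: RasterGrid
    date_t1: datetime.date
    date_t2: datetime.date
    interval_years: float


def decimal_years(date1: datetime.date, date2: datetime.date) -> float:
    """Interval in decimal years, day count / 365.25."""
    return (date2 - date1).days / 365.25


def read_raster(path: str | Path) -> RasterGrid:
    """Load a single-band GeoTIFF into a :class:`RasterGrid`.

    Raises ``ValueError`` on multi-band input or non-square pixels.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim == 3:
            raise ValueError(f"{path}: expected single band, got shape {values.shape}")
        tags = page.tags
        x_origin, y_origin, pixel_size = 0.0, 0.0, 1.0
        if _TAG_MODEL_PIXEL_SCALE in tags:
            sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
            if abs(sx - sy) > 1e-9 * max(abs(sx), abs(sy)):
                raise ValueError(f"{path}: non-square pixels ({sx} x {sy})")
            pixel_size = float(sx)
        if _TAG_MODEL_TIEPOINT in tags:
            tp = tags[_TAG_MODEL_TIEPOINT].value
            # (i, j, k, x, y, z) for pixel corner (0, 0)
            x_origin, y_origin = float(tp[3]), float(tp[4])
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value))
        crs_id = "local"
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                crs_id = meta.get("crs_id", crs_id)
            except (json.JSONDecodeError, TypeError, AttributeError):
                pass
    return RasterGrid(values, x_origin, y_origin, pixel_size, nodata, crs_id)


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a :class:`RasterGrid` as a single-band GeoTIFF."""
    path = Path(path)
    nodata_str = (
        str(int(grid.nodata))
        if float(grid.nodata) == int(grid.nodata)
        else repr(float(grid.nodata))
    )
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x_origin, grid.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_str),
    ]
    tifffile.imwrite(
        path,
        grid.values,
        description=json.dumps({"crs_id": grid.crs_id}),
        extratags=extratags,
    )


def align_pair(
    chm1: RasterGrid,
    chm2: RasterGrid,
    date1: datetime.date,
    date2: datetime.date,
) -> ChmPair:
    """Pair two CHMs after verifying exact co-registration.

    Fails with an offset report on any shape/transform mismatch, and on a
    non-positive time interval.
    """
    if chm1.crs_id != chm2.crs_id:
        raise ValueError(f"CRS mismatch: {chm1.crs_id!r} vs {chm2.crs_id!r}")
    if chm1.shape != chm2.shape:
        raise ValueError(f"shape mismatch: {chm1.shape} vs {chm2.shape}")
    if chm1.transform != chm2.transform:
        dx = chm2.x_origin - chm1.x_origin
        dy = chm2.y_origin - chm1.y_origin
        raise ValueError(
            f"transform mismatch: origin offset ({dx:+g}, {dy:+g}) m, "
            f"pixel sizes {chm1.pixel_size} vs {chm2.pixel_size}"
        )
    interval = decimal_years(date1, date2)
    if interval <= 0:
        raise ValueError(f"interval must be positive, got {interval} yr")
    return ChmPair(chm1, chm2, date1, date2, interval)


def apply_quality_mask(
    chm: RasterGrid,
    density: Optional[RasterGrid] = None,
    scan_angle: Optional[RasterGrid] = None,
    q: Optional[QualityThresholds] = None,
) -> RasterGrid:
    """Mask CHM pixels failing pulse-density / scan-angle thresholds.

    Absent auxiliary rasters are treated as passing everywhere.
    """
    q = q or QualityThresholds()
    for name, aux in (("density", density), ("scan_angle", scan_angle)):
        if aux is not None and not chm.same_grid(aux):
            raise ValueError(f"{name} raster is not aligned with the CHM")
    out = chm.values.astype(np.float32, copy=True)
    bad = np.zeros(chm.shape, dtype=bool)
    if density is not None:
        bad |= density.valid_mask() & (density.values < q.min_pulse_density)
        bad |= ~density.valid_mask()
    if scan_angle is not None:
        bad |= scan_angle.valid_mask() & (scan_angle.values > q.max_scan_angle)
    out[bad] = chm.nodata
    return chm.with_values(out)


def tile_cells(grid: RasterGrid, cell_size: float = 100.0) -> list[CellWindow]:
    """Partition the raster into non-overlapping square analysis cells.

    ``cell_size`` must be an integer multiple of the pixel size. Windows are
    half-open; edge cells that do not fully fit are returned flagged
    ``partial`` (downstream analysis excludes them).
    """
    n = cell_size / grid.pixel_size
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"cell_size {cell_size} is not an integer multiple of pixel size {grid.pixel_size}"
        )
    n = int(round(n))
    nrow, ncol = grid.shape
    origin = (grid.x_origin, grid.y_origin)
    windows: list[CellWindow] = []
    for i in range((nrow + n - 1) // n):
        for j in range((ncol + n - 1) // n):
            r1, c1 = min((i + 1) * n, nrow), min((j + 1) * n, ncol)
            partial = (r1 - i * n != n) or (c1 - j * n != n)
            windows.append(
                CellWindow(
                    CellIndex(i, j, cell_size, origin),
                    slice(i * n, r1),
                    slice(j * n, c1),
                    partial,
                )
            )
    return windows


def cell_validity(
    chm_cell: np.ndarray,
    q: QualityThresholds,
    type_fractions: Mapping[object, float],
    nodata: float = -9999.0,
) -> tuple[bool, Optional[object]]:
    """Decide whether one 1-ha cell enters the analysis, and its forest type.

    Invalid when missing data exceed ``max_missing_fraction`` of the cell or
    no single forest type reaches ``min_type_purity``; otherwise returns the
    majority type.
    """
    v = np.asarray(chm_cell)
    if np.issubdtype(v.dtype, np.floating):
        missing = np.isnan(v) | (v == nodata)
    else:
        missing = v == nodata
    frac_missing = missing.mean() if v.size else 1.0
    if frac_missing > q.max_missing_fraction:
        return False, None
    if not type_fractions:
        return False, None
    best_type, best_frac = max(type_fractions.items(), key=lambda kv: kv[1])
    if best_frac < q.min_type_purity:
        return False, None
    return True, best_type
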