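"""Topographic covariates from the DTM: elevation, slope, and wetness.

Slope uses Horn's 3x3 kernel on the 10-m aggregated DTM. The topographic
wetness index TWI = ln(a / tan(beta)) is computed at 25-m resolution from
the pit-filled DTM with single-direction (D8) flow routing, where ``a`` is
the specific catchment area (accumulated contributing area divided by cell
width) and beta the local slope. Coarsening before TWI smooths over small
pits and mounds so the index reflects hillslope-scale convergence.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .raster_io import CellIndex, CellWindow, RasterGrid, tile_cells

__all__ = [
    "CellTopography",
    "aggregate_dtm",
    "resample_mean",
    "slope",
    "fill_pits",
    "flow_accumulation",
    "twi",
    "cell_topography",
]

# D8 neighbor order used for all tie-breaking: E, SE, S, SW, W, NW, N, NE
_D8 = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_D8_DIST = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2)])

TAN_BETA_FLOOR = 1e-3


@dataclass
class CellTopography:
    """Per-cell topographic summary (means over valid pixels)."""

    cell: CellIndex
    elevation_mean: Optional[float]
    slope_mean: Optional[float]
    twi_mean: Optional[float]


def aggregate_dtm(dtm: RasterGrid, factor: int) -> RasterGrid:
    """Block-mean aggregation by an integer factor.

    Any nodata pixel poisons its block. Edge rows/columns not filling a
    whole block are dropped with a warning.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return dtm.copy()
    nrow, ncol = dtm.shape
    nr, nc = nrow // factor, ncol // factor
    if nr * factor != nrow or nc * factor != ncol:
        warnings.warn(
            f"grid {dtm.shape} not divisible by {factor}; dropping edge pixels",
            stacklevel=2,
        )
    v = dtm.values[: nr * factor, : nc * factor].astype(np.float64)
    valid = dtm.valid_mask()[: nr * factor, : nc * factor]
    v = np.where(valid, v, np.nan)
    blocks = v.reshape(nr, factor, nc, factor)
    out = blocks.mean(axis=(1, 3))
    out = np.where(np.isnan(out), dtm.nodata, out)
    return RasterGrid(
        out.astype(np.float32),
        dtm.x_origin,
        dtm.y_origin,
        dtm.pixel_size * factor,
        dtm.nodata,
        dtm.crs_id,
    )


def resample_mean(grid: RasterGrid, target_pixel_size: float) -> RasterGrid:
    """Mean-resample to an arbitrary coarser pixel size.

    Source pixels are assigned to the target cell containing their center;
    handles non-integer ratios (e.g. 10 m -> 25 m). Target cells containing
    any nodata source pixel become nodata.
    """
    ratio = target_pixel_size / grid.pixel_size
    if ratio < 1:
        raise ValueError("resample_mean only coarsens")
    if abs(ratio - round(ratio)) < 1e-9:
        return aggregate_dtm(grid, int(round(ratio)))
    nrow, ncol = grid.shape
    nr = int(nrow / ratio)
    nc = int(ncol / ratio)
    rows = np.minimum((np.arange(nrow) / ratio).astype(int), nr - 1)
    cols = np.minimum((np.arange(ncol) / ratio).astype(int), nc - 1)
    keep_r = (np.arange(nrow) / ratio) < nr
    keep_c = (np.arange(ncol) / ratio) < nc
    v = grid.values.astype(np.float64)
    valid = grid.valid_mask()
    sums = np.zeros((nr, nc))
    counts = np.zeros((nr, nc))
    bad = np.zeros((nr, nc), dtype=bool)
    for i in np.nonzero(keep_r)[0]:
        ti = rows[i]
        np.add.at(sums[ti], cols[keep_c], np.where(valid[i, keep_c], v[i, keep_c], 0.0))
        np.add.at(counts[ti], cols[keep_c], valid[i, keep_c].astype(float))
        np.logical_or.at(bad[ti], cols[keep_c], ~valid[i, keep_c])
    out = np.where((counts > 0) & ~bad, sums / np.maximum(counts, 1), grid.nodata)
    return RasterGrid(
        out.astype(np.float32),
        grid.x_origin,
        grid.y_origin,
        target_pixel_size,
        grid.nodata,
        grid.crs_id,
    )


def slope(dtm: RasterGrid) -> RasterGrid:
    """Terrain slope in degrees by Horn's 3x3 finite-difference kernel.

    Border pixels (and pixels whose 3x3 neighborhood touches nodata) are
    nodata.
    """
    nrow, ncol = dtm.shape
    if nrow < 3 or ncol < 3:
        raise ValueError("grid must be at least 3x3 for slope")
    z = dtm.values.astype(np.float64)
    valid = dtm.valid_mask()
    p = dtm.pixel_size
    out = np.full(dtm.shape, dtm.nodata, dtype=np.float64)
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                   f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * p)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * p)
    deg = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    ok = np.ones(deg.shape, dtype=bool)
    for dr in range(3):
        for dc in range(3):
            ok &= valid[dr : dr + deg.shape[0], dc : dc + deg.shape[1]]
    out[1:-1, 1:-1] = np.where(ok, deg, dtm.nodata)
    return dtm.with_values(out.astype(np.float32))


def fill_pits(dtm: RasterGrid, epsilon: float = 1e-5) -> RasterGrid:
    """Priority-flood depression filling.

    Floods inward from the grid edge (and from nodata holes, which act as
    drains), raising every cell to at least its spill elevation plus a tiny
    ``epsilon`` gradient so downstream flow routing never stalls on flats.
    The filled surface is >= the input everywhere and the operation is
    idempotent up to ``epsilon`` accumulation on filled flats.
    """
    z = dtm.values.astype(np.float64).copy()
    valid = dtm.valid_mask()
    nrow, ncol = z.shape
    closed = ~valid
    heap: list[tuple[float, int, int]] = []
    for r in range(nrow):
        for c in range(ncol):
            if not valid[r, c]:
                continue
            edge = r in (0, nrow - 1) or c in (0, ncol - 1)
            if not edge:
                edge = any(
                    not valid[r + dr, c + dc]
                    for dr, dc in _D8
                    if 0 <= r + dr < nrow and 0 <= c + dc < ncol
                )
            if edge:
                heapq.heappush(heap, (z[r, c], r, c))
                closed[r, c] = True
    while heap:
        zc, r, c = heapq.heappop(heap)
        for dr, dc in _D8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol and not closed[rr, cc]:
                closed[rr, cc] = True
                if z[rr, cc] <= zc:
                    z[rr, cc] = zc + epsilon
                heapq.heappush(heap, (z[rr, cc], rr, cc))
    out = np.where(valid, z, dtm.nodata)
    return dtm.with_values(out)


def _d8_receivers(z: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Steepest-descent D8 receiver index per cell (-1 = outlet/no descent).

    Ties broken by fixed neighbor order E, SE, S, SW, W, NW, N, NE.
    """
    nrow, ncol = z.shape
    best_drop = np.zeros((nrow, ncol))
    receiver = np.full((nrow, ncol), -1, dtype=np.int64)
    # off-grid / nodata neighbors are never flow targets; a cell with no
    # lower in-grid neighbor is an outlet (drains off the grid)
    zz = np.where(valid, z, np.inf)
    for k, (dr, dc) in enumerate(_D8):
        nb = np.full((nrow, ncol), np.inf)
        rs = slice(max(dr, 0), nrow + min(dr, 0))
        rd = slice(max(-dr, 0), nrow + min(-dr, 0))
        cs = slice(max(dc, 0), ncol + min(dc, 0))
        cd = slice(max(-dc, 0), ncol + min(-dc, 0))
        nb[rd, cd] = zz[rs, cs]
        drop = (z - nb) / _D8_DIST[k]
        better = valid & (drop > best_drop)
        rr = (np.arange(nrow)[:, None] + dr) * ncol + (np.arange(ncol)[None, :] + dc)
        receiver[better] = rr[better]
        best_drop[better] = drop[better]
    return receiver


def flow_accumulation(dtm_filled: RasterGrid) -> RasterGrid:
    """D8 flow accumulation in contributing-area units (m^2).

    Each cell drains wholly to its steepest-descent neighbor; accumulation
    counts the cell's own area. Requires a pit-filled input so every valid
    cell has a descending path to the edge.
    """
    z = dtm_filled.values.astype(np.float64)
    valid = dtm_filled.valid_mask()
    nrow, ncol = z.shape
    receiver = _d8_receivers(z, valid)
    acc = np.where(valid, 1.0, 0.0).ravel()
    order = np.argsort(z, axis=None, kind="stable")[::-1]
    recv = receiver.ravel()
    vflat = valid.ravel()
    for idx in order:
        if not vflat[idx]:
            continue
        r = recv[idx]
        if r >= 0:
            acc[r] += acc[idx]
    area = dtm_filled.pixel_size ** 2
    out = np.where(valid, acc.reshape(nrow, ncol) * area, dtm_filled.nodata)
    return dtm_filled.with_values(out)


def twi(dtm: RasterGrid, target_resolution: float = 25.0) -> RasterGrid:
    """Topographic wetness index ln(a / tan(beta)) at the target resolution.

    ``dtm`` is the (10-m) aggregated terrain; it is mean-resampled to
    ``target_resolution``, pit-filled, and routed with D8. tan(beta) is
    floored at 1e-3 to keep the index finite on flats.
    """
    coarse = dtm if dtm.pixel_size >= target_resolution else resample_mean(dtm, target_resolution)
    filled = fill_pits(coarse)
    acc = flow_accumulation(filled)
    slp = slope(filled)
    valid = filled.valid_mask() & slp.valid_mask()
    tan_beta = np.maximum(np.tan(np.radians(slp.values.astype(np.float64))), TAN_BETA_FLOOR)
    sca = acc.values.astype(np.float64) / filled.pixel_size
    with np.errstate(divide="ignore", invalid="ignore"):
        index = np.log(sca / tan_beta)
    out = np.where(valid, index, filled.nodata)
    return filled.with_values(out.astype(np.float32))


def _window_in(grid: RasterGrid, cell: CellIndex) -> tuple[slice, slice]:
    n = cell.cell_size / grid.pixel_size
    ni = int(round(n))
    r0, c0 = cell.row * ni, cell.col * ni
    return slice(r0, r0 + ni), slice(c0, c0 + ni)


def _cell_mean(grid: RasterGrid, cell: CellIndex) -> Optional[float]:
    rs, cs = _window_in(grid, cell)
    w = grid.values[rs, cs]
    m = grid.valid_mask()[rs, cs]
    if w.size == 0 or not m.any():
        return None
    return float(w[m].mean())


def cell_topography(
    dtm: RasterGrid,
    twi_map: RasterGrid,
    cells: Sequence[CellIndex],
    slope_resolution: float = 10.0,
) -> list[CellTopography]:
    """Per-cell mean elevation (native DTM), slope (10-m), and TWI (25-m).

    Slope is derived internally from the DTM aggregated to
    ``slope_resolution``; nodata pixels are ignored in each mean, and a cell
    that is entirely nodata in a layer gets ``None`` for that value.
    """
    factor = max(1, int(round(slope_resolution / dtm.pixel_size)))
    slope_map = slope(aggregate_dtm(dtm, factor))
    return [
        CellTopography(
            cell=cell,
            elevation_mean=_cell_mean(dtm, cell),
            slope_mean=_cell_mean(slope_map, cell),
            twi_mean=_cell_mean(twi_map, cell),
        )
        for cell in cells
    ]
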