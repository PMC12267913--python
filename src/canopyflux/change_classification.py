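"""Five-class canopy-change partition between two CHM epochs.

Every valid pixel is assigned exactly one of five dynamic classes from the
epoch-wise qualifying-gap sets and the height difference:

1. gap formation    - in a qualifying gap at t2 but not at t1
2. canopy disturbance - height drop > 5 m over a connected >= 25 m^2 patch
                        that never enters a gap at either epoch
3. gap persistence  - in a qualifying gap at both epochs
4. gap closure      - in a t1 gap that no longer belongs to any t2 gap
5. intact canopy    - everything else

Classes 1+2 are canopy losses; 3+4+5 are canopy gains (which can be
negative when intact or persistent-gap areas lose height). Per 1-ha cell
the partition yields area fractions, class-conditional height rates
(m/yr), and signed volume rates (m^3 ha^-1 yr^-1, height change times
pixel area).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .gap_detection import GapDefinition, GapSet
from .raster_io import CellWindow, ChmPair, RasterGrid

__all__ = [
    "FORMATION",
    "DISTURBANCE",
    "PERSISTENCE",
    "CLOSURE",
    "INTACT",
    "NODATA_CLASS",
    "CLASS_NAMES",
    "LOSS_CLASSES",
    "GAIN_CLASSES",
    "ChangeParams",
    "ChangeMap",
    "CellDynamics",
    "delta",
    "detect_disturbance",
    "classify_change",
    "summarize_cell",
    "summarize_cells",
]

FORMATION, DISTURBANCE, PERSISTENCE, CLOSURE, INTACT = 1, 2, 3, 4, 5
NODATA_CLASS = 255
CLASS_NAMES = {
    FORMATION: "gap_formation",
    DISTURBANCE: "canopy_disturbance",
    PERSISTENCE: "gap_persistence",
    CLOSURE: "gap_closure",
    INTACT: "intact_canopy",
}
LOSS_CLASSES = (FORMATION, DISTURBANCE)
GAIN_CLASSES = (PERSISTENCE, CLOSURE, INTACT)


@dataclass
class ChangeParams:
    """Thresholds of the change partition."""

    gap_def: GapDefinition = field(default_factory=GapDefinition)
    disturbance_drop: float = 5.0
    disturbance_min_area: float = 25.0
    interval_years: float = 1.0

    def __post_init__(self) -> None:
        if self.disturbance_drop <= 0 or self.disturbance_min_area <= 0:
            raise ValueError("disturbance thresholds must be positive")
        if self.interval_years <= 0:
            raise ValueError("interval_years must be positive")


@dataclass
class ChangeMap:
    """Per-pixel class codes (uint8, nodata = 255) on the CHM grid."""

    class_map: RasterGrid

    def mask(self, code: int) -> np.ndarray:
        return self.class_map.values == code

    def valid_mask(self) -> np.ndarray:
        return self.class_map.values != NODATA_CLASS


@dataclass
class CellDynamics:
    """One cell's dynamics rates; the row unit of the statistics layer."""

    cell: object
    forest_type: object
    valid_pixels: int
    area_fraction: dict[int, float]
    height_rate: dict[int, float]  # class-conditional mean dh / yr
    volume_rate: dict[int, float]  # signed, m^3 ha^-1 yr^-1
    gains_volume: float
    losses_volume: float  # absolute value
    net_volume: float
    gains_height: float  # cell-normalized, m/yr
    losses_height: float  # absolute value
    net_height: float


def delta(pair: ChmPair) -> RasterGrid:
    """Per-pixel height change chm_t2 - chm_t1; nodata where either is."""
    valid = pair.chm_t1.valid_mask() & pair.chm_t2.valid_mask()
    d = pair.chm_t2.values.astype(np.float64) - pair.chm_t1.values.astype(np.float64)
    out = np.where(valid, d, pair.chm_t1.nodata)
    return pair.chm_t1.with_values(out.astype(np.float32))


def detect_disturbance(
    delta_grid: RasterGrid,
    gap1: GapSet,
    gap2: GapSet,
    p: ChangeParams,
) -> np.ndarray:
    """Connected height-loss patches that never meet the gap definition.

    Candidates drop by more than ``disturbance_drop`` and lie outside both
    epochs' gap sets; candidate components (gap-definition connectivity)
    smaller than ``disturbance_min_area`` are dropped.
    """
    valid = delta_grid.valid_mask()
    cand = (
        valid
        & (delta_grid.values < -p.disturbance_drop)
        & ~gap1.mask
        & ~gap2.mask
    )
    labels, n = ndimage.label(cand, structure=p.gap_def.structure)
    if n == 0:
        return cand
    pixel_area = delta_grid.pixel_size ** 2
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    ok = counts * pixel_area >= p.disturbance_min_area
    ok[0] = False
    return ok[labels]


def classify_change(
    pair: ChmPair,
    gap1: GapSet,
    gap2: GapSet,
    p: ChangeParams,
) -> ChangeMap:
    """Assign every valid pixel to one of the five dynamic classes.

    Gap membership takes precedence: persistence (both epochs), closure
    (t1 only), formation (t2 only); then disturbance patches; all remaining
    valid pixels are intact canopy.
    """
    valid = pair.chm_t1.valid_mask() & pair.chm_t2.valid_mask()
    d = delta(pair)
    dist = detect_disturbance(d, gap1, gap2, p)
    g1, g2 = gap1.mask, gap2.mask
    out = np.full(pair.chm_t1.shape, NODATA_CLASS, dtype=np.uint8)
    out[valid] = INTACT
    out[valid & dist] = DISTURBANCE
    out[valid & ~g1 & g2] = FORMATION
    out[valid & g1 & ~g2] = CLOSURE
    out[valid & g1 & g2] = PERSISTENCE
    grid = pair.chm_t1.with_values(out, nodata=NODATA_CLASS)
    return ChangeMap(grid)


def summarize_cell(
    change: ChangeMap,
    delta_grid: RasterGrid,
    window: CellWindow,
    p: ChangeParams,
    forest_type: object = None,
) -> CellDynamics:
    """Aggregate the change partition over one analysis cell.

    Volume rates are normalized to the cell's nominal area in hectares so
    a 1-ha cell reads directly in m^3 ha^-1 yr^-1; height gains/losses/net
    are cell-normalized (sum of dh over the class group / valid pixels /
    interval), while ``height_rate`` keeps the class-conditional mean.
    Losses are reported as absolute values.
    """
    codes = window.extract(change.class_map)
    dh = window.extract(delta_grid).astype(np.float64)
    valid = codes != NODATA_CLASS
    nvalid = int(valid.sum())
    pixel_area = delta_grid.pixel_size ** 2
    area_ha = window.cell.cell_size ** 2 / 1e4
    T = p.interval_years

    area_fraction: dict[int, float] = {}
    height_rate: dict[int, float] = {}
    volume_rate: dict[int, float] = {}
    for c in CLASS_NAMES:
        sel = codes == c
        n = int(sel.sum())
        area_fraction[c] = n / nvalid if nvalid else 0.0
        if n:
            s = float(dh[sel].sum())
            height_rate[c] = s / n / T
            volume_rate[c] = s * pixel_area / area_ha / T
        else:
            height_rate[c] = 0.0
            volume_rate[c] = 0.0

    gains_v = sum(volume_rate[c] for c in GAIN_CLASSES)
    losses_v_signed = sum(volume_rate[c] for c in LOSS_CLASSES)
    gain_dh = float(dh[np.isin(codes, GAIN_CLASSES)].sum()) if nvalid else 0.0
    loss_dh = float(dh[np.isin(codes, LOSS_CLASSES)].sum()) if nvalid else 0.0
    gains_h = gain_dh / nvalid / T if nvalid else 0.0
    losses_h_signed = loss_dh / nvalid / T if nvalid else 0.0

    return CellDynamics(
        cell=window.cell,
        forest_type=forest_type,
        valid_pixels=nvalid,
        area_fraction=area_fraction,
        height_rate=height_rate,
        volume_rate=volume_rate,
        gains_volume=gains_v,
        losses_volume=abs(losses_v_signed),
        net_volume=gains_v + losses_v_signed,
        gains_height=gains_h,
        losses_height=abs(losses_h_signed),
        net_height=gains_h + losses_h_signed,
    )


def summarize_cells(
    change: ChangeMap,
    delta_grid: RasterGrid,
    windows: Sequence[CellWindow],
    p: ChangeParams,
    forest_types: Optional[Sequence[object]] = None,
) -> pd.DataFrame:
    """Tabulate :func:`summarize_cell` over many cells (partial cells skipped)."""
    rows = []
    for i, w in enumerate(windows):
        if w.partial:
            continue
        ftype = forest_types[i] if forest_types is not None else None
        cd = summarize_cell(change, delta_grid, w, p, ftype)
        row: dict[str, object] = {
            "cell_row": w.cell.row,
            "cell_col": w.cell.col,
            "x": w.cell.centroid()[0],
            "y": w.cell.centroid()[1],
            "forest_type": cd.forest_type,
            "valid_pixels": cd.valid_pixels,
            "gains_volume": cd.gains_volume,
            "losses_volume": cd.losses_volume,
            "net_volume": cd.net_volume,
            "gains_height": cd.gains_height,
            "losses_height": cd.losses_height,
            "net_height": cd.net_height,
        }
        for c, name in CLASS_NAMES.items():
            row[f"frac_{name}"] = cd.area_fraction[c]
            row[f"hrate_{name}"] = cd.height_rate[c]
            row[f"vrate_{name}"] = cd.volume_rate[c]
        rows.append(row)
    return pd.DataFrame(rows)
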