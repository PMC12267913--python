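"""End-to-end assembly of the 1-ha cell record table.

Chains gap detection on both epochs, the five-class change partition,
terrain covariates, and structural metrics into one row per valid 1-ha
cell — the table the statistical layer consumes.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import terrain as terrain_mod
from .change_classification import ChangeParams, classify_change, delta, summarize_cells
from .gap_detection import GapDefinition, detect_gaps
from .raster_io import ChmPair, QualityThresholds, RasterGrid, cell_validity, tile_cells
from .structure_metrics import cell_structure

__all__ = ["build_cell_records"]


def build_cell_records(
    pair: ChmPair,
    dtm: RasterGrid,
    types: RasterGrid,
    gap_def: Optional[GapDefinition] = None,
    quality: Optional[QualityThresholds] = None,
    cell_size: float = 100.0,
    disturbance_drop: float = 5.0,
    disturbance_min_area: float = 25.0,
    twi_resolution: float = 25.0,
    slope_resolution: float = 10.0,
) -> pd.DataFrame:
    """One row per valid 1-ha cell: type, topography, structure, dynamics.

    Cells failing the missing-data (> 5%) or forest-type purity (>= 75%)
    rules, and partial edge cells, are dropped.
    """
    gap_def = gap_def or GapDefinition()
    quality = quality or QualityThresholds()
    params = ChangeParams(
        gap_def=gap_def,
        disturbance_drop=disturbance_drop,
        disturbance_min_area=disturbance_min_area,
        interval_years=pair.interval_years,
    )
    gaps1 = detect_gaps(pair.chm_t1, gap_def)
    gaps2 = detect_gaps(pair.chm_t2, gap_def)
    change = classify_change(pair, gaps1, gaps2, params)
    dgrid = delta(pair)

    windows = [w for w in tile_cells(pair.chm_t1, cell_size) if not w.partial]
    type_valid = types.valid_mask()

    keep = []
    forest_types = []
    for w in windows:
        chm_win = w.extract(pair.chm_t1)
        t_win = w.extract(types)
        tv = t_win[type_valid[w.row_slice, w.col_slice]]
        fracs = (
            {int(t): c / t_win.size for t, c in zip(*np.unique(tv, return_counts=True))}
            if tv.size
            else {}
        )
        valid, ftype = cell_validity(chm_win, quality, fracs, nodata=pair.chm_t1.nodata)
        if valid:
            keep.append(w)
            forest_types.append(ftype)
    if not keep:
        return pd.DataFrame()

    dyn = summarize_cells(change, dgrid, keep, params, forest_types)

    factor = max(1, int(round(slope_resolution / dtm.pixel_size)))
    twi_map = terrain_mod.twi(
        terrain_mod.aggregate_dtm(dtm, factor), target_resolution=twi_resolution
    )
    topo = terrain_mod.cell_topography(
        dtm, twi_map, [w.cell for w in keep], slope_resolution=slope_resolution
    )
    dyn["elevation"] = [t.elevation_mean for t in topo]
    dyn["slope"] = [t.slope_mean for t in topo]
    dyn["twi"] = [t.twi_mean for t in topo]

    structs = [
        cell_structure(
            w.extract(pair.chm_t1),
            gap_height_cutoff=gap_def.height_cutoff,
            nodata=pair.chm_t1.nodata,
            min_valid_fraction=1 - quality.max_missing_fraction,
            cell=w.cell,
        )
        for w in keep
    ]
    dyn["h_mean"] = [s.h_mean for s in structs]
    dyn["h_max"] = [s.h_max for s in structs]
    dyn["h_cv"] = [s.h_cv for s in structs]
    dyn["gf10"] = [s.gf10 for s in structs]
    return dyn
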