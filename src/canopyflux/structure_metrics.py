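"""Per-cell canopy structural metrics from a CHM window.

Four distributional metrics per 1-ha cell: mean top-of-canopy height
(H_mean), maximum canopy height as the 98th percentile (H_max), an
outlier-robust 0-1 bounded coefficient of height variation (H_cv), and the
canopy gap fraction at 10 m above ground (GF10, fraction of pixels < 10 m).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .raster_io import CellIndex

__all__ = ["CellStructure", "robust_cv", "cell_structure"]

H_MAX_PERCENTILE = 98.0


@dataclass
class CellStructure:
    cell: Optional[CellIndex]
    h_mean: float
    h_max: float
    h_cv: float
    gf10: float


def robust_cv(values: np.ndarray, lower: float = 5.0, upper: float = 95.0) -> float:
    """Quantile-ratio coefficient of variation (q95 - q5) / (q95 + q5).

    Bounded in [0, 1) for non-negative heights and insensitive to the top
    and bottom 5% of values. Returns 0 when all values are zero.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("robust_cv needs at least 2 values")
    qlo, qhi = np.percentile(v, [lower, upper])
    denom = qhi + qlo
    if denom == 0:
        return 0.0
    return float((qhi - qlo) / denom)


def cell_structure(
    chm_cell: np.ndarray,
    gap_height_cutoff: float = 10.0,
    nodata: float = -9999.0,
    min_valid_fraction: float = 0.95,
    cell: Optional[CellIndex] = None,
    cv_statistic: Callable[[np.ndarray], float] = robust_cv,
) -> CellStructure:
    """Structural metrics over the valid pixels of one cell window.

    Percentiles use linear interpolation between order statistics. The CV
    statistic is injectable; the default is the quantile-ratio form.
    Raises ``ValueError`` when fewer than ``min_valid_fraction`` of the
    cell's pixels are valid.
    """
    w = np.asarray(chm_cell, dtype=np.float64)
    valid = ~(np.isnan(w) | (w == nodata))
    if w.size == 0 or valid.mean() < min_valid_fraction:
        raise ValueError(
            f"cell has only {valid.mean() if w.size else 0:.1%} valid pixels "
            f"(need >= {min_valid_fraction:.0%})"
        )
    v = w[valid]
    return CellStructure(
        cell=cell,
        h_mean=float(v.mean()),
        h_max=float(np.percentile(v, H_MAX_PERCENTILE)),
        h_cv=float(cv_statistic(v)),
        gf10=float((v < gap_height_cutoff).mean()),
    )
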