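import numpy as np
import pytest

from canopyflux.raster_io import RasterGrid
from canopyflux.synthetic_landscape import LandscapeConfig, simulate_landscape


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Brute-force flood-fill labeling oracle (raster-scan seed order)."""
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    nrow, ncol = mask.shape
    labels = np.zeros(mask.shape, dtype=np.int32)
    next_id = 0
    for r0 in range(nrow):
        for c0 in range(ncol):
            if not mask[r0, c0] or labels[r0, c0]:
                continue
            next_id += 1
            stack = [(r0, c0)]
            labels[r0, c0] = next_id
            while stack:
                r, c = stack.pop()
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < nrow
                        and 0 <= cc < ncol
                        and mask[rr, cc]
                        and not labels[rr, cc]
                    ):
                        labels[rr, cc] = next_id
                        stack.append((rr, cc))
    return labels


def components_as_sets(labels: np.ndarray) -> set[frozenset]:
    out = set()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        out.add(frozenset(map(tuple, np.argwhere(labels == lab))))
    return out


@pytest.fixture
def grid_factory():
    def make(values, pixel_size=1.0, nodata=-9999.0, **kw):
        return RasterGrid(np.asarray(values, dtype=np.float32),
                          pixel_size=pixel_size, nodata=nodata, **kw)

    return make


@pytest.fixture(scope="session")
def small_bundle():
    """Fast 4-ha noise-free landscape with all three forest types."""
    cfg = LandscapeConfig(seed=11, extent=(200.0, 200.0), measurement_noise_sd=0.0)
    return simulate_landscape(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The default 25-ha landscape, noise-free."""
    cfg = LandscapeConfig(seed=3, measurement_noise_sd=0.0)
    return simulate_landscape(cfg)
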