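import numpy as np
import pytest

from mitofoi import (
    AnnotationSet,
    CellAnnotation,
    CellLabel,
    FOIShape,
    GridSpec,
    SlideGeometry,
    SyntheticConfig,
    foi_pixel_dims,
    mc_at_rect,
    rect_from_center,
)


@pytest.fixture(scope="session")
def coarse_shape() -> FOIShape:
    """The standard 2.37 mm² 4:3 FOI at 2.5 µm/px (711 x 533 px)."""
    return foi_pixel_dims(mpp=2.5)


@pytest.fixture(scope="session")
def coarse_cfg() -> SyntheticConfig:
    return SyntheticConfig.coarse(seed=0)


@pytest.fixture
def small_aset() -> AnnotationSet:
    """A tiny hand-built slide with a known mix of labels."""
    g = SlideGeometry(2000, 1500, mpp=2.5)
    cells = [
        CellAnnotation(100, 100, CellLabel.MITOSIS),
        CellAnnotation(900, 700, CellLabel.MITOSIS),
        CellAnnotation(905, 710, CellLabel.MITOSIS),
        CellAnnotation(910, 695, CellLabel.MITOSIS),
        CellAnnotation(1800, 1400, CellLabel.HARD_NEGATIVE),
        CellAnnotation(50, 1400, CellLabel.HARD_NEGATIVE),
    ]
    return AnnotationSet(slide_id="tiny", geometry=g, cells=cells)


def brute_force_count_map(points, geometry, shape, grid):
    """Reference windowed-count map: double loop over grid positions, clipped
    half-open window, vectorized point-in-rect test. Independent of the
    integral-image implementation."""
    out = np.zeros((grid.n_rows, grid.n_cols))
    for i, cy in enumerate(grid.centers_y()):
        for j, cx in enumerate(grid.centers_x()):
            rect = rect_from_center(int(cx), int(cy), shape).clip(geometry)
            out[i, j] = mc_at_rect(points, rect)
    return out


def brute_force_max_mc(points, geometry, shape, valid):
    """Max ground-truth MC over all valid grid positions, by exhaustive scan."""
    grid = valid.grid
    best = -1
    for i, j in np.argwhere(valid.mask):
        cx, cy = grid.center_at(int(i), int(j))
        rect = rect_from_center(cx, cy, shape).clip(geometry)
        best = max(best, mc_at_rect(points, rect))
    return best
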