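"""Position-dependent ground-truth mitotic count and moving-average machinery.

The central object is the :class:`DensityMap`: for every center on a regular
grid, the number of mitotic figures inside the 10-HPF window centered there.
The map is computed exactly with an integral image (2-D cumulative sum) over
a point-count histogram whose bin edges are the union of all clipped window
edges, so each windowed count is a four-corner lookup — O(rows·cols) total
after an O(n log n) histogram, and integer-exact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import FOIShape, Rect, SlideGeometry, rect_from_center

__all__ = [
    "GridSpec",
    "DensityMap",
    "windowed_count_map",
    "mc_at_rect",
    "moving_average",
    "mc_distribution",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular grid of candidate FOI centers.

    Centers are ``(origin_x + j*stride, origin_y + i*stride)`` for
    ``j < n_cols``, ``i < n_rows``; all centers must lie on the slide.
    """

    stride: int
    origin_x: int
    origin_y: int
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @classmethod
    def cover(cls, geometry: SlideGeometry, stride: int = 50) -> "GridSpec":
        """Grid covering the slide with centers at cell midpoints."""
        ox, oy = stride // 2, stride // 2
        ox = min(ox, geometry.width_px - 1)
        oy = min(oy, geometry.height_px - 1)
        n_cols = (geometry.width_px - 1 - ox) // stride + 1
        n_rows = (geometry.height_px - 1 - oy) // stride + 1
        return cls(stride=stride, origin_x=ox, origin_y=oy, n_cols=n_cols, n_rows=n_rows)

    def centers_x(self) -> np.ndarray:
        return self.origin_x + self.stride * np.arange(self.n_cols)

    def centers_y(self) -> np.ndarray:
        return self.origin_y + self.stride * np.arange(self.n_rows)

    def center_at(self, row: int, col: int) -> tuple[int, int]:
        return (self.origin_x + self.stride * col, self.origin_y + self.stride * row)


@dataclass
class DensityMap:
    """Raster of windowed mitotic counts (or count estimates) on a GridSpec."""

    grid: GridSpec
    window_w: int
    window_h: int
    values: np.ndarray  # float64, shape (n_rows, n_cols), >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_rows}, {self.grid.n_cols})"
            )
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    def write(self, path: str | Path, mpp: float | None = None) -> None:
        """Write as 32-bit float single-channel TIFF + JSON sidecar."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.values.astype(np.float32))
        sidecar = {
            "stride": self.grid.stride,
            "origin_x": self.grid.origin_x,
            "origin_y": self.grid.origin_y,
            "window_w": self.window_w,
            "window_h": self.window_h,
        }
        if mpp is not None:
            sidecar["mpp"] = mpp
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "DensityMap":
        import tifffile

        path = Path(path)
        values = tifffile.imread(path).astype(np.float64)
        meta = json.loads(path.with_suffix(".json").read_text())
        grid = GridSpec(
            stride=meta["stride"],
            origin_x=meta["origin_x"],
            origin_y=meta["origin_y"],
            n_cols=values.shape[1],
            n_rows=values.shape[0],
        )
        return cls(grid=grid, window_w=meta["window_w"], window_h=meta["window_h"], values=values)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        return np.empty((0, 2))
    return pts.reshape(-1, 2)


def windowed_count_map(
    points,
    geometry: SlideGeometry,
    shape: FOIShape,
    grid: GridSpec,
) -> DensityMap:
    """Count, for every grid center, the points in the half-open FOI window there.

    Windows extending past the slide border are clipped to the slide (the
    valid mask later removes such centers anyway); if the window exceeds the
    slide in either dimension a warning is emitted.
    """
    pts = _as_points(points)
    if shape.width_px > geometry.width_px or shape.height_px > geometry.height_px:
        warnings.warn(
            "FOI window larger than slide; counts are over the clipped window",
            stacklevel=2,
        )

    cx = grid.centers_x()
    cy = grid.centers_y()
    x0 = np.clip(cx - shape.width_px // 2, 0, geometry.width_px)
    x1 = np.clip(cx - shape.width_px // 2 + shape.width_px, 0, geometry.width_px)
    y0 = np.clip(cy - shape.height_px // 2, 0, geometry.height_px)
    y1 = np.clip(cy - shape.height_px // 2 + shape.height_px, 0, geometry.height_px)

    # Coordinate-compressed histogram: bin edges are every distinct window
    # edge plus the slide bounds, so each window boundary falls exactly on a
    # bin edge and the count is exact.
    xedges = np.unique(np.concatenate(([0, geometry.width_px], x0, x1)))
    yedges = np.unique(np.concatenate(([0, geometry.height_px], y0, y1)))

    if len(pts):
        hist, _, _ = np.histogram2d(pts[:, 1], pts[:, 0], bins=[yedges, xedges])
    else:
        hist = np.zeros((len(yedges) - 1, len(xedges) - 1))

    # F[k, l] = number of points with y < yedges[k] and x < xedges[l]
    F = np.zeros((len(yedges), len(xedges)))
    F[1:, 1:] = hist.cumsum(axis=0).cumsum(axis=1)

    ix0 = np.searchsorted(xedges, x0)
    ix1 = np.searchsorted(xedges, x1)
    iy0 = np.searchsorted(yedges, y0)
    iy1 = np.searchsorted(yedges, y1)

    values = (
        F[np.ix_(iy1, ix1)]
        - F[np.ix_(iy0, ix1)]
        - F[np.ix_(iy1, ix0)]
        + F[np.ix_(iy0, ix0)]
    )
    return DensityMap(grid=grid, window_w=shape.width_px, window_h=shape.height_px, values=values)


def mc_at_rect(points, rect: Rect) -> int:
    """Number of points inside a half-open rectangle."""
    pts = _as_points(points)
    if not len(pts):
        return 0
    inside = (
        (pts[:, 0] >= rect.x0)
        & (pts[:, 0] < rect.x1)
        & (pts[:, 1] >= rect.y0)
        & (pts[:, 1] < rect.y1)
    )
    return int(inside.sum())


def moving_average(raster: np.ndarray, kernel_w: int, kernel_h: int) -> np.ndarray:
    """Valid-mode 2-D mean filter via an integral image.

    Output shape is ``(rows - kernel_h + 1, cols - kernel_w + 1)``; each
    output value is the mean of the covered ``kernel_h x kernel_w`` block.
    """
    raster = np.asarray(raster, dtype=np.float64)
    if raster.ndim != 2:
        raise ValueError("raster must be 2-D")
    rows, cols = raster.shape
    if kernel_w < 1 or kernel_h < 1:
        raise ValueError("kernel dimensions must be >= 1")
    if kernel_w > cols or kernel_h > rows:
        raise ValueError("kernel larger than raster")
    S = np.zeros((rows + 1, cols + 1))
    S[1:, 1:] = raster.cumsum(axis=0).cumsum(axis=1)
    total = (
        S[kernel_h:, kernel_w:]
        - S[:-kernel_h, kernel_w:]
        - S[kernel_h:, :-kernel_w]
        + S[:-kernel_h, :-kernel_w]
    )
    return total / (kernel_w * kernel_h)


def mc_distribution(dmap: DensityMap, valid) -> np.ndarray:
    """Ascending multiset of map values at valid grid positions.

    This is the distribution of achievable mitotic counts over all admissible
    FOI placements on the slide — the reference against which a particular
    selection is scored.
    """
    mask = np.asarray(valid.mask if hasattr(valid, "mask") else valid, dtype=bool)
    if mask.shape != dmap.values.shape:
        raise ValueError("valid mask not aligned to density map grid")
    vals = dmap.values[mask]
    if vals.size == 0:
        raise ValueError("no valid FOI position: empty mitotic-count distribution")
    return np.sort(vals)
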