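"""Tissue segmentation and the valid-FOI-center mask.

FOI candidates are restricted to positions whose 10-HPF window is at least
95% covered by tissue and lies fully on the slide. Tissue is segmented on a
low-resolution render by Otsu thresholding of the grayscale image followed
by morphological closing; windowed tissue coverage is then evaluated with an
integral image over the downsampled tissue raster.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .density import GridSpec
from .geometry import FOIShape, SlideGeometry

__all__ = ["TissueMask", "ValidMask", "tissue_mask", "valid_mask"]

DEFAULT_DOWNSAMPLE = 32
DEFAULT_CLOSING_RADIUS = 5
DEFAULT_COVERAGE = 0.95


@dataclass
class TissueMask:
    """Boolean tissue raster at a stated integer downsample factor."""

    mask: np.ndarray
    downsample: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("tissue mask must be 2-D")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())

    def area_mm2(self, mpp: float) -> float:
        """Tissue area in mm² given the full-resolution pixel size."""
        px_um = self.downsample * mpp
        return float(self.mask.sum()) * px_um ** 2 / 1e6

    def write(self, path: str | Path) -> None:
        import imageio.v3 as iio

        path = Path(path)
        iio.imwrite(path, (self.mask.astype(np.uint8) * 255))
        path.with_suffix(".json").write_text(
            json.dumps({"downsample": self.downsample}) + "\n"
        )

    @classmethod
    def read(cls, path: str | Path) -> "TissueMask":
        import imageio.v3 as iio

        path = Path(path)
        raw = iio.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(mask=raw > 127, downsample=int(meta["downsample"]))


@dataclass
class ValidMask:
    """Boolean raster over a GridSpec marking admissible FOI centers."""

    grid: GridSpec
    mask: np.ndarray
    coverage_threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("valid mask shape does not match grid")


def tissue_mask(
    rgb: np.ndarray,
    downsample: int = DEFAULT_DOWNSAMPLE,
    closing_radius: int = DEFAULT_CLOSING_RADIUS,
) -> TissueMask:
    """Segment tissue on a low-resolution RGB render.

    A pixel is tissue iff its grayscale intensity is below the Otsu threshold
    of the grayscale histogram (tissue is darker than the white slide
    background); small holes and gaps are then closed with a disk structuring
    element of ``closing_radius`` pixels at the render's resolution.

    A degenerate (uniform) image yields an all-background mask with a warning.
    """
    rgb = np.asarray(rgb)
    if rgb.size == 0:
        raise ValueError("empty image")
    gray = rgb2gray(rgb) if rgb.ndim == 3 else rgb.astype(np.float64)
    if np.ptp(gray) == 0:
        warnings.warn("uniform image: cannot separate tissue from background", stacklevel=2)
        return TissueMask(mask=np.zeros(gray.shape, dtype=bool), downsample=downsample)
    t = threshold_otsu(gray)
    mask = gray < t
    if closing_radius > 0:
        mask = closing(mask, disk(closing_radius))
    return TissueMask(mask=mask, downsample=downsample)


def valid_mask(
    tissue: TissueMask,
    grid: GridSpec,
    shape: FOIShape,
    coverage: float = DEFAULT_COVERAGE,
    geometry: SlideGeometry | None = None,
) -> ValidMask:
    """Mark grid centers whose FOI window is fully on-slide and >= ``coverage`` tissue.

    The tissue fraction of each window is evaluated on the downsampled tissue
    raster (window edges rounded to downsampled pixels) via an integral
    image; the coverage comparison is inclusive (a window at exactly the
    threshold is valid).

    ``geometry`` supplies the exact full-resolution slide bounds; if omitted
    they are inferred from the tissue raster shape times the downsample.
    """
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    ds = tissue.downsample
    mh, mw = tissue.mask.shape
    if geometry is None:
        geometry = SlideGeometry(width_px=mw * ds, height_px=mh * ds, mpp=shape.mpp)

    cx = grid.centers_x()
    cy = grid.centers_y()
    x0 = cx - shape.width_px // 2
    y0 = cy - shape.height_px // 2
    x1 = x0 + shape.width_px
    y1 = y0 + shape.height_px
    inside_x = (x0 >= 0) & (x1 <= geometry.width_px)
    inside_y = (y0 >= 0) & (y1 <= geometry.height_px)

    S = np.zeros((mh + 1, mw + 1))
    S[1:, 1:] = tissue.mask.astype(np.float64).cumsum(axis=0).cumsum(axis=1)

    x0d = np.clip(np.rint(x0 / ds).astype(int), 0, mw)
    x1d = np.clip(np.rint(x1 / ds).astype(int), 0, mw)
    y0d = np.clip(np.rint(y0 / ds).astype(int), 0, mh)
    y1d = np.clip(np.rint(y1 / ds).astype(int), 0, mh)
    x1d = np.maximum(x1d, x0d + 1)
    y1d = np.maximum(y1d, y0d + 1)
    x1d = np.clip(x1d, 0, mw)
    y1d = np.clip(y1d, 0, mh)
    x0d = np.minimum(x0d, x1d - 1).clip(0, mw)
    y0d = np.minimum(y0d, y1d - 1).clip(0, mh)

    tissue_px = (
        S[np.ix_(y1d, x1d)]
        - S[np.ix_(y0d, x1d)]
        - S[np.ix_(y1d, x0d)]
        + S[np.ix_(y0d, x0d)]
    )
    window_px = np.outer(y1d - y0d, x1d - x0d).astype(np.float64)
    frac = tissue_px / window_px
    # inclusive threshold; epsilon guards against float round-off at the boundary
    covered = frac >= coverage - 1e-12
    mask = covered & np.outer(inside_y, inside_x)
    return ValidMask(grid=grid, mask=mask, coverage_threshold=coverage)
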