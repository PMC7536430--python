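"""Pluggable per-slide mitotic-density estimators.

Every estimator produces an :class:`EstimatorOutput` — a windowed-count
DensityMap plus a provenance tag — so the selection head is agnostic to the
source. The annotation-based oracle is the upper bound; the noisy oracle
emulates detector error (missed figures, false positives); the adapters turn
externally produced detection lists or segmentation rasters into density
maps, so trained models can plug into the pipeline without changing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .annotations import AnnotationSet, CellLabel
from .density import DensityMap, GridSpec, windowed_count_map
from .geometry import FOIShape
from .tissue import TissueMask

__all__ = [
    "Detection",
    "EstimatorOutput",
    "oracle_density",
    "noisy_oracle",
    "detections_to_points",
    "segmap_to_density",
]


@dataclass(frozen=True)
class Detection:
    """A candidate mitotic figure from an external detector.

    ``score1`` is the first-stage (detector) confidence; ``score2`` is the
    optional second-stage (refining classifier) confidence.
    """

    x: float
    y: float
    score1: float
    score2: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.score1 <= 1):
            raise ValueError("score1 must be in [0, 1]")
        if self.score2 is not None and not (0 <= self.score2 <= 1):
            raise ValueError("score2 must be in [0, 1]")


@dataclass
class EstimatorOutput:
    """A density map with a provenance tag.

    ``per_patch`` marks maps of raw per-grid-cell estimates that still need
    the 10-HPF moving average in the selection head; all estimators in this
    module already emit windowed counts (``per_patch=False``).
    """

    density: DensityMap
    provenance: str
    per_patch: bool = False


def oracle_density(aset: AnnotationSet, shape: FOIShape, grid: GridSpec) -> EstimatorOutput:
    """Ground-truth windowed mitotic count map (the ideal estimator)."""
    pts = aset.points(CellLabel.MITOSIS)
    dmap = windowed_count_map(pts, aset.geometry, shape, grid)
    return EstimatorOutput(density=dmap, provenance="oracle")


def _uniform_points_in_tissue(
    rng: np.random.Generator, n: int, tissue: TissueMask, width: int, height: int
) -> np.ndarray:
    """Rejection-sample n uniform integer points over the tissue region."""
    if n == 0:
        return np.empty((0, 2), dtype=np.int64)
    out = []
    need = n
    frac = max(tissue.tissue_fraction, 1e-6)
    while need > 0:
        m = int(need / frac * 1.5) + 16
        xs = rng.integers(0, width, size=m)
        ys = rng.integers(0, height, size=m)
        keep = tissue.mask[
            np.minimum(ys // tissue.downsample, tissue.mask.shape[0] - 1),
            np.minimum(xs // tissue.downsample, tissue.mask.shape[1] - 1),
        ]
        pts = np.column_stack([xs[keep], ys[keep]])
        out.append(pts[:need])
        need -= min(need, len(pts))
    return np.concatenate(out)


def noisy_oracle(
    aset: AnnotationSet,
    shape: FOIShape,
    grid: GridSpec,
    fn_rate: float = 0.0,
    fp_per_mm2: float = 0.0,
    seed: int = 0,
    tissue: TissueMask | None = None,
) -> EstimatorOutput:
    """Oracle degraded by misses and spurious detections.

    Each true mitosis is dropped independently with probability ``fn_rate``;
    false positives are added as a uniform Poisson process at ``fp_per_mm2``
    over the tissue region (over the whole slide if no tissue mask is given).
    Deterministic given ``seed``. The per-point drop uniforms are drawn first
    and depend only on the seed, so runs sharing a seed but differing in
    fn_rate have nested retained point sets.
    """
    if not (0 <= fn_rate <= 1):
        raise ValueError("fn_rate must be in [0, 1]")
    if fp_per_mm2 < 0:
        raise ValueError("fp_per_mm2 must be >= 0")
    rng = np.random.default_rng(seed)
    g = aset.geometry
    pts = aset.points(CellLabel.MITOSIS)
    u = rng.random(len(pts))
    kept = pts[u >= fn_rate] if len(pts) else pts

    if fp_per_mm2 > 0:
        area = tissue.area_mm2(g.mpp) if tissue is not None else g.area_mm2
        n_fp = int(rng.poisson(fp_per_mm2 * area))
        if tissue is not None:
            fp = _uniform_points_in_tissue(rng, n_fp, tissue, g.width_px, g.height_px)
        else:
            fp = np.column_stack(
                [rng.integers(0, g.width_px, n_fp), rng.integers(0, g.height_px, n_fp)]
            )
        kept = np.concatenate([kept.reshape(-1, 2), fp.reshape(-1, 2)])

    dmap = windowed_count_map(kept, g, shape, grid)
    return EstimatorOutput(density=dmap, provenance="noisy_oracle")


def detections_to_points(
    dets: list[Detection], t1: float = 0.5, t2: float = 0.5
) -> np.ndarray:
    """Threshold a detection list into accepted mitosis points.

    Keeps detections with ``score1 >= t1`` whose second-stage score, where
    present, is ``>= t2``; order-preserving. Antitone in both thresholds.
    """
    if not (0 <= t1 <= 1 and 0 <= t2 <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    kept = [
        (d.x, d.y)
        for d in dets
        if d.score1 >= t1 and (d.score2 is None or d.score2 >= t2)
    ]
    if not kept:
        return np.empty((0, 2))
    return np.asarray(kept, dtype=np.float64)


def segmap_to_density(
    mask: np.ndarray,
    shape: FOIShape,
    grid: GridSpec,
    d: float = 50.0,
    downsample: int = 1,
    geometry=None,
) -> EstimatorOutput:
    """Convert a binary mitosis-segmentation raster into a windowed count estimate.

    The value at each grid center is the segmented area inside the window,
    rescaled to full-resolution pixel units, divided by the area of one ideal
    figure disc, pi*(d/2)**2 — i.e., "how many figure discs' worth of mask"
    the window holds.
    """
    from .geometry import SlideGeometry

    mask = np.asarray(mask, dtype=bool)
    mh, mw = mask.shape
    if geometry is None:
        geometry = SlideGeometry(
            width_px=mw * downsample, height_px=mh * downsample, mpp=shape.mpp
        )

    S = np.zeros((mh + 1, mw + 1))
    S[1:, 1:] = mask.astype(np.float64).cumsum(axis=0).cumsum(axis=1)

    cx = grid.centers_x()
    cy = grid.centers_y()
    x0 = np.clip(np.rint((cx - shape.width_px // 2) / downsample).astype(int), 0, mw)
    x1 = np.clip(
        np.rint((cx - shape.width_px // 2 + shape.width_px) / downsample).astype(int), 0, mw
    )
    y0 = np.clip(np.rint((cy - shape.height_px // 2) / downsample).astype(int), 0, mh)
    y1 = np.clip(
        np.rint((cy - shape.height_px // 2 + shape.height_px) / downsample).astype(int), 0, mh
    )
    seg_px = (
        S[np.ix_(y1, x1)] - S[np.ix_(y0, x1)] - S[np.ix_(y1, x0)] + S[np.ix_(y0, x0)]
    )
    disc_area = np.pi * (d / 2) ** 2
    values = seg_px * downsample ** 2 / disc_area
    dmap = DensityMap(
        grid=grid, window_w=shape.width_px, window_h=shape.height_px, values=values
    )
    return EstimatorOutput(density=dmap, provenance="segmentation")
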