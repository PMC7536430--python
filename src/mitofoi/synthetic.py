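"""Synthetic slide generator: clustered mitoses inside irregular tissue.

Real tumor sections show a patchy, clustered spatial distribution of mitotic
figures; this module emulates that structure with a Thomas cluster process
(Poisson parents with Gaussian-displaced Poisson offspring) restricted to a
tissue region built from random soft-edged blobs, plus a uniform background
of mitoses and of mitosis-like hard negatives. The generator produces the
same artifacts the pipeline consumes from real data — an annotation set, a
tissue mask, and a low-resolution H&E-like RGB render — and is fully
deterministic given its seed.

Default scale: a 2.5 x 2.0 mm slide at 0.25 µm/px (10000 x 8000 px), a
10x-scaled-down analog of a typical tumor section, with rates placing the
hottest windows near the 7-per-10-HPF grading threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotations import AnnotationSet, CellAnnotation, CellLabel
from .density import GridSpec
from .geometry import FOIShape, SlideGeometry, foi_pixel_dims
from .tissue import TissueMask, valid_mask

__all__ = [
    "SyntheticConfig",
    "generate_tissue",
    "generate_annotations",
    "generate_planted_hotspot",
]

_PINK = np.array([230.0, 160.0, 200.0])  # H&E-like tissue color


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the tissue-blob and clustered point-process generator.

    Rates are per mm² of tissue; pixel-valued parameters are at full
    resolution.
    """

    width_px: int = 10000
    height_px: int = 8000
    mpp: float = 0.25
    downsample: int = 32
    n_tissue_blobs: int = 5
    blob_radius_mean: float = 4600.0
    blob_radius_sd: float = 400.0
    parent_rate: float = 0.25       # cluster centers per mm² of tissue
    offspring_mean: float = 8.0     # expected figures per cluster
    cluster_sigma: float = 150.0    # isotropic Gaussian spread, px
    background_rate: float = 1.0    # uniform mitoses per mm²
    hard_negative_rate: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0 or self.mpp <= 0:
            raise ValueError("slide dimensions and mpp must be positive")
        for name in ("parent_rate", "offspring_mean", "background_rate", "hard_negative_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def geometry(self) -> SlideGeometry:
        return SlideGeometry(self.width_px, self.height_px, self.mpp)

    @classmethod
    def coarse(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Same physical extents represented at 2.5 µm/px (1000 x 800 px).

        Pixel-valued parameters are rescaled; rates are physical and
        unchanged. Convenient for simulation studies with many replicates.
        """
        cfg = cls(
            width_px=1000,
            height_px=800,
            mpp=2.5,
            downsample=4,
            blob_radius_mean=460.0,
            blob_radius_sd=40.0,
            cluster_sigma=15.0,
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg


def generate_tissue(cfg: SyntheticConfig) -> tuple[TissueMask, np.ndarray]:
    """Generate a tissue mask (union of random discs) and an H&E-like RGB render.

    The render colors tissue in pink on a white background with a soft
    (blurred) edge and mild noise, so the tissue-segmentation branch can
    recover the mask from it.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    ds = cfg.downsample
    mh = -(-cfg.height_px // ds)
    mw = -(-cfg.width_px // ds)
    mask = np.zeros((mh, mw), dtype=bool)

    xs = (np.arange(mw) + 0.5) * ds
    ys = (np.arange(mh) + 0.5) * ds
    # principal tumor mass centered on the slide, plus random satellite lobes
    # for an irregular outline
    for i in range(cfg.n_tissue_blobs):
        if i == 0:
            cx, cy = cfg.width_px / 2, cfg.height_px / 2
            r = cfg.blob_radius_mean
        else:
            cx = rng.uniform(0.15 * cfg.width_px, 0.85 * cfg.width_px)
            cy = rng.uniform(0.15 * cfg.height_px, 0.85 * cfg.height_px)
            r = max(abs(rng.normal(0.5 * cfg.blob_radius_mean, cfg.blob_radius_sd)), 4 * ds)
        mask |= (ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2 <= r * r

    alpha = gaussian_filter(mask.astype(np.float64), sigma=1.0)
    img = 255.0 * (1.0 - alpha[..., None]) + _PINK * alpha[..., None]
    img += rng.normal(0.0, 2.0, size=img.shape)
    rgb = np.clip(img, 0, 255).astype(np.uint8)
    return TissueMask(mask=mask, downsample=ds), rgb


def _uniform_in_tissue(
    rng: np.random.Generator, n: int, tissue: TissueMask, cfg: SyntheticConfig
) -> np.ndarray:
    """n uniform integer points over the tissue region (rejection sampling)."""
    if n == 0 or not tissue.mask.any():
        return np.empty((0, 2), dtype=np.int64)
    ds = tissue.downsample
    frac = tissue.tissue_fraction
    chunks, need = [], n
    while need > 0:
        m = int(need / frac * 1.5) + 16
        x = rng.integers(0, cfg.width_px, size=m)
        y = rng.integers(0, cfg.height_px, size=m)
        keep = tissue.mask[
            np.minimum(y // ds, tissue.mask.shape[0] - 1),
            np.minimum(x // ds, tissue.mask.shape[1] - 1),
        ]
        pts = np.column_stack([x[keep], y[keep]])[:need]
        chunks.append(pts)
        need -= len(pts)
    return np.concatenate(chunks)


def _in_tissue(pts: np.ndarray, tissue: TissueMask, cfg: SyntheticConfig) -> np.ndarray:
    ds = tissue.downsample
    inb = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] < cfg.width_px)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] < cfg.height_px)
    )
    out = np.zeros(len(pts), dtype=bool)
    if inb.any():
        p = pts[inb]
        out[inb] = tissue.mask[
            np.minimum(p[:, 1] // ds, tissue.mask.shape[0] - 1),
            np.minimum(p[:, 0] // ds, tissue.mask.shape[1] - 1),
        ]
    return out


def generate_annotations(cfg: SyntheticConfig, tissue: TissueMask) -> AnnotationSet:
    """Thomas cluster process of mitoses restricted to tissue, plus uniform
    background mitoses and hard negatives.

    Parents are Poisson(parent_rate * tissue area) placed uniformly in
    tissue; each gets Poisson(offspring_mean) offspring displaced by an
    isotropic Gaussian of sd ``cluster_sigma``; offspring falling outside the
    tissue (or slide) are rejected. Expected mitosis count is approximately
    (parent_rate * offspring_mean + background_rate) * tissue area, minus a
    small edge loss.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    area = tissue.area_mm2(cfg.mpp)

    n_parents = int(rng.poisson(cfg.parent_rate * area))
    parents = _uniform_in_tissue(rng, n_parents, tissue, cfg)
    cluster_pts = np.empty((0, 2), dtype=np.int64)
    if len(parents):
        counts = rng.poisson(cfg.offspring_mean, size=len(parents))
        total = int(counts.sum())
        if total:
            centers = np.repeat(parents, counts, axis=0)
            disp = rng.normal(0.0, cfg.cluster_sigma, size=(total, 2))
            pts = np.rint(centers + disp).astype(np.int64)
            cluster_pts = pts[_in_tissue(pts, tissue, cfg)]

    n_bg = int(rng.poisson(cfg.background_rate * area))
    bg = _uniform_in_tissue(rng, n_bg, tissue, cfg)
    n_hn = int(rng.poisson(cfg.hard_negative_rate * area))
    hn = _uniform_in_tissue(rng, n_hn, tissue, cfg)

    cells = [
        CellAnnotation(int(x), int(y), CellLabel.MITOSIS)
        for x, y in np.concatenate([cluster_pts, bg])
    ] + [CellAnnotation(int(x), int(y), CellLabel.HARD_NEGATIVE) for x, y in hn]
    return AnnotationSet(slide_id=f"synthetic-{cfg.seed}", geometry=cfg.geometry, cells=cells)


def generate_planted_hotspot(
    cfg: SyntheticConfig,
    hotspot_mc: int = 30,
    shape: FOIShape | None = None,
    stride: int = 50,
    coverage: float = 0.95,
) -> tuple[AnnotationSet, tuple[int, int], TissueMask]:
    """Background slide plus one dense planted cluster at a known valid center.

    The planted cluster holds exactly ``hotspot_mc`` mitoses drawn tightly
    (Gaussian, truncated to the central half of the FOI window) around a
    randomly chosen valid grid center, so the window there is guaranteed to
    contain all of them and the selection pipeline can be checked against the
    known center. Requires ``hotspot_mc >= 2 * expected background window MC
    + 5`` (the margin), else raises.

    Returns (annotation set, planted center, tissue mask).
    """
    if shape is None:
        shape = foi_pixel_dims(mpp=cfg.mpp)
    expected_bg = (cfg.parent_rate * cfg.offspring_mean + cfg.background_rate) * shape.area_mm2
    if hotspot_mc < 2 * expected_bg + 5:
        raise ValueError(
            f"hotspot_mc={hotspot_mc} does not exceed the expected background window "
            f"MC ({expected_bg:.1f}) by the required margin (>= {2 * expected_bg + 5:.1f})"
        )

    tissue, _ = generate_tissue(cfg)
    base = generate_annotations(cfg, tissue)

    grid = GridSpec.cover(cfg.geometry, stride)
    vm = valid_mask(tissue, grid, shape, coverage=coverage, geometry=cfg.geometry)
    valid_idx = np.argwhere(vm.mask)
    if len(valid_idx) == 0:
        raise ValueError("no valid FOI position on the generated slide; margin unsatisfiable")

    rng = np.random.default_rng([cfg.seed, 2])
    row, col = valid_idx[rng.integers(len(valid_idx))]
    cx, cy = grid.center_at(int(row), int(col))

    sigma = min(shape.width_px, shape.height_px) / 12
    lim_x = shape.width_px / 4 - 1
    lim_y = shape.height_px / 4 - 1
    dx = np.clip(rng.normal(0.0, sigma, hotspot_mc), -lim_x, lim_x)
    dy = np.clip(rng.normal(0.0, sigma, hotspot_mc), -lim_y, lim_y)
    hx = np.clip(np.rint(cx + dx), 0, cfg.width_px - 1).astype(int)
    hy = np.clip(np.rint(cy + dy), 0, cfg.height_px - 1).astype(int)

    cells = list(base.cells) + [
        CellAnnotation(int(x), int(y), CellLabel.MITOSIS) for x, y in zip(hx, hy)
    ]
    aset = AnnotationSet(slide_id=base.slide_id, geometry=cfg.geometry, cells=cells)
    return aset, (int(cx), int(cy)), tissue
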