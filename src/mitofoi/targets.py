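"""Training-target construction: fractional regression counts, segmentation
circle maps, and the three-group training-patch sampler.

The regression target counts mitotic figures in a patch *including partial
figures at the border*: a figure is modelled as a d x d axis-aligned box
around its center, and contributes the fraction of that box overlapping the
patch. The per-axis partial weight is the trapezoid

    gamma(x; d) = d            for x <= -d/2
                = d/2 - x      for -d/2 < x < d/2
                = 0            for x >= d/2

where x is the signed offset of the figure center past the patch half-width
(x = |p| - w/2); gamma(x)/d is exactly the overlap fraction of the interval
[x - d/2, x + d/2] with the half-line (-inf, 0]. The full target is

    C = (1/beta) * sum_i gamma(|p_x(i)| - w/2) * gamma(|p_y(i)| - h/2) / d**2

so a figure fully inside the patch contributes exactly 1/beta.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationSet, CellLabel

__all__ = [
    "PatchFrame",
    "RegressionConfig",
    "PatchGroup",
    "gamma_weight",
    "regression_target",
    "segmentation_target",
    "sample_training_patches",
    "patch_fits_slide",
    "points_in_rotated_patch",
]

#: Approximated mitotic-figure diameter in px at 0.25 µm/px (12.5 µm),
#: matching the segmentation circle diameter.
DEFAULT_DIAMETER = 50.0

#: Heuristic normalization of the regression target.
DEFAULT_BETA = 10.0

DEFAULT_PATCH = (512, 512)


@dataclass(frozen=True)
class PatchFrame:
    """A patch of size w x h with figure centers in patch-center-relative coordinates."""

    w: float
    h: float
    points: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("patch dimensions must be positive")
        object.__setattr__(self, "points", tuple((float(x), float(y)) for x, y in self.points))


@dataclass(frozen=True)
class RegressionConfig:
    """Parameters of the regression count: figure diameter d (px) and
    normalization beta."""

    d: float = DEFAULT_DIAMETER
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("diameter d must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


class PatchGroup(str, enum.Enum):
    """Training-patch sampling groups."""

    WITH_MITOSIS = "with_mitosis"
    WITH_HARD_NEGATIVE = "with_hard_negative"
    RANDOM = "random"


def gamma_weight(x, d: float):
    """Per-axis partial weight of a figure straddling a patch border.

    Continuous, non-increasing, bounded in [0, d]; accepts scalars or arrays.
    """
    if d <= 0:
        raise ValueError("diameter d must be positive")
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x <= -d / 2, d, np.where(x < d / 2, d / 2 - x, 0.0))
    return out if out.ndim else float(out)


def regression_target(patch: PatchFrame, cfg: RegressionConfig = RegressionConfig()) -> float:
    """Normalized fractional mitotic count C of a patch.

    Each figure contributes its fractional d x d box overlap with the patch,
    divided by beta; a fully interior figure contributes exactly 1/beta.
    """
    if not patch.points:
        return 0.0
    pts = np.asarray(patch.points, dtype=np.float64)
    gx = gamma_weight(np.abs(pts[:, 0]) - patch.w / 2, cfg.d)
    gy = gamma_weight(np.abs(pts[:, 1]) - patch.h / 2, cfg.d)
    return float(np.sum(gx * gy) / cfg.d ** 2 / cfg.beta)


def segmentation_target(patch: PatchFrame, d: float = DEFAULT_DIAMETER) -> np.ndarray:
    """Binary h x w raster with a filled circle of diameter d at every figure.

    Pixel (row, col) covers the unit square [col, col+1) x [row, row+1) in
    patch coordinates; it is set iff its center lies within d/2 of a figure
    center.
    """
    w, h = int(round(patch.w)), int(round(patch.h))
    out = np.zeros((h, w), dtype=bool)
    if not patch.points:
        return out
    # pixel centers in patch-center-relative coordinates
    xs = np.arange(w) + 0.5 - w / 2
    ys = np.arange(h) + 0.5 - h / 2
    r2 = (d / 2) ** 2
    for px, py in patch.points:
        dx2 = (xs - px) ** 2
        dy2 = (ys - py) ** 2
        out |= dy2[:, None] + dx2[None, :] <= r2
    return out


def patch_fits_slide(cx: float, cy: float, patch_wh: tuple[int, int], aset: AnnotationSet) -> bool:
    """True iff the bounding circle of the (arbitrarily rotated) patch is on-slide."""
    w, h = patch_wh
    r = math.hypot(w, h) / 2
    g = aset.geometry
    return r <= cx <= g.width_px - r and r <= cy <= g.height_px - r


def points_in_rotated_patch(
    points: np.ndarray, cx: float, cy: float, patch_wh: tuple[int, int], rotation: float
) -> np.ndarray:
    """Boolean mask of points inside the patch rotated by ``rotation`` about its center.

    Containment is evaluated in the rotated patch frame: a point p is inside
    iff R(rotation) @ (p - center) falls within the axis-aligned w x h box.
    """
    w, h = patch_wh
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    d = pts - np.array([cx, cy])
    c, s = math.cos(rotation), math.sin(rotation)
    u = c * d[:, 0] + s * d[:, 1]
    v = -s * d[:, 0] + c * d[:, 1]
    return (np.abs(u) <= w / 2) & (np.abs(v) <= h / 2)


def sample_training_patches(
    aset: AnnotationSet,
    group: PatchGroup,
    n: int,
    patch: tuple[int, int] = DEFAULT_PATCH,
    seed: int = 0,
    max_tries: int = 1000,
) -> list[tuple[float, float, float]]:
    """Sample n training-patch specs (center_x, center_y, rotation_rad).

    Patches are rotated arbitrarily (uniform in [0, 2*pi)) about their center
    before cropping and must lie fully on the slide (bounding-circle
    criterion). For the conditioned groups, a cell of the required label is
    guaranteed inside the rotated patch. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    w, h = patch
    g = aset.geometry
    r = math.hypot(w, h) / 2
    if 2 * r > g.width_px or 2 * r > g.height_px:
        raise ValueError("rotated patch cannot fit inside the slide")

    if group == PatchGroup.WITH_MITOSIS:
        pool = aset.points(CellLabel.MITOSIS)
    elif group == PatchGroup.WITH_HARD_NEGATIVE:
        pool = aset.points(CellLabel.HARD_NEGATIVE)
    else:
        pool = None
    if pool is not None and len(pool) == 0:
        raise ValueError(f"no cells available for sampling group {group.value!r}")

    out: list[tuple[float, float, float]] = []
    for _ in range(n):
        for _attempt in range(max_tries):
            theta = float(rng.uniform(0, 2 * math.pi))
            if pool is None:
                cx = float(rng.uniform(r, g.width_px - r))
                cy = float(rng.uniform(r, g.height_px - r))
                out.append((cx, cy, theta))
                break
            # choose an anchor cell and a position for it inside the rotated frame,
            # then back out the patch center
            px, py = pool[rng.integers(len(pool))]
            u = float(rng.uniform(-w / 2 + 1, w / 2 - 1))
            v = float(rng.uniform(-h / 2 + 1, h / 2 - 1))
            c, s = math.cos(theta), math.sin(theta)
            cx = px - (c * u - s * v)
            cy = py - (s * u + c * v)
            if patch_fits_slide(cx, cy, patch, aset):
                out.append((cx, cy, theta))
                break
        else:
            raise RuntimeError(
                f"could not place a {group.value} patch on the slide in {max_tries} tries"
            )
    return out
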