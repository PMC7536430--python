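"""Resolution-aware geometry: physical-unit/pixel conversion and the 10-HPF rectangle.

Conventions: coordinates are 0-based with the origin at the top-left corner,
x increasing rightward and y downward; rectangles are half-open,
``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

__all__ = ["SlideGeometry", "FOIShape", "Rect", "foi_pixel_dims", "rect_from_center"]

#: Scanner resolution of the reference dataset, in microns per pixel.
DEFAULT_MPP = 0.25

#: Standard 10-HPF counting area in mm² (Meuten's recommendation).
DEFAULT_AREA_MM2 = 2.37

#: Standard FOI aspect ratio (width:height).
DEFAULT_ASPECT = (4, 3)


@dataclass(frozen=True)
class SlideGeometry:
    """Pixel dimensions and resolution of a whole-slide image.

    Parameters
    ----------
    width_px, height_px
        Slide dimensions at full resolution, in pixels.
    mpp
        Isotropic pixel size in microns per pixel.
    """

    width_px: int
    height_px: int
    mpp: float = DEFAULT_MPP

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")

    @property
    def area_mm2(self) -> float:
        """Total slide area in mm²."""
        return self.width_px * self.height_px * self.mpp ** 2 / 1e6


@dataclass(frozen=True)
class FOIShape:
    """Pixel dimensions of a field of interest of fixed physical area.

    Produced by :func:`foi_pixel_dims`; carries the physical parameters it
    was derived from so it can be serialized and re-derived.
    """

    area_mm2: float
    aspect_w: int
    aspect_h: int
    width_px: int
    height_px: int
    mpp: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "area_mm2": self.area_mm2,
                "aspect": [self.aspect_w, self.aspect_h],
                "width_px": self.width_px,
                "height_px": self.height_px,
                "mpp": self.mpp,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FOIShape":
        d = json.loads(s)
        return cls(
            area_mm2=d["area_mm2"],
            aspect_w=d["aspect"][0],
            aspect_h=d["aspect"][1],
            width_px=d["width_px"],
            height_px=d["height_px"],
            mpp=d["mpp"],
        )


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned rectangle [x0, x1) x [y0, y1) in pixels."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def clip(self, geometry: SlideGeometry) -> "Rect":
        """Intersect with the slide bounds."""
        return Rect(
            max(self.x0, 0),
            max(self.y0, 0),
            min(self.x1, geometry.width_px),
            min(self.y1, geometry.height_px),
        )

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


def foi_pixel_dims(
    area_mm2: float = DEFAULT_AREA_MM2,
    aspect: tuple[int, int] = DEFAULT_ASPECT,
    mpp: float = DEFAULT_MPP,
) -> FOIShape:
    """Derive the FOI pixel dimensions from its physical area and aspect ratio.

    Solves ``w * h = area_mm2 * 1e6 / mpp**2`` subject to ``w : h`` equal to
    the requested aspect ratio, rounding each dimension to the nearest
    integer (which minimizes the area error).

    Examples
    --------
    >>> s = foi_pixel_dims(2.37, (4, 3), 0.25)
    >>> (s.width_px, s.height_px)
    (7111, 5333)
    """
    aw, ah = aspect
    if area_mm2 <= 0 or aw <= 0 or ah <= 0 or mpp <= 0:
        raise ValueError("area, aspect and mpp must all be strictly positive")
    area_px = area_mm2 * 1e6 / mpp ** 2
    width = round(math.sqrt(area_px * aw / ah))
    height = round(math.sqrt(area_px * ah / aw))
    return FOIShape(
        area_mm2=area_mm2,
        aspect_w=aw,
        aspect_h=ah,
        width_px=width,
        height_px=height,
        mpp=mpp,
    )


def rect_from_center(cx: int, cy: int, shape: FOIShape) -> Rect:
    """Half-open rectangle of the given shape centered (to floor) at (cx, cy).

    The rectangle may extend outside the slide; clipping is the caller's
    concern (see :meth:`Rect.clip`).
    """
    x0 = int(cx) - shape.width_px // 2
    y0 = int(cy) - shape.height_px // 2
    return Rect(x0, y0, x0 + shape.width_px, y0 + shape.height_px)
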