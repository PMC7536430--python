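"""The selection head: moving average over 10 HPF, valid masking, argmax -> FOI.

The selected center is the position of the maximum estimated mitotic density
within the valid mask V. Because the argmax is invariant under positive
affine transforms of the estimate, a consistent over- or underestimation of
the density (a scaling factor or an offset) does not change the selection.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .annotations import AnnotationSet, CellLabel, RaterSelection
from .density import mc_at_rect, moving_average
from .estimators import EstimatorOutput
from .geometry import FOIShape, Rect, rect_from_center
from .tissue import ValidMask

__all__ = ["FOIResult", "select_foi", "evaluate_selection"]


@dataclass
class FOIResult:
    """A selected field of interest: center, rectangle, estimate and ground truth."""

    center_x: int
    center_y: int
    shape: FOIShape
    estimate_value: float
    gt_mc: Optional[int] = None

    @property
    def rect(self) -> Rect:
        return rect_from_center(self.center_x, self.center_y, self.shape)

    def to_json(self) -> str:
        r = self.rect
        return json.dumps(
            {
                "center_x": self.center_x,
                "center_y": self.center_y,
                "rect": [r.x0, r.y0, r.x1, r.y1],
                "estimate_value": self.estimate_value,
                "gt_mc": self.gt_mc,
                "shape": json.loads(self.shape.to_json()),
            }
        )


def select_foi(
    est: EstimatorOutput,
    valid: ValidMask,
    shape: FOIShape,
    aset: AnnotationSet | None = None,
) -> FOIResult:
    """Select the FOI center maximizing the estimated density within the valid mask.

    For estimators that already emit windowed counts the moving-average step
    is the identity and the argmax is taken directly; for raw per-patch maps
    (``est.per_patch``) a valid-mode moving average with kernel
    ``ceil(window/stride)`` grid cells is applied first and its outputs are
    re-centered on the grid. Ties break deterministically to the smallest row
    index, then smallest column index. If ``aset`` is given, the ground-truth
    mitotic count of the selected rectangle is attached.
    """
    grid = est.density.grid
    if valid.grid != grid:
        raise ValueError("estimator grid and valid mask grid are not aligned")

    if est.per_patch:
        kw = math.ceil(est.density.window_w / grid.stride)
        kh = math.ceil(est.density.window_h / grid.stride)
        kw = min(kw, grid.n_cols)
        kh = min(kh, grid.n_rows)
        ma = moving_average(est.density.values, kw, kh)
        values = np.full((grid.n_rows, grid.n_cols), -np.inf)
        r_off = (kh - 1) // 2
        c_off = (kw - 1) // 2
        values[r_off : r_off + ma.shape[0], c_off : c_off + ma.shape[1]] = ma
    else:
        values = est.density.values

    masked = np.where(valid.mask & np.isfinite(values), values, -np.inf)
    if not np.any(masked > -np.inf):
        raise ValueError("no valid FOI position")
    # np.argmax returns the first maximum in row-major order: the tie-break rule
    idx = int(np.argmax(masked))
    row, col = divmod(idx, grid.n_cols)
    cx, cy = grid.center_at(row, col)

    gt: Optional[int] = None
    if aset is not None:
        gt = evaluate_selection(aset, (cx, cy), shape)
    return FOIResult(
        center_x=cx,
        center_y=cy,
        shape=shape,
        estimate_value=float(masked[row, col]),
        gt_mc=gt,
    )


def evaluate_selection(
    aset: AnnotationSet,
    sel,
    shape: FOIShape,
) -> int:
    """Ground-truth mitotic count of the 10-HPF rectangle around a selection.

    ``sel`` may be a RaterSelection, an FOIResult, or a plain (cx, cy) pair.
    A rectangle extending past the slide is clipped with a warning.
    """
    if isinstance(sel, RaterSelection):
        cx, cy = sel.center_x, sel.center_y
    elif isinstance(sel, FOIResult):
        cx, cy = sel.center_x, sel.center_y
    else:
        cx, cy = sel
    rect = rect_from_center(cx, cy, shape)
    clipped = rect.clip(aset.geometry)
    if clipped != rect:
        warnings.warn("selection rectangle extends outside the slide; clipped", stacklevel=2)
    return mc_at_rect(aset.points(CellLabel.MITOSIS), clipped)
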