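"""Data model and I/O for labeled cell point annotations and rater FOI selections.

Canonical on-disk format: a CSV with header ``slide,x,y,label`` holding one
cell per row, plus a JSON sidecar ``{slide_id, width_px, height_px, mpp}``
supplying the slide geometry. Rater selections are a CSV with header
``slide,rater,group,center_x,center_y``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import SlideGeometry

__all__ = [
    "CellLabel",
    "CellAnnotation",
    "AnnotationSet",
    "RaterGroup",
    "RaterSelection",
    "read_annotations",
    "write_annotations",
    "read_selections",
    "write_selections",
    "filter_label",
]


class CellLabel(str, enum.Enum):
    """Cell classes: true mitotic figures and mitosis-like hard negatives."""

    MITOSIS = "mitosis"
    HARD_NEGATIVE = "hard_negative"


class RaterGroup(str, enum.Enum):
    """Rater categories: board-certified pathologists, pathologists in
    training, and algorithmic selectors."""

    BCVP = "BCVP"
    VPIT = "VPIT"
    ALGORITHM = "algorithm"


@dataclass(frozen=True)
class CellAnnotation:
    """A single annotated cell at full-resolution pixel coordinates."""

    x: int
    y: int
    label: CellLabel


@dataclass
class AnnotationSet:
    """All cell annotations of one slide, with its geometry.

    Invariant: every cell lies inside the slide, ``0 <= x < width_px`` and
    ``0 <= y < height_px`` (half-open bounds).
    """

    slide_id: str
    geometry: SlideGeometry
    cells: list[CellAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, c in enumerate(self.cells):
            if not (0 <= c.x < self.geometry.width_px and 0 <= c.y < self.geometry.height_px):
                raise ValueError(
                    f"cell {i} at ({c.x}, {c.y}) outside slide bounds "
                    f"{self.geometry.width_px}x{self.geometry.height_px}"
                )

    def points(self, label: CellLabel | None = None) -> np.ndarray:
        """(n, 2) integer array of (x, y), optionally restricted to a label."""
        cells = self.cells if label is None else [c for c in self.cells if c.label == label]
        if not cells:
            return np.empty((0, 2), dtype=np.int64)
        return np.array([(c.x, c.y) for c in cells], dtype=np.int64)


@dataclass(frozen=True)
class RaterSelection:
    """One rater's chosen FOI center on one slide."""

    slide_id: str
    rater_id: str
    rater_group: RaterGroup
    center_x: int
    center_y: int


def filter_label(aset: AnnotationSet, label: CellLabel) -> np.ndarray:
    """Order-preserving (n, 2) array of points carrying the given label."""
    return aset.points(label)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_annotations(path: str | Path, sidecar: str | Path | None = None) -> AnnotationSet:
    """Read an annotation CSV plus its geometry sidecar into an AnnotationSet.

    Raises
    ------
    ValueError
        If required columns are missing, a label is unknown, or a point lies
        outside the slide bounds (the offending row is named).
    FileNotFoundError
        If the CSV or sidecar does not exist.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    meta = json.loads(sidecar.read_text())
    geometry = SlideGeometry(
        width_px=int(meta["width_px"]), height_px=int(meta["height_px"]), mpp=float(meta["mpp"])
    )
    df = pd.read_csv(path)
    required = {"slide", "x", "y", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    valid_labels = {l.value for l in CellLabel}
    cells: list[CellAnnotation] = []
    for row in df.itertuples(index=True):
        if row.label not in valid_labels:
            raise ValueError(f"{path} row {row.Index}: unknown label {row.label!r}")
        x, y = int(row.x), int(row.y)
        if not (0 <= x < geometry.width_px and 0 <= y < geometry.height_px):
            raise ValueError(
                f"{path} row {row.Index}: point ({x}, {y}) outside slide bounds"
            )
        cells.append(CellAnnotation(x=x, y=y, label=CellLabel(row.label)))
    return AnnotationSet(slide_id=str(meta["slide_id"]), geometry=geometry, cells=cells)


def write_annotations(aset: AnnotationSet, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write an AnnotationSet as canonical CSV + JSON sidecar (round-trip exact)."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    df = pd.DataFrame(
        {
            "slide": [aset.slide_id] * len(aset.cells),
            "x": [c.x for c in aset.cells],
            "y": [c.y for c in aset.cells],
            "label": [c.label.value for c in aset.cells],
        }
    )
    df.to_csv(path, index=False)
    sidecar.write_text(
        json.dumps(
            {
                "slide_id": aset.slide_id,
                "width_px": aset.geometry.width_px,
                "height_px": aset.geometry.height_px,
                "mpp": aset.geometry.mpp,
            },
            indent=2,
        )
        + "\n"
    )


def read_selections(path: str | Path) -> list[RaterSelection]:
    """Read rater FOI selections from CSV ``slide,rater,group,center_x,center_y``."""
    df = pd.read_csv(path)
    required = {"slide", "rater", "group", "center_x", "center_y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        RaterSelection(
            slide_id=str(r.slide),
            rater_id=str(r.rater),
            rater_group=RaterGroup(r.group),
            center_x=int(r.center_x),
            center_y=int(r.center_y),
        )
        for r in df.itertuples(index=False)
    ]


def write_selections(selections: list[RaterSelection], path: str | Path) -> None:
    pd.DataFrame(
        {
            "slide": [s.slide_id for s in selections],
            "rater": [s.rater_id for s in selections],
            "group": [s.rater_group.value for s in selections],
            "center_x": [s.center_x for s in selections],
            "center_y": [s.center_y for s in selections],
        }
    ).to_csv(path, index=False)
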