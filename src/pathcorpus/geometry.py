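"""Axis-aligned bounding-box geometry in normalized page coordinates.

All coordinates are fractions of page width/height with a top-left origin
(the convention used by layout-aware OCR engines). Every geometric decision
in the pipeline -- table-region merging, line/region overlap, keyword box
expansion -- is made on these primitives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

#: Slack for upstream rounding of normalized coordinates.
EPS = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised when an operation requires a box of positive area."""


@dataclass(frozen=True)
class BBox:
    """Axis-aligned rectangle in normalized page coordinates.

    Parameters
    ----------
    left, top : float
        Position of the top-left corner as a fraction of page width/height.
    width, height : float
        Extent as a fraction of page width/height. Zero extent is allowed
        (degenerate boxes occur in real OCR output) but rejected by
        operations that need an area denominator.
    """

    left: float
    top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.left < -EPS or self.top < -EPS:
            raise ValueError(f"box origin must be non-negative: {self}")
        if self.width < 0 or self.height < 0:
            raise ValueError(f"box extent must be non-negative: {self}")
        if self.left + self.width > 1 + EPS or self.top + self.height > 1 + EPS:
            raise ValueError(f"box exceeds unit page: {self}")

    @property
    def right(self) -> float:
        return self.left + self.width

    @property
    def bottom(self) -> float:
        return self.top + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, other: "BBox", eps: float = EPS) -> bool:
        """True if *other* lies inside this box, within *eps* slack."""
        return (
            other.left >= self.left - eps
            and other.top >= self.top - eps
            and other.right <= self.right + eps
            and other.bottom <= self.bottom + eps
        )


@dataclass(frozen=True)
class Offsets:
    """Per-side expansion amounts (page fractions, all non-negative)."""

    left: float = 0.0
    right: float = 0.0
    up: float = 0.0
    down: float = 0.0

    def __post_init__(self) -> None:
        if min(self.left, self.right, self.up, self.down) < 0:
            raise ValueError(f"offsets must be non-negative: {self}")


def intersection_area(a: BBox, b: BBox) -> float:
    """Area of the rectangle intersection; 0.0 when disjoint. Symmetric."""
    w = min(a.right, b.right) - max(a.left, b.left)
    h = min(a.bottom, b.bottom) - max(a.top, b.top)
    if w <= 0 or h <= 0:
        return 0.0
    return w * h


def overlap_fraction(line_box: BBox, region: BBox) -> float:
    """Fraction of *line_box*'s area covered by *region*.

    Normalizing by the line's own area puts the value in [0, 1] and makes
    thresholds like 0.25 interpretable as "a quarter of the line sits
    inside the region", regardless of how large the region is.
    """
    if line_box.area <= 0:
        raise DegenerateGeometryError(
            f"overlap_fraction needs a line box of positive area, got {line_box}"
        )
    frac = intersection_area(line_box, region) / line_box.area
    # numerical guard: float noise around full containment snaps to 1
    if frac >= 1.0 - 1e-9:
        return 1.0
    return frac


def merge_boxes(boxes: Sequence[BBox] | Iterable[BBox]) -> BBox:
    """Smallest axis-aligned rectangle containing every input box."""
    boxes = list(boxes)
    if not boxes:
        raise ValueError("merge_boxes requires at least one box")
    left = min(b.left for b in boxes)
    top = min(b.top for b in boxes)
    right = max(b.right for b in boxes)
    bottom = max(b.bottom for b in boxes)
    return BBox(left, top, right - left, bottom - top)


def expand_box(box: BBox, offsets: Offsets) -> BBox:
    """Grow *box* by per-side offsets, clipped to the unit page."""
    left = max(0.0, box.left - offsets.left)
    top = max(0.0, box.top - offsets.up)
    right = min(1.0, box.right + offsets.right)
    bottom = min(1.0, box.bottom + offsets.down)
    return BBox(left, top, right - left, bottom - top)
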