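"""Per-slice scored bounding boxes and their JSON round trip.

The annotation dialect is plain JSON with an explicit schema version.  Boxes
use the package-wide pixel convention: top-left origin, half-open
``[x, x+w) x [y, y+h)``, 0-based slice index.
"""

from __future__ import annotations

import dataclasses
import json

from .errors import AnnotationError, AutopatchError

SCHEMA_VERSION = 1


@dataclasses.dataclass(frozen=True)
class ScoredBox:
    """A scored 2D bounding box on one slice of a stack."""

    slice_index: int
    x: float
    y: float
    w: float
    h: float
    confidence: float = 1.0
    label: str = "cell"

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise AutopatchError(f"box width/height must be positive, got {self.w}x{self.h}")
        if not (0.0 <= self.confidence <= 1.0):
            raise AutopatchError(f"confidence must be in [0, 1], got {self.confidence}")
        if self.slice_index < 0:
            raise AutopatchError("slice_index must be non-negative")

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> tuple:
        """(cx, cy) in pixels."""
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def rect(self) -> tuple:
        """Half-open rectangle (x0, y0, x1, y1)."""
        return (self.x, self.y, self.x + self.w, self.y + self.h)


def intersect_rects(a: tuple, b: tuple) -> tuple | None:
    """Intersection of two half-open rectangles, or None if empty."""
    x0 = max(a[0], b[0])
    y0 = max(a[1], b[1])
    x1 = min(a[2], b[2])
    y1 = min(a[3], b[3])
    if x1 <= x0 or y1 <= y0:
        return None
    return (x0, y0, x1, y1)


def rect_area(r: tuple | None) -> float:
    if r is None:
        return 0.0
    return (r[2] - r[0]) * (r[3] - r[1])


def expand_center_box(box: ScoredBox, n_slices: int, depth: int = 5) -> list:
    """Expand a single center-slice annotation to a multi-slice one.

    Annotators mark the 3D center of a cell with one 2D box and the same box is
    copied to the neighbouring slices (two above and two below for the default
    depth of five), clipped at the stack boundaries.
    """
    if depth < 1 or depth % 2 == 0:
        raise AutopatchError("depth must be a positive odd number")
    half = depth // 2
    lo = max(0, box.slice_index - half)
    hi = min(n_slices - 1, box.slice_index + half)
    return [dataclasses.replace(box, slice_index=k) for k in range(lo, hi + 1)]


def write_annotations(boxes, path) -> None:
    """Write boxes as versioned JSON."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "boxes": [dataclasses.asdict(b) for b in boxes],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_annotations(path) -> list:
    """Read boxes written by :func:`write_annotations`.

    Malformed records are reported per record (with their index) in a single
    :class:`AnnotationError`.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict) or "boxes" not in payload:
        raise AnnotationError(f"{path}: not an annotation file")
    boxes = []
    record_errors = []
    for i, rec in enumerate(payload["boxes"]):
        try:
            boxes.append(ScoredBox(**rec))
        except (TypeError, AutopatchError) as exc:
            record_errors.append((i, str(exc)))
    if record_errors:
        raise AnnotationError(
            f"{path}: {len(record_errors)} malformed record(s): {record_errors}",
            record_errors,
        )
    return boxes
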