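"""Annotation data model for photoconversion EM synapse cross-sections.

A *section* is one representative 2D electron-micrograph cross-section of a
presynaptic terminal whose vesicles have been labeled by FM-dye
photoconversion: each vesicle is either *recycled* (photoconverted, PC+,
electron-dense lumen) or *resting* (PC-, clear lumen).  Alongside the vesicle
centers the annotation carries a polyline trace of the active zone (AZ)
membrane and, optionally, a polygon delimiting the vesicle cluster.

All coordinates are continuous 2D positions in nanometres; there is no pixel
grid at this level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import LineString, Point, Polygon

Coord = Tuple[float, float]

RECYCLED = "recycled"
RESTING = "resting"
LABELS = (RECYCLED, RESTING)

CONDITIONS = ("control", "LTP", "forskolin", "other")

#: Default vesicle radius in nm (small synaptic vesicles are ~40 nm across).
DEFAULT_VESICLE_RADIUS = 20.0


@dataclass(frozen=True)
class VesicleAnnotation:
    """One annotated synaptic vesicle.

    Parameters
    ----------
    id : str
        Identifier, unique within its section.
    x, y : float
        Center coordinates in nm.
    label : {"recycled", "resting"}
        Functional pool class (recycled = photoconverted PC+).
    radius : float, default 20.0
        Vesicle radius in nm; used only for surface-based geometry
        (AZ-associated pool membership and line-of-sight occlusion).
    """

    id: str
    x: float
    y: float
    label: str
    radius: float = DEFAULT_VESICLE_RADIUS

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"vesicle {self.id!r}: coordinates must be finite")
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise ValueError(f"vesicle {self.id!r}: radius must be > 0")
        if self.label not in LABELS:
            raise ValueError(
                f"vesicle {self.id!r}: unknown label {self.label!r}; "
                f"allowed labels are {LABELS}"
            )

    @property
    def center(self) -> Coord:
        return (self.x, self.y)

    @property
    def is_recycled(self) -> bool:
        return self.label == RECYCLED


@dataclass(frozen=True)
class ActiveZoneTrace:
    """Polyline trace of the active-zone membrane in one section.

    ``center`` defaults to the arc-length midpoint of the polyline and must
    lie on (or within 1 nm of) the trace.
    """

    points: Tuple[Coord, ...]
    center: Optional[Coord] = None

    def __post_init__(self) -> None:
        pts = tuple((float(x), float(y)) for x, y in self.points)
        if len(pts) < 2:
            raise ValueError("active zone trace needs at least 2 points")
        for x, y in pts:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError("active zone trace has non-finite coordinates")
        object.__setattr__(self, "points", pts)
        line = LineString(pts)
        if line.length <= 0:
            raise ValueError("active zone trace degenerates to a point")
        if self.center is None:
            mid = line.interpolate(0.5, normalized=True)
            object.__setattr__(self, "center", (mid.x, mid.y))
        else:
            c = (float(self.center[0]), float(self.center[1]))
            object.__setattr__(self, "center", c)
            if Point(c).distance(line) > 1.0:
                raise ValueError(
                    "active zone center must lie within 1 nm of the trace"
                )

    @property
    def line(self) -> LineString:
        return LineString(self.points)

    @property
    def length(self) -> float:
        return self.line.length


@dataclass(frozen=True)
class SynapseSection:
    """One annotated representative middle section of a synapse."""

    id: str
    condition: str
    vesicles: Tuple[VesicleAnnotation, ...]
    active_zones: Tuple[ActiveZoneTrace, ...]
    boundary: Optional[Tuple[Coord, ...]] = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "vesicles", tuple(self.vesicles))
        object.__setattr__(self, "active_zones", tuple(self.active_zones))
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"section {self.id!r}: unknown condition {self.condition!r}; "
                f"allowed conditions are {CONDITIONS}"
            )
        ids = [v.id for v in self.vesicles]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"section {self.id!r}: duplicate vesicle ids {dupes}")
        if self.boundary is not None:
            pts = tuple((float(x), float(y)) for x, y in self.boundary)
            if len(pts) < 3:
                raise ValueError(f"section {self.id!r}: boundary needs >= 3 points")
            object.__setattr__(self, "boundary", pts)
            poly = Polygon(pts)
            if not poly.is_valid:
                raise ValueError(f"section {self.id!r}: invalid boundary polygon")
            for v in self.vesicles:
                if Point(v.center).distance(poly) > 1e-6:
                    raise ValueError(
                        f"section {self.id!r}: vesicle {v.id!r} lies outside "
                        "the boundary polygon"
                    )

    # -- convenience accessors -------------------------------------------

    @property
    def n_vesicles(self) -> int:
        return len(self.vesicles)

    @property
    def n_recycled(self) -> int:
        return sum(v.is_recycled for v in self.vesicles)

    def centers(self) -> np.ndarray:
        """(n, 2) array of vesicle center coordinates in nm."""
        if not self.vesicles:
            return np.empty((0, 2))
        return np.array([[v.x, v.y] for v in self.vesicles], dtype=float)

    def labels(self) -> np.ndarray:
        return np.array([v.label for v in self.vesicles])

    def recycled_mask(self) -> np.ndarray:
        return np.array([v.is_recycled for v in self.vesicles], dtype=bool)

    @property
    def boundary_polygon(self) -> Optional[Polygon]:
        return Polygon(self.boundary) if self.boundary is not None else None


class FilterReason(str, Enum):
    """Why a section was excluded from analysis."""

    LOW_FRACTION = "low_fraction"
    TOO_MANY_VESICLES = "too_many_vesicles"
    MULTI_AZ = "multi_az"
    INVALID = "invalid"


@dataclass(frozen=True)
class FilterReport:
    """Outcome of the inclusion filters over a set of sections."""

    included: Tuple[str, ...]
    excluded: Tuple[Tuple[str, FilterReason], ...]

    def __post_init__(self) -> None:
        inc = set(self.included)
        exc = {sid for sid, _ in self.excluded}
        if inc & exc:
            raise ValueError(f"sections both included and excluded: {inc & exc}")

    @property
    def excluded_ids(self) -> Tuple[str, ...]:
        return tuple(sid for sid, _ in self.excluded)

    def reason_for(self, section_id: str) -> Optional[FilterReason]:
        for sid, reason in self.excluded:
            if sid == section_id:
                return reason
        return None
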