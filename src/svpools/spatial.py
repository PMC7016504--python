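"""Section orientation, nearest-AZ distances, and spatial density maps.

Sections are rigidly re-oriented so the active zone lies at the bottom:
the best-fit line through the AZ trace becomes horizontal, the AZ center
moves to the origin, and the vesicle cloud sits at positive y.  Quantitative
statistics use raw (non-normalized) Euclidean distances from vesicle centers
to the nearest point on the AZ polyline; the 10x10 density maps are
cluster-normalized visual summaries only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point

from .model import (
    RECYCLED,
    RESTING,
    ActiveZoneTrace,
    SynapseSection,
    VesicleAnnotation,
)
from .pool_metrics import TestResult, compare_groups

GRID_SIZE = 10


@dataclass(frozen=True)
class OrientedSection:
    """A section after rigid re-orientation (rotation + translation only)."""

    section: SynapseSection
    angle: float          # rotation applied, radians, counter-clockwise
    offset: Tuple[float, float]  # translation applied after rotation


@dataclass(frozen=True)
class DensityMap:
    """10x10 spatial frequency matrix for one pool, normalized to sum 1."""

    pool: str
    grid: np.ndarray
    note: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(f"grid must be {GRID_SIZE}x{GRID_SIZE}")
        object.__setattr__(self, "grid", g)


def _rotate(points: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return points @ rot.T


def orient_section(section: SynapseSection) -> OrientedSection:
    """Rigidly transform a section so its AZ is horizontal at the bottom.

    The best-fit line through the AZ trace (principal axis) is rotated to
    horizontal, the AZ center translated to the origin, and the section
    rotated a further 180 degrees if the vesicle centroid ends up below the
    axis.  Only rotation and translation are used, so all pairwise distances
    are preserved.
    """
    if len(section.active_zones) != 1:
        raise ValueError(
            f"section {section.id!r}: orientation requires exactly one active zone"
        )
    az = section.active_zones[0]
    pts = np.asarray(az.points, dtype=float)
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError(f"section {section.id!r}: active zone degenerates to a point")
    # principal axis of the AZ trace
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    angle = -math.atan2(direction[1], direction[0])

    def transform(p: np.ndarray, extra_flip: bool) -> np.ndarray:
        q = _rotate(np.atleast_2d(p), angle)
        q = q - _rotate(np.atleast_2d(np.asarray(az.center, dtype=float)), angle)
        if extra_flip:
            q = -q
        return q

    flip = False
    if section.vesicles:
        mean_y = transform(section.centers(), False)[:, 1].mean()
        flip = mean_y < 0

    def coords(p) -> np.ndarray:
        return transform(np.asarray(p, dtype=float), flip)

    new_vesicles = tuple(
        VesicleAnnotation(
            id=v.id,
            x=float(coords((v.x, v.y))[0, 0]),
            y=float(coords((v.x, v.y))[0, 1]),
            label=v.label,
            radius=v.radius,
        )
        for v in section.vesicles
    )
    new_az = ActiveZoneTrace(
        points=tuple(map(tuple, coords(pts))),
        center=tuple(coords(az.center)[0]),
    )
    new_boundary = None
    if section.boundary is not None:
        new_boundary = tuple(map(tuple, coords(np.asarray(section.boundary))))
    total_angle = angle + (math.pi if flip else 0.0)
    shift = -_rotate(np.atleast_2d(np.asarray(az.center, dtype=float)), angle)[0]
    if flip:
        shift = -shift
    oriented = SynapseSection(
        id=section.id,
        condition=section.condition,
        vesicles=new_vesicles,
        active_zones=(new_az,),
        boundary=new_boundary,
        metadata=dict(section.metadata),
    )
    return OrientedSection(section=oriented, angle=total_angle, offset=tuple(shift))


def nearest_az_distance(vesicle, az: ActiveZoneTrace) -> float:
    """Minimum Euclidean distance from a vesicle center to the AZ polyline.

    ``vesicle`` may be a :class:`VesicleAnnotation` or an ``(x, y)`` pair.
    Interior projections onto each segment are included, not just the trace
    vertices.
    """
    if isinstance(vesicle, VesicleAnnotation):
        p = Point(vesicle.x, vesicle.y)
    else:
        p = Point(float(vesicle[0]), float(vesicle[1]))
    return float(p.distance(az.line))


def distance_records(sections: Sequence[SynapseSection]) -> pd.DataFrame:
    """Per-vesicle nearest-AZ distances, long format.

    Columns: ``section_id, vesicle_id, label, d_az_nm``.
    """
    rows = []
    for s in sections:
        if not s.active_zones:
            raise ValueError(f"section {s.id!r} has no active zone")
        az = s.active_zones[0]
        line = az.line
        for v in s.vesicles:
            rows.append(
                {
                    "section_id": s.id,
                    "vesicle_id": v.id,
                    "label": v.label,
                    "d_az_nm": float(Point(v.x, v.y).distance(line)),
                }
            )
    return pd.DataFrame(rows, columns=["section_id", "vesicle_id", "label", "d_az_nm"])


def ecdf(values: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted values and cumulative probabilities in (0, 1]."""
    v = np.sort(np.asarray(values, dtype=float))
    return v, np.arange(1, v.size + 1) / v.size


def distance_distributions(sections: Sequence[SynapseSection]) -> dict:
    """Pooled per-pool distance records and empirical CDFs.

    Returns ``{"records": DataFrame, "ecdf": {label: (x, F)}, "empty_pools":
    [...]}``; a pool with no vesicles is flagged rather than raising.
    """
    records = distance_records(sections)
    out = {"records": records, "ecdf": {}, "empty_pools": []}
    for label in (RECYCLED, RESTING):
        d = records.loc[records["label"] == label, "d_az_nm"].to_numpy()
        if d.size == 0:
            out["empty_pools"].append(label)
            out["ecdf"][label] = (np.array([]), np.array([]))
        else:
            out["ecdf"][label] = ecdf(d)
    return out


def compare_distances(groups: Dict[str, Sequence[float]]) -> Dict[Tuple[str, str], TestResult]:
    """Two-tailed unpaired t tests between every pair of distance samples."""
    names = list(groups)
    results = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            results[(a, b)] = compare_groups(groups[a], groups[b])["t_test"]
    return results


# ---------------------------------------------------------------------------
# density maps


def _cluster_extent(section: SynapseSection) -> Tuple[float, float, float, float]:
    """(x0, x1, y0, y1) of the cluster: boundary bbox if supplied, else the
    bounding box of all vesicle centers."""
    if section.boundary is not None:
        b = np.asarray(section.boundary, dtype=float)
    else:
        b = section.centers()
    if b.size == 0:
        raise ValueError(f"section {section.id!r} has no vesicles")
    return float(b[:, 0].min()), float(b[:, 0].max()), float(b[:, 1].min()), float(b[:, 1].max())


def _bin_index(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Half-open bins over [lo, hi); the final bin is closed at hi."""
    if hi == lo:
        return np.zeros(values.shape, dtype=int)
    idx = np.floor((values - lo) / (hi - lo) * GRID_SIZE).astype(int)
    return np.clip(idx, 0, GRID_SIZE - 1)


def density_map(section: SynapseSection, pool: str) -> DensityMap:
    """10x10 spatial frequency map of one pool in cluster-normalized space.

    Each grid square covers 1% of the cluster bounding box; counts are
    divided by pool size so the map sums to one.
    """
    mask = section.labels() == pool
    if not mask.any():
        raise ValueError(f"section {section.id!r}: pool {pool!r} is empty")
    centers = section.centers()[mask]
    x0, x1, y0, y1 = _cluster_extent(section)
    ix = _bin_index(centers[:, 0], x0, x1)
    iy = _bin_index(centers[:, 1], y0, y1)
    grid = np.zeros((GRID_SIZE, GRID_SIZE))
    np.add.at(grid, (iy, ix), 1.0)
    grid /= centers.shape[0]
    return DensityMap(pool=pool, grid=grid, note="normalized to cluster bounding box")


def fold_lateral(grid: np.ndarray) -> np.ndarray:
    """Average a map with its left-right mirror image (lateral symmetry)."""
    return (grid + np.fliplr(grid)) / 2.0


def mean_density_map(
    sections: Sequence[SynapseSection], pool: str, smooth_sigma: float = 1.0
) -> DensityMap:
    """Population mean density map with lateral folding and smoothing.

    Per-section maps are averaged with their mirror images (synapses are
    sampled at arbitrary orientations, so laterality is uninformative), then
    averaged across sections, Gaussian-smoothed (sigma in grid cells,
    reflective boundaries), re-folded so mirror symmetry is exact, and
    renormalized to unit sum.
    """
    maps = []
    for s in sections:
        if (s.labels() == pool).any():
            maps.append(fold_lateral(density_map(s, pool).grid))
    if not maps:
        raise ValueError(f"no section has a non-empty {pool!r} pool")
    mean = np.mean(maps, axis=0)
    if smooth_sigma > 0:
        mean = gaussian_filter(mean, sigma=smooth_sigma, mode="reflect")
    mean = fold_lateral(mean)
    mean = mean / mean.sum()
    return DensityMap(
        pool=pool,
        grid=mean,
        note=f"mean of {len(maps)} folded section maps, sigma={smooth_sigma}",
    )
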