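"""Reading, writing, and inclusion filtering of section annotations.

On-disk layout
--------------
* Vesicle table (CSV or TSV, by extension): one row per vesicle with header
  ``section_id,x_nm,y_nm,label,radius_nm`` (``radius_nm`` and ``vesicle_id``
  optional).
* Metadata sidecar (JSON): maps section id to ``condition``,
  ``active_zone`` (list of ``[x, y]`` nm points), optional ``az_center``,
  optional ``boundary`` polygon, and optional ``pixel_size_nm`` /
  ``slice_id`` provenance fields.

All coordinates are serialized in nm as decimal numbers and carried through
unchanged.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .model import (
    LABELS,
    DEFAULT_VESICLE_RADIUS,
    ActiveZoneTrace,
    FilterReason,
    FilterReport,
    SynapseSection,
    VesicleAnnotation,
)

REQUIRED_COLUMNS = ("section_id", "x_nm", "y_nm", "label")

#: Inclusion thresholds: recycled fraction strictly above MIN_POOL_FRACTION
#: and at most MAX_VESICLES_PER_SECTION vesicles in the section.
MIN_POOL_FRACTION = 0.049
MAX_VESICLES_PER_SECTION = 100


class AnnotationError(ValueError):
    """Raised when annotation files fail validation; carries per-record context."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("\n".join(self.problems))


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_sections(table_path, metadata_path) -> List[SynapseSection]:
    """Read annotated sections from a vesicle table plus a JSON sidecar.

    Raises
    ------
    AnnotationError
        Listing every offending record with file and line context (line
        numbers refer to the table file, header = line 1).
    """
    table_path = Path(table_path)
    metadata_path = Path(metadata_path)
    df = pd.read_csv(table_path, sep=_sep_for(table_path), float_precision="round_trip")
    problems: List[str] = []

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(
            [f"{table_path}: missing required columns {missing}; "
             f"expected header {list(REQUIRED_COLUMNS)}"]
        )

    with open(metadata_path) as fh:
        metadata = json.load(fh)

    sections: List[SynapseSection] = []
    for section_id, group in df.groupby("section_id", sort=False):
        sid = str(section_id)
        meta = metadata.get(sid)
        if meta is None or "active_zone" not in meta:
            problems.append(
                f"{metadata_path}: section {sid!r} has no active_zone entry"
            )
            continue
        vesicles = []
        ok = True
        for i, (row_idx, row) in enumerate(group.iterrows()):
            line_no = row_idx + 2  # header occupies line 1
            label = str(row["label"])
            if label not in LABELS:
                problems.append(
                    f"{table_path}:{line_no}: unknown label {label!r} for "
                    f"section {sid!r}; allowed labels are {list(LABELS)}"
                )
                ok = False
                continue
            if "vesicle_id" in group.columns and not pd.isna(row.get("vesicle_id")):
                vid = str(row["vesicle_id"])
            else:
                vid = f"{sid}:v{i}"
            radius = DEFAULT_VESICLE_RADIUS
            if "radius_nm" in group.columns and not pd.isna(row.get("radius_nm")):
                radius = float(row["radius_nm"])
            try:
                vesicles.append(
                    VesicleAnnotation(
                        id=vid,
                        x=float(row["x_nm"]),
                        y=float(row["y_nm"]),
                        label=label,
                        radius=radius,
                    )
                )
            except (ValueError, TypeError) as exc:
                problems.append(f"{table_path}:{line_no}: {exc}")
                ok = False
        if not ok:
            continue
        try:
            az_list = meta["active_zone"]
            # one polyline, or a list of polylines for multi-AZ sections
            if az_list and isinstance(az_list[0][0], (int, float)):
                az_list = [az_list]
            azs = tuple(
                ActiveZoneTrace(
                    points=tuple((p[0], p[1]) for p in az),
                    center=tuple(meta["az_center"]) if (
                        "az_center" in meta and len(az_list) == 1
                    ) else None,
                )
                for az in az_list
            )
            boundary = None
            if meta.get("boundary"):
                boundary = tuple((p[0], p[1]) for p in meta["boundary"])
            extra = {
                k: meta[k]
                for k in ("slice_id", "pixel_size_nm")
                if k in meta
            }
            sections.append(
                SynapseSection(
                    id=sid,
                    condition=str(meta.get("condition", "other")),
                    vesicles=tuple(vesicles),
                    active_zones=azs,
                    boundary=boundary,
                    metadata=extra,
                )
            )
        except (ValueError, TypeError, KeyError, IndexError) as exc:
            problems.append(f"{metadata_path}: section {sid!r}: {exc}")

    if problems:
        raise AnnotationError(problems)
    return sections


def write_sections(sections: Iterable[SynapseSection], table_path, metadata_path) -> None:
    """Write sections in the same CSV/TSV + JSON layout ``read_sections`` reads."""
    table_path = Path(table_path)
    metadata_path = Path(metadata_path)
    rows = []
    metadata = {}
    for s in sections:
        for v in s.vesicles:
            rows.append(
                {
                    "section_id": s.id,
                    "vesicle_id": v.id,
                    "x_nm": repr(v.x),
                    "y_nm": repr(v.y),
                    "label": v.label,
                    "radius_nm": repr(v.radius),
                }
            )
        entry = {
            "condition": s.condition,
            "active_zone": [
                [list(p) for p in az.points] for az in s.active_zones
            ],
        }
        if len(s.active_zones) == 1:
            entry["active_zone"] = [list(p) for p in s.active_zones[0].points]
            entry["az_center"] = list(s.active_zones[0].center)
        if s.boundary is not None:
            entry["boundary"] = [list(p) for p in s.boundary]
        entry.update({k: s.metadata[k] for k in s.metadata})
        metadata[s.id] = entry
    pd.DataFrame(
        rows,
        columns=["section_id", "vesicle_id", "x_nm", "y_nm", "label", "radius_nm"],
    ).to_csv(table_path, sep=_sep_for(table_path), index=False)
    with open(metadata_path, "w") as fh:
        json.dump(metadata, fh, indent=1)


def apply_inclusion_filters(
    sections: Sequence[SynapseSection],
    min_fraction: float = MIN_POOL_FRACTION,
    max_vesicles: int = MAX_VESICLES_PER_SECTION,
    require_single_az: bool = True,
) -> FilterReport:
    """Apply the section inclusion filters and report per-section outcomes.

    A section is included iff its recycled fraction is strictly greater than
    ``min_fraction``, its total vesicle count is at most ``max_vesicles``
    (the bound itself is included), and — when ``require_single_az`` — it has
    exactly one active zone.  Exclusion reasons are recorded in the fixed
    priority order ``low_fraction`` -> ``too_many_vesicles`` -> ``multi_az``
    so reports are deterministic; a section with no vesicles or no active
    zone is recorded as ``invalid``.
    """
    included: List[str] = []
    excluded: List[tuple] = []
    for s in sections:
        if s.n_vesicles == 0 or len(s.active_zones) == 0:
            excluded.append((s.id, FilterReason.INVALID))
            continue
        fraction = s.n_recycled / s.n_vesicles
        if not fraction > min_fraction:
            excluded.append((s.id, FilterReason.LOW_FRACTION))
        elif s.n_vesicles > max_vesicles:
            excluded.append((s.id, FilterReason.TOO_MANY_VESICLES))
        elif require_single_az and len(s.active_zones) != 1:
            excluded.append((s.id, FilterReason.MULTI_AZ))
        else:
            included.append(s.id)
    return FilterReport(included=tuple(included), excluded=tuple(excluded))


def filter_sections(
    sections: Sequence[SynapseSection], **kwargs
) -> tuple:
    """Convenience wrapper: returns ``(kept_sections, FilterReport)``."""
    report = apply_inclusion_filters(sections, **kwargs)
    keep = set(report.included)
    return [s for s in sections if s.id in keep], report
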