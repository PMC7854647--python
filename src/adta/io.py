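"""Readers and writers for every on-disk format the pipeline touches.

Canonical dialects:

* patch probability table — UTF-8 CSV, header ``x,y,prob``, ``.`` decimal,
  no index column.  One row per patch; ``(x, y)`` is the upper-left vertex
  of the patch in pixel coordinates (0-based, origin top-left, x rightward,
  y downward).  A patch covers the half-open box
  ``[x, x + patch_size) x [y, y + patch_size)``.
* tumor annotation — GeoJSON (RFC 7946) ``Polygon`` / ``MultiPolygon``
  geometry in pixel coordinates, optionally wrapped in a ``Feature`` or
  ``FeatureCollection``.
* tumor mask — single-channel 8-bit PNG, nonzero = tumor.
* clinical table, score tables — CSV with the documented headers below.

Readers validate rather than coerce: out-of-range probabilities, duplicate
patch coordinates, non-positive follow-up times and out-of-domain ordinal
codes raise :class:`ValidationError` naming the offending row.  Rows are
never silently dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "PatchRecord",
    "ImagePatchSet",
    "TumorAnnotation",
    "ClinicalRecord",
    "PatientImageIndex",
    "read_patch_table",
    "write_patch_table",
    "read_annotation",
    "write_annotation",
    "read_clinical_table",
    "write_clinical_table",
    "read_mask_png",
    "write_mask_png",
]


class FormatError(ValueError):
    """A file is structurally not the expected format (wrong columns, wrong
    geometry type, unparseable content)."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant (probability out of
    [0, 1], duplicate patch coordinates, bad ordinal code, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchRecord:
    """One detector-output row: upper-left vertex and lymphocyte probability."""

    x: int
    y: int
    prob: float


@dataclass
class ImagePatchSet:
    """One image's patch probability map on a fixed grid."""

    image_id: str
    patch_size: int
    patches: list[PatchRecord]

    def __post_init__(self) -> None:
        if self.patch_size <= 0:
            raise ValidationError(f"patch_size must be > 0, got {self.patch_size}")
        seen: set[tuple[int, int]] = set()
        for p in self.patches:
            key = (p.x, p.y)
            if key in seen:
                raise ValidationError(
                    f"image {self.image_id!r}: duplicate patch coordinates {key}"
                )
            seen.add(key)

    def coords(self) -> np.ndarray:
        """(n, 2) int array of upper-left vertices."""
        return np.array([(p.x, p.y) for p in self.patches], dtype=int).reshape(-1, 2)

    def probs(self) -> np.ndarray:
        return np.array([p.prob for p in self.patches], dtype=float)


@dataclass
class TumorAnnotation:
    """Pathologist tumor loops for one image.

    ``polygons`` is a list of (outer_ring, holes) pairs; every ring is a list
    of (x, y) vertex tuples, normalized to be explicitly closed (first vertex
    repeated last).
    """

    image_id: str
    polygons: list[tuple[list[tuple[float, float]], list[list[tuple[float, float]]]]]

    def all_vertices(self) -> np.ndarray:
        pts: list[tuple[float, float]] = []
        for outer, holes in self.polygons:
            pts.extend(outer)
            for h in holes:
                pts.extend(h)
        return np.asarray(pts, dtype=float).reshape(-1, 2)


_T_STAGE_LABELS = ["T1a", "T1b", "T2a", "T2b", "T3a", "T3b", "T4a", "T4b"]
T_STAGE_CODE: Mapping[str, int] = {lab: i + 1 for i, lab in enumerate(_T_STAGE_LABELS)}


@dataclass
class ClinicalRecord:
    """One patient's clinical covariates and disease-specific survival outcome.

    Optional covariates are ``None`` when unknown; downstream model fits use
    complete-case analysis.  ``til_grade`` is the ordinal pathologist grade
    (0 absent, 1 non-brisk, 2 brisk); ``t_stage`` is the ordinal AJCC code
    1..8 for T1a..T4b; ``stage`` is 1..3 for I..III.
    """

    patient_id: str
    dss_event: int
    followup_months: float
    depth_mm: float | None = None
    ulceration: int | None = None
    t_stage: int | None = None
    til_grade: int | None = None
    node_or_satellite_positive: int | None = None
    stage: int | None = None
    institution: str | None = None

    def __post_init__(self) -> None:
        if self.dss_event not in (0, 1):
            raise ValidationError(
                f"patient {self.patient_id!r}: dss_event must be 0 or 1, "
                f"got {self.dss_event!r}"
            )
        if not (self.followup_months > 0):
            raise ValidationError(
                f"patient {self.patient_id!r}: followup_months must be > 0, "
                f"got {self.followup_months!r}"
            )
        if self.til_grade is not None and self.til_grade not in (0, 1, 2):
            raise ValidationError(
                f"patient {self.patient_id!r}: til_grade must be in {{0,1,2}}, "
                f"got {self.til_grade!r}"
            )
        if self.t_stage is not None and self.t_stage not in range(1, 9):
            raise ValidationError(
                f"patient {self.patient_id!r}: t_stage must be in 1..8, "
                f"got {self.t_stage!r}"
            )
        if self.depth_mm is not None and not (self.depth_mm > 0):
            raise ValidationError(
                f"patient {self.patient_id!r}: depth_mm must be > 0, "
                f"got {self.depth_mm!r}"
            )
        for name in ("ulceration", "node_or_satellite_positive"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValidationError(
                    f"patient {self.patient_id!r}: {name} must be 0 or 1, got {v!r}"
                )
        if self.stage is not None and self.stage not in (1, 2, 3):
            raise ValidationError(
                f"patient {self.patient_id!r}: stage must be in {{1,2,3}}, "
                f"got {self.stage!r}"
            )


@dataclass
class PatientImageIndex:
    """patient_id -> list of image_ids; each image belongs to one patient."""

    mapping: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        owner: dict[str, str] = {}
        for pid, images in self.mapping.items():
            for iid in images:
                if iid in owner:
                    raise ValidationError(
                        f"image {iid!r} assigned to both {owner[iid]!r} and {pid!r}"
                    )
                owner[iid] = pid

    def patient_of(self, image_id: str) -> str:
        for pid, images in self.mapping.items():
            if image_id in images:
                return pid
        raise KeyError(image_id)


# ---------------------------------------------------------------------------
# patch tables
# ---------------------------------------------------------------------------


def read_patch_table(
    path: str | Path, patch_size: int = 100, image_id: str | None = None
) -> ImagePatchSet:
    """Read a detector-output CSV (header ``x,y,prob``) into an ImagePatchSet.

    Upstream detectors emit one such file per image; convert other dialects
    to this canonical one before calling (the header is the contract).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"x", "y", "prob"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    bad = df.index[(df["prob"] < 0) | (df["prob"] > 1) | df["prob"].isna()]
    if len(bad):
        row = int(bad[0])
        raise ValidationError(
            f"{path}: row {row}: prob={df.loc[row, 'prob']!r} outside [0, 1]"
        )
    if df[["x", "y"]].duplicated().any():
        row = int(df.index[df[["x", "y"]].duplicated()][0])
        raise ValidationError(
            f"{path}: row {row}: duplicate patch coordinates "
            f"({df.loc[row, 'x']}, {df.loc[row, 'y']})"
        )
    patches = [
        PatchRecord(int(r.x), int(r.y), float(r.prob))
        for r in df.itertuples(index=False)
    ]
    return ImagePatchSet(
        image_id=image_id if image_id is not None else path.stem,
        patch_size=patch_size,
        patches=patches,
    )


def write_patch_table(patch_set: ImagePatchSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "x": [p.x for p in patch_set.patches],
            "y": [p.y for p in patch_set.patches],
            "prob": [p.prob for p in patch_set.patches],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def _normalize_ring(ring: Sequence[Sequence[float]]) -> list[tuple[float, float]]:
    pts = [(float(x), float(y)) for x, y in ring]
    if len(pts) >= 2 and pts[0] == pts[-1]:
        pts = pts[:-1]
    if len({p for p in pts}) < 3:
        raise ValidationError(f"ring with fewer than 3 distinct vertices: {pts}")
    return pts + [pts[0]]


def _polygon_coords(coords: Sequence) -> tuple[list, list]:
    rings = [_normalize_ring(r) for r in coords]
    return rings[0], rings[1:]


def read_annotation(path: str | Path, image_id: str | None = None) -> TumorAnnotation:
    """Read a GeoJSON tumor annotation (Polygon or MultiPolygon, pixel coords).

    Feature / FeatureCollection wrappers are unwrapped; all polygon parts are
    concatenated.  Ring closure is normalized so the first vertex repeats
    last; the first ring of each polygon is the outer loop and the rest are
    holes, per RFC 7946.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)

    def geometries(node) -> Iterable[dict]:
        t = node.get("type")
        if t == "FeatureCollection":
            for feat in node.get("features", []):
                yield from geometries(feat)
        elif t == "Feature":
            yield from geometries(node["geometry"])
        elif t == "GeometryCollection":
            for g in node.get("geometries", []):
                yield from geometries(g)
        else:
            yield node

    polygons = []
    for geom in geometries(obj):
        t = geom.get("type")
        if t == "Polygon":
            polygons.append(_polygon_coords(geom["coordinates"]))
        elif t == "MultiPolygon":
            for part in geom["coordinates"]:
                polygons.append(_polygon_coords(part))
        else:
            raise FormatError(
                f"{path}: unsupported geometry type {t!r} (need Polygon/MultiPolygon)"
            )
    if not polygons:
        raise FormatError(f"{path}: no polygon geometry found")
    return TumorAnnotation(
        image_id=image_id if image_id is not None else path.stem, polygons=polygons
    )


def write_annotation(annotation: TumorAnnotation, path: str | Path) -> None:
    coords = [
        [[list(pt) for pt in outer]] + [[list(pt) for pt in h] for h in holes]
        for outer, holes in annotation.polygons
    ]
    geom = (
        {"type": "Polygon", "coordinates": coords[0]}
        if len(coords) == 1
        else {"type": "MultiPolygon", "coordinates": coords}
    )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "Feature", "geometry": geom, "properties": {}}, fh)


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

_CLINICAL_OPTIONAL = {
    "depth_mm": float,
    "ulceration": int,
    "t_stage": int,
    "til_grade": int,
    "node_or_satellite_positive": int,
    "stage": int,
}


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read the per-patient clinical CSV.

    Required columns: ``patient_id``, ``dss_event``, ``followup_months``.
    Optional: ``depth_mm``, ``ulceration``, ``t_stage``, ``til_grade``,
    ``node_or_satellite_positive``, ``stage``, ``institution``; blank cells
    mean unknown.  ``t_stage`` accepts either the 1..8 code or the label
    (T1a..T4b).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"patient_id", "dss_event", "followup_months"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")

    records: list[ClinicalRecord] = []
    for i, row in df.iterrows():
        kwargs: dict = {
            "patient_id": str(row["patient_id"]),
            "dss_event": int(row["dss_event"]),
            "followup_months": float(row["followup_months"]),
        }
        for col, caster in _CLINICAL_OPTIONAL.items():
            if col in df.columns and not _is_missing(row[col]):
                v = row[col]
                if col == "t_stage" and isinstance(v, str):
                    if v not in T_STAGE_CODE:
                        raise ValidationError(
                            f"{path}: row {i}: unknown t_stage label {v!r}"
                        )
                    v = T_STAGE_CODE[v]
                kwargs[col] = caster(v)
        if "institution" in df.columns and not _is_missing(row["institution"]):
            kwargs["institution"] = str(row["institution"])
        try:
            records.append(ClinicalRecord(**kwargs))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
    return records


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or v == ""


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "dss_event": r.dss_event,
                "followup_months": r.followup_months,
                "depth_mm": r.depth_mm,
                "ulceration": r.ulceration,
                "t_stage": r.t_stage,
                "til_grade": r.til_grade,
                "node_or_satellite_positive": r.node_or_satellite_positive,
                "stage": r.stage,
                "institution": r.institution,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a single-channel 8-bit PNG mask; nonzero pixels are tumor.

    Returns a (height, width) uint8 array of {0, 1}.
    """
    from PIL import Image

    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return (arr != 0).astype(np.uint8)


def write_mask_png(bitmap: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    arr = (np.asarray(bitmap) != 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)
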