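"""Named 2D facial landmark sets: schema, validation and CSV/JSON I/O.

Coordinate convention: image frame, origin at the top-left corner, ``x``
increasing rightward and ``y`` increasing downward.  Side suffixes ``_L`` /
``_R`` are anatomical (the subject's own left/right), so ``_L`` landmarks
normally sit on the viewer's right in an upright frontal photograph.
"""

from __future__ import annotations

import csv
import io
import json
import math
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Union

import pandas as pd

from .errors import ParseError, SchemaError

__all__ = [
    "CORE_LANDMARKS",
    "Point2D",
    "LandmarkSet",
    "CohortEntry",
    "read_landmarks",
    "write_landmarks",
    "validate_core",
    "read_cohort_table",
    "write_cohort_table",
]

#: Midline landmarks required by the measurement battery.
_CORE_MIDLINE = (
    "trichion",
    "glabella",
    "nasion",
    "pronasale",
    "subnasale",
    "menton",
)

#: Paired landmarks required on both sides (suffixes ``_L`` and ``_R``).
_CORE_PAIRED = (
    "zygion",
    "gonion",
    "alare",
    "endocanthion",
    "exocanthion",
    "pupil",
    "brow_medial",
    "brow_apex",
    "brow_lateral",
    "iris_inferior",
    "lowerlid_margin",
)

CORE_LANDMARKS: tuple[str, ...] = tuple(
    sorted(_CORE_MIDLINE + tuple(f"{n}_{s}" for n in _CORE_PAIRED for s in "LR"))
)


@dataclass(frozen=True)
class Point2D:
    """A 2D point in image pixel coordinates (y increases downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise SchemaError(f"non-finite coordinates ({self.x}, {self.y})")

    def distance(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class LandmarkSet:
    """Named landmark points for one subject.

    Parameters
    ----------
    subject_id
        Free-form subject identifier.
    points
        Mapping of landmark name to :class:`Point2D`.  Arbitrary extra names
        beyond :data:`CORE_LANDMARKS` are permitted and preserved.
    """

    subject_id: str = ""
    points: dict[str, Point2D] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, name: str) -> Point2D:
        try:
            return self.points[name]
        except KeyError:
            raise SchemaError(
                f"subject {self.subject_id!r}: missing landmark {name!r}"
            ) from None

    def add(self, name: str, x: float, y: float) -> None:
        if name in self.points:
            raise SchemaError(f"duplicate landmark name {name!r}")
        self.points[name] = Point2D(float(x), float(y))

    def get(self, name: str) -> Point2D | None:
        return self.points.get(name)

    def names(self) -> list[str]:
        return list(self.points)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        return self.subject_id == other.subject_id and self.points == other.points


def validate_core(ls: LandmarkSet) -> list[str]:
    """Return the lexicographically sorted list of missing core landmarks.

    An empty list means ``ls`` carries everything the measurement battery
    needs.
    """
    return sorted(name for name in CORE_LANDMARKS if name not in ls.points)


# ---------------------------------------------------------------------------
# File I/O.  CSV: one header line ``name,x,y``.  JSON: flat name -> [x, y].
# ---------------------------------------------------------------------------

Source = Union[str, os.PathLike, IO[str]]


def _infer_format(source: Source, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("csv", "json"):
            raise ValueError(f"unsupported landmark format {fmt!r}")
        return fmt
    name = os.fspath(source) if isinstance(source, (str, os.PathLike)) else ""
    return "json" if str(name).lower().endswith(".json") else "csv"


def _subject_id_from(source: Source) -> str:
    if isinstance(source, (str, os.PathLike)):
        return os.path.splitext(os.path.basename(os.fspath(source)))[0]
    return ""


def read_landmarks(
    source: Source, format: str | None = None, subject_id: str | None = None
) -> LandmarkSet:
    """Read a landmark file (CSV ``name,x,y`` or flat JSON map).

    ``format`` defaults to the file extension (``.json`` -> json, else csv).
    ``subject_id`` defaults to the file basename without extension.
    """
    fmt = _infer_format(source, format)
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source.read()
    sid = subject_id if subject_id is not None else _subject_id_from(source)
    ls = LandmarkSet(subject_id=sid)

    if fmt == "json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid landmark JSON: {exc}") from exc
        if not isinstance(data, Mapping):
            raise ParseError("landmark JSON must be an object of name -> [x, y]")
        for name, xy in data.items():
            if (
                not isinstance(xy, (list, tuple))
                or len(xy) != 2
                or not all(isinstance(v, (int, float)) for v in xy)
            ):
                raise ParseError(f"landmark {name!r}: expected [x, y], got {xy!r}")
            ls.add(str(name), float(xy[0]), float(xy[1]))
        return ls

    reader = csv.reader(io.StringIO(text))
    for lineno, row in enumerate(reader, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if lineno == 1 and row[0].strip().lower() == "name":
            continue  # header
        if len(row) != 3:
            raise ParseError(f"line {lineno}: expected 3 fields 'name,x,y', got {row!r}")
        name = row[0].strip()
        try:
            x, y = float(row[1]), float(row[2])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric coordinate in {row!r}") from exc
        try:
            ls.add(name, x, y)
        except SchemaError as exc:
            raise SchemaError(f"line {lineno}: {exc}") from exc
    return ls


def write_landmarks(ls: LandmarkSet, sink: Source, format: str | None = None) -> None:
    """Write a landmark set; output is re-readable by :func:`read_landmarks`."""
    fmt = _infer_format(sink, format)
    if fmt == "json":
        payload = {name: [p.x, p.y] for name, p in ls.points.items()}
        text = json.dumps(payload, indent=1)
    else:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["name", "x", "y"])
        for name, p in ls.points.items():
            writer.writerow([name, repr(p.x), repr(p.y)])
        text = buf.getvalue()
    if isinstance(sink, (str, os.PathLike)):
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        sink.write(text)


# ---------------------------------------------------------------------------
# Cohort table: subject_id,group,landmarks_path,eye_left_path,eye_right_path
# (optional extra columns wtw_px_left / wtw_px_right for image-free runs).
# ---------------------------------------------------------------------------


@dataclass
class CohortEntry:
    subject_id: str
    group: str
    landmarks_path: str
    eye_left_path: str | None = None
    eye_right_path: str | None = None
    wtw_px_left: float | None = None
    wtw_px_right: float | None = None


_COHORT_COLUMNS = (
    "subject_id",
    "group",
    "landmarks_path",
    "eye_left_path",
    "eye_right_path",
)


def read_cohort_table(path: Source, check_paths: bool = True) -> list[CohortEntry]:
    """Read a cohort CSV; verifies id uniqueness and file resolvability."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _COHORT_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        dups = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"])
        raise SchemaError(f"duplicate subject_ids in cohort table: {dups}")
    base = os.path.dirname(os.fspath(path)) if isinstance(path, (str, os.PathLike)) else ""

    def _resolve(p: object) -> str | None:
        if p is None or (isinstance(p, float) and math.isnan(p)) or p == "":
            return None
        p = os.fspath(str(p))
        return p if os.path.isabs(p) else os.path.join(base, p)

    entries: list[CohortEntry] = []
    for _, row in df.iterrows():
        entry = CohortEntry(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            landmarks_path=_resolve(row["landmarks_path"]),
            eye_left_path=_resolve(row.get("eye_left_path")),
            eye_right_path=_resolve(row.get("eye_right_path")),
            wtw_px_left=(
                float(row["wtw_px_left"])
                if "wtw_px_left" in df.columns and pd.notna(row["wtw_px_left"])
                else None
            ),
            wtw_px_right=(
                float(row["wtw_px_right"])
                if "wtw_px_right" in df.columns and pd.notna(row["wtw_px_right"])
                else None
            ),
        )
        if entry.landmarks_path is None:
            raise SchemaError(f"subject {entry.subject_id!r}: landmarks_path is empty")
        if check_paths:
            for p in (entry.landmarks_path, entry.eye_left_path, entry.eye_right_path):
                if p is not None and not os.path.exists(p):
                    raise SchemaError(
                        f"subject {entry.subject_id!r}: file not found: {p}"
                    )
        entries.append(entry)
    return entries


def write_cohort_table(entries: Iterable[CohortEntry], path: Source) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "subject_id": e.subject_id,
                "group": e.group,
                "landmarks_path": e.landmarks_path,
                "eye_left_path": e.eye_left_path or "",
                "eye_right_path": e.eye_right_path or "",
            }
        )
    pd.DataFrame(rows, columns=list(_COHORT_COLUMNS)).to_csv(path, index=False)
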