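"""Domain types and I/O for stem-map analysis.

A stem map is a fully mapped rectangular plot in which every stem above a
minimum diameter (5 cm DBH here) is recorded with plot-local metric
coordinates and size/status marks.  These types are the universal currency
of the package: point-pattern statistics, crown allometry, patch/gap
delineation and the pipeline all consume :class:`StemMap`.

Coordinates are plot-local metres with the origin at the window's
lower-left corner.  Window membership is boundary-inclusive (closed
window).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MIN_DBH_CM",
    "PlotWindow",
    "TreeRecord",
    "StemMap",
    "SizeClassScheme",
    "FireScarSample",
    "FireScarRecordSet",
    "StemMapFormatError",
    "StemMapValidationError",
    "read_stemmap",
    "write_stemmap",
    "partition_by_buffer",
    "read_firescars",
    "write_firescars",
    "read_fhx",
]

#: Minimum stem diameter at breast height included in a stem map (cm).
MIN_DBH_CM = 5.0


class StemMapFormatError(ValueError):
    """Raised when a stem-map file cannot be parsed (missing columns, bad header)."""


class StemMapValidationError(ValueError):
    """Raised when parsed rows violate stem-map invariants; carries offending ids."""

    def __init__(self, message: str, bad_ids: Sequence[str] = ()):
        super().__init__(message)
        self.bad_ids = list(bad_ids)


@dataclass(frozen=True)
class PlotWindow:
    """Rectangular observation window with an inner edge buffer.

    Parameters
    ----------
    x_min, y_min, x_max, y_max : float
        Window extent in metres.
    buffer_width : float
        Width of the inner perimeter buffer (default 5 m) used by the
        mosaic summaries to control crown edge effects.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    buffer_width: float = 5.0

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("window must have positive extent")
        if not (0.0 <= self.buffer_width < min(self.width, self.height) / 2.0):
            raise ValueError(
                "buffer_width must satisfy 0 <= buffer < min(width, height)/2"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x, y) -> np.ndarray:
        """Boundary-inclusive membership test (vectorized)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min) & (x <= self.x_max)
            & (y >= self.y_min) & (y <= self.y_max)
        )

    def interior(self) -> "PlotWindow":
        """The window shrunk by ``buffer_width`` on every side (buffer 0)."""
        b = self.buffer_width
        return PlotWindow(self.x_min + b, self.y_min + b,
                          self.x_max - b, self.y_max - b, buffer_width=0.0)


@dataclass
class TreeRecord:
    """One mapped stem: location, species, size, live/snag status."""

    id: str
    x: float
    y: float
    species: str
    dbh: float
    height: float | None = None
    crown_base_height: float | None = None
    status: str = "live"
    crown_radius: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("live", "snag"):
            raise ValueError(f"tree {self.id}: status must be 'live' or 'snag'")
        if not self.dbh > MIN_DBH_CM:
            raise ValueError(f"tree {self.id}: dbh must exceed {MIN_DBH_CM} cm")
        if self.crown_radius is not None and not self.crown_radius > 0:
            raise ValueError(f"tree {self.id}: crown_radius must be positive")
        if (
            self.height is not None
            and self.crown_base_height is not None
            and not self.crown_base_height < self.height
        ):
            raise ValueError(f"tree {self.id}: crown base must lie below tree top")

    @property
    def basal_area(self) -> float:
        """Stem basal area in m² (DBH in cm)."""
        return np.pi * (self.dbh / 200.0) ** 2

    @property
    def crown_ratio(self) -> float | None:
        """(height − crown base)/height when both measurements are present."""
        if self.height is None or self.crown_base_height is None:
            return None
        return (self.height - self.crown_base_height) / self.height


@dataclass
class StemMap:
    """A plot window plus its ordered tree records."""

    window: PlotWindow
    trees: list[TreeRecord] = field(default_factory=list)
    site_label: str = ""

    def __post_init__(self) -> None:
        ids = [t.id for t in self.trees]
        if len(set(ids)) != len(ids):
            seen, dup = set(), set()
            for i in ids:
                (dup if i in seen else seen).add(i)
            raise StemMapValidationError(
                f"duplicate tree ids: {sorted(dup)}", sorted(dup)
            )
        if self.trees:
            inside = self.window.contains(
                [t.x for t in self.trees], [t.y for t in self.trees]
            )
            if not inside.all():
                bad = [t.id for t, ok in zip(self.trees, inside) if not ok]
                raise StemMapValidationError(
                    f"trees outside window: {bad}", bad
                )

    def __len__(self) -> int:
        return len(self.trees)

    def coords(self) -> np.ndarray:
        """(n, 2) array of stem coordinates in record order."""
        return np.array([[t.x, t.y] for t in self.trees], dtype=float).reshape(-1, 2)

    def subset(self, mask: Iterable[bool], site_label: str | None = None) -> "StemMap":
        trees = [t for t, m in zip(self.trees, mask) if m]
        return StemMap(self.window, trees,
                       self.site_label if site_label is None else site_label)

    def live(self) -> "StemMap":
        return self.subset([t.status == "live" for t in self.trees])

    def snags(self) -> "StemMap":
        return self.subset([t.status == "snag" for t in self.trees])


@dataclass(frozen=True)
class SizeClassScheme:
    """DBH size classes partitioning (5, inf) cm.

    Defaults are small [5, 25), medium [25, 75), large [75, inf) — the
    scheme used throughout the univariate and bivariate analyses.
    """

    boundaries: tuple[float, ...] = (25.0, 75.0)
    labels: tuple[str, ...] = ("small", "medium", "large")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError("need one label per class")
        bnds = list(self.boundaries)
        if bnds != sorted(bnds) or (bnds and bnds[0] <= MIN_DBH_CM):
            raise ValueError("boundaries must ascend and exceed the 5 cm minimum")

    def classify(self, dbh) -> np.ndarray:
        """Class label for each DBH; total and exclusive over dbh > 5."""
        dbh = np.atleast_1d(np.asarray(dbh, dtype=float))
        if not (dbh > MIN_DBH_CM).all():
            raise ValueError("dbh values must exceed 5 cm")
        idx = np.searchsorted(np.asarray(self.boundaries), dbh, side="right")
        return np.asarray(self.labels, dtype=object)[idx]


# ---------------------------------------------------------------------------
# Fire-scar records


@dataclass
class FireScarSample:
    """One fire-scarred specimen: scar years and spans during which it records."""

    id: str
    scar_years: list[int]
    recording_intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.scar_years = sorted(int(y) for y in self.scar_years)
        ivs = sorted((int(a), int(b)) for a, b in self.recording_intervals)
        for (a, b) in ivs:
            if b < a:
                raise ValueError(f"sample {self.id}: interval ({a}, {b}) reversed")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 <= b0:
                raise ValueError(f"sample {self.id}: recording intervals overlap")
        self.recording_intervals = ivs
        for y in self.scar_years:
            if not self.is_recording(y):
                raise ValueError(
                    f"sample {self.id}: scar year {y} outside recording spans"
                )

    def is_recording(self, year: int) -> bool:
        return any(a <= year <= b for a, b in self.recording_intervals)


@dataclass
class FireScarRecordSet:
    """Collection of fire-scar samples feeding composite FRI statistics."""

    samples: list[FireScarSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")

    def __len__(self) -> int:
        return len(self.samples)

    def recording_count(self, year: int) -> int:
        return sum(s.is_recording(year) for s in self.samples)

    def scar_count(self, year: int) -> int:
        return sum(year in s.scar_years for s in self.samples)

    def all_scar_years(self) -> list[int]:
        return sorted({y for s in self.samples for y in s.scar_years})


# ---------------------------------------------------------------------------
# Stem-map I/O
#
# Format: '#'-prefixed key: value header block (site, window, buffer) followed
# by a CSV table.  Floats are written with repr so read(write(m)) == m exactly.

_COLUMNS = ("id", "x", "y", "species", "dbh", "height", "crown_base", "status",
            "crown_radius")


def _fmt(v: float | None) -> str:
    return "" if v is None else repr(float(v))


def write_stemmap(stemmap: StemMap, path: str | Path) -> None:
    """Write a stem map as headered CSV; lossless for all record fields."""
    path = Path(path)
    w = stemmap.window
    with open(path, "w", newline="") as fh:
        fh.write(f"# site: {stemmap.site_label}\n")
        fh.write(
            f"# window: {_fmt(w.x_min)} {_fmt(w.y_min)} {_fmt(w.x_max)} {_fmt(w.y_max)}\n"
        )
        fh.write(f"# buffer: {_fmt(w.buffer_width)}\n")
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for t in stemmap.trees:
            writer.writerow([
                t.id, _fmt(t.x), _fmt(t.y), t.species, _fmt(t.dbh),
                _fmt(t.height), _fmt(t.crown_base_height), t.status,
                _fmt(t.crown_radius),
            ])


def read_stemmap(path: str | Path, dialect: dict[str, str] | None = None) -> StemMap:
    """Read a stem map written by :func:`write_stemmap` (or a mapped CSV).

    ``dialect`` optionally maps this package's column names to the file's
    column names, e.g. ``{"dbh": "DBH_CM"}``.  The plot window must appear
    in the ``# window:`` header line (with optional ``# buffer:`` and
    ``# site:`` lines).
    """
    path = Path(path)
    dialect = dialect or {}
    header: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                m = re.match(r"#\s*([\w]+)\s*:\s*(.*)", line)
                if m:
                    header[m.group(1).lower()] = m.group(2).strip()
            else:
                body_lines.append(line)
    if "window" not in header:
        raise StemMapFormatError(f"{path}: missing '# window:' header line")
    try:
        x0, y0, x1, y1 = (float(v) for v in header["window"].split())
    except Exception as exc:  # noqa: BLE001
        raise StemMapFormatError(f"{path}: malformed window header") from exc
    buffer_width = float(header.get("buffer", 5.0))
    window = PlotWindow(x0, y0, x1, y1, buffer_width=buffer_width)

    reader = csv.DictReader(io.StringIO("".join(body_lines)))
    cols = reader.fieldnames or []
    colmap = {k: dialect.get(k, k) for k in _COLUMNS}
    for mandatory in ("id", "x", "y", "species", "dbh"):
        if colmap[mandatory] not in cols:
            raise StemMapFormatError(
                f"{path}: missing mandatory column '{colmap[mandatory]}'"
            )

    def _get(row: dict, key: str) -> str | None:
        v = row.get(colmap[key], "")
        v = (v or "").strip()
        return v or None

    trees: list[TreeRecord] = []
    errors: list[str] = []
    bad_ids: list[str] = []
    for lineno, row in enumerate(reader, start=2):
        tid = _get(row, "id") or f"<row {lineno}>"
        try:
            x = float(_get(row, "x"))  # type: ignore[arg-type]
            y = float(_get(row, "y"))  # type: ignore[arg-type]
            if not bool(window.contains(x, y)):
                raise ValueError(f"tree {tid}: coordinate outside window")
            h = _get(row, "height")
            cb = _get(row, "crown_base")
            cr = _get(row, "crown_radius")
            trees.append(TreeRecord(
                id=tid, x=x, y=y,
                species=_get(row, "species") or "",
                dbh=float(_get(row, "dbh")),  # type: ignore[arg-type]
                height=None if h is None else float(h),
                crown_base_height=None if cb is None else float(cb),
                status=_get(row, "status") or "live",
                crown_radius=None if cr is None else float(cr),
            ))
        except (TypeError, ValueError) as exc:
            errors.append(f"row {lineno} (id={tid}): {exc}")
            bad_ids.append(tid)
    if errors:
        raise StemMapValidationError(
            "invalid rows:\n  " + "\n  ".join(errors), bad_ids
        )
    return StemMap(window, trees, site_label=header.get("site", ""))


def partition_by_buffer(stemmap: StemMap) -> np.ndarray:
    """Label each tree ``'interior'`` or ``'buffer'``.

    A tree is in the buffer iff its *stem* lies within ``buffer_width`` of
    any window edge (crown extent is irrelevant here).  With buffer 0 all
    trees are interior.  Conserves tree count and is idempotent by
    construction.
    """
    w = stemmap.window
    if len(stemmap) == 0:
        return np.array([], dtype=object)
    xy = stemmap.coords()
    d_edge = np.minimum.reduce([
        xy[:, 0] - w.x_min, w.x_max - xy[:, 0],
        xy[:, 1] - w.y_min, w.y_max - xy[:, 1],
    ])
    return np.where(d_edge < w.buffer_width, "buffer", "interior").astype(object)


# ---------------------------------------------------------------------------
# Fire-scar chronology I/O


def write_firescars(records: FireScarRecordSet, path: str | Path) -> None:
    """Per-sample CSV: id, semicolon-joined scar years, semicolon-joined spans."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "scar_years", "recording_intervals"])
        for s in records.samples:
            writer.writerow([
                s.id,
                ";".join(str(y) for y in s.scar_years),
                ";".join(f"{a}-{b}" for a, b in s.recording_intervals),
            ])


def read_firescars(path: str | Path) -> FireScarRecordSet:
    """Read the per-sample chronology CSV written by :func:`write_firescars`."""
    samples = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            years = [int(v) for v in row["scar_years"].split(";") if v]
            ivs = []
            for span in row["recording_intervals"].split(";"):
                if span:
                    a, b = span.split("-")
                    ivs.append((int(a), int(b)))
            samples.append(FireScarSample(row["id"], years, ivs))
    return FireScarRecordSet(samples)


def read_fhx(path: str | Path) -> FireScarRecordSet:
    """Importer stub for FHX-style fire-history event files.

    Not implemented: dendro archives vary in convention; convert to the
    per-sample CSV format (see :func:`read_firescars`) instead.
    """
    raise NotImplementedError(
        "FHX import is a stub; convert to the per-sample CSV format"
    )
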