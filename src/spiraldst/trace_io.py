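"""Domain types and file I/O for pen traces, sessions, and cohort tables.

A drawing session on the tablet produces a stream of per-point records:
screen position in pixels, a millisecond timestamp, and the calibrated pen
force in newtons.  Traces are stored as plain CSV with header
``t_ms,x_px,y_px,pressure_n``; cohort score tables as CSV with header
``code,group,sex,age_band,sd_score,tt_s,pp_score``; session metadata as a
JSON array.  Coordinates follow the touch-screen convention: origin at the
top-left corner, x rightward, y downward.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateTraceError,
    TraceFormatError,
    TraceValidationError,
)

DEFAULT_SCREEN_W_PX = 1280
DEFAULT_SCREEN_H_PX = 800

TRACE_HEADER = ["t_ms", "x_px", "y_px", "pressure_n"]
COHORT_HEADER = ["code", "group", "sex", "age_band", "sd_score", "tt_s", "pp_score"]

GROUPS = ("PD", "HC")
SEXES = ("F", "M")
AGE_BANDS = ("40-50", "50-60")


@dataclass(frozen=True)
class TraceSample:
    """One recorded pen-down point."""

    t_ms: float
    x_px: float
    y_px: float
    pressure_n: float

    def __post_init__(self) -> None:
        if self.t_ms < 0:
            raise TraceValidationError(f"negative timestamp {self.t_ms} ms")
        if self.pressure_n < 0:
            raise TraceValidationError(f"negative pen pressure {self.pressure_n} N")


@dataclass(frozen=True)
class DrawingTrace:
    """An ordered pen trace plus the recording screen's resolution.

    Timestamps must be nondecreasing and at least two samples are required;
    shorter traces cannot be scored and are rejected outright rather than
    silently repaired.
    """

    samples: tuple[TraceSample, ...]
    screen_w_px: int = DEFAULT_SCREEN_W_PX
    screen_h_px: int = DEFAULT_SCREEN_H_PX

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        if len(self.samples) < 2:
            raise DegenerateTraceError(
                f"trace has {len(self.samples)} sample(s); at least 2 required"
            )
        if self.screen_w_px <= 0 or self.screen_h_px <= 0:
            raise TraceValidationError("screen dimensions must be positive")
        t = np.array([s.t_ms for s in self.samples])
        if np.any(np.diff(t) < 0):
            i = int(np.argmax(np.diff(t) < 0)) + 1
            raise TraceValidationError(
                f"timestamps decrease at sample {i} ({t[i - 1]} -> {t[i]} ms)"
            )
        for s in self.samples:
            if not (0 <= s.x_px < self.screen_w_px and 0 <= s.y_px < self.screen_h_px):
                raise TraceValidationError(
                    f"sample at t={s.t_ms} ms lies off-screen: ({s.x_px}, {s.y_px})"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def t_ms(self) -> np.ndarray:
        return np.array([s.t_ms for s in self.samples], dtype=float)

    @property
    def x_px(self) -> np.ndarray:
        return np.array([s.x_px for s in self.samples], dtype=float)

    @property
    def y_px(self) -> np.ndarray:
        return np.array([s.y_px for s in self.samples], dtype=float)

    @property
    def pressure_n(self) -> np.ndarray:
        return np.array([s.pressure_n for s in self.samples], dtype=float)


@dataclass(frozen=True)
class SessionRecord:
    """Registration metadata for one subject, as entered by the clinician."""

    code: int
    surname: str
    name: str
    birth_year: int
    sex: str
    patient_type: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise TraceValidationError(f"unknown sex token {self.sex!r}")
        if self.patient_type not in GROUPS:
            raise TraceValidationError(f"unknown patient type {self.patient_type!r}")


@dataclass(frozen=True)
class CohortRecord:
    """One subject's grouping factors plus the three test scores.

    ``sd_score`` is the Spiral Deviation (area between the drawn and the
    reference spiral over screen area, x 10,000 — "% pixels"); ``tt_s`` the
    Total Time in seconds; ``pp_score`` the Pen Pressure score in
    newton-pixels.
    """

    code: int
    group: str
    sex: str
    age_band: str
    sd_score: float
    tt_s: float
    pp_score: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise TraceValidationError(f"unknown group token {self.group!r}")
        if self.sex not in SEXES:
            raise TraceValidationError(f"unknown sex token {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise TraceValidationError(f"unknown age band token {self.age_band!r}")
        if self.sd_score < 0 or self.pp_score < 0:
            raise TraceValidationError("scores must be nonnegative")
        if self.tt_s <= 0:
            raise TraceValidationError("total time must be positive")


def read_trace(
    path: str | Path,
    screen_w_px: int = DEFAULT_SCREEN_W_PX,
    screen_h_px: int = DEFAULT_SCREEN_H_PX,
) -> DrawingTrace:
    """Read a trace CSV, validating the header and every row.

    Raises :class:`TraceFormatError` naming the offending line on malformed
    input, :class:`DegenerateTraceError` for traces with fewer than two
    samples, and :class:`TraceValidationError` for invariant violations
    (decreasing timestamps, negative pressure, off-screen points).
    """
    path = Path(path)
    samples: list[TraceSample] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TraceFormatError(f"{path}: empty file") from None
        if [h.strip() for h in header] != TRACE_HEADER:
            raise TraceFormatError(
                f"{path}: line 1: expected header {','.join(TRACE_HEADER)!r}, "
                f"got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise TraceFormatError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(row)}"
                )
            try:
                values = [float(v) for v in row]
            except ValueError as exc:
                raise TraceFormatError(f"{path}: line {lineno}: {exc}") from None
            try:
                samples.append(TraceSample(*values))
            except TraceValidationError as exc:
                raise TraceValidationError(f"{path}: line {lineno}: {exc}") from None
    return DrawingTrace(tuple(samples), screen_w_px, screen_h_px)


def write_trace(trace: DrawingTrace, path: str | Path) -> Path:
    """Write a trace as CSV (header + one row per sample); returns the path."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRACE_HEADER)
        for s in trace.samples:
            writer.writerow(
                [repr(s.t_ms), repr(s.x_px), repr(s.y_px), repr(s.pressure_n)]
            )
    return path


def read_cohort(path: str | Path) -> list[CohortRecord]:
    """Read a cohort score table (CSV); validates categorical tokens."""
    path = Path(path)
    records: list[CohortRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != COHORT_HEADER:
            raise TraceFormatError(
                f"{path}: expected header {','.join(COHORT_HEADER)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    CohortRecord(
                        code=int(row["code"]),
                        group=row["group"].strip(),
                        sex=row["sex"].strip(),
                        age_band=row["age_band"].strip(),
                        sd_score=float(row["sd_score"]),
                        tt_s=float(row["tt_s"]),
                        pp_score=float(row["pp_score"]),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise TraceFormatError(f"{path}: line {lineno}: {exc}") from None
            except TraceValidationError as exc:
                raise TraceValidationError(f"{path}: line {lineno}: {exc}") from None
    return records


def write_cohort(records: Iterable[CohortRecord], path: str | Path) -> Path:
    """Write cohort records as CSV; returns the path."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_HEADER)
        for r in records:
            writer.writerow(
                [r.code, r.group, r.sex, r.age_band,
                 repr(r.sd_score), repr(r.tt_s), repr(r.pp_score)]
            )
    return path


def read_sessions(path: str | Path) -> list[SessionRecord]:
    """Read the session store (JSON array of session objects)."""
    with Path(path).open(encoding="utf-8") as fh:
        raw = json.load(fh)
    records = [SessionRecord(**obj) for obj in raw]
    codes = [r.code for r in records]
    if len(set(codes)) != len(codes):
        raise TraceValidationError("duplicate session codes in store")
    return records


def write_sessions(records: Sequence[SessionRecord], path: str | Path) -> Path:
    codes = [r.code for r in records]
    if len(set(codes)) != len(codes):
        raise TraceValidationError("duplicate session codes in store")
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump([vars(r) for r in records], fh, indent=2)
        fh.write("\n")
    return Path(path)
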