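"""The three clinical measurements of the dynamic spiral test.

* **Spiral Deviation (SD)** — the area enclosed between the drawn curve and
  the reference spiral, as a fraction of the screen area, multiplied by
  10,000 ("% pixels").  Each drawn point is matched to the reference point at
  the same unwrapped polar angle about the spiral center; the area between
  the two curves is the polar integral (1/2) |r_drawn^2 - r_ref^2| d(theta),
  evaluated with the trapezoid rule over the per-sample angles.
* **Total Time (TT)** — elapsed time from the first to the last recorded
  sample, in seconds.
* **Pen Pressure (PP)** — the sum over samples of the pen's pixel footprint
  times the force in excess of typical handwriting force (1.4-1.5 N), in
  newton-pixels.  Typical handwriting therefore scores ~0; pressing harder
  both enlarges the footprint and adds excess force, so the score grows
  quickly with sustained high force.

Angle assignment unwraps the polar angle cumulatively (no reset at 360
degrees), pins the first sample to the spiral's start angle (90 degrees),
clamps backtracking to the running maximum so the two-turn correspondence
stays single-valued, and clamps angles beyond the sweep end so doodling
after completion cannot inflate the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (
    ConfigError,
    InsufficientCoverageError,
    UndefinedAngleError,
)
from .spiral import ReferenceSpiral
from .trace_io import DrawingTrace

#: Minimum angular coverage (degrees) for a trace to be scoreable.
MIN_COVERAGE_DEG = 10.0

#: Typical handwriting force band, newtons.
TYPICAL_FORCE_BAND_N = (1.4, 1.5)


@dataclass(frozen=True)
class PressureModel:
    """Pen footprint and typical-force parameters for the PP score.

    ``f_typ_n`` is the typical handwriting force (default 1.45 N, the
    midpoint of the 1.4-1.5 N band).  The pen's pixel footprint ("stamp")
    grows linearly with excess force: ``1 + round(gain * max(0, p - f_typ))``
    pixels, a minimal model of the thicker rendered line under pressure.
    """

    f_typ_n: float = 1.45
    stamp_base_px: float = 1.0
    stamp_gain_px_per_n: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = TYPICAL_FORCE_BAND_N
        if not lo <= self.f_typ_n <= hi:
            raise ConfigError(
                f"typical force {self.f_typ_n} N outside the band {lo}-{hi} N"
            )
        if self.stamp_base_px < 1:
            raise ConfigError("stamp area must be at least 1 pixel")
        if self.stamp_gain_px_per_n < 0:
            raise ConfigError("stamp gain must be nonnegative")

    def excess_n(self, pressure_n):
        return np.maximum(0.0, np.asarray(pressure_n, dtype=float) - self.f_typ_n)

    def stamp_area_px(self, pressure_n):
        """Pixel footprint at a given force; nondecreasing in pressure."""
        area = self.stamp_base_px + np.rint(
            self.stamp_gain_px_per_n * self.excess_n(pressure_n)
        )
        if np.isscalar(pressure_n):
            return float(area)
        return area


@dataclass(frozen=True)
class AngleProfile:
    """Per-sample spiral correspondence: unwrapped angle, drawn and reference radius."""

    angle_deg: np.ndarray
    r_drawn_px: np.ndarray
    r_ref_px: np.ndarray

    def __len__(self) -> int:
        return len(self.angle_deg)

    def write_csv(self, path: str | Path) -> Path:
        """Diagnostic export as ``angle_deg,r_drawn_px,r_ref_px`` CSV."""
        path = Path(path)
        rows = np.column_stack([self.angle_deg, self.r_drawn_px, self.r_ref_px])
        with path.open("w", encoding="utf-8") as fh:
            fh.write("angle_deg,r_drawn_px,r_ref_px\n")
            for a, rd, rr in rows:
                fh.write(f"{a!r},{rd!r},{rr!r}\n")
        return path


@dataclass(frozen=True)
class ScoreTriple:
    """The three measurements for one trace: SD ("% pixels"), TT (s), PP (N*pixels)."""

    sd_score: float
    tt_s: float
    pp_score: float


def assign_spiral_angles(trace: DrawingTrace, spiral: ReferenceSpiral) -> AngleProfile:
    """Match each trace sample to a reference-spiral point by unwrapped angle.

    The per-sample angle accumulates wrapped atan2 increments about the
    spiral center, offset so the first sample's angle is exactly the spiral's
    start angle.  Negative increments (backtracking) are clamped to the
    running maximum, and angles past the sweep end are clamped to it, so the
    angle profile is nondecreasing and stays inside the sweep.

    Raises :class:`UndefinedAngleError` if a sample coincides with the
    center, and :class:`InsufficientCoverageError` if the trace covers less
    than ``MIN_COVERAGE_DEG`` of the sweep.
    """
    dx = trace.x_px - spiral.center_x_px
    dy = spiral.center_y_px - trace.y_px  # y-up frame
    r_drawn = np.hypot(dx, dy)
    if np.any(r_drawn < 1e-9):
        i = int(np.argmax(r_drawn < 1e-9))
        raise UndefinedAngleError(
            f"sample {i} coincides with the spiral center; polar angle undefined"
        )
    raw_deg = np.rad2deg(np.arctan2(dy, dx))
    # wrapped increments in (-180, 180]
    steps = np.diff(raw_deg)
    steps = (steps + 180.0) % 360.0 - 180.0
    unwrapped = spiral.start_angle_deg + np.concatenate([[0.0], np.cumsum(steps)])
    monotone = np.maximum.accumulate(unwrapped)
    clamped = np.minimum(monotone, spiral.end_angle_deg)
    coverage = clamped[-1] - spiral.start_angle_deg
    if coverage < MIN_COVERAGE_DEG:
        raise InsufficientCoverageError(
            f"trace covers only {coverage:.2f} degrees of the "
            f"{spiral.sweep_deg:.0f}-degree sweep (minimum {MIN_COVERAGE_DEG})"
        )
    r_ref = spiral.radius_at_angle(clamped)
    return AngleProfile(angle_deg=clamped, r_drawn_px=r_drawn, r_ref_px=r_ref)


def _area_between_px2(profile: AngleProfile) -> float:
    theta = np.deg2rad(profile.angle_deg)
    integrand = 0.5 * np.abs(profile.r_drawn_px**2 - profile.r_ref_px**2)
    return float(np.trapezoid(integrand, theta))


def spiral_deviation(trace: DrawingTrace, spiral: ReferenceSpiral) -> float:
    """Spiral Deviation: area between drawn and reference curves over screen area, x 10,000.

    The area is the polar integral (1/2) |r_drawn^2 - r_ref^2| d(theta) over
    the per-sample unwrapped angles (trapezoid rule); duplicate angles from
    clamped backtracking contribute zero width.
    """
    profile = assign_spiral_angles(trace, spiral)
    screen_area = trace.screen_w_px * trace.screen_h_px
    return _area_between_px2(profile) / screen_area * 10_000.0


def total_time(trace: DrawingTrace) -> float:
    """Total Time: last minus first timestamp, in seconds."""
    t = trace.t_ms
    return float(t[-1] - t[0]) / 1000.0


def pen_pressure_score(
    trace: DrawingTrace, pressure_model: PressureModel | None = None
) -> float:
    """Pen Pressure: sum of pixel footprint times excess force, newton-pixels."""
    model = pressure_model if pressure_model is not None else PressureModel()
    p = trace.pressure_n
    excess = model.excess_n(p)
    area = model.stamp_base_px + np.rint(model.stamp_gain_px_per_n * excess)
    return float(np.sum(area * excess))


def score_trace(
    trace: DrawingTrace,
    spiral: ReferenceSpiral,
    pressure_model: PressureModel | None = None,
) -> ScoreTriple:
    """Compute the full (SD, TT, PP) triple for one trace. Deterministic."""
    return ScoreTriple(
        sd_score=spiral_deviation(trace, spiral),
        tt_s=total_time(trace),
        pp_score=pen_pressure_score(trace, pressure_model),
    )
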