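"""Geometry of the on-screen reference Archimedean spiral.

The drawing template is a two-turn Archimedean spiral drawn inward-out: the
polar angle of the first point is 90 degrees (screen-up) and increases by 720
degrees over two full counterclockwise turns.  The radius is affine in the
angle, r(theta) = inner + (outer - inner) * (theta - start) / sweep, which
gives the evenly spaced turns of the classical Archimedean curve r = a +
b*theta.

Angles are in degrees and measured counterclockwise in a y-up frame; because
screen y points down, point coordinates negate the sine term, so 90 degrees
maps to the top of the screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AngleDomainError, SpiralConfigError

DEFAULT_START_ANGLE_DEG = 90.0
DEFAULT_SWEEP_DEG = 720.0
DEFAULT_MARGIN_PX = 50.0
DEFAULT_INNER_RADIUS_PX = 20.0


@dataclass(frozen=True)
class ReferenceSpiral:
    """The target spiral shown on screen, in pixel coordinates."""

    center_x_px: float
    center_y_px: float
    inner_radius_px: float
    outer_radius_px: float
    start_angle_deg: float = DEFAULT_START_ANGLE_DEG
    sweep_deg: float = DEFAULT_SWEEP_DEG

    def __post_init__(self) -> None:
        if self.sweep_deg <= 0:
            raise SpiralConfigError(f"sweep must be positive, got {self.sweep_deg}")
        if not 0 <= self.inner_radius_px < self.outer_radius_px:
            raise SpiralConfigError(
                "need 0 <= inner radius < outer radius, got "
                f"inner {self.inner_radius_px}, outer {self.outer_radius_px}"
            )

    @property
    def end_angle_deg(self) -> float:
        return self.start_angle_deg + self.sweep_deg

    def radius_at_angle(self, angle_deg):
        return radius_at_angle(self, angle_deg)

    def point_at_angle(self, angle_deg):
        return point_at_angle(self, angle_deg)


def make_reference_spiral(
    screen_w_px: float = 1280,
    screen_h_px: float = 800,
    margin_px: float = DEFAULT_MARGIN_PX,
    inner_radius_px: float = DEFAULT_INNER_RADIUS_PX,
    start_angle_deg: float = DEFAULT_START_ANGLE_DEG,
    sweep_deg: float = DEFAULT_SWEEP_DEG,
) -> ReferenceSpiral:
    """Center a reference spiral on a screen, filling it up to ``margin_px``.

    The outer radius is ``min(screen_w, screen_h)/2 - margin``; raises
    :class:`SpiralConfigError` when that leaves no room outside the inner
    radius.
    """
    if margin_px < 0:
        raise SpiralConfigError("margin must be nonnegative")
    outer = min(screen_w_px, screen_h_px) / 2.0 - margin_px
    if outer <= inner_radius_px:
        raise SpiralConfigError(
            f"outer radius {outer} px <= inner radius {inner_radius_px} px; "
            "reduce the margin or the inner radius"
        )
    return ReferenceSpiral(
        center_x_px=screen_w_px / 2.0,
        center_y_px=screen_h_px / 2.0,
        inner_radius_px=inner_radius_px,
        outer_radius_px=outer,
        start_angle_deg=start_angle_deg,
        sweep_deg=sweep_deg,
    )


def _check_domain(spiral: ReferenceSpiral, angle_deg: np.ndarray) -> None:
    lo, hi = spiral.start_angle_deg, spiral.end_angle_deg
    if np.any(angle_deg < lo - 1e-9) or np.any(angle_deg > hi + 1e-9):
        raise AngleDomainError(
            f"angle outside the spiral sweep [{lo}, {hi}] degrees"
        )


def radius_at_angle(spiral: ReferenceSpiral, angle_deg):
    """Radius of the reference spiral at an unwrapped angle (degrees).

    Affine in angle; accepts scalars or arrays. Angles outside the sweep
    raise :class:`AngleDomainError`.
    """
    a = np.asarray(angle_deg, dtype=float)
    _check_domain(spiral, a)
    frac = (a - spiral.start_angle_deg) / spiral.sweep_deg
    r = spiral.inner_radius_px + (spiral.outer_radius_px - spiral.inner_radius_px) * frac
    return float(r) if np.isscalar(angle_deg) else r


def point_at_angle(spiral: ReferenceSpiral, angle_deg):
    """Screen coordinates of the spiral point at an unwrapped angle.

    x = cx + r cos(theta), y = cy - r sin(theta): the sine is negated because
    screen y grows downward while angles are counterclockwise in a y-up frame.
    """
    r = radius_at_angle(spiral, angle_deg)
    theta = np.deg2rad(np.asarray(angle_deg, dtype=float))
    x = spiral.center_x_px + r * np.cos(theta)
    y = spiral.center_y_px - r * np.sin(theta)
    if np.isscalar(angle_deg):
        return float(x), float(y)
    return x, y


def sample_spiral(spiral: ReferenceSpiral, n_points: int) -> np.ndarray:
    """Sample the spiral at ``n_points`` equally spaced angles.

    Returns an array of shape (n_points, 3) with columns
    ``angle_deg, x_px, y_px``; both endpoints are included.
    """
    if n_points < 2:
        raise SpiralConfigError(f"need at least 2 points, got {n_points}")
    angles = np.linspace(spiral.start_angle_deg, spiral.end_angle_deg, n_points)
    x, y = point_at_angle(spiral, angles)
    return np.column_stack([angles, x, y])
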