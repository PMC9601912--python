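import numpy as np
import pytest

from spiraldst import DrawingTrace, TraceSample, make_reference_spiral


@pytest.fixture
def spiral():
    """Default on-screen template: 1280x800 screen, margin 50, inner radius 20."""
    return make_reference_spiral()


def polar_trace(
    spiral,
    angle_deg,
    radius_px,
    t_ms=None,
    pressure_n=0.0,
    screen=(1280, 800),
):
    """Build a trace from polar coordinates about the spiral center.

    Angles are unwrapped degrees in the y-up frame (90 = screen top);
    timestamps default to 10 ms per sample.
    """
    angle_deg = np.asarray(angle_deg, dtype=float)
    radius_px = np.broadcast_to(np.asarray(radius_px, dtype=float), angle_deg.shape)
    theta = np.deg2rad(angle_deg)
    x = spiral.center_x_px + radius_px * np.cos(theta)
    y = spiral.center_y_px - radius_px * np.sin(theta)
    n = len(angle_deg)
    if t_ms is None:
        t_ms = 10.0 * np.arange(n)
    p = np.broadcast_to(np.asarray(pressure_n, dtype=float), (n,))
    samples = tuple(
        TraceSample(float(t_ms[i]), float(x[i]), float(y[i]), float(p[i]))
        for i in range(n)
    )
    return DrawingTrace(samples, *screen)


def template_trace(spiral, n=500, duration_s=12.73, pressure_n=0.5, screen=(1280, 800)):
    """A perfect replay of the reference template at constant angular speed."""
    angles = np.linspace(spiral.start_angle_deg, spiral.end_angle_deg, n)
    radii = spiral.radius_at_angle(angles)
    t_ms = np.linspace(0.0, duration_s * 1000.0, n)
    return polar_trace(spiral, angles, radii, t_ms=t_ms, pressure_n=pressure_n, screen=screen)
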