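"""Score a drawing trace against the reference spiral.

Builds two traces in memory — a perfect replay of the on-screen template and
a copy displaced 10 px radially outward — and scores both.  The Spiral
Deviation is the area between drawn and reference curve over the screen
area, x 10,000; the displaced trace's value matches the closed-form polar
area of a constant offset (about 233.2 on a 1280x800 screen).
"""

import numpy as np

from spiraldst import DrawingTrace, TraceSample, make_reference_spiral, score_trace


def trace_from_radii(spiral, radii, duration_s=12.73, pressure_n=1.0):
    angles = np.linspace(spiral.start_angle_deg, spiral.end_angle_deg, len(radii))
    theta = np.deg2rad(angles)
    x = spiral.center_x_px + radii * np.cos(theta)
    y = spiral.center_y_px - radii * np.sin(theta)
    t_ms = np.linspace(0, duration_s * 1000, len(radii))
    return DrawingTrace(
        tuple(TraceSample(float(t), float(xi), float(yi), pressure_n)
              for t, xi, yi in zip(t_ms, x, y))
    )


spiral = make_reference_spiral()  # 1280x800 screen, two turns from 90 deg
angles = np.linspace(spiral.start_angle_deg, spiral.end_angle_deg, 1000)
r_ref = spiral.radius_at_angle(angles)

for name, radii in [("template replay", r_ref), ("+10 px radial offset", r_ref + 10)]:
    triple = score_trace(trace_from_radii(spiral, radii), spiral)
    print(f"{name}:")
    print(f"  SD (% pixels): {triple.sd_score:.4f}   "
          "(0 means the drawing lies exactly on the template)")
    print(f"  TT (s):        {triple.tt_s:.4f}   (first-to-last timestamp)")
    print(f"  PP (N*pixels): {triple.pp_score:.4f}   "
          "(0 means force never exceeded the 1.45 N typical band)")
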