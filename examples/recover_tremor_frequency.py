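"""Recover an injected tremor frequency from a simulated patient trace.

Simulates a slow (20 s) spiral drawing with a 5.4 Hz, 3 px sinusoidal
radial tremor on top of smooth wobble, then estimates the tremor frequency
as the dominant periodogram peak of the radial residual (drawn minus
reference radius) in the 3-10 Hz band.  Recovery within 0.25 Hz is the
simulator's parameter-recovery guarantee at amplitudes of 2 px and above.
"""

from spiraldst import (
    ProfileParams,
    estimate_tremor_frequency,
    make_reference_spiral,
    simulate_trace,
)

spiral = make_reference_spiral()
params = ProfileParams(
    angular_speed_deg_s=36.0,      # 720 deg / 36 deg/s = 20 s total time
    tremor_amp_px=3.0,
    tremor_freq_hz=5.4,
    radial_noise_sd_px=1.65,
    pressure_base_n=1.45,
    pressure_excess_n=0.4,
    pressure_noise_sd_n=0.15,
    sample_rate_hz=120.0,
    seed=2024,
)
trace = simulate_trace(spiral, params)
f_hat = estimate_tremor_frequency(trace, spiral)
print(f"injected tremor frequency: {params.tremor_freq_hz:.2f} Hz")
print(f"recovered from periodogram: {f_hat:.2f} Hz")
print(f"absolute error: {abs(f_hat - params.tremor_freq_hz):.3f} Hz "
      "(recovery criterion: <= 0.25 Hz)")
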